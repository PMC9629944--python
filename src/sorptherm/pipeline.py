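"""End-to-end orchestration: fit -> select -> thermodynamics -> surface.

`run_pipeline` runs the full analysis on a sorption CSV (or the packaged
cherry dataset) and writes a bundle of CSV tables plus a JSON summary.
Outputs are deterministic: identical input and configuration produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .fitting import (
    IsothermFit,
    fit_dataset,
    fits_to_frame,
    select_best,
    select_overall,
)
from .models import AW_MAX, ModelId, monolayer_moisture
from .records import IsothermSeries, Mode, load_sorption_csv
from .surface import optimal_storage, spreading_pressure_curve, surface_area
from .thermo import compensation, isosteric_analysis, smooth_polynomial

__all__ = ["PipelineConfig", "run_pipeline", "load_input"]

logger = logging.getLogger(__name__)

FIXTURE_PREFIX = "fixture:"
_FLOAT_FMT = "%.4f"


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run."""

    input_path: str = "fixture:cherry"
    outdir: str | Path = "results"
    models: tuple[ModelId, ...] = tuple(ModelId)
    grid_min: float = 10.0
    grid_max: float = 30.0
    grid_step: float = 1.0
    poly_degree: int = 3
    aw_max: float = AW_MAX

    def __post_init__(self) -> None:
        if not (self.grid_min < self.grid_max and self.grid_step > 0):
            raise ValueError("grid bounds must satisfy min < max and step > 0")

    @property
    def xeq_grid(self) -> np.ndarray:
        return np.arange(self.grid_min, self.grid_max + 1e-9, self.grid_step)


def load_input(input_path: str) -> list[IsothermSeries]:
    """Resolve an input spec: a CSV path or ``fixture:cherry``."""
    if input_path.startswith(FIXTURE_PREFIX):
        name = input_path[len(FIXTURE_PREFIX):]
        if name != "cherry":
            raise ValueError(f"unknown fixture {name!r}")
        return datasets.load_cherry_dataset()
    path = Path(input_path)
    if not path.exists():
        raise FileNotFoundError(path)
    return load_sorption_csv(path)


def _gab_fits_by_group(
    fits: list[IsothermFit],
) -> dict[tuple[str, str], dict[float, IsothermFit]]:
    groups: dict[tuple[str, str], dict[float, IsothermFit]] = {}
    for f in fits:
        if f.model_id is ModelId.GAB and f.converged:
            groups.setdefault((f.sample_id, f.mode), {})[f.temperature_c] = f
    return groups


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Writes ``fits.csv``, ``thermo.csv``, ``compensation.csv``,
    ``surface.csv``, ``spreading_pressure.csv``, ``storage.csv`` and
    ``summary.json`` under ``config.outdir``; returns the summary dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series = load_input(config.input_path)
    logger.info("loaded %d series from %s", len(series), config.input_path)

    # --- model fits and selection -------------------------------------
    fits = fit_dataset(series, config.models)
    fit_frame = fits_to_frame(fits)
    fit_frame.to_csv(outdir / "fits.csv", index=False, float_format=_FLOAT_FMT)
    by_series: dict[tuple, list[IsothermFit]] = {}
    for f in fits:
        by_series.setdefault(f.key, []).append(f)
    winners = {k: select_best(v).winner.value for k, v in sorted(by_series.items())}
    overall = select_overall(fits).value if len(by_series) > 1 else next(
        iter(winners.values())
    )

    # --- isosteric heat / entropy / compensation ----------------------
    thermo_frames, comp_rows, smooth_rows = [], [], []
    for (sid, mode), gab_fits in sorted(_gab_fits_by_group(fits).items()):
        if len(gab_fits) < 2:
            logger.warning("(%s, %s): < 2 GAB fits; thermodynamics skipped", sid, mode)
            continue
        table = isosteric_analysis(gab_fits, config.xeq_grid, config.aw_max)
        thermo_frames.append(table.to_frame())
        try:
            comp = compensation(table)
        except ValueError as exc:
            logger.warning("(%s, %s): compensation failed: %s", sid, mode, exc)
            continue
        comp_rows.append(
            {
                "sample_id": sid,
                "mode": mode,
                "t_beta_k": comp.t_beta_k,
                "dg_beta_j_mol": comp.dg_beta_j_mol,
                "r": comp.r,
                "t_hm_k": comp.t_hm_k,
                "n_points": comp.n_points,
                "spontaneous": comp.spontaneous,
                "compensation_valid": comp.compensation_valid,
            }
        )
        for quantity, values in (
            ("qst_kj_mol", table.qst_kj_mol),
            ("ds_j_mol_k", table.ds_j_mol_k),
        ):
            coeffs, r = smooth_polynomial(
                table.xeq_grid, values, config.poly_degree
            )
            smooth_rows.append(
                {
                    "sample_id": sid,
                    "mode": mode,
                    "quantity": quantity,
                    "degree": config.poly_degree,
                    **{f"c{len(coeffs) - 1 - i}": c for i, c in enumerate(coeffs)},
                    "r": r,
                }
            )
    thermo_frame = (
        pd.concat(thermo_frames, ignore_index=True) if thermo_frames else pd.DataFrame()
    )
    thermo_frame.to_csv(outdir / "thermo.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(comp_rows).to_csv(
        outdir / "compensation.csv", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(smooth_rows).to_csv(
        outdir / "smooths.csv", index=False, float_format=_FLOAT_FMT
    )

    # --- surface properties -------------------------------------------
    surf_rows, curve_rows = [], []
    for f in sorted(fits, key=lambda f: (f.sample_id, f.mode, f.temperature_c)):
        if f.model_id is not ModelId.GAB or not f.converged:
            continue
        s0 = surface_area(monolayer_moisture(f.params))
        surf_rows.append(
            {
                "sample_id": f.sample_id,
                "mode": f.mode,
                "temperature_c": f.temperature_c,
                "monolayer_percent_db": f.params[0],
                "surface_area_m2_g": s0,
            }
        )
        for a, pi in spreading_pressure_curve(f.temperature_c, f.params):
            curve_rows.append(
                {
                    "sample_id": f.sample_id,
                    "mode": f.mode,
                    "temperature_c": f.temperature_c,
                    "aw": a,
                    "pi_j_m2": pi,
                }
            )
    pd.DataFrame(surf_rows).to_csv(
        outdir / "surface.csv", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(curve_rows).to_csv(
        outdir / "spreading_pressure.csv", index=False, float_format="%.6g"
    )

    # --- optimal storage (desorption, highest temperature) -------------
    storage_rows = []
    des = [s for s in series if s.mode is Mode.DESORPTION]
    by_sample: dict[str, list[IsothermSeries]] = {}
    for s in des:
        by_sample.setdefault(s.sample_id, []).append(s)
    for sid, group in sorted(by_sample.items()):
        top = max(group, key=lambda s: s.temperature_c)
        try:
            opt = optimal_storage(top)
        except (ValueError, ArithmeticError) as exc:
            logger.warning("%s: storage analysis failed: %s", sid, exc)
            continue
        storage_rows.append(
            {
                "sample_id": sid,
                "temperature_c": top.temperature_c,
                "aw_optimal": opt.aw_optimal,
                "xeq_optimal": opt.xeq_optimal,
                "method_inferred": opt.method_inferred,
            }
        )
    pd.DataFrame(storage_rows).to_csv(
        outdir / "storage.csv", index=False, float_format=_FLOAT_FMT
    )

    summary = {
        "input": config.input_path,
        "n_series": len(series),
        "n_fits": len(fits),
        "selected_model_overall": overall,
        "selected_model_by_series": {
            f"{k[0]}|{k[1]}|{k[2]:g}": v for k, v in winners.items()
        },
        "compensation": comp_rows,
        "surface_area": surf_rows,
        "storage": storage_rows,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
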