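"""Synthetic sorption datasets with known ground truth.

The generator emulates the static gravimetric design: a small set of
salt-fixed water activities per temperature, three temperatures, and an
equilibrium moisture content that follows a chosen isotherm model whose
amplitude decreases with temperature (foods are less hygroscopic when
warm).  Observation noise is multiplicative Gaussian -- sorption balances
err proportionally to the measured mass -- truncated at +-3 sigma and
floored at 0.1 % d.b. so small moistures stay positive.

Because the truth is known, every downstream stage (fitting, isosteric
analysis, compensation, surface area) can be validated exactly at sigma=0
and statistically at realistic noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fitting import IsothermFit, fit_model, goodness
from .models import ModelId, evaluate, monolayer_moisture
from .records import IsothermSeries, Mode, SorptionRecord
from .surface import surface_area
from .thermo import compensation, isosteric_analysis

__all__ = ["GeneratorConfig", "generate", "make_series", "recovery_report"]

# The six salt-fixed design water activities at each temperature (degC).
_DESIGN_AW = {
    30.0: (0.0738, 0.3238, 0.4317, 0.7275, 0.8362, 0.898),
    40.0: (0.0626, 0.3159, 0.423, 0.71, 0.8232, 0.891),
    50.0: (0.0572, 0.3054, 0.4091, 0.6904, 0.812, 0.8823),
}


def _default_params() -> dict[float, tuple[float, ...]]:
    # Monolayer amplitude decreasing with temperature; typical type-II
    # multilayer factor and Guggenheim constant for sugar-rich fruit.
    return {30.0: (12.0, 0.85, 8.0), 40.0: (9.0, 0.85, 8.0), 50.0: (7.0, 0.85, 8.0)}


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic sorption-data generator."""

    model_id: ModelId = ModelId.GAB
    params_by_temperature: Mapping[float, tuple[float, ...]] = field(
        default_factory=_default_params
    )
    aw_by_temperature: Mapping[float, tuple[float, ...]] | None = None
    sigma: float = 0.02            # multiplicative noise std
    n_replicates: int = 1
    seed: int = 0
    sample_id: str = "synthetic"
    mode: Mode = Mode.DESORPTION
    xeq_floor: float = 0.1         # % d.b.

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_id", ModelId(self.model_id))
        object.__setattr__(self, "mode", Mode(self.mode))
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        for t, p in self.params_by_temperature.items():
            evaluate(self.model_id, p, 0.5)  # raises on out-of-domain params

    @property
    def temperatures(self) -> tuple[float, ...]:
        return tuple(sorted(self.params_by_temperature))

    def design_aw(self, temperature: float) -> tuple[float, ...]:
        if self.aw_by_temperature is not None:
            return tuple(self.aw_by_temperature[temperature])
        return _DESIGN_AW[float(temperature)]


def _noisy(xeq: np.ndarray, sigma: float, floor: float, rng: np.random.Generator):
    if sigma == 0:
        return np.maximum(xeq, floor)
    eps = rng.normal(0.0, sigma, size=xeq.shape)
    np.clip(eps, -3.0 * sigma, 3.0 * sigma, out=eps)
    return np.maximum(xeq * (1.0 + eps), floor)


def make_series(
    config: GeneratorConfig, rng: np.random.Generator, replicate: int = 0
) -> list[IsothermSeries]:
    """One replicate: one noisy isotherm series per temperature."""
    sid = config.sample_id if config.n_replicates == 1 else (
        f"{config.sample_id}_{replicate}"
    )
    out = []
    for t in config.temperatures:
        aw = np.asarray(config.design_aw(t))
        truth = np.asarray(evaluate(config.model_id, config.params_by_temperature[t], aw))
        xeq = _noisy(truth, config.sigma, config.xeq_floor, rng)
        recs = tuple(
            SorptionRecord(sid, config.mode, t, float(a), float(x))
            for a, x in zip(aw, xeq)
        )
        out.append(IsothermSeries(sid, config.mode, t, recs))
    return out


def generate(
    config: GeneratorConfig,
) -> tuple[list[IsothermSeries], dict]:
    """Generate all replicates plus a serializable ground-truth record.

    Identical config (including seed) yields identical data.
    """
    rng = np.random.default_rng(config.seed)
    series: list[IsothermSeries] = []
    for rep in range(config.n_replicates):
        series.extend(make_series(config, rng, rep))
    truth = {
        "model_id": config.model_id.value,
        "params_by_temperature": {
            str(t): list(p) for t, p in sorted(config.params_by_temperature.items())
        },
        "sigma": config.sigma,
        "seed": config.seed,
        "n_replicates": config.n_replicates,
    }
    return series, truth


def _truth_fits(config: GeneratorConfig) -> dict[float, IsothermFit]:
    """Pseudo-fits carrying the exact generator parameters."""
    fits = {}
    for t in config.temperatures:
        p = tuple(config.params_by_temperature[t])
        aw = np.asarray(config.design_aw(t))
        pred = np.asarray(evaluate(config.model_id, p, aw))
        fits[t] = IsothermFit(
            config.sample_id, config.mode.value, t, config.model_id,
            p, tuple(pred), 1.0, 0.0, True, 0,
        )
    return fits


def recovery_report(
    config: GeneratorConfig,
    qst_at: float = 18.0,
) -> pd.DataFrame:
    """Monte-Carlo parameter- and pipeline-recovery summary.

    For each replicate, refits the generating model per temperature and
    reruns the downstream pipeline (isosteric heat at ``qst_at`` % d.b.,
    isokinetic temperature, surface area at the lowest temperature);
    reports bias, RMSE and median absolute relative error of each
    quantity against the noiseless truth.
    """
    truth_fits = _truth_fits(config)
    t_lo = config.temperatures[0]
    truth_table = isosteric_analysis(truth_fits)
    if qst_at not in truth_table.xeq_grid:
        raise ValueError(f"qst_at={qst_at} not on the default isosteric grid")
    truth_vals = {
        "A": truth_fits[t_lo].params[0],
        "B": truth_fits[t_lo].params[1],
        "C": truth_fits[t_lo].params[2],
        f"qst_{qst_at:g}": truth_table.qst_kj_mol[truth_table.xeq_grid.index(qst_at)],
        "t_beta": compensation(truth_table).t_beta_k,
        "s0": surface_area(monolayer_moisture(truth_fits[t_lo].params)),
    }
    rng = np.random.default_rng(config.seed)
    rows = []
    for rep in range(config.n_replicates):
        series = make_series(config, rng, rep)
        fits = {s.temperature_c: fit_model(s, config.model_id) for s in series}
        est: dict[str, float] = {}
        est["A"], est["B"], est["C"] = fits[t_lo].params[:3]
        est["s0"] = surface_area(monolayer_moisture(fits[t_lo].params))
        try:
            table = isosteric_analysis(fits)
            if qst_at in table.xeq_grid:
                est[f"qst_{qst_at:g}"] = table.qst_kj_mol[
                    table.xeq_grid.index(qst_at)
                ]
            est["t_beta"] = compensation(table).t_beta_k
        except (ValueError, ArithmeticError):
            pass
        rows.append(est)
    reps = pd.DataFrame(rows)
    summary = []
    for name, true in truth_vals.items():
        if name not in reps:
            continue
        vals = reps[name].dropna().to_numpy()
        rel = (vals - true) / true
        summary.append(
            {
                "quantity": name,
                "truth": true,
                "n": len(vals),
                "bias": float(np.mean(vals - true)),
                "rmse": float(np.sqrt(np.mean((vals - true) ** 2))),
                "median_abs_rel_err": float(np.median(np.abs(rel))),
            }
        )
    return pd.DataFrame(summary)


def write_generated(
    config: GeneratorConfig, csv_path: str | Path, truth_path: str | Path
) -> None:
    """Emit a generated dataset as CSV plus its ground truth as JSON."""
    from .records import write_sorption_csv

    series, truth = generate(config)
    write_sorption_csv(series, csv_path)
    Path(truth_path).write_text(json.dumps(truth, indent=2))
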