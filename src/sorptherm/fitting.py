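"""Nonlinear least-squares fitting of isotherm models and model selection.

Parameters are estimated per isotherm series by minimizing the plain sum
of squared deviations between observed and predicted moisture content,
using bounded trust-region least squares started from a fixed,
data-adaptive grid of initial values (deterministic multi-start: identical
input always yields identical output).

Goodness of fit follows the conventions of the sorption literature:

* ``r``: square root of the ratio of the regression sum of squares to the
  total sum of squares, clipped to [0, 1];
* ``MRE``: mean relative error in percent,
  ``(100/N) * sum(|X_exp - X_pred| / X_exp)``.

A model is conventionally deemed acceptable when its MRE is below (or
close to) 10 %.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .models import MODELS, ModelId, evaluate
from .records import IsothermSeries, ValidationError

__all__ = [
    "IsothermFit",
    "ModelSelection",
    "fit_model",
    "fit_series",
    "fit_dataset",
    "goodness",
    "select_best",
    "select_overall",
    "MRE_ACCEPTABLE",
    "fits_to_frame",
]

logger = logging.getLogger(__name__)

#: Acceptability threshold on the mean relative error (percent).
MRE_ACCEPTABLE = 10.0

_FIT_TOL = 1e-10   # cost tolerance of the trust-region optimizer
_MAX_NFEV = 5000   # generous: degenerate BET-like ridges converge slowly


@dataclass(frozen=True)
class IsothermFit:
    """Result of fitting one model to one isotherm series."""

    sample_id: str
    mode: str
    temperature_c: float
    model_id: ModelId
    params: tuple[float, ...]
    predictions: tuple[float, ...]
    r: float
    mre: float
    converged: bool
    n_starts_used: int

    @property
    def key(self) -> tuple[str, str, float]:
        return (self.sample_id, self.mode, self.temperature_c)

    @property
    def param_dict(self) -> dict[str, float]:
        return dict(zip(MODELS[self.model_id].param_names, self.params))

    @property
    def acceptable(self) -> bool:
        return self.converged and self.mre <= MRE_ACCEPTABLE


def goodness(x_exp: Sequence[float], x_pred: Sequence[float]) -> tuple[float, float]:
    """Correlation coefficient ``r`` and mean relative error (percent).

    Points with ``x_exp == 0`` are excluded from the MRE (division guard)
    with a warning; they still enter ``r``.
    """
    x_exp = np.asarray(x_exp, dtype=float)
    x_pred = np.asarray(x_pred, dtype=float)
    if x_exp.shape != x_pred.shape:
        raise ValueError("observations and predictions must have equal length")
    sst = float(np.sum((x_exp - x_exp.mean()) ** 2))
    ssr = float(np.sum((x_pred - x_exp.mean()) ** 2))
    r = 1.0 if sst == 0.0 else float(np.sqrt(np.clip(ssr / sst, 0.0, 1.0)))
    nonzero = x_exp != 0
    if not np.all(nonzero):
        logger.warning(
            "%d observation(s) with zero moisture excluded from MRE",
            int(np.sum(~nonzero)),
        )
    n = int(np.sum(nonzero))
    if n == 0:
        raise ValueError("no nonzero observations for MRE")
    mre = 100.0 / n * float(
        np.sum(np.abs(x_exp[nonzero] - x_pred[nonzero]) / x_exp[nonzero])
    )
    return r, mre


def _interp_at(aw: np.ndarray, x: np.ndarray, target: float) -> float:
    """Observed moisture at the design point nearest ``target`` water activity."""
    return float(x[np.argmin(np.abs(aw - target))])


def _start_grid(model_id: ModelId, aw: np.ndarray, x: np.ndarray) -> list[tuple]:
    """Deterministic multi-start initial values, adapted to the data scale."""
    if model_id is ModelId.GAB:
        a_mono = max(_interp_at(aw, x, 0.32), 1e-3)
        return [
            (a_mono * f, b0, c0)
            for f in (0.5, 1.0, 2.0)
            for b0 in (0.5, 0.7, 0.9)
            for c0 in (1.0, 5.0, 20.0)
        ]
    if model_id is ModelId.PELEG:
        # Low-exponent term carries the low-a_w plateau, the high-exponent
        # term the final upswing: x(1) ~ A + B.
        a0 = max(_interp_at(aw, x, 0.32), 1e-3)
        b0 = max(float(x[-1]) - a0, 1e-3)
        return [(a0, b0, c0, d0) for c0 in (0.5, 1.0) for d0 in (2.0, 5.0)]
    if model_id is ModelId.ENDERBY:
        half = max(_interp_at(aw, x, 0.3) / 2.0, 1e-3)
        return [(half, b0, half, d0) for b0 in (0.3, 0.7, 0.9) for d0 in (0.3, 0.7, 0.9)]
    raise ValueError(model_id)  # pragma: no cover


def _residuals(model_id: ModelId, aw: np.ndarray, x: np.ndarray):
    spec = MODELS[model_id]
    lo = np.asarray(spec.lower)
    hi = np.asarray(spec.upper)

    def fn(p):
        try:
            return np.asarray(evaluate(model_id, p, aw)) - x
        except ValueError:
            return np.full_like(x, 1e8)

    return fn, lo, hi


def fit_model(series: IsothermSeries, model_id: ModelId | str) -> IsothermFit:
    """Fit one model to one series by deterministic multi-start least squares.

    Requires at least ``n_params + 1`` records (4-parameter models need 5
    points).  If no start converges the result carries
    ``converged=False`` with NaN statistics rather than raising.
    """
    model_id = ModelId(model_id)
    spec = MODELS[model_id]
    if len(series) < spec.n_params + 1:
        raise ValidationError(
            f"series {series.key} has {len(series)} records; "
            f"{model_id} needs at least {spec.n_params + 1}"
        )
    aw = np.asarray(series.aw)
    x = np.asarray(series.xeq)
    resid, lo, hi = _residuals(model_id, aw, x)
    best = None
    fallback = None  # best run that stopped on the evaluation budget
    n_used = 0
    for p0 in _start_grid(model_id, aw, x):
        p0 = np.clip(p0, lo, hi)
        try:
            res = least_squares(
                resid, p0, bounds=(lo, hi), method="trf",
                ftol=_FIT_TOL, xtol=_FIT_TOL, gtol=_FIT_TOL, max_nfev=_MAX_NFEV,
            )
        except Exception:  # singular Jacobian etc.: skip this start
            continue
        if not res.success:
            if np.isfinite(res.cost) and (fallback is None or res.cost < fallback.cost):
                fallback = res
            continue
        n_used += 1
        if best is None or res.cost < best.cost:
            best = res
    converged = best is not None
    if best is None:
        best = fallback
    if best is None:
        logger.warning("all starts diverged for %s / %s", series.key, model_id)
        return IsothermFit(
            *series.key, model_id, (), (), float("nan"), float("nan"), False, 0
        )
    pred = np.asarray(evaluate(model_id, best.x, aw))
    r, mre = goodness(x, pred)
    return IsothermFit(
        series.sample_id,
        series.mode.value,
        series.temperature_c,
        model_id,
        tuple(float(v) for v in best.x),
        tuple(float(v) for v in pred),
        r,
        mre,
        converged,
        n_used,
    )


def fit_series(
    series: IsothermSeries, models: Iterable[ModelId | str] = tuple(ModelId)
) -> list[IsothermFit]:
    """Fit every requested model to one series."""
    return [fit_model(series, m) for m in models]


def fit_dataset(
    dataset: Sequence[IsothermSeries], models: Iterable[ModelId | str] = tuple(ModelId)
) -> list[IsothermFit]:
    """Fit every requested model to every series of a dataset."""
    models = [ModelId(m) for m in models]
    return [fit_model(s, m) for s in dataset for m in models]


@dataclass(frozen=True)
class ModelSelection:
    """Winner of a model comparison plus per-model acceptability flags."""

    winner: ModelId
    acceptable: dict[ModelId, bool]


def select_best(fits: Sequence[IsothermFit]) -> ModelSelection:
    """Pick the best fit: highest ``r`` (to 3 decimals), ties by lower MRE.

    Only converged fits compete; fits with MRE above 10 % are flagged
    unacceptable but may still win if nothing better converged.
    """
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged fit to select from")
    winner = min(converged, key=lambda f: (-round(f.r, 3), f.mre))
    return ModelSelection(
        winner.model_id, {f.model_id: f.acceptable for f in fits}
    )


def select_overall(fits: Sequence[IsothermFit]) -> ModelId:
    """Overall best model across many series: the most per-series wins.

    Ties are broken by lower mean MRE across all series.
    """
    by_series: dict[tuple, list[IsothermFit]] = {}
    for f in fits:
        by_series.setdefault(f.key, []).append(f)
    wins: dict[ModelId, int] = {}
    for group in by_series.values():
        wins[select_best(group).winner] = wins.get(select_best(group).winner, 0) + 1
    mean_mre = {
        m: float(np.mean([f.mre for f in fits if f.model_id == m and f.converged]))
        for m in {f.model_id for f in fits}
    }
    return max(wins, key=lambda m: (wins[m], -mean_mre.get(m, np.inf)))


def fits_to_frame(fits: Sequence[IsothermFit]):
    """Tabulate fits (one row per series x model), mirroring a fit-summary table."""
    import pandas as pd

    rows = []
    for f in fits:
        row = {
            "sample_id": f.sample_id,
            "mode": f.mode,
            "temperature_c": f.temperature_c,
            "model": f.model_id.value,
            "r": f.r,
            "mre": f.mre,
            "converged": f.converged,
            "n_starts_used": f.n_starts_used,
        }
        row.update({f"param_{k}": v for k, v in f.param_dict.items()})
        rows.append(row)
    return pd.DataFrame(rows)
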