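"""Sorption thermodynamics: isosteric heat, entropy, Gibbs energy,
enthalpy-entropy compensation.

At constant moisture content the Clausius-Clapeyron relation links water
activity and temperature::

    ln a_w = -(q_st / R) * (1/T) + dS / R

so an ordinary least-squares line of ``ln a_w`` on ``1/T`` (T in Kelvin)
across the experimental temperatures yields the net isosteric heat of
sorption ``q_st`` (from the slope) and the differential entropy ``dS``
(from the intercept) at that moisture level.  Repeating over a grid of
moisture contents gives the q_st(X_eq) and dS(X_eq) curves; regressing
q_st on dS across the grid tests enthalpy-entropy compensation: the slope
is the isokinetic temperature ``T_beta`` and the intercept the Gibbs
energy at that temperature, ``dG_beta``.  Compensation is credible only
when ``T_beta`` differs from the harmonic mean of the experimental
temperatures, and the sorption process is spontaneous iff ``dG_beta < 0``.

All heats are *net* quantities: the latent heat of condensation of pure
water is not added back.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .fitting import IsothermFit
from .models import AW_MAX, invert_isotherm

__all__ = [
    "GAS_CONSTANT",
    "KELVIN_OFFSET",
    "ThermoTable",
    "CompensationResult",
    "default_moisture_grid",
    "isosteric_analysis",
    "gibbs_free_energy",
    "smooth_polynomial",
    "harmonic_mean_temperature",
    "compensation",
]

logger = logging.getLogger(__name__)

GAS_CONSTANT = 8.314  # J/(mol K)
KELVIN_OFFSET = 273.15


def default_moisture_grid() -> np.ndarray:
    """Moisture grid for isosteric analysis: 10-30 % d.b. in 1 % steps.

    Chosen to bracket the 14-24 % band where the isosteric heat and
    entropy vary most sharply; points not attainable at every temperature
    are dropped during analysis.
    """
    return np.arange(10.0, 30.0 + 1e-9, 1.0)


@dataclass(frozen=True)
class ThermoTable:
    """Isosteric heat and differential entropy over a moisture grid."""

    sample_id: str
    mode: str
    temperatures_c: tuple[float, ...]
    xeq_grid: tuple[float, ...]            # % d.b., retained points only
    aw: tuple[tuple[float, ...], ...]      # per grid point, per temperature
    qst_kj_mol: tuple[float, ...]          # net isosteric heat
    ds_j_mol_k: tuple[float, ...]          # differential entropy
    line_r2: tuple[float, ...]             # r^2 of each ln a_w ~ 1/T line

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, x in enumerate(self.xeq_grid):
            row = {
                "sample_id": self.sample_id,
                "mode": self.mode,
                "xeq_percent_db": x,
                "qst_kj_mol": self.qst_kj_mol[i],
                "ds_j_mol_k": self.ds_j_mol_k[i],
                "line_r2": self.line_r2[i],
            }
            for t, a in zip(self.temperatures_c, self.aw[i]):
                row[f"aw_{t:g}C"] = a
                row[f"dG_{t:g}C_j_mol"] = gibbs_free_energy(a, t + KELVIN_OFFSET)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CompensationResult:
    """Enthalpy-entropy compensation line and its spontaneity verdict."""

    t_beta_k: float        # isokinetic temperature (slope), K
    dg_beta_j_mol: float   # Gibbs energy at T_beta (intercept), J/mol
    r: float               # correlation of the q_st ~ dS line
    t_hm_k: float          # harmonic mean of the experimental temperatures
    n_points: int

    @property
    def spontaneous(self) -> bool:
        return self.dg_beta_j_mol < 0

    @property
    def compensation_valid(self) -> bool:
        """Compensation is credible when T_beta differs from T_hm."""
        return not math.isclose(self.t_beta_k, self.t_hm_k, rel_tol=1e-3)


def isosteric_analysis(
    fits_by_temperature: Mapping[float, IsothermFit],
    xeq_grid: Sequence[float] | None = None,
    aw_max: float = AW_MAX,
) -> ThermoTable:
    """Net isosteric heat and differential entropy over a moisture grid.

    Parameters
    ----------
    fits_by_temperature : mapping temperature (degC) -> converged fit
        One fitted isotherm (normally GAB) per temperature for the same
        sample and mode; at least two temperatures.
    xeq_grid : moisture grid in % d.b. (default 10-30 step 1)

    Grid points whose moisture is not attainable at every temperature are
    dropped with a warning.
    """
    temps = sorted(fits_by_temperature)
    if len(temps) < 2:
        raise ValueError("need fits at >= 2 temperatures")
    fits = [fits_by_temperature[t] for t in temps]
    keys = {(f.sample_id, f.mode) for f in fits}
    if len(keys) != 1:
        raise ValueError(f"fits mix samples/modes: {keys}")
    if not all(f.converged for f in fits):
        raise ValueError("all fits must have converged")
    (sample_id, mode), = keys
    if xeq_grid is None:
        xeq_grid = default_moisture_grid()
    inv_t = np.array([1.0 / (t + KELVIN_OFFSET) for t in temps])
    kept, aw_rows, qst, ds, r2 = [], [], [], [], []
    for x in xeq_grid:
        try:
            aws = [
                invert_isotherm(f.model_id, f.params, float(x), aw_max) for f in fits
            ]
        except ValueError:
            logger.warning(
                "grid point %.3g %% d.b. not attainable at all temperatures "
                "for (%s, %s); dropped", x, sample_id, mode,
            )
            continue
        line = linregress(inv_t, np.log(aws))
        kept.append(float(x))
        aw_rows.append(tuple(aws))
        qst.append(-GAS_CONSTANT * line.slope / 1000.0)   # kJ/mol
        ds.append(GAS_CONSTANT * line.intercept)           # J/(mol K)
        r2.append(line.rvalue**2)
    return ThermoTable(
        sample_id, mode, tuple(float(t) for t in temps), tuple(kept),
        tuple(aw_rows), tuple(qst), tuple(ds), tuple(r2),
    )


def gibbs_free_energy(aw: float, temperature_k: float) -> float:
    """Gibbs free energy of sorption, ``dG = R*T*ln(a_w)`` in J/mol.

    Negative for ``a_w < 1`` (sorption releases free energy relative to
    pure water).
    """
    if not (0.0 < aw < 1.0):
        raise ValueError(f"water activity must lie in (0, 1), got {aw}")
    return GAS_CONSTANT * temperature_k * math.log(aw)


def smooth_polynomial(
    x: Sequence[float], y: Sequence[float], degree: int = 3
) -> tuple[np.ndarray, float]:
    """Least-squares polynomial smooth of a thermodynamic curve.

    Returns ``(coefficients, r)`` with coefficients in decreasing degree
    (numpy ``polyfit`` convention) and ``r`` the correlation coefficient of
    the fit.  Cubic by default, matching how q_st(X_eq) and dS(X_eq)
    curves are conventionally reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < degree + 1:
        raise ValueError(f"need >= {degree + 1} points for degree {degree}")
    coeffs = np.polyfit(x, y, degree)
    pred = np.polyval(coeffs, x)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return coeffs, 1.0
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / sst
    return coeffs, float(np.sqrt(np.clip(r2, 0.0, 1.0)))


def harmonic_mean_temperature(temperatures_c: Sequence[float]) -> float:
    """Harmonic mean of the experimental temperatures, in Kelvin."""
    t_k = np.asarray(temperatures_c, dtype=float) + KELVIN_OFFSET
    return float(len(t_k) / np.sum(1.0 / t_k))


def compensation(table: ThermoTable) -> CompensationResult:
    """Enthalpy-entropy compensation regression over a thermo table.

    Ordinary least squares of ``q_st`` (J/mol) on ``dS`` (J/(mol K));
    the slope is the isokinetic temperature in Kelvin and the intercept
    the free energy at that temperature.
    """
    if len(table.xeq_grid) < 3:
        raise ValueError("need >= 3 grid points for the compensation line")
    ds = np.asarray(table.ds_j_mol_k)
    qst = np.asarray(table.qst_kj_mol) * 1000.0
    if np.ptp(ds) < 1e-12:
        raise ValueError("degenerate entropy spread; compensation line undefined")
    line = linregress(ds, qst)
    return CompensationResult(
        t_beta_k=float(line.slope),
        dg_beta_j_mol=float(line.intercept),
        r=float(line.rvalue),
        t_hm_k=harmonic_mean_temperature(table.temperatures_c),
        n_points=len(table.xeq_grid),
    )
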