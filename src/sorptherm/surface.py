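"""Surface thermodynamics: spreading pressure, sorption surface area, and
the optimal-storage-humidity analysis.

The spreading pressure ``pi`` is the surface excess free energy of the
sorbed water film::

    pi(a_w) = (k_B * T / A_m) * integral_0^a_w  theta(u) / u  du

with ``theta = X_eq / X_m`` the moisture ratio, ``k_B`` the Boltzmann
constant and ``A_m`` the area of one water molecule.  Under the GAB model
the integral has the closed form::

    pi = (k_B * T / A_m) * ln[(1 - B*a_w + C*B*a_w) / (1 - B*a_w)]

which this module exposes alongside an adaptive-quadrature evaluation of
the defining integral as an independent numerical oracle.

The sorption surface area per gram of dry solid follows from the
monolayer moisture ``M_m`` (kg water / kg dry solid)::

    S_0 = M_m / PM_H2O * N_0 * A_H2O = 3.5e3 * M_m   [m^2/g]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .models import AW_MAX, gab
from .records import IsothermSeries
from .thermo import KELVIN_OFFSET

__all__ = [
    "BOLTZMANN",
    "WATER_MOLECULE_AREA",
    "SURFACE_AREA_FACTOR",
    "spreading_pressure_closed",
    "spreading_pressure_numeric",
    "spreading_pressure_curve",
    "surface_area",
    "OptimalStorage",
    "optimal_storage",
]

BOLTZMANN = 1.380e-23           # J/K
WATER_MOLECULE_AREA = 1.06e-19  # m^2
#: N_0 * A_H2O / PM_H2O with M_m in kg/kg and S_0 in m^2/g.
SURFACE_AREA_FACTOR = 3.5e3


def spreading_pressure_closed(aw: float, temperature_k: float, gab_params) -> float:
    """Spreading pressure (J/m^2) from the GAB closed form."""
    A, B, C = gab_params
    if not (0.0 <= aw) or B * aw >= 1.0:
        raise ValueError(f"a_w={aw} outside the valid GAB range (pole at {1/B:.4g})")
    u = B * aw
    return (
        BOLTZMANN * temperature_k / WATER_MOLECULE_AREA
        * float(np.log((1.0 - u + C * u) / (1.0 - u)))
    )


def spreading_pressure_numeric(aw: float, temperature_k: float, gab_params) -> float:
    """Spreading pressure (J/m^2) by adaptive quadrature of the integral.

    Serves as the independent oracle for the closed form.  The integrand
    ``theta(u)/u`` is finite at 0 (limit ``B*C``).
    """
    A, B, C = gab_params
    if not (0.0 <= aw) or B * aw >= 1.0:
        raise ValueError(f"a_w={aw} outside the valid GAB range")
    if aw == 0.0:
        return 0.0

    def integrand(u: float) -> float:
        if u == 0.0:
            return B * C
        return gab(u, A, B, C) / A / u

    value, err = quad(integrand, 0.0, aw, epsabs=1e-13, epsrel=1e-12, limit=200)
    if not np.isfinite(value):
        raise ArithmeticError(f"quadrature failed (estimate {value}, error {err})")
    return BOLTZMANN * temperature_k / WATER_MOLECULE_AREA * value


def spreading_pressure_curve(
    temperature_c: float, gab_params, aw_points=None
) -> "np.ndarray":
    """Spreading pressure at a grid of water activities (default 0.05..0.90).

    Returns an array of (a_w, pi) rows.
    """
    if aw_points is None:
        aw_points = np.arange(0.05, 0.901, 0.05)
    t_k = temperature_c + KELVIN_OFFSET
    return np.array(
        [(a, spreading_pressure_closed(float(a), t_k, gab_params)) for a in aw_points]
    )


def surface_area(monolayer_fraction: float) -> float:
    """Sorption surface area S_0 (m^2 per g dry solid) from monolayer moisture.

    ``monolayer_fraction`` is M_m in kg water per kg dry solid.
    """
    if monolayer_fraction <= 0:
        raise ValueError("monolayer moisture must be positive")
    return SURFACE_AREA_FACTOR * monolayer_fraction


@dataclass(frozen=True)
class OptimalStorage:
    """Inflection of a cubic smooth of one isotherm: the storage optimum.

    The optimum humidity for storage is read off the sigmoid isotherm at
    the point where its curvature changes between the two limbs.  The
    attribution of one printed (a_w, X_eq) pair per sample to a specific
    temperature/mode is method-inferred, hence the flag.
    """

    aw_optimal: float
    xeq_optimal: float
    coefficients: tuple[float, float, float, float]  # c3, c2, c1, c0
    method_inferred: bool = True


def optimal_storage(series: IsothermSeries) -> OptimalStorage:
    """Optimal storage humidity from a cubic fit of one isotherm.

    Fits ``x_eq = c3*a^3 + c2*a^2 + c1*a + c0`` by least squares and
    returns the inflection point ``a = -c2 / (3*c3)`` with the moisture
    the cubic predicts there.  A vanishing cubic coefficient (no
    inflection) raises.
    """
    if len(series) < 4:
        raise ValueError("need >= 4 points for a cubic fit")
    aw = np.asarray(series.aw)
    x = np.asarray(series.xeq)
    c3, c2, c1, c0 = np.polyfit(aw, x, 3)
    if abs(c3) < 1e-9 * max(1.0, abs(c2)):
        raise ArithmeticError("cubic coefficient ~ 0: no inflection point")
    a_op = float(-c2 / (3.0 * c3))
    x_op = float(np.polyval([c3, c2, c1, c0], a_op))
    return OptimalStorage(a_op, x_op, (float(c3), float(c2), float(c1), float(c0)))
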