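"""Forward sorption-isotherm models and their numeric inverse.

Three classical equations relating equilibrium moisture content ``X_eq``
(% dry basis) to water activity ``a_w`` at fixed temperature:

GAB (Guggenheim-Anderson-de Boer), three parameters::

    X_eq = A*B*C*a_w / [(1 - B*a_w) * (1 - B*a_w + C*B*a_w)]

where ``A`` is the monolayer moisture content X_m (% d.b.), ``B`` the
multilayer correction factor K (0 < B < 1) and ``C`` the Guggenheim energy
constant.

Peleg, four parameters::

    X_eq = A*a_w**C + B*a_w**D

Enderby, four parameters (sum of two hyperbolic terms)::

    X_eq = [A/(1 - B*a_w) + C/(1 - D*a_w)] * a_w

All models pass through the origin.  The GAB and Enderby forms have poles
at ``a_w = 1/B`` (and ``1/D``); evaluation beyond a pole raises.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ModelId",
    "ModelSpec",
    "MODELS",
    "gab",
    "peleg",
    "enderby",
    "evaluate",
    "invert_isotherm",
    "monolayer_moisture",
    "AW_MAX",
]

#: Upper water-activity cap for inversions and integrations.  Beyond the
#: last experimental design point the fitted curve is extrapolation.
AW_MAX = 0.95


class ModelId(str, enum.Enum):
    GAB = "GAB"
    PELEG = "PELEG"
    ENDERBY = "ENDERBY"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ModelSpec:
    """Static description of one isotherm model for the fitting machinery."""

    model_id: ModelId
    param_names: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    @property
    def n_params(self) -> int:
        return len(self.param_names)


# Finite caps keep the bounded trust-region optimizer well-posed; A is in
# % d.b. so 1e4 is far above any food moisture content.
MODELS: dict[ModelId, ModelSpec] = {
    ModelId.GAB: ModelSpec(
        ModelId.GAB,
        ("A", "B", "C"),
        (1e-8, 1e-8, 1e-8),
        (1e4, 1.0 - 1e-9, 1e6),
    ),
    ModelId.PELEG: ModelSpec(
        ModelId.PELEG,
        ("A", "B", "C", "D"),
        (1e-8, 1e-8, 1e-3, 1e-3),
        (1e4, 1e4, 50.0, 50.0),
    ),
    ModelId.ENDERBY: ModelSpec(
        ModelId.ENDERBY,
        ("A", "B", "C", "D"),
        (-1e4, 1e-8, -1e4, 1e-8),
        (1e4, 1.0 - 1e-9, 1e4, 1.0 - 1e-9),
    ),
}


def gab(aw, A: float, B: float, C: float):
    """GAB equilibrium moisture content (% d.b.) at water activity ``aw``."""
    aw = np.asarray(aw, dtype=float)
    u = B * aw
    if np.any(u >= 1.0):
        raise ValueError(f"GAB pole crossed: B*a_w >= 1 (B={B})")
    out = A * C * u / ((1.0 - u) * (1.0 - u + C * u))
    return out if out.ndim else float(out)


def peleg(aw, A: float, B: float, C: float, D: float):
    """Peleg double power-law moisture content (% d.b.)."""
    aw = np.asarray(aw, dtype=float)
    if np.any(aw < 0.0):
        raise ValueError("water activity must be non-negative")
    out = A * aw**C + B * aw**D
    return out if out.ndim else float(out)


def enderby(aw, A: float, B: float, C: float, D: float):
    """Enderby two-term hyperbolic moisture content (% d.b.)."""
    aw = np.asarray(aw, dtype=float)
    if np.any(B * aw >= 1.0) or np.any(D * aw >= 1.0):
        raise ValueError(f"Enderby pole crossed (B={B}, D={D})")
    out = (A / (1.0 - B * aw) + C / (1.0 - D * aw)) * aw
    return out if out.ndim else float(out)


_FORWARD = {ModelId.GAB: gab, ModelId.PELEG: peleg, ModelId.ENDERBY: enderby}


def evaluate(model_id: ModelId | str, params, aw):
    """Evaluate a model by id with a parameter sequence (ordered as in MODELS)."""
    return _FORWARD[ModelId(model_id)](aw, *params)


def invert_isotherm(
    model_id: ModelId | str,
    params,
    xeq_target: float,
    aw_max: float = AW_MAX,
) -> float:
    """Water activity at which the model attains ``xeq_target`` (% d.b.).

    Uses bracketed root finding on (0, aw_max]; the model must be
    increasing there (true for valid parameters of all three models on the
    attainable range).  Targets outside [0, model(aw_max)] raise
    ``ValueError`` -- such moisture levels are excluded from isosteric
    grids.
    """
    model_id = ModelId(model_id)
    if xeq_target < 0:
        raise ValueError("target moisture must be >= 0")
    if xeq_target == 0:
        return 0.0
    fn = _FORWARD[model_id]
    lo = 1e-12
    hi = aw_max
    f_hi = fn(hi, *params) - xeq_target
    if f_hi < 0:
        raise ValueError(
            f"target {xeq_target} % d.b. above attainable range "
            f"(model({aw_max}) = {f_hi + xeq_target:.4f})"
        )
    f_lo = fn(lo, *params) - xeq_target
    if f_lo > 0:
        raise ValueError(f"target {xeq_target} % d.b. below attainable range")
    root = brentq(
        lambda a: fn(a, *params) - xeq_target, lo, hi, xtol=1e-15, rtol=1e-15
    )
    return float(root)


def monolayer_moisture(gab_params) -> float:
    """GAB monolayer moisture M_m as a fraction (kg water / kg dry solid).

    The GAB amplitude A is fitted in % d.b.; the surface-area relation
    wants the fractional value.
    """
    A = gab_params[0] if not hasattr(gab_params, "get") else gab_params["A"]
    if A <= 0:
        raise ValueError("monolayer parameter must be positive")
    return A / 100.0
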