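"""Data model and CSV I/O for equilibrium moisture sorption records.

A sorption experiment observes the equilibrium moisture content (EMC,
expressed in % dry basis) of a sample held at fixed temperature over a
saturated salt solution that pins the water activity ``a_w``.  One
:class:`SorptionRecord` is one such observation; an :class:`IsothermSeries`
groups the observations of one sample/mode/temperature into an isotherm,
sorted by increasing water activity.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Mode",
    "SorptionRecord",
    "IsothermSeries",
    "ValidationError",
    "compute_emc",
    "load_sorption_csv",
    "write_sorption_csv",
    "group_records",
    "salt_water_activity",
    "SALT_WATER_ACTIVITY",
]

logger = logging.getLogger(__name__)

CSV_COLUMNS = ["sample_id", "mode", "temperature_c", "aw", "xeq_percent_db"]


class ValidationError(ValueError):
    """Raised when sorption data violate the domain invariants."""


class Mode(str, enum.Enum):
    """Direction of the moisture exchange experiment."""

    DESORPTION = "desorption"
    ADSORPTION = "adsorption"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True, order=True)
class SorptionRecord:
    """One (a_w, X_eq) observation at a given temperature.

    Attributes
    ----------
    sample_id : str
        Sample label (here: cultivar name).
    mode : Mode
        Desorption (drying from fresh) or adsorption (rewetting of
        pre-dried material).
    temperature_c : float
        Experiment temperature in degrees Celsius.
    aw : float
        Water activity, dimensionless, strictly inside (0, 1).
    xeq : float
        Equilibrium moisture content in % dry basis (>= 0).
    """

    sample_id: str
    mode: Mode
    temperature_c: float
    aw: float
    xeq: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", Mode(self.mode))
        if not (0.0 < self.aw < 1.0):
            raise ValidationError(f"water activity must lie in (0, 1), got {self.aw}")
        if self.xeq < 0.0:
            raise ValidationError(f"moisture content must be >= 0, got {self.xeq}")
        if not math.isfinite(self.temperature_c):
            raise ValidationError("temperature must be finite")


@dataclass(frozen=True)
class IsothermSeries:
    """All records of one (sample, mode, temperature) isotherm, sorted by a_w."""

    sample_id: str
    mode: Mode
    temperature_c: float
    records: tuple[SorptionRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", Mode(self.mode))
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise ValidationError("an isotherm series needs at least one record")
        for r in self.records:
            if (r.sample_id, r.mode, r.temperature_c) != (
                self.sample_id,
                self.mode,
                self.temperature_c,
            ):
                raise ValidationError(
                    f"record {r} does not belong to series "
                    f"({self.sample_id}, {self.mode}, {self.temperature_c})"
                )
        aws = [r.aw for r in self.records]
        if any(b <= a for a, b in zip(aws, aws[1:])):
            raise ValidationError(
                f"a_w values must be strictly increasing, got {aws} for "
                f"({self.sample_id}, {self.mode}, {self.temperature_c})"
            )

    @property
    def key(self) -> tuple[str, Mode, float]:
        return (self.sample_id, self.mode, self.temperature_c)

    @property
    def aw(self) -> tuple[float, ...]:
        return tuple(r.aw for r in self.records)

    @property
    def xeq(self) -> tuple[float, ...]:
        return tuple(r.xeq for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


def compute_emc(mass_wet: float, mass_dry: float) -> float:
    """Equilibrium moisture content on a fractional dry basis.

    ``EMC = (M_h - M_s) / M_s`` where ``M_h`` is the equilibrated (wet) mass
    and ``M_s`` the bone-dry mass.  Multiply by 100 for % dry basis.
    """
    if mass_dry <= 0:
        raise ValueError(f"dry mass must be positive, got {mass_dry}")
    if mass_wet < mass_dry:
        raise ValidationError(
            f"wet mass {mass_wet} below dry mass {mass_dry}: negative moisture"
        )
    return (mass_wet - mass_dry) / mass_dry


def group_records(records: Iterable[SorptionRecord]) -> list[IsothermSeries]:
    """Group loose records into sorted :class:`IsothermSeries`.

    Duplicate (sample, mode, temperature, a_w) combinations are rejected.
    Series order follows first appearance of each key.
    """
    by_key: dict[tuple, list[SorptionRecord]] = {}
    for rec in records:
        by_key.setdefault((rec.sample_id, rec.mode, rec.temperature_c), []).append(rec)
    series = []
    for (sid, mode, temp), recs in by_key.items():
        recs = sorted(recs, key=lambda r: r.aw)
        aws = [r.aw for r in recs]
        if len(set(aws)) != len(aws):
            raise ValidationError(
                f"duplicate a_w value in series ({sid}, {mode}, {temp}): {aws}"
            )
        series.append(IsothermSeries(sid, mode, temp, tuple(recs)))
    return series


def load_sorption_csv(path: str | Path) -> list[IsothermSeries]:
    """Read a sorption CSV (``sample_id,mode,temperature_c,aw,xeq_percent_db``).

    Returns one :class:`IsothermSeries` per (sample, mode, temperature)
    group.  Malformed rows raise :class:`ValidationError` naming the first
    offending row (1-based, excluding the header).  An empty file returns an
    empty list with a logged warning.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    if df.empty:
        logger.warning("%s: no sorption records found", path)
        return []
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                SorptionRecord(
                    sample_id=str(row.sample_id),
                    mode=Mode(str(row.mode)),
                    temperature_c=float(row.temperature_c),
                    aw=float(row.aw),
                    xeq=float(row.xeq_percent_db),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return group_records(records)


def write_sorption_csv(series: Sequence[IsothermSeries], path: str | Path) -> None:
    """Write series back to the CSV schema read by :func:`load_sorption_csv`."""
    rows = [
        {
            "sample_id": r.sample_id,
            "mode": r.mode.value,
            "temperature_c": r.temperature_c,
            "aw": r.aw,
            "xeq_percent_db": r.xeq,
        }
        for s in series
        for r in s.records
    ]
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def _load_salt_table() -> dict[str, dict[float, float]]:
    from .datasets import salt_reference_path

    df = pd.read_csv(salt_reference_path())
    table: dict[str, dict[float, float]] = {}
    for row in df.itertuples(index=False):
        table.setdefault(row.salt, {})[float(row.temperature_c)] = float(row.aw)
    return table


#: Reference water activities of the saturated salt solutions used to fix
#: relative humidity, keyed by salt then temperature (deg C).  Loaded lazily.
SALT_WATER_ACTIVITY: dict[str, dict[float, float]] = {}


def salt_water_activity(salt: str, temperature_c: float) -> float:
    """Water activity over a saturated salt solution at ``temperature_c``.

    Exact lookup at the tabulated temperatures (30/40/50 degC); linear
    interpolation in between.  Temperatures outside the tabulated range and
    unknown salts raise.
    """
    if not SALT_WATER_ACTIVITY:
        SALT_WATER_ACTIVITY.update(_load_salt_table())
    try:
        by_temp = SALT_WATER_ACTIVITY[salt]
    except KeyError:
        raise KeyError(
            f"unknown salt {salt!r}; known: {sorted(SALT_WATER_ACTIVITY)}"
        ) from None
    temps = sorted(by_temp)
    if not (temps[0] <= temperature_c <= temps[-1]):
        raise ValueError(
            f"temperature {temperature_c} degC outside tabulated range "
            f"[{temps[0]}, {temps[-1]}]"
        )
    if temperature_c in by_temp:
        return by_temp[temperature_c]
    hi = next(t for t in temps if t > temperature_c)
    lo = max(t for t in temps if t < temperature_c)
    frac = (temperature_c - lo) / (hi - lo)
    return by_temp[lo] + frac * (by_temp[hi] - by_temp[lo])
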