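"""Packaged reference datasets.

The package ships a five-cultivar sweet-cherry equilibrium sorption dataset
(desorption and adsorption at 30/40/50 degC, six salt-fixed water activities
per temperature), the salt/water-activity reference table those design
points come from, and per-cultivar metadata (soluble solids, fresh
moisture).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .records import IsothermSeries, load_sorption_csv

__all__ = [
    "cherry_sorption_path",
    "salt_reference_path",
    "cultivar_metadata_path",
    "load_cherry_dataset",
    "load_cultivar_metadata",
    "CULTIVARS",
]

#: The five sweet-cherry cultivars in the packaged dataset.
CULTIVARS = ("Burlat", "Van", "Napoleon", "Cerisette", "Coeur pigeon")


def _data_path(name: str) -> Path:
    return Path(resources.files("sorptherm").joinpath("data", name))


def cherry_sorption_path() -> Path:
    """Path of the packaged cherry sorption CSV (180 records, 30 series)."""
    return _data_path("cherry_sorption.csv")


def salt_reference_path() -> Path:
    """Path of the saturated-salt water-activity reference CSV."""
    return _data_path("salt_aw.csv")


def cultivar_metadata_path() -> Path:
    """Path of the cultivar metadata CSV (degrees Brix, fresh moisture %)."""
    return _data_path("cultivar_meta.csv")


def load_cherry_dataset() -> list[IsothermSeries]:
    """Load the packaged cherry dataset as 30 isotherm series.

    5 cultivars x 2 modes x 3 temperatures, 6 records each.
    """
    return load_sorption_csv(cherry_sorption_path())


def load_cultivar_metadata() -> pd.DataFrame:
    """Cultivar metadata: soluble solids (degrees Brix) and fresh moisture (%)."""
    return pd.read_csv(cultivar_metadata_path())
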