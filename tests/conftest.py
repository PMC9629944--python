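import pytest

from sorptherm import datasets, fit_dataset, load_cherry_dataset
from sorptherm.models import ModelId


@pytest.fixture(scope="session")
def cherry():
    """The packaged 30-series cherry dataset."""
    return load_cherry_dataset()


@pytest.fixture(scope="session")
def cherry_by_key(cherry):
    return {s.key: s for s in cherry}


@pytest.fixture(scope="session")
def cherry_gab_fits(cherry):
    """GAB fits for all 30 fixture series (computed once per session)."""
    return {f.key: f for f in fit_dataset(cherry, [ModelId.GAB])}


@pytest.fixture(scope="session")
def cherry_all_fits(cherry):
    """All-model fits (30 series x 3 models) for the fixture."""
    return fit_dataset(cherry)
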