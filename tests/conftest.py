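import numpy as np
import pytest

from binmix import datasets
from binmix.barker_wilson import IsothermalPxDataset, fit_isotherm_barker


@pytest.fixture(scope="session")
def components():
    return datasets.load_components()


@pytest.fixture(scope="session")
def isotherms():
    return datasets.load_isotherms()


@pytest.fixture(scope="session")
def wilson_reference():
    return datasets.load_wilson_reference()


def make_dataset(T, components):
    iso = datasets.load_isotherms()
    sub = iso[np.isclose(iso["T_K"], T)]
    p1, p2 = datasets.pure_pressures_at(T)
    return IsothermalPxDataset.from_components(
        T, sub["x2"].to_numpy(), sub["P_Pa"].to_numpy(), *components, p1, p2
    )


@pytest.fixture(scope="session")
def dataset_298(components):
    return make_dataset(298.15, components)


@pytest.fixture(scope="session")
def barker_fits(components):
    """All ten isotherm reductions (shared: the regression is deterministic)."""
    iso = datasets.load_isotherms()
    return [
        fit_isotherm_barker(make_dataset(T, components))
        for T in sorted(iso["T_K"].unique())
    ]
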