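"""Loaders for the bundled experimental fixtures.

The study data ship with the package as plain-text fixtures: the pure
component molar volumes and vapor pressures, the ten isothermal P-x
isotherms, the excess-enthalpy and density tables, the reference Wilson
reduction, and the per-model binary-interaction coefficients.  Subscript 1
is 2-propanol, subscript 2 is 1,8-cineole throughout.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .pure_components import AntoineConstants, Component, fit_antoine

_DATA = resources.files("binmix") / "data"


def _read_csv(name: str) -> pd.DataFrame:
    with (_DATA / name).open() as fh:
        return pd.read_csv(fh, comment="#")


@lru_cache(maxsize=None)
def load_pure_table() -> pd.DataFrame:
    """Pure-component table: T_K, V0 (x1e6 m3/mol) and P0 (Pa) per component."""
    return _read_csv("pure_components.csv")


@lru_cache(maxsize=None)
def load_isotherms() -> pd.DataFrame:
    """Long-format P-x isotherms with the reported dP, gamma and GE columns."""
    return _read_csv("px_isotherms.csv")


@lru_cache(maxsize=None)
def load_wilson_reference() -> pd.DataFrame:
    """Reference Wilson parameters, s, and lambda differences per isotherm."""
    return _read_csv("wilson_reference.csv")


@lru_cache(maxsize=None)
def load_excess_enthalpies() -> pd.DataFrame:
    return _read_csv("excess_enthalpies.csv")


@lru_cache(maxsize=None)
def load_densities() -> pd.DataFrame:
    return _read_csv("densities.csv")


@lru_cache(maxsize=None)
def load_kij_coefficients() -> dict:
    """Quadratic kij(T) coefficients (a, b, c) and R^2 per EoS model."""
    with (_DATA / "kij_coefficients.json").open() as fh:
        return json.load(fh)


def _component_from_json(name: str) -> Component:
    with (_DATA / f"{name}.json").open() as fh:
        raw = json.load(fh)
    antoine = None
    if raw.get("antoine"):
        antoine = AntoineConstants(
            A=raw["antoine"]["A"], B=raw["antoine"]["B"], C=raw["antoine"]["C"]
        )
    return Component(
        name=raw["name"],
        molar_mass=raw["molar_mass"],
        Tc=raw["Tc"],
        Pc=raw["Pc"],
        omega=raw["omega"],
        Tb=raw["Tb"],
        molar_volume_table=np.asarray(raw["molar_volume_table"], dtype=float),
        antoine=antoine,
        B_ref=raw.get("B_ref"),
        T_ref=raw.get("T_ref", 325.0),
        cubic_params=raw.get("cubic_params", {}),
        saft_params=raw.get("saft_params"),
    )


@lru_cache(maxsize=None)
def load_components() -> tuple[Component, Component]:
    """(2-propanol, 1,8-cineole) with all parameter blocks populated.

    The 1,8-cineole Antoine constants are not part of the printed record;
    they are regenerated here by refitting the bundled pure-pressure table,
    so the component always carries a usable correlation.
    """
    propanol = _component_from_json("2-propanol")
    cineole = _component_from_json("1,8-cineole")
    if cineole.antoine is None:
        tab = load_pure_table()
        fit = fit_antoine(tab["T_K"].to_numpy(), tab["P0_Pa_c2"].to_numpy())
        cineole.antoine = fit.constants
    return propanol, cineole


def pure_pressures_at(T: float) -> tuple[float, float]:
    """(P1_0, P2_0) in Pa at a tabulated isotherm temperature."""
    tab = load_pure_table()
    row = tab[np.isclose(tab["T_K"], T)]
    if row.empty:
        raise KeyError(f"no pure-pressure entry at T = {T} K")
    return float(row["P0_Pa_c1"].iloc[0]), float(row["P0_Pa_c2"].iloc[0])


@lru_cache(maxsize=None)
def load_saft_dispersion_constants() -> np.ndarray:
    """The 4x9 universal dispersion-constant matrix D_ij (zeros padded)."""
    df = _read_csv("saft_dispersion_constants.csv")
    D = np.zeros((4, 9))
    for _, row in df.iterrows():
        D[int(row["i"]) - 1, int(row["j"]) - 1] = row["D"]
    return D
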