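"""Excess molar properties: VE from densities, Redlich-Kister smoothing,
excess heat capacity, and the Gibbs-Helmholtz consistency test.

Excess molar volumes follow from mixture and pure densities,

    VE = x1 M1 (1/rho - 1/rho1) + x2 M2 (1/rho - 1/rho2),

and both VE and the calorimetric HE are smoothed with the Redlich-Kister
expansion QE = x1 x2 sum_j A_j (x1 - x2)^j, which vanishes identically at
the pure limits.  The Gibbs-Helmholtz identity HE = d(GE/T)/d(1/T) at fixed
composition links the vapor-pressure-derived GE(T) surface to the measured
HE and provides the cross-consistency check between the two experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .barker_wilson import LambdaTrend, lambda_interconvert, wilson_excess_gibbs
from .constants import R
from .pure_components import Component, molar_volume, std_deviation

__all__ = [
    "ExcessCurve",
    "RKFit",
    "ConsistencyReport",
    "excess_volume_point",
    "excess_volume_curve",
    "fit_redlich_kister",
    "eval_redlich_kister",
    "cp_excess_slope",
    "gibbs_helmholtz_HE",
]

PropertyTag = Literal["HE", "VE"]


@dataclass
class ExcessCurve:
    """One excess-property isotherm: (x2, value) points plus endpoints.

    ``values`` are J/mol for HE and m3/mol for VE; both vanish at x2 = 0, 1.
    """

    property: PropertyTag
    T: float
    x2: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.x2 = np.asarray(self.x2, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.x2.shape != self.values.shape:
            raise ValueError("x2 and values must have equal length")
        endpoint = np.isclose(self.x2, 0.0) | np.isclose(self.x2, 1.0)
        if np.any(self.values[endpoint] != 0.0):
            raise ValueError("excess property must be zero at the pure limits")

    @property
    def interior(self) -> tuple[np.ndarray, np.ndarray]:
        m = (self.x2 > 0.0) & (self.x2 < 1.0)
        return self.x2[m], self.values[m]


@dataclass
class RKFit:
    """Redlich-Kister coefficient vector A0..A(k-1) with its fit quality."""

    property: PropertyTag
    T: float
    coefficients: np.ndarray
    s: float


@dataclass
class ConsistencyReport:
    """Gibbs-Helmholtz comparison at one temperature.

    ``HE_gibbs_helmholtz`` comes from differentiating the vapor-pressure GE
    surface; ``HE_experimental`` from the calorimetric Redlich-Kister fit;
    ``TSE = HE - GE`` pointwise by construction (on the Gibbs-Helmholtz
    route).
    """

    T: float
    x2: np.ndarray
    GE: np.ndarray
    HE_gibbs_helmholtz: np.ndarray
    TSE: np.ndarray
    HE_experimental: np.ndarray | None = None

    @property
    def max_discrepancy(self) -> float:
        if self.HE_experimental is None:
            raise ValueError("no experimental curve attached")
        return float(np.max(np.abs(self.HE_gibbs_helmholtz - self.HE_experimental)))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def excess_volume_point(
    x2: float, rho: float, rho1: float, rho2: float, M1: float, M2: float
) -> float:
    """Excess molar volume (m3/mol) from densities in kg/m3 and M in g/mol."""
    x1 = 1.0 - x2
    m1 = M1 * 1e-3  # kg/mol
    m2 = M2 * 1e-3
    ve = x1 * m1 * (1.0 / rho - 1.0 / rho1) + x2 * m2 * (1.0 / rho - 1.0 / rho2)
    return float(ve)


def excess_volume_curve(
    T: float,
    x2: Sequence[float],
    rho: Sequence[float],
    M1: float,
    M2: float,
) -> ExcessCurve:
    """Build a VE isotherm from a density-composition table.

    The table's own x2 = 0 and x2 = 1 rows serve as the pure densities, so
    the endpoints are exactly zero by construction.
    """
    x2 = np.asarray(x2, dtype=float)
    rho = np.asarray(rho, dtype=float)
    i0 = np.flatnonzero(np.isclose(x2, 0.0))
    i1 = np.flatnonzero(np.isclose(x2, 1.0))
    if i0.size != 1 or i1.size != 1:
        raise ValueError("density table must contain exactly one x2=0 and one x2=1 row")
    rho1 = float(rho[i0[0]])
    rho2 = float(rho[i1[0]])
    ve = np.array([excess_volume_point(x, r, rho1, rho2, M1, M2) for x, r in zip(x2, rho)])
    # the pure rows are zero up to roundoff; pin them exactly
    ve[i0[0]] = 0.0
    ve[i1[0]] = 0.0
    return ExcessCurve(property="VE", T=T, x2=x2, values=ve)


def _rk_design(x1: np.ndarray, n_coeffs: int) -> np.ndarray:
    x2 = 1.0 - x1
    d = x1 - x2
    return np.column_stack([x1 * x2 * d**j for j in range(n_coeffs)])


def fit_redlich_kister(curve: ExcessCurve, n_coeffs: int) -> RKFit:
    """Linear least-squares Redlich-Kister fit on the interior points.

    Basis x1 x2 (x1-x2)^j for j = 0..n_coeffs-1; the identically-zero
    endpoint rows carry no information and are excluded.  The standard
    deviation uses n = n_coeffs adjusted parameters.
    """
    x2, q = curve.interior
    if x2.size < n_coeffs + 1:
        raise ValueError("not enough interior points for the requested coefficients")
    X = _rk_design(1.0 - x2, n_coeffs)
    coeffs, _, rank, _ = np.linalg.lstsq(X, q, rcond=None)
    if rank < n_coeffs:
        raise ValueError(f"rank-deficient design for {n_coeffs} coefficients")
    resid = q - X @ coeffs
    return RKFit(
        property=curve.property,
        T=curve.T,
        coefficients=coeffs,
        s=std_deviation(resid, n_coeffs),
    )


def eval_redlich_kister(fit: RKFit | Sequence[float], x1):
    """Evaluate x1 x2 sum_j A_j (x1-x2)^j; accepts a fit or a raw A vector."""
    coeffs = np.asarray(fit.coefficients if isinstance(fit, RKFit) else fit, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    out = _rk_design(np.atleast_1d(x1), coeffs.size) @ coeffs
    return float(out[0]) if x1.ndim == 0 else out


def cp_excess_slope(HE_by_T: Sequence[tuple[float, float]]) -> float:
    """Excess heat capacity as the OLS slope of HE against T at fixed x.

    Valid when the temperature dependence of HE is close to linear, which
    holds for this system near the equimolar composition.
    """
    pts = np.asarray(HE_by_T, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("need at least two temperatures")
    slope, _ = np.polyfit(pts[:, 0], pts[:, 1], 1)
    return float(slope)


def _wilson_ge_from_trend(
    trend: LambdaTrend,
    component1: Component,
    component2: Component,
    x1: np.ndarray,
    T: float,
) -> np.ndarray:
    """GE (J/mol) at (x1, T) rebuilding Lambda(T) from the lambda trends.

    The Lambdas inherit temperature dependence both from the linear
    lambda(T) lines and from the molar-volume ratio V2(T)/V1(T).
    """
    v1 = molar_volume(component1, T)
    v2 = molar_volume(component2, T)
    lam11 = float(trend.lam12_minus_lam11(T))
    lam22 = float(trend.lam12_minus_lam22(T))
    L12, L21 = lambda_interconvert("to_Lambda", (lam11, lam22), v1, v2, T)
    return wilson_excess_gibbs(x1, L12, L21) * R * T


def gibbs_helmholtz_HE(
    trend: LambdaTrend,
    component1: Component,
    component2: Component,
    x2_grid: Sequence[float],
    T: float,
    dT: float = 5.0,
    HE_fit: RKFit | None = None,
) -> ConsistencyReport:
    """Excess enthalpy from the Gibbs-Helmholtz identity.

    HE(x) = d(GE/T)/d(1/T) at fixed x, evaluated by a central difference
    between T - dT and T + dT with GE rebuilt from the lambda(T) trends and
    the molar-volume interpolation.  Also returns GE(x, T) and
    TSE = HE - GE; optionally attaches the experimental Redlich-Kister HE
    evaluated on the same grid.
    """
    x2 = np.asarray(x2_grid, dtype=float)
    x1 = 1.0 - x2
    t_lo, t_hi = T - dT, T + dT
    g_lo = _wilson_ge_from_trend(trend, component1, component2, x1, t_lo)
    g_hi = _wilson_ge_from_trend(trend, component1, component2, x1, t_hi)
    he = (g_lo / t_lo - g_hi / t_hi) / (1.0 / t_lo - 1.0 / t_hi)
    ge = _wilson_ge_from_trend(trend, component1, component2, x1, T)
    he_exp = None
    if HE_fit is not None:
        he_exp = np.atleast_1d(eval_redlich_kister(HE_fit, x1))
    return ConsistencyReport(
        T=T,
        x2=x2,
        GE=np.atleast_1d(ge),
        HE_gibbs_helmholtz=np.atleast_1d(he),
        TSE=np.atleast_1d(he - ge),
        HE_experimental=he_exp,
    )
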