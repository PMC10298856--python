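"""Wilson activity model and Barker reduction of isothermal P-x data.

Barker's method regresses an excess-Gibbs model directly on total-pressure
measurements: vapor compositions are never measured, only computed.  Here
the liquid phase is described by the two-parameter Wilson equation

    GE/RT = -x1 ln(x1 + L12 x2) - x2 ln(x2 + L21 x1)

and the vapor phase is corrected for nonideality through the second virial
coefficients (factors R1, R2 below).  The Wilson parameters L12, L21 combine
the molar-volume ratio with interaction-energy differences lam_ij - lam_ii
via L_ij = (Vj0/Vi0) exp(-(lam_ij - lam_ii)/RT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import R
from .pure_components import Component, molar_volume, std_deviation, virial_cross_and_delta

__all__ = [
    "IsothermalPxDataset",
    "WilsonFit",
    "LambdaTrend",
    "wilson_excess_gibbs",
    "wilson_activity",
    "lambda_interconvert",
    "barker_pressure",
    "fit_isotherm_barker",
    "fit_lambda_trend",
]


# ---------------------------------------------------------------------------
# Wilson model
# ---------------------------------------------------------------------------

def wilson_excess_gibbs(x1, Lambda12: float, Lambda21: float):
    """Dimensionless excess Gibbs energy GE/RT of the Wilson model.

    Exactly zero at both pure limits and for L12 = L21 = 1 (ideal solution).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = 1.0 - x1
    g = -x1 * np.log(x1 + Lambda12 * x2) - x2 * np.log(x2 + Lambda21 * x1)
    return float(g) if g.ndim == 0 else g


def wilson_activity(x1, Lambda12: float, Lambda21: float):
    """Activity coefficients (gamma1, gamma2) from the Wilson model.

    Obtained by differentiation of the excess Gibbs energy; satisfies
    x1 ln g1 + x2 ln g2 = GE/RT identically and gamma_i -> 1 in the pure-i
    limit.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = 1.0 - x1
    d1 = x1 + Lambda12 * x2
    d2 = x2 + Lambda21 * x1
    bracket = Lambda12 / d1 - Lambda21 / d2
    ln_g1 = -np.log(d1) + x2 * bracket
    ln_g2 = -np.log(d2) - x1 * bracket
    g1, g2 = np.exp(ln_g1), np.exp(ln_g2)
    if g1.ndim == 0:
        return float(g1), float(g2)
    return g1, g2


def lambda_interconvert(
    direction: str,
    values: tuple[float, float],
    V1: float,
    V2: float,
    T: float,
) -> tuple[float, float]:
    """Convert between (L12, L21) and (lam12-lam11, lam12-lam22).

    ``direction`` is ``"to_lambda"`` (Wilson Lambdas in, J/mol energy
    differences out) or ``"to_Lambda"`` (inverse).  Uses
    L12 = (V2/V1) exp(-(lam12-lam11)/RT), L21 = (V1/V2) exp(-(lam12-lam22)/RT)
    with the symmetric convention lam21 = lam12; the round trip is exact.
    """
    rt = R * T
    if direction == "to_lambda":
        L12, L21 = values
        lam12_11 = -rt * np.log(L12 * V1 / V2)
        lam12_22 = -rt * np.log(L21 * V2 / V1)
        return float(lam12_11), float(lam12_22)
    if direction == "to_Lambda":
        lam12_11, lam12_22 = values
        L12 = (V2 / V1) * np.exp(-lam12_11 / rt)
        L21 = (V1 / V2) * np.exp(-lam12_22 / rt)
        return float(L12), float(L21)
    raise ValueError("direction must be 'to_lambda' or 'to_Lambda'")


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

@dataclass
class IsothermalPxDataset:
    """One isotherm of total-pressure measurements for the binary pair.

    ``x2`` is the liquid mole fraction of component 2 (1,8-cineole),
    strictly increasing; pure pressures and molar volumes are the values at
    this temperature; B11/B22 are the (temperature-independent) second
    virial coefficients, from which B12 and delta12 follow by the cubic
    Lorenz rule.
    """

    T: float
    x2: np.ndarray
    P: np.ndarray
    P1_0: float
    P2_0: float
    V1_0: float
    V2_0: float
    B11: float
    B22: float

    def __post_init__(self) -> None:
        self.x2 = np.asarray(self.x2, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.x2.shape != self.P.shape:
            raise ValueError("x2 and P must have the same length")
        if np.any((self.x2 <= 0) | (self.x2 >= 1)):
            raise ValueError("x2 must lie strictly inside (0, 1)")
        if np.any(np.diff(self.x2) <= 0):
            raise ValueError("x2 must be strictly increasing")
        lo = min(self.P1_0, self.P2_0)
        hi = max(self.P1_0, self.P2_0) * 1.5
        if np.any((self.P < lo) | (self.P > hi)):
            raise ValueError("pressures outside the sanity band for this isotherm")

    @property
    def x1(self) -> np.ndarray:
        return 1.0 - self.x2

    @property
    def virials(self) -> tuple[float, float, float]:
        b12, _ = virial_cross_and_delta(self.B11, self.B22)
        return self.B11, self.B22, b12

    @classmethod
    def from_components(
        cls,
        T: float,
        x2,
        P,
        component1: Component,
        component2: Component,
        P1_0: float,
        P2_0: float,
    ) -> "IsothermalPxDataset":
        return cls(
            T=T,
            x2=x2,
            P=P,
            P1_0=P1_0,
            P2_0=P2_0,
            V1_0=molar_volume(component1, T),
            V2_0=molar_volume(component2, T),
            B11=component1.B_ref,
            B22=component2.B_ref,
        )


@dataclass
class WilsonFit:
    """Result of a Barker reduction of one isotherm."""

    T: float
    Lambda12: float
    Lambda21: float
    s: float                       # Pa, Eq.-2 with n = 2
    lam12_minus_lam11: float       # J/mol
    lam12_minus_lam22: float       # J/mol
    x2: np.ndarray
    P_exp: np.ndarray
    P_calc: np.ndarray
    deltaP: np.ndarray             # P_exp - P_calc
    gamma1: np.ndarray
    gamma2: np.ndarray
    GE: np.ndarray                 # J/mol
    y1: np.ndarray
    n_obj_evals: int = 0

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "x2": self.x2,
                "P_exp_Pa": self.P_exp,
                "P_calc_Pa": self.P_calc,
                "dP_Pa": self.deltaP,
                "gamma1": self.gamma1,
                "gamma2": self.gamma2,
                "GE_J_mol": self.GE,
                "y1": self.y1,
            }
        )


@dataclass
class LambdaTrend:
    """Linear temperature trends of the Wilson energy differences."""

    slope_12_11: float
    intercept_12_11: float
    slope_12_22: float
    intercept_12_22: float
    T_fitted: np.ndarray = field(default_factory=lambda: np.empty(0))

    def lam12_minus_lam11(self, T):
        return self.intercept_12_11 + self.slope_12_11 * np.asarray(T, dtype=float)

    def lam12_minus_lam22(self, T):
        return self.intercept_12_22 + self.slope_12_22 * np.asarray(T, dtype=float)


# ---------------------------------------------------------------------------
# Barker pressure and regression
# ---------------------------------------------------------------------------

def barker_pressure(
    x1,
    T: float,
    Lambda12: float,
    Lambda21: float,
    pure: tuple[float, float, float, float],
    virials: tuple[float, float, float],
    tol: float = 0.01,
    max_iter: int = 200,
):
    """Total pressure and vapor composition from the Wilson/virial model.

    Solves the fixed point of

        P = x1 g1 P1_0 R1 + x2 g2 P2_0 R2
        R1 = exp{[(V1_0 - B11)(P - P1_0) - P d12 y2^2] / RT}
        R2 = exp{[(V2_0 - B22)(P - P2_0) - P d12 y1^2] / RT}
        y1 = x1 g1 P1_0 R1 / P

    starting from R1 = R2 = 1, to within ``tol`` Pa on P.  With all B = 0
    and V0 = 0 the corrections vanish and the expression reduces to the
    modified Raoult law.  Accepts scalar or array x1 (iterated pointwise in
    vectorized form).
    """
    x1 = np.atleast_1d(np.asarray(x1, dtype=float))
    scalar = x1.size == 1
    x2 = 1.0 - x1
    P1_0, P2_0, V1_0, V2_0 = pure
    B11, B22, B12 = virials
    d12 = 2.0 * B12 - B11 - B22
    rt = R * T

    g1, g2 = wilson_activity(x1, Lambda12, Lambda21)
    g1, g2 = np.atleast_1d(g1), np.atleast_1d(g2)

    part1 = x1 * g1 * P1_0
    part2 = x2 * g2 * P2_0
    P = part1 + part2  # R = 1 start
    y1 = np.where(P > 0, part1 / np.where(P > 0, P, 1.0), x1)
    for _ in range(max_iter):
        y2 = 1.0 - y1
        r1 = np.exp(((V1_0 - B11) * (P - P1_0) - P * d12 * y2**2) / rt)
        r2 = np.exp(((V2_0 - B22) * (P - P2_0) - P * d12 * y1**2) / rt)
        P_new = part1 * r1 + part2 * r2
        y1 = np.where(P_new > 0, part1 * r1 / np.where(P_new > 0, P_new, 1.0), x1)
        if np.max(np.abs(P_new - P)) < tol:
            P = P_new
            break
        P = P_new
    else:
        raise RuntimeError(
            f"Barker pressure iteration did not reach {tol} Pa in {max_iter} steps "
            f"(last residual {np.max(np.abs(P_new - P)):.3g} Pa)"
        )
    if scalar:
        return float(P[0]), float(y1[0])
    return P, y1


def fit_isotherm_barker(
    dataset: IsothermalPxDataset,
    x0: tuple[float, float] = (0.5, 0.5),
    vapor_correction: bool = True,
) -> WilsonFit:
    """Barker reduction: (L12, L21) minimizing the squared pressure misfit.

    The objective is the unweighted sum of (P_exp - P_calc)^2 with the full
    vapor-corrected pressure inside; the reported standard deviation uses
    n = 2 adjusted parameters.  A warning is issued when either Lambda
    leaves the physically plausible band (0.05, 20).
    """
    if dataset.x2.size < 4:
        raise ValueError("need at least 4 points to fit two Wilson parameters")
    pure = (dataset.P1_0, dataset.P2_0, dataset.V1_0, dataset.V2_0)
    virials = dataset.virials if vapor_correction else (0.0, 0.0, 0.0)
    if not vapor_correction:
        pure = (dataset.P1_0, dataset.P2_0, 0.0, 0.0)
    x1 = dataset.x1

    def resid(params):
        L12, L21 = params
        if L12 <= 0 or L21 <= 0:
            return np.full(dataset.P.shape, 1e6)
        p_calc, _ = barker_pressure(x1, dataset.T, L12, L21, pure, virials)
        return dataset.P - p_calc

    sol = least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    if not sol.success:
        raise RuntimeError(f"Barker fit failed after {sol.nfev} evaluations: {sol.message}")
    L12, L21 = map(float, sol.x)
    if not (0.05 < L12 < 20.0 and 0.05 < L21 < 20.0):
        warnings.warn(
            f"Wilson parameters outside the plausible band: L12={L12:.4g}, L21={L21:.4g}",
            stacklevel=2,
        )

    p_calc, y1 = barker_pressure(x1, dataset.T, L12, L21, pure, virials)
    g1, g2 = wilson_activity(x1, L12, L21)
    ge = wilson_excess_gibbs(x1, L12, L21) * R * dataset.T
    lam12_11, lam12_22 = lambda_interconvert(
        "to_lambda", (L12, L21), dataset.V1_0, dataset.V2_0, dataset.T
    )
    return WilsonFit(
        T=dataset.T,
        Lambda12=L12,
        Lambda21=L21,
        s=std_deviation(dataset.P - p_calc, 2),
        lam12_minus_lam11=lam12_11,
        lam12_minus_lam22=lam12_22,
        x2=dataset.x2.copy(),
        P_exp=dataset.P.copy(),
        P_calc=p_calc,
        deltaP=dataset.P - p_calc,
        gamma1=np.atleast_1d(g1),
        gamma2=np.atleast_1d(g2),
        GE=np.atleast_1d(ge),
        y1=np.atleast_1d(y1),
        n_obj_evals=int(sol.nfev),
    )


def fit_lambda_trend(fits: list[WilsonFit]) -> LambdaTrend:
    """Ordinary least-squares line of each lambda difference against T."""
    if len(fits) < 3:
        raise ValueError("need at least 3 isotherms for a temperature trend")
    T = np.array([f.T for f in fits])
    l11 = np.array([f.lam12_minus_lam11 for f in fits])
    l22 = np.array([f.lam12_minus_lam22 for f in fits])
    s11, i11 = np.polyfit(T, l11, 1)
    s22, i22 = np.polyfit(T, l22, 1)
    return LambdaTrend(
        slope_12_11=float(s11),
        intercept_12_11=float(i11),
        slope_12_22=float(s22),
        intercept_12_22=float(i22),
        T_fitted=T,
    )
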