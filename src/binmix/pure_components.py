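"""Pure-component data model and low-level thermophysical plumbing.

This module holds the :class:`Component` container (critical constants,
molar-volume table, Antoine constants, second virial coefficient and the
per-equation-of-state parameter blocks), the Antoine vapor-pressure
correlation with its nonlinear refit, linear molar-volume interpolation, and
the cross second-virial combination rule used in the vapor-phase correction
of the Barker reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import KPA, R


class ExtrapolationWarning(UserWarning):
    """Raised when a molar volume is linearly extrapolated beyond the table."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AntoineConstants:
    """Constants of ln(P/kPa) = A - B/(T/K - C).

    The ln-based kPa form is the convention used for the bundled 2-propanol
    correlation; ``antoine_pressure`` converts to Pa.
    """

    A: float
    B: float  # K
    C: float  # K
    pressure_unit: str = "kPa"

    def __post_init__(self) -> None:
        if self.B < 0:
            raise ValueError("Antoine B must be non-negative")
        if self.pressure_unit != "kPa":
            raise ValueError("only the kPa-based form is supported")


@dataclass
class Component:
    """One pure chemical with every parameter the pipeline needs.

    ``molar_volume_table`` rows are (T/K, V0 in m3/mol), strictly increasing
    in T.  ``B_ref`` is the second virial coefficient (m3/mol, negative) at
    the reference temperature of the vapor-phase thermostat.  ``cubic_params``
    maps "PRM"/"PRSV" to dicts with the alpha-function parameter (``p1`` or
    ``kappa1``) and the Peneloux ``c_over_b`` ratio; ``saft_params`` carries
    the segment number ``m``, segment volume ``v00`` (L/mol), segment energy
    ``u0_over_k`` (K), the square-well temperature constant ``e_over_k`` (K)
    and, for self-associating species, ``kappa_AB`` and ``eps_AB_over_k``.
    """

    name: str
    molar_mass: float           # g/mol
    Tc: float                   # K
    Pc: float                   # MPa
    omega: float
    Tb: float                   # K (informational)
    molar_volume_table: np.ndarray  # shape (n, 2): T/K, V0 m3/mol
    antoine: AntoineConstants | None = None
    B_ref: float | None = None  # m3/mol at T_ref
    T_ref: float = 325.0
    cubic_params: dict = field(default_factory=dict)
    saft_params: dict | None = None

    def __post_init__(self) -> None:
        self.molar_volume_table = np.asarray(self.molar_volume_table, dtype=float)
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")
        if not (self.Tc > self.Tb > 0):
            raise ValueError("require Tc > Tb > 0")
        if self.Pc <= 0:
            raise ValueError("Pc must be positive")
        tab = self.molar_volume_table
        if tab.ndim != 2 or tab.shape[1] != 2:
            raise ValueError("molar_volume_table must be (n, 2)")
        if np.any(np.diff(tab[:, 0]) <= 0):
            raise ValueError("molar_volume_table temperatures must increase")
        if np.any(tab[:, 1] <= 0):
            raise ValueError("molar volumes must be positive")
        sp = self.saft_params
        if sp is not None:
            if sp["m"] < 1 or sp["v00"] <= 0 or sp["u0_over_k"] <= 0:
                raise ValueError("invalid SAFT segment parameters")
            if not (0.0 <= sp.get("kappa_AB", 0.0) < 1.0):
                raise ValueError("kappa_AB must lie in [0, 1)")
            if sp.get("eps_AB_over_k", 0.0) < 0:
                raise ValueError("eps_AB_over_k must be non-negative")


@dataclass
class AntoineFitResult:
    constants: AntoineConstants
    s: float                 # Eq.-2 standard deviation, Pa
    residuals: np.ndarray    # P_exp - P_calc, Pa
    max_residual: float      # Pa (absolute value)
    T_max_residual: float    # K
    objective: str
    n_iterations: int


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def antoine_pressure(constants: AntoineConstants, T):
    """Vapor pressure in Pa from ln(P/kPa) = A - B/(T - C).

    Raises ``ValueError`` when any T lies at or below the pole T = C.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= constants.C):
        raise ValueError(f"T must exceed the Antoine pole C = {constants.C} K")
    p = np.exp(constants.A - constants.B / (T - constants.C)) * KPA
    return float(p) if p.ndim == 0 else p


def std_deviation(residuals: Sequence[float], n_params: int) -> float:
    """Root of SSE/(N - n): the standard deviation of a fit.

    N is the number of residuals and n the number of adjusted parameters;
    undefined (ValueError) when N <= n.
    """
    r = np.asarray(residuals, dtype=float)
    n_obs = r.size
    if n_obs <= n_params:
        raise ValueError(f"need more residuals ({n_obs}) than parameters ({n_params})")
    return float(np.sqrt(np.sum(r * r) / (n_obs - n_params)))


def fit_antoine(
    T_points: Sequence[float],
    P_points: Sequence[float],
    objective: Literal["lnp", "pressure"] = "lnp",
    x0: tuple[float, float, float] | None = None,
) -> AntoineFitResult:
    """Nonlinear least-squares Antoine fit.

    The default objective minimizes squared deviations in ln P, the usual
    choice for a vapor-pressure correlation spanning an order of magnitude
    (it weights the data evenly on the relative scale, and it is the
    objective that reproduces the bundled 2-propanol correlation from its
    source data); the ``"pressure"`` alternative minimizes absolute Pa
    deviations instead.  The returned ``s`` always uses the pressure
    residuals (Pa) with n = 3 adjusted parameters.
    """
    T = np.asarray(T_points, dtype=float)
    P = np.asarray(P_points, dtype=float)
    if T.size < 4:
        raise ValueError("at least 4 points are required for a 3-parameter fit")
    if np.unique(T).size != T.size:
        raise ValueError("temperatures must be distinct")
    if np.any(P <= 0):
        raise ValueError("pressures must be positive")

    if x0 is None:
        # Two-point Clausius-Clapeyron start with C = 0.
        lnp = np.log(P / KPA)
        slope = (lnp[-1] - lnp[0]) / (1.0 / T[-1] - 1.0 / T[0])
        x0 = (lnp[-1] - slope / T[-1], -slope, 0.0)

    def model(params):
        a, b, c = params
        return np.exp(a - b / (T - c)) * KPA

    def resid(params):
        p_calc = model(params)
        if objective == "pressure":
            return P - p_calc
        return np.log(P) - np.log(p_calc)

    sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise RuntimeError(
            f"Antoine fit did not converge after {sol.nfev} evaluations: {sol.message}"
        )
    constants = AntoineConstants(*map(float, sol.x))
    residuals = P - model(sol.x)
    s = std_deviation(residuals, 3)
    imax = int(np.argmax(np.abs(residuals)))
    return AntoineFitResult(
        constants=constants,
        s=s,
        residuals=residuals,
        max_residual=float(abs(residuals[imax])),
        T_max_residual=float(T[imax]),
        objective=objective,
        n_iterations=int(sol.nfev),
    )


def molar_volume(
    component: Component, T: float, return_flag: bool = False
) -> float | tuple[float, bool]:
    """Pure liquid molar volume (m3/mol) by linear interpolation in T.

    Linear extrapolation is allowed up to 5 K beyond either end of the table
    and is flagged (``ExtrapolationWarning``, and ``True`` in the optional
    flag); beyond that band a ValueError is raised.
    """
    tab = component.molar_volume_table
    t_min, t_max = tab[0, 0], tab[-1, 0]
    if not (t_min - 5.0 <= T <= t_max + 5.0):
        raise ValueError(
            f"T = {T} K outside the tabulated range [{t_min}, {t_max}] K (+/- 5 K)"
        )
    extrapolated = not (t_min <= T <= t_max)
    if extrapolated:
        # np.interp clips; extend linearly from the terminal segment instead.
        if T < t_min:
            t0, v0 = tab[0]
            t1, v1 = tab[1]
        else:
            t0, v0 = tab[-2]
            t1, v1 = tab[-1]
        v = v0 + (v1 - v0) * (T - t0) / (t1 - t0)
        warnings.warn(
            f"molar volume of {component.name} extrapolated to {T} K",
            ExtrapolationWarning,
            stacklevel=2,
        )
    else:
        v = float(np.interp(T, tab[:, 0], tab[:, 1]))
    if return_flag:
        return float(v), extrapolated
    return float(v)


def virial_cross_and_delta(B11: float, B22: float) -> tuple[float, float]:
    """Cross second virial coefficient and delta12.

    B12 = (1/8) (B11^(1/3) + B22^(1/3))^3 with signed cube roots (the cubic
    Lorenz combination rule), and delta12 = 2 B12 - B11 - B22, the group that
    enters the vapor-phase corrections of the Barker pressure.
    """
    b12 = 0.125 * (np.cbrt(B11) + np.cbrt(B22)) ** 3
    delta12 = 2.0 * b12 - B11 - B22
    return float(b12), float(delta12)
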