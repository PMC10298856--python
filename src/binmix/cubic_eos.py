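"""Peng-Robinson-family cubic equations of state.

Two alpha-function variants are implemented on the same Peng-Robinson
repulsion/attraction skeleton:

* PRM  - Mathias's polar extension,
  sqrt(alpha) = 1 + kappa_PR(omega) (1 - sqrt(Tr)) - p1 (1 - Tr)(0.7 - Tr),
  with kappa_PR = 0.37464 + 1.54226 w - 0.26992 w^2 and a per-component
  polar parameter p1;
* PRSV - the Stryjek-Vera form,
  sqrt(alpha) = 1 + kappa (1 - sqrt(Tr)),
  kappa = kappa0 + kappa1 (1 + sqrt(Tr)) (0.7 - Tr),
  kappa0 = 0.378893 + 1.4897153 w - 0.17131848 w^2 + 0.0196554 w^3.

Both can be combined with the Peneloux volume translation (a constant,
composition-linear shift c of the molar volume that improves liquid
densities but cancels exactly in the fugacity-equality conditions, so all
equilibrium pressures and vapor compositions are unchanged).  Mixtures use
van der Waals one-fluid mixing with a single, temperature-dependent binary
interaction parameter k12(T) = a + b T + c T^2 on the cross energy term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .constants import R
from .pure_components import Component

__all__ = [
    "OMEGA_A",
    "OMEGA_B",
    "CubicModelSpec",
    "PhaseResult",
    "alpha_function",
    "pure_saturation_pressure",
    "fit_pure_alpha_param",
    "mixture_parameters",
    "bubble_point",
    "fit_kij",
    "aad_percent",
]

OMEGA_A = 0.457235
OMEGA_B = 0.077796

SQRT2 = np.sqrt(2.0)

Variant = Literal["PRM", "PRSV"]


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass
class CubicModelSpec:
    """A cubic EoS applied to the binary pair.

    ``alpha_params`` and ``c_over_b`` are per-component; ``kij_coeffs`` are
    the (a, b, c) of the quadratic k12(T); ``mathias_sign`` fixes the sign
    convention of the polar term (the shipped default subtracts
    p1 (1-Tr)(0.7-Tr) from sqrt(alpha), validated against the bundled pure
    vapor pressures).
    """

    variant: Variant
    components: tuple[Component, Component]
    use_translation: bool = True
    kij_coeffs: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mathias_sign: float = -1.0

    def alpha_param(self, i: int) -> float:
        p = self.components[i].cubic_params[self.variant]
        return p["p1"] if self.variant == "PRM" else p["kappa1"]

    def c_over_b(self, i: int) -> float:
        return self.components[i].cubic_params[self.variant]["c_over_b"]

    def kij(self, T: float) -> float:
        a, b, c = self.kij_coeffs
        return a + b * T + c * T * T


@dataclass
class PhaseResult:
    """Converged bubble-point state."""

    P: float                 # Pa
    y1: float
    v_liquid: float          # m3/mol (translated when enabled)
    v_vapor: float           # m3/mol
    phi_liquid: np.ndarray
    phi_vapor: np.ndarray
    iterations: int


# ---------------------------------------------------------------------------
# Pure-component building blocks
# ---------------------------------------------------------------------------

def kappa_pr(omega: float) -> float:
    return 0.37464 + 1.54226 * omega - 0.26992 * omega**2


def kappa0_prsv(omega: float) -> float:
    return 0.378893 + 1.4897153 * omega - 0.17131848 * omega**2 + 0.0196554 * omega**3


def alpha_function(
    variant: Variant,
    T: float,
    Tc: float,
    omega: float,
    alpha_param: float,
    mathias_sign: float = -1.0,
) -> float:
    """Temperature function alpha(T) of the attraction parameter; 1 at Tc."""
    tr = T / Tc
    sqrt_tr = np.sqrt(tr)
    if variant == "PRM":
        root = 1.0 + kappa_pr(omega) * (1.0 - sqrt_tr) \
            + mathias_sign * alpha_param * (1.0 - tr) * (0.7 - tr)
    elif variant == "PRSV":
        kappa = kappa0_prsv(omega) + alpha_param * (1.0 + sqrt_tr) * (0.7 - tr)
        root = 1.0 + kappa * (1.0 - sqrt_tr)
    else:
        raise ValueError(f"unknown cubic variant {variant!r}")
    if root < 0:
        warnings.warn(f"negative sqrt(alpha) at T={T} K for {variant}", stacklevel=2)
    return float(root * root)


def _ab_pure(spec: CubicModelSpec, i: int, T: float) -> tuple[float, float]:
    comp = spec.components[i]
    pc = comp.Pc * 1e6  # MPa -> Pa
    alpha = alpha_function(
        spec.variant, T, comp.Tc, comp.omega, spec.alpha_param(i), spec.mathias_sign
    )
    a = OMEGA_A * alpha * (R * comp.Tc) ** 2 / pc
    b = OMEGA_B * R * comp.Tc / pc
    return a, b


def _c_pure(spec: CubicModelSpec, i: int) -> float:
    comp = spec.components[i]
    b = OMEGA_B * R * comp.Tc / (comp.Pc * 1e6)
    return spec.c_over_b(i) * b


# ---------------------------------------------------------------------------
# Cubic solution and fugacities (untranslated variables; the Peneloux shift
# is applied to reported volumes only, since it cancels in phase equilibrium)
# ---------------------------------------------------------------------------

def _z_roots(A: float, B: float) -> np.ndarray:
    """Real compressibility roots of the Peng-Robinson cubic with Z > B."""
    coeffs = [1.0, -(1.0 - B), A - 3.0 * B * B - 2.0 * B, -(A * B - B * B - B**3)]
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-10].real
    return np.sort(real[real > B])


def _ln_phi_pure(Z: float, A: float, B: float) -> float:
    return (
        Z - 1.0
        - np.log(Z - B)
        - A / (2.0 * SQRT2 * B)
        * np.log((Z + (1.0 + SQRT2) * B) / (Z + (1.0 - SQRT2) * B))
    )


def pure_saturation_pressure(
    spec: CubicModelSpec, i: int, T: float, P_init: float | None = None
) -> tuple[float, float, float]:
    """Saturation pressure and coexisting molar volumes of component i.

    Solves the equal-fugacity condition on the smallest/largest cubic
    volume roots by successive substitution P <- P * phiL/phiV.  Returns
    (Psat/Pa, vL, vV) with volumes translated when enabled; the translation
    leaves Psat itself unchanged.
    """
    comp = spec.components[i]
    if T >= comp.Tc:
        raise ValueError("saturation undefined at or above Tc")
    a, b = _ab_pure(spec, i, T)

    if P_init is None:
        # Wilson-type reduced-pressure guess from the acentric factor.
        P_init = comp.Pc * 1e6 * np.exp(
            5.373 * (1.0 + comp.omega) * (1.0 - comp.Tc / T)
        )
    P = float(P_init)
    for _ in range(200):
        A = a * P / (R * T) ** 2
        B = b * P / (R * T)
        roots = _z_roots(A, B)
        if roots.size < 2:
            # single-root region: nudge the pressure toward two-phase
            P *= 0.5 if roots.size and roots[0] > 3.0 * B else 2.0
            continue
        zl, zv = roots[0], roots[-1]
        ratio = np.exp(_ln_phi_pure(zl, A, B) - _ln_phi_pure(zv, A, B))
        P_new = P * ratio
        if abs(P_new - P) < 1e-9 * P:
            P = P_new
            break
        P = P_new
    else:
        raise RuntimeError(f"pure saturation solve did not converge at T={T} K")
    A = a * P / (R * T) ** 2
    B = b * P / (R * T)
    roots = _z_roots(A, B)
    vl = roots[0] * R * T / P
    vv = roots[-1] * R * T / P
    if spec.use_translation:
        c = _c_pure(spec, i)
        vl -= c
        vv -= c
    return float(P), float(vl), float(vv)


def fit_pure_alpha_param(
    variant: Variant,
    component: Component,
    T_points: Sequence[float],
    P_points: Sequence[float],
    bracket: tuple[float, float] = (-1.0, 1.0),
) -> float:
    """Regress the single alpha-function parameter (p1 or kappa1) against
    pure saturation pressures, minimizing the relative pressure misfit."""
    T_points = np.asarray(T_points, dtype=float)
    P_points = np.asarray(P_points, dtype=float)
    if T_points.size < 5:
        raise ValueError("need at least 5 saturation points")

    base = {"name": component.name, "Tc": component.Tc, "Pc": component.Pc,
            "omega": component.omega}

    def objective(param: float) -> float:
        comp = _component_with_param(component, variant, param)
        spec = CubicModelSpec(variant, (comp, comp), use_translation=False)
        sse = 0.0
        for t, p in zip(T_points, P_points):
            try:
                psat, _, _ = pure_saturation_pressure(spec, 0, t, P_init=p)
            except RuntimeError:
                return 1e6
            sse += ((psat - p) / p) ** 2
        return sse

    res = minimize_scalar(objective, bounds=bracket, method="bounded",
                          options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"alpha-parameter fit failed: {res.message}")
    return float(res.x)


def _component_with_param(component: Component, variant: Variant, param: float) -> Component:
    import copy

    comp = copy.copy(component)
    comp.cubic_params = dict(component.cubic_params)
    key = "p1" if variant == "PRM" else "kappa1"
    block = dict(component.cubic_params.get(variant, {"c_over_b": 0.0}))
    block[key] = param
    comp.cubic_params[variant] = block
    return comp


# ---------------------------------------------------------------------------
# Mixtures
# ---------------------------------------------------------------------------

def mixture_parameters(
    spec: CubicModelSpec, x: Sequence[float], T: float
) -> tuple[float, float, float]:
    """van der Waals one-fluid (a_mix, b_mix, c_mix) at composition x.

    a_mix = sum_ij x_i x_j (1 - k_ij) sqrt(a_i a_j) with k12(T) from the
    quadratic trend; b and the translation c mix linearly.
    """
    x = np.asarray(x, dtype=float)
    if not np.isclose(x.sum(), 1.0):
        raise ValueError("mole fractions must sum to 1")
    a = np.array([_ab_pure(spec, i, T)[0] for i in range(2)])
    b = np.array([_ab_pure(spec, i, T)[1] for i in range(2)])
    kij = spec.kij(T)
    K = np.array([[0.0, kij], [kij, 0.0]])
    sq = np.sqrt(np.outer(a, a))
    a_mix = float(x @ ((1.0 - K) * sq) @ x)
    b_mix = float(x @ b)
    c_mix = float(sum(x[i] * _c_pure(spec, i) for i in range(2)))
    return a_mix, b_mix, c_mix


def _ln_phi_mix(
    spec: CubicModelSpec, x: np.ndarray, T: float, P: float, phase: str
) -> tuple[np.ndarray, float]:
    """Component fugacity coefficients and compressibility of one phase."""
    a = np.array([_ab_pure(spec, i, T)[0] for i in range(2)])
    b = np.array([_ab_pure(spec, i, T)[1] for i in range(2)])
    kij = spec.kij(T)
    K = np.array([[0.0, kij], [kij, 0.0]])
    sq = np.sqrt(np.outer(a, a)) * (1.0 - K)
    a_mix = float(x @ sq @ x)
    b_mix = float(x @ b)
    A = a_mix * P / (R * T) ** 2
    B = b_mix * P / (R * T)
    roots = _z_roots(A, B)
    if roots.size == 0:
        raise RuntimeError("no physical compressibility root")
    Z = roots[0] if phase == "liquid" else roots[-1]
    sum_xa = sq @ x  # sum_j x_j (1-kij) sqrt(ai aj)
    ln_phi = (
        b / b_mix * (Z - 1.0)
        - np.log(Z - B)
        - A / (2.0 * SQRT2 * B)
        * (2.0 * sum_xa / a_mix - b / b_mix)
        * np.log((Z + (1.0 + SQRT2) * B) / (Z + (1.0 - SQRT2) * B))
    )
    return ln_phi, float(Z)


def bubble_point(
    spec: CubicModelSpec,
    T: float,
    x1: float,
    P_init: float | None = None,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PhaseResult:
    """Bubble pressure and incipient vapor composition at (T, x).

    Outer successive substitution on (P, y): K_i = phiL_i/phiV_i,
    y_i = x_i K_i, P <- P sum_i x_i K_i, until the K-sum residual and the
    pressure are converged.  Vapor and liquid volumes are reported with the
    Peneloux shift applied when translation is enabled.
    """
    if not (0.0 < x1 < 1.0):
        raise ValueError("x1 must be interior")
    x = np.array([x1, 1.0 - x1])
    if P_init is None:
        psat = [pure_saturation_pressure(spec, i, T)[0] for i in range(2)]
        P = float(x @ psat)
        y = x * psat / P
    else:
        P = float(P_init)
        y = x.copy()
    it = 0
    for it in range(1, max_iter + 1):
        ln_phi_l, Zl = _ln_phi_mix(spec, x, T, P, "liquid")
        ln_phi_v, Zv = _ln_phi_mix(spec, y / y.sum(), T, P, "vapor")
        if abs(Zl - Zv) < 1e-12:
            raise RuntimeError("trivial-root collapse: liquid and vapor states identical")
        Kf = np.exp(ln_phi_l - ln_phi_v)
        y_new = x * Kf
        S = float(y_new.sum())
        P_new = P * S
        if abs(S - 1.0) < tol and abs(P_new - P) < max(1e-8, 1e-12 * P):
            P, y = P_new, y_new / S
            break
        P, y = P_new, y_new / S
    else:
        raise RuntimeError(f"bubble point did not converge in {max_iter} iterations")
    ln_phi_l, Zl = _ln_phi_mix(spec, x, T, P, "liquid")
    ln_phi_v, Zv = _ln_phi_mix(spec, y, T, P, "vapor")
    vl = Zl * R * T / P
    vv = Zv * R * T / P
    if spec.use_translation:
        _, _, c_liq = mixture_parameters(spec, x, T)
        _, _, c_vap = mixture_parameters(spec, y, T)
        vl -= c_liq
        vv -= c_vap
    return PhaseResult(
        P=float(P),
        y1=float(y[0]),
        v_liquid=float(vl),
        v_vapor=float(vv),
        phi_liquid=np.exp(ln_phi_l),
        phi_vapor=np.exp(ln_phi_v),
        iterations=it,
    )


# ---------------------------------------------------------------------------
# Correlation against P-x data
# ---------------------------------------------------------------------------

def aad_percent(P_exp: Sequence[float], P_calc: Sequence[float]) -> float:
    """Absolute average percentage deviation (100/N) sum |dP|/P_exp."""
    P_exp = np.asarray(P_exp, dtype=float)
    P_calc = np.asarray(P_calc, dtype=float)
    if P_exp.shape != P_calc.shape:
        raise ValueError("length mismatch")
    if np.any(P_exp <= 0):
        raise ValueError("experimental pressures must be positive")
    return float(100.0 * np.mean(np.abs(P_exp - P_calc) / P_exp))


def _bubble_curve(spec: CubicModelSpec, T: float, x2: np.ndarray) -> np.ndarray:
    out = np.empty_like(x2)
    P_prev = None
    for k, x in enumerate(x2):
        res = bubble_point(spec, T, 1.0 - x, P_init=P_prev)
        out[k] = res.P
        P_prev = res.P
    return out


def fit_kij(
    spec: CubicModelSpec,
    isotherms: Sequence[tuple[float, np.ndarray, np.ndarray]],
    bubble_solver=None,
    bracket: tuple[float, float] = (-0.15, 0.25),
) -> dict:
    """Per-isotherm k12 regression and its quadratic temperature trend.

    ``isotherms`` is a sequence of (T, x2, P_exp).  Each isotherm gets a
    scalar k12 minimizing the relative pressure misfit (pressures span more
    than two decades across the temperature range, so relative deviations
    keep the isotherms commensurate); the per-T values are then fitted with
    k12 = a + b T + c T^2 by ordinary least squares.  ``bubble_solver`` may
    replace the cubic bubble-point routine (signature (spec, T, x2_array) ->
    P_array) so the same machinery can regress k12 for other models.
    """
    if bubble_solver is None:
        bubble_solver = _bubble_curve

    kij_per_T = []
    for T, x2, P_exp in isotherms:
        x2 = np.asarray(x2, dtype=float)
        P_exp = np.asarray(P_exp, dtype=float)

        def objective(k: float) -> float:
            trial = _with_fixed_kij(spec, k)
            try:
                p_calc = bubble_solver(trial, T, x2)
            except RuntimeError:
                return 1e6
            return float(np.sum(((P_exp - p_calc) / P_exp) ** 2))

        res = minimize_scalar(objective, bounds=bracket, method="bounded",
                              options={"xatol": 1e-7})
        if not res.success:
            raise RuntimeError(f"k12 fit failed at T={T}: {res.message}")
        k = float(res.x)
        if abs(k) > 0.3:
            warnings.warn(f"|k12| = {abs(k):.3f} > 0.3 at T={T} K", stacklevel=2)
        kij_per_T.append((T, k))

    if len(kij_per_T) >= 3:
        Ts = np.array([t for t, _ in kij_per_T])
        ks = np.array([k for _, k in kij_per_T])
        c, b, a = np.polyfit(Ts, ks, 2)
        k_fit = a + b * Ts + c * Ts**2
        ss_res = float(np.sum((ks - k_fit) ** 2))
        ss_tot = float(np.sum((ks - ks.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        quad = {"a": float(a), "b": float(b), "c": float(c), "R2": r2}
    else:
        quad = None
    return {"per_isotherm": kij_per_T, "quadratic": quad}


def _with_fixed_kij(spec: CubicModelSpec, k: float) -> CubicModelSpec:
    return CubicModelSpec(
        variant=spec.variant,
        components=spec.components,
        use_translation=spec.use_translation,
        kij_coeffs=(k, 0.0, 0.0),
        mathias_sign=spec.mathias_sign,
    )
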