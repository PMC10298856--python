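"""Original (Huang-Radosz-form) SAFT equation of state.

The residual Helmholtz energy per mole of molecules is the sum of four
contributions,

    a_res/RT = a_hs + a_disp + a_chain + a_assoc,

with square-well segments:

* hard sphere: the Boublik/Mansoori-Carnahan-Starling-Leland (MCSL)
  mixture expression in the partial packing fractions zeta_0..zeta_3
  (reducing to m (4 eta - 3 eta^2)/(1 - eta)^2 for a pure fluid);
* dispersion: m_bar sum_ij D_ij (u/kT)^i (eta/tau)^j with the 24
  Chen-Kreglewski universal constants, tau = 0.74048 and eta = zeta_3;
  the segment energy u/k is averaged with the van der Waals one-fluid
  rule, and the binary parameter k_ij corrects only its cross term;
* chain: sum_i x_i (1 - m_i) ln g_ii(d_ii) with the MCSL pair contact
  value g_ij;
* association: per site, ln X - X/2 (+1/2), with the site fractions X
  from the mass-action law and the association strength built on g_11.

The temperature-dependent segment volume is
v0(T) = v00 [1 - 0.12 exp(-3 u0/kT)]^3 (L/mol of segments), the well depth
u/k = (u0/k)(1 + e/kT) with e/k = 10 K, and the effective segment diameter
follows from N_A d^3 = sqrt(2) v0.  2-propanol associates with the 2B
scheme (one donor + one acceptor, X_A = X_B); 1,8-cineole carries no sites,
so there is no cross-association.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .constants import R
from .datasets import load_saft_dispersion_constants
from .pure_components import Component

__all__ = [
    "SaftParams",
    "SaftState",
    "saft_params_from_component",
    "residual_helmholtz",
    "association_fractions",
    "pressure",
    "density_solver",
    "pure_saturation_pressure_saft",
    "bubble_point_saft",
    "ln_phi_saft",
    "ln_phi_saft_numeric",
    "excess_volume_prediction",
    "saft_liquid_volume",
    "cubic_liquid_volume",
]

TAU = 0.74048
N_AV = 6.02214076e23


@dataclass(frozen=True)
class SaftParams:
    """Pure-component SAFT parameters (Huang-Radosz convention).

    ``m``: segments per molecule; ``v00``: temperature-independent segment
    molar volume, L/mol; ``u0_over_k``: segment energy, K; ``e_over_k``:
    square-well temperature constant, K; ``kappa_AB``/``eps_AB_over_k``:
    association volume and energy of the 2B scheme (zero for a
    non-associating species, which forces all site fractions to 1).
    """

    m: float
    v00: float
    u0_over_k: float
    e_over_k: float = 10.0
    kappa_AB: float = 0.0
    eps_AB_over_k: float = 0.0
    scheme: str = "none"

    @property
    def associating(self) -> bool:
        return self.kappa_AB > 0.0

    def v0(self, T: float) -> float:
        """Temperature-dependent segment volume, m3/mol of segments."""
        return 1e-3 * self.v00 * (1.0 - 0.12 * np.exp(-3.0 * self.u0_over_k / T)) ** 3

    def u_over_k(self, T: float) -> float:
        return self.u0_over_k * (1.0 + self.e_over_k / T)

    def d_segment(self, T: float) -> float:
        """Effective hard-segment diameter (m), from N_A d^3 = sqrt(2) v0."""
        return (np.sqrt(2.0) * self.v0(T) / N_AV) ** (1.0 / 3.0)


def saft_params_from_component(component: Component) -> SaftParams:
    sp = component.saft_params
    if sp is None:
        raise ValueError(f"{component.name} carries no SAFT parameter block")
    return SaftParams(
        m=sp["m"],
        v00=sp["v00"],
        u0_over_k=sp["u0_over_k"],
        e_over_k=sp.get("e_over_k", 10.0),
        kappa_AB=sp.get("kappa_AB", 0.0),
        eps_AB_over_k=sp.get("eps_AB_over_k", 0.0),
        scheme=sp.get("scheme", "none"),
    )


@dataclass
class SaftState:
    """Residual state at (T, rho, x): term-by-term Helmholtz energies
    (dimensionless, per mole of molecules), packing fraction, site
    fractions, and the compressibility factor."""

    T: float
    rho: float              # mol/m3
    x: np.ndarray
    eta: float              # zeta_3
    X: np.ndarray           # site fraction per component (1 for no sites)
    a_hs: float
    a_disp: float
    a_chain: float
    a_assoc: float
    Z: float

    @property
    def a_res(self) -> float:
        return self.a_hs + self.a_disp + self.a_chain + self.a_assoc


# ---------------------------------------------------------------------------
# Geometry and mixing helpers
# ---------------------------------------------------------------------------

def _geometry(params: Sequence[SaftParams], T: float):
    m = np.array([p.m for p in params])
    v = np.array([p.v0(T) for p in params])        # m3/mol segment
    u = np.array([p.u_over_k(T) for p in params])  # K
    d = np.array([p.d_segment(T) for p in params])  # m
    return m, v, u, d


def _zetas(m, d, x, rho):
    """Partial packing fractions zeta_0..zeta_3; rho in mol/m3."""
    rho_n = rho * N_AV
    return np.array(
        [np.pi / 6.0 * rho_n * float(np.sum(x * m * d**k)) for k in range(4)]
    )


def _u_mix(m, v, u, x, kij: float) -> tuple[float, np.ndarray, np.ndarray]:
    """One-fluid segment energy and the quadratic sums it is built from."""
    n = m.size
    K = np.zeros((n, n))
    if n == 2:
        K[0, 1] = K[1, 0] = kij
    vij = ((np.cbrt(v)[:, None] + np.cbrt(v)[None, :]) / 2.0) ** 3
    uij = np.sqrt(np.outer(u, u)) * (1.0 - K)
    w = np.outer(x * m, x * m)
    qv = float(np.sum(w * vij))
    qu = float(np.sum(w * uij * vij))
    return qu / qv, vij, uij


def _hs_F(z: np.ndarray) -> float:
    z0, z1, z2, z3 = z
    one = 1.0 - z3
    return (
        3.0 * z1 * z2 / one
        + z2**3 / (z3 * one**2)
        + (z2**3 / z3**2 - z0) * np.log(one)
    )


def _hs_F_grad(z: np.ndarray) -> np.ndarray:
    z0, z1, z2, z3 = z
    one = 1.0 - z3
    ln1 = np.log(one)
    f0 = -ln1
    f1 = 3.0 * z2 / one
    f2 = 3.0 * z1 / one + 3.0 * z2**2 / (z3 * one**2) + 3.0 * z2**2 / z3**2 * ln1
    f3 = (
        3.0 * z1 * z2 / one**2
        - z2**3 / (z3**2 * one**2)
        + 2.0 * z2**3 / (z3 * one**3)
        - 2.0 * z2**3 / z3**3 * ln1
        - (z2**3 / z3**2 - z0) / one
    )
    return np.array([f0, f1, f2, f3])


def _g_contact(z: np.ndarray, A: float) -> float:
    """MCSL pair contact value; A = d_i d_j / (d_i + d_j)."""
    one = 1.0 - z[3]
    return 1.0 / one + 3.0 * A * z[2] / one**2 + 2.0 * (A * z[2]) ** 2 / one**3


def _g_contact_grad(z: np.ndarray, A: float) -> tuple[float, float]:
    """(dg/dzeta2, dg/dzeta3) of the MCSL contact value."""
    one = 1.0 - z[3]
    dg2 = 3.0 * A / one**2 + 4.0 * A**2 * z[2] / one**3
    dg3 = (
        1.0 / one**2
        + 6.0 * A * z[2] / one**3
        + 6.0 * (A * z[2]) ** 2 / one**4
    )
    return dg2, dg3


# ---------------------------------------------------------------------------
# Association
# ---------------------------------------------------------------------------

def _delta_molar(p: SaftParams, T: float, g11: float) -> float:
    """2B association strength on a molar-volume basis, m3/mol.

    Delta = sqrt(2) v0 g_11 kappa_AB [exp(eps_AB/kT) - 1]; the sqrt(2)
    carries the close-packing geometry linking d^3 to the segment volume.
    """
    return np.sqrt(2.0) * p.v0(T) * g11 * p.kappa_AB * np.expm1(p.eps_AB_over_k / T)


def _closed_form_X(t: float) -> float:
    """2B site fraction for dimensionless rho_a*Delta = t.

    Algebraically (-1 + sqrt(1+4t))/(2t), written in the form that stays
    precise as t -> 0 (no subtractive cancellation).
    """
    return 2.0 / (1.0 + np.sqrt(1.0 + 4.0 * t))


def association_fractions(
    params: Sequence[SaftParams],
    x: Sequence[float],
    T: float,
    rho: float,
    kij: float = 0.0,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> np.ndarray:
    """Fraction of unbonded sites X per component (1 where no sites).

    With a single self-associating 2B component the mass-action law has the
    closed form X = (-1 + sqrt(1 + 4 t))/(2 t) with t = x_a rho Delta; the
    damped successive-substitution solver is retained for generality and is
    verified against the closed form.
    """
    x = np.asarray(x, dtype=float)
    m, v, u, d = _geometry(params, T)
    z = _zetas(m, d, x, rho)
    X = np.ones(len(params))
    for i, p in enumerate(params):
        if not p.associating:
            continue
        A = d[i] / 2.0
        t = x[i] * rho * _delta_molar(p, T, _g_contact(z, A))
        if t <= 0:
            continue
        xi = 1.0
        for _ in range(max_iter):
            xi_next = 0.5 * xi + 0.5 / (1.0 + t * xi)
            if abs(xi_next - xi) < tol:
                xi = xi_next
                break
            xi = xi_next
        else:
            raise RuntimeError(
                f"association solver stalled at t={t:.3g} (last X={xi:.6g})"
            )
        X[i] = xi
    return X


# ---------------------------------------------------------------------------
# Residual Helmholtz energy and pressure
# ---------------------------------------------------------------------------

def residual_helmholtz(
    params: Sequence[SaftParams],
    x: Sequence[float],
    T: float,
    rho: float,
    kij: float = 0.0,
) -> SaftState:
    """All residual terms and the compressibility factor at (T, rho, x).

    ``rho`` is the molar density in mol/m3.  The compressibility factor is
    assembled from the analytic density derivatives of each term; every
    zeta is linear in rho, so rho d/drho = sum_k zeta_k d/dzeta_k.
    """
    x = np.asarray(x, dtype=float)
    D = load_saft_dispersion_constants()
    m, v, u, d = _geometry(params, T)
    z = _zetas(m, d, x, rho)
    eta = float(z[3])
    if not (0.0 < eta < TAU):
        raise ValueError(f"packing fraction {eta:.4f} outside (0, {TAU})")
    rho_n = rho * N_AV
    pref = 6.0 / (np.pi * rho_n)

    F = _hs_F(z)
    Fg = _hs_F_grad(z)
    a_hs = pref * F
    z_hs = pref * (float(z @ Fg) - F)  # rho d(a_hs)/drho

    m_bar = float(x @ m)
    u_mix, _, _ = _u_mix(m, v, u, x, kij)
    ur = u_mix / T
    etar = eta / TAU
    ip = np.arange(1, 5)[:, None]
    jp = np.arange(1, 10)[None, :]
    terms = D * ur**ip * etar**jp
    a_disp = m_bar * float(terms.sum())
    z_disp = m_bar * float((terms * jp).sum())

    a_chain = 0.0
    z_chain = 0.0
    g_ii = np.empty(len(params))
    for i in range(len(params)):
        A = d[i] / 2.0
        g_ii[i] = _g_contact(z, A)
        dg2, dg3 = _g_contact_grad(z, A)
        rho_dlng = (z[2] * dg2 + z[3] * dg3) / g_ii[i]
        a_chain += x[i] * (1.0 - m[i]) * np.log(g_ii[i])
        z_chain += x[i] * (1.0 - m[i]) * rho_dlng

    a_assoc = 0.0
    z_assoc = 0.0
    X = np.ones(len(params))
    for i, p in enumerate(params):
        if not p.associating:
            continue
        A = d[i] / 2.0
        dg2, dg3 = _g_contact_grad(z, A)
        rho_dlng = (z[2] * dg2 + z[3] * dg3) / g_ii[i]
        t = x[i] * rho * _delta_molar(p, T, g_ii[i])
        xi = _closed_form_X(t)
        X[i] = xi
        # 2B: two equivalent sites per molecule
        a_assoc += x[i] * (2.0 * np.log(xi) - xi + 1.0)
        dX_dt = -(xi * xi) / (1.0 + 2.0 * t * xi)
        z_assoc += x[i] * 2.0 * (1.0 / xi - 0.5) * dX_dt * t * (1.0 + rho_dlng)

    Z = 1.0 + z_hs + z_disp + z_chain + z_assoc
    return SaftState(
        T=T, rho=rho, x=x, eta=eta, X=X,
        a_hs=float(a_hs), a_disp=a_disp, a_chain=float(a_chain),
        a_assoc=float(a_assoc), Z=float(Z),
    )


def pressure(params, x, T, rho, kij: float = 0.0) -> float:
    """P(T, rho, x) in Pa from the analytic compressibility factor."""
    state = residual_helmholtz(params, x, T, rho, kij)
    return state.Z * rho * R * T


# ---------------------------------------------------------------------------
# Density solver
# ---------------------------------------------------------------------------

def density_solver(
    params: Sequence[SaftParams],
    x: Sequence[float],
    T: float,
    P: float,
    phase: str,
    kij: float = 0.0,
) -> float:
    """Molar density (mol/m3) solving P_eos(rho) = P on one branch.

    The vapor branch is bracketed upward from the ideal-gas density; the
    liquid branch takes the highest-density crossing below close packing.
    Raises when the branch holds no root at this pressure.
    """
    if P <= 0:
        raise ValueError("P must be positive")
    x = np.asarray(x, dtype=float)
    m, v, u, d = _geometry(params, T)
    s3 = float(np.sum(x * m * v))  # zeta3 = tau * rho * s3 / ... (linear)
    rho_of_eta = lambda eta: eta / (TAU * s3)

    def f(eta: float) -> float:
        return pressure(params, x, T, rho_of_eta(eta), kij) - P

    eta_ig = TAU * (P / (R * T)) * s3
    if phase == "vapor":
        lo = min(1e-14, eta_ig * 1e-3)
        hi = min(max(eta_ig * 3.0, 1e-10), 0.55)
        flo, fhi = f(lo), f(hi)
        tries = 0
        while flo * fhi > 0 and tries < 60 and hi < 0.70:
            hi = min(hi * 1.3, 0.70)
            fhi = f(hi)
            tries += 1
        if flo * fhi > 0:
            raise RuntimeError("no vapor-branch density root")
        eta = brentq(f, lo, hi, xtol=1e-16, rtol=8.9e-16)
    elif phase == "liquid":
        grid = np.linspace(0.70, 1e-4, 240)
        vals = np.array([f(e) for e in grid])
        crossings = np.nonzero(vals[:-1] * vals[1:] <= 0)[0]
        if crossings.size == 0:
            raise RuntimeError("no liquid-branch density root")
        k = crossings[0]
        eta = brentq(f, grid[k + 1], grid[k], xtol=1e-16, rtol=8.9e-16)
    else:
        raise ValueError("phase must be 'vapor' or 'liquid'")
    return float(rho_of_eta(eta))


# ---------------------------------------------------------------------------
# Fugacity coefficients: analytic and numeric routes
# ---------------------------------------------------------------------------

def _dadx_analytic(params, x, T: float, rho: float, kij: float) -> np.ndarray:
    """d(a_res/RT)/dx_i at fixed (T, rho), components unconstrained."""
    x = np.asarray(x, dtype=float)
    D = load_saft_dispersion_constants()
    m, v, u, d = _geometry(params, T)
    n = len(params)
    z = _zetas(m, d, x, rho)
    rho_n = rho * N_AV
    pref = 6.0 / (np.pi * rho_n)
    # dzeta_k/dx_i
    dz = np.array(
        [[np.pi / 6.0 * rho_n * m[i] * d[i] ** k for k in range(4)] for i in range(n)]
    )  # shape (n, 4)

    Fg = _hs_F_grad(z)
    d_hs = pref * dz @ Fg

    m_bar = float(x @ m)
    K = np.zeros((n, n))
    if n == 2:
        K[0, 1] = K[1, 0] = kij
    vij = ((np.cbrt(v)[:, None] + np.cbrt(v)[None, :]) / 2.0) ** 3
    uij = np.sqrt(np.outer(u, u)) * (1.0 - K)
    w = np.outer(x * m, x * m)
    qv = float(np.sum(w * vij))
    qu = float(np.sum(w * uij * vij))
    u_mix = qu / qv
    dqv = 2.0 * m * (vij @ (x * m))
    dqu = 2.0 * m * ((uij * vij) @ (x * m))
    du = (dqu * qv - qu * dqv) / qv**2

    eta = z[3]
    ur = u_mix / T
    etar = eta / TAU
    ip = np.arange(1, 5)[:, None]
    jp = np.arange(1, 10)[None, :]
    terms = D * ur**ip * etar**jp
    s0 = float(terms.sum())
    s_i = float((terms * ip).sum())
    s_j = float((terms * jp).sum())
    deta = dz[:, 3]
    d_disp = m * s0 + m_bar * (s_i / u_mix * du + s_j / eta * deta)

    d_chain = np.zeros(n)
    g_ii = np.empty(n)
    for k in range(n):
        A = d[k] / 2.0
        g_ii[k] = _g_contact(z, A)
        d_chain += (
            x[k] * (1.0 - m[k]) / g_ii[k]
            * (np.array(_g_contact_grad(z, A)) @ dz[:, 2:4].T)
        )
    d_chain += (1.0 - m) * np.log(g_ii)

    d_assoc = np.zeros(n)
    for i, p in enumerate(params):
        if not p.associating:
            continue
        A = d[i] / 2.0
        dg2, dg3 = _g_contact_grad(z, A)
        dm_ = _delta_molar(p, T, g_ii[i])
        t = x[i] * rho * dm_
        xi = _closed_form_X(t)
        h = 2.0 * np.log(xi) - xi + 1.0
        hp = 2.0 / xi - 1.0
        dX_dt = -(xi * xi) / (1.0 + 2.0 * t * xi)
        # dt/dx_k = delta_ik rho Delta + t dln(g11)/dx_k
        dt = t * (dg2 * dz[:, 2] + dg3 * dz[:, 3]) / g_ii[i]
        dt[i] += rho * dm_
        d_assoc += x[i] * hp * dX_dt * dt
        d_assoc[i] += h
    return d_hs + d_disp + d_chain + d_assoc


def ln_phi_saft(
    params, x, T: float, P: float, phase: str, kij: float = 0.0
) -> np.ndarray:
    """Analytic fugacity coefficients ln phi_i at (T, P, x) on one branch.

    Uses mu_i^res/RT = a_res + (Z - 1) + da/dx_i - sum_j x_j da/dx_j with
    the composition derivatives of every term in closed form at fixed
    (T, rho), then ln phi_i = mu_i^res/RT - ln Z.
    """
    x = np.asarray(x, dtype=float)
    rho = density_solver(params, x, T, P, phase, kij)
    state = residual_helmholtz(params, x, T, rho, kij)
    dadx = _dadx_analytic(params, x, T, rho, kij)
    mu = state.a_res + (state.Z - 1.0) + dadx - float(x @ dadx)
    return mu - np.log(state.Z)


def _residual_A_total(params, n: np.ndarray, T: float, V: float, kij: float) -> float:
    """Total residual Helmholtz energy / RT for n moles in volume V (m3)."""
    ntot = float(np.sum(n))
    x = n / ntot
    rho = ntot / V
    return ntot * residual_helmholtz(params, x, T, rho, kij).a_res


def ln_phi_saft_numeric(
    params, x, T: float, P: float, phase: str, kij: float = 0.0, h: float = 1e-6
) -> np.ndarray:
    """Fugacity coefficients by central-difference mole-number derivatives.

    Differentiates the total residual Helmholtz energy with respect to the
    mole numbers at fixed (T, V); serves as the independent check on the
    analytic route.
    """
    x = np.asarray(x, dtype=float)
    rho = density_solver(params, x, T, P, phase, kij)
    state = residual_helmholtz(params, x, T, rho, kij)
    V = 1.0 / rho  # basis: 1 mol total
    out = np.empty(len(params))
    for i in range(len(params)):
        n_hi = x.copy()
        n_lo = x.copy()
        n_hi[i] += h
        n_lo[i] -= h
        a_hi = _residual_A_total(params, n_hi, T, V, kij)
        a_lo = _residual_A_total(params, n_lo, T, V, kij)
        mu_res = (a_hi - a_lo) / (2.0 * h)
        out[i] = mu_res - np.log(state.Z)
    return out


# ---------------------------------------------------------------------------
# Phase-equilibrium solvers
# ---------------------------------------------------------------------------

def pure_saturation_pressure_saft(
    p: SaftParams, T: float, P_init: float, max_iter: int = 200
) -> tuple[float, float, float]:
    """Pure saturation pressure by equal-fugacity successive substitution.

    Returns (Psat/Pa, vL, vV in m3/mol).  ``P_init`` seeds the iteration
    (an Antoine estimate works well)."""
    params = [p]
    x = np.array([1.0])
    P = float(P_init)
    for _ in range(max_iter):
        lpl = ln_phi_saft(params, x, T, P, "liquid")[0]
        lpv = ln_phi_saft(params, x, T, P, "vapor")[0]
        P_new = P * np.exp(lpl - lpv)
        if abs(P_new - P) < 1e-7 * P:
            P = P_new
            break
        P = P_new
    else:
        raise RuntimeError("pure SAFT saturation did not converge")
    vl = 1.0 / density_solver(params, x, T, P, "liquid")
    vv = 1.0 / density_solver(params, x, T, P, "vapor")
    return float(P), float(vl), float(vv)


def bubble_point_saft(
    params: Sequence[SaftParams],
    kij: float,
    T: float,
    x1: float,
    P_init: float,
    tol: float = 1e-9,
    max_iter: int = 500,
):
    """Bubble pressure and vapor composition at (T, x) for the SAFT model.

    Same outer successive-substitution contract as the cubic solver:
    K_i = phiL_i/phiV_i, y = x K / sum, P <- P sum.  Returns
    (P/Pa, y1, vL, vV, iterations).
    """
    if not (0.0 < x1 < 1.0):
        raise ValueError("x1 must be interior")
    x = np.array([x1, 1.0 - x1])
    P = float(P_init)
    y = x.copy()
    for it in range(1, max_iter + 1):
        lpl = ln_phi_saft(params, x, T, P, "liquid", kij)
        lpv = ln_phi_saft(params, y, T, P, "vapor", kij)
        Kf = np.exp(lpl - lpv)
        y_new = x * Kf
        S = float(y_new.sum())
        P_new = P * S
        if abs(S - 1.0) < tol and abs(P_new - P) < max(1e-6, 1e-8 * P):
            P, y = P_new, y_new / S
            break
        P, y = P_new, y_new / S
    else:
        raise RuntimeError(f"SAFT bubble point did not converge in {max_iter} iterations")
    vl = 1.0 / density_solver(params, x, T, P, "liquid", kij)
    vv = 1.0 / density_solver(params, y, T, P, "vapor", kij)
    return float(P), float(y[0]), float(vl), float(vv), it


# ---------------------------------------------------------------------------
# Volumetric predictions (shared by cubic and SAFT specs)
# ---------------------------------------------------------------------------

def excess_volume_prediction(
    liquid_volume: Callable[[float], float],
    x1_grid: Sequence[float],
) -> np.ndarray:
    """VE(x) = v(x) - x1 v1 - x2 v2 from any liquid molar-volume function.

    ``liquid_volume`` maps x1 -> v_liq (m3/mol) at fixed (T, P); the pure
    endpoint volumes are evaluated from the same function, so the curve is
    exactly zero at x1 = 0, 1.
    """
    x1_grid = np.asarray(x1_grid, dtype=float)
    v1 = liquid_volume(1.0)
    v2 = liquid_volume(0.0)
    out = np.empty_like(x1_grid)
    for k, x1 in enumerate(x1_grid):
        out[k] = liquid_volume(float(x1)) - x1 * v1 - (1.0 - x1) * v2
    return out


def saft_liquid_volume(params, kij: float, T: float, P: float):
    """Liquid molar-volume function x1 -> v (m3/mol) for the SAFT model."""

    def v(x1: float) -> float:
        x = np.array([x1, 1.0 - x1])
        return 1.0 / density_solver(params, x, T, P, "liquid", kij)

    return v


def cubic_liquid_volume(spec, T: float, P: float):
    """Liquid molar-volume function for a cubic spec (translated volumes)."""
    from .cubic_eos import _ln_phi_mix, mixture_parameters

    def v(x1: float) -> float:
        x = np.array([x1, 1.0 - x1])
        _, Z = _ln_phi_mix(spec, x, T, P, "liquid")
        vol = Z * R * T / P
        if spec.use_translation:
            _, _, c = mixture_parameters(spec, x, T)
            vol -= c
        return vol

    return v
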