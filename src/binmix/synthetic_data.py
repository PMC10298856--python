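"""Synthetic-data generation for parameter-recovery experiments.

Emulates the study's measurements so every pipeline stage is testable
without external data: isothermal P-x curves are generated from the full
Barker forward model (Wilson activities plus virial vapor corrections) with
known Wilson parameters and additive Gaussian pressure noise matching the
static apparatus's 13 Pa reproducibility; excess-property curves come from
known Redlich-Kister coefficient vectors, with densities built by inverting
the excess-volume relation from the pure-density endpoints.  A fixed seed
makes the full output stream bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .barker_wilson import IsothermalPxDataset, barker_pressure, fit_isotherm_barker
from .excess_props import ExcessCurve, eval_redlich_kister, fit_redlich_kister
from .pure_components import AntoineConstants, antoine_pressure, virial_cross_and_delta

#: Pressure reproducibility of the static apparatus, Pa; default noise scale.
DEFAULT_SIGMA_P = 13.0

#: The 12 liquid compositions of the reference 298.15 K isotherm, reused as
#: the default grid so synthetic and real datasets are drop-in interchangeable.
DEFAULT_X2_GRID = (
    0.0321, 0.1009, 0.2035, 0.3302, 0.4356, 0.5238,
    0.6312, 0.7193, 0.8185, 0.8673, 0.9384, 0.9882,
)


@dataclass
class SynthSpec:
    """Ground truth for one synthetic study.

    ``wilson_by_T`` maps temperature to the true (Lambda12, Lambda21);
    ``antoine`` is the pair of pure-pressure correlations; the pure molar
    volumes and virial coefficients close the Barker forward model.
    ``rk_he``/``rk_ve`` are true Redlich-Kister vectors (J/mol and m3/mol)
    and ``density_endpoints`` maps T to (rho1, rho2) in kg/m3.
    """

    wilson_by_T: dict[float, tuple[float, float]]
    antoine: tuple[AntoineConstants, AntoineConstants]
    V1_0: float = 76.93e-6
    V2_0: float = 167.7e-6
    B11: float = -1810.0e-6
    B22: float = -5490.0e-6
    x2_grid: tuple[float, ...] = DEFAULT_X2_GRID
    sigma_P: float = DEFAULT_SIGMA_P
    rk_he: Sequence[float] | None = None
    rk_ve: Sequence[float] | None = None
    density_endpoints: dict[float, tuple[float, float]] = field(default_factory=dict)
    molar_masses: tuple[float, float] = (60.096, 154.25)
    sigma_HE: float = 5.0       # J/mol
    sigma_rho: float = 0.04     # kg/m3, densimeter uncertainty
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_P < 0 or self.sigma_HE < 0 or self.sigma_rho < 0:
            raise ValueError("noise scales must be non-negative")
        g = np.asarray(self.x2_grid, dtype=float)
        if np.any((g <= 0) | (g >= 1)):
            raise ValueError("composition grid must be interior to (0, 1)")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def synth_isotherm(
    spec: SynthSpec, T: float, rng: np.random.Generator | None = None
) -> IsothermalPxDataset:
    """One synthetic isotherm from the Barker forward model plus noise."""
    if T not in spec.wilson_by_T:
        raise KeyError(f"no ground-truth Wilson pair at T = {T}")
    L12, L21 = spec.wilson_by_T[T]
    p1 = antoine_pressure(spec.antoine[0], T)
    p2 = antoine_pressure(spec.antoine[1], T)
    b12, _ = virial_cross_and_delta(spec.B11, spec.B22)
    x2 = np.asarray(spec.x2_grid, dtype=float)
    P, _ = barker_pressure(
        1.0 - x2, T, L12, L21,
        pure=(p1, p2, spec.V1_0, spec.V2_0),
        virials=(spec.B11, spec.B22, b12),
    )
    if spec.sigma_P > 0:
        if rng is None:
            rng = spec.rng(stream=int(T * 100))
        P = P + rng.normal(0.0, spec.sigma_P, size=P.shape)
    return IsothermalPxDataset(
        T=T, x2=x2, P=P, P1_0=p1, P2_0=p2,
        V1_0=spec.V1_0, V2_0=spec.V2_0, B11=spec.B11, B22=spec.B22,
    )


def synth_excess_curves(
    spec: SynthSpec, T: float, rng: np.random.Generator | None = None
) -> tuple[ExcessCurve, np.ndarray]:
    """(HE curve, density table) generated from the true RK vectors.

    The density table is an (n, 2) array of (x2, rho/kg m^-3) including the
    pure rows, built by inverting the excess-volume relation: noise is
    added to the interior densities only, so the endpoints stay exact.
    """
    if spec.rk_he is None or spec.rk_ve is None:
        raise ValueError("spec carries no Redlich-Kister ground truth")
    if T not in spec.density_endpoints:
        raise KeyError(f"no density endpoints at T = {T}")
    if rng is None:
        rng = spec.rng(stream=1_000_000 + int(T * 100))
    x2 = np.asarray(spec.x2_grid, dtype=float)
    x1 = 1.0 - x2

    he = eval_redlich_kister(list(spec.rk_he), x1)
    if spec.sigma_HE > 0:
        he = he + rng.normal(0.0, spec.sigma_HE, size=he.shape)
    he_curve = ExcessCurve(
        property="HE", T=T,
        x2=np.concatenate(([0.0], x2, [1.0])),
        values=np.concatenate(([0.0], he, [0.0])),
    )

    rho1, rho2 = spec.density_endpoints[T]
    m1, m2 = (m * 1e-3 for m in spec.molar_masses)  # kg/mol
    ve = eval_redlich_kister(list(spec.rk_ve), x1)
    # invert VE = x1 M1 (1/rho - 1/rho1) + x2 M2 (1/rho - 1/rho2) for rho
    ideal = x1 * m1 / rho1 + x2 * m2 / rho2
    rho = (x1 * m1 + x2 * m2) / (ideal + ve)
    if spec.sigma_rho > 0:
        rho = rho + rng.normal(0.0, spec.sigma_rho, size=rho.shape)
    table = np.column_stack(
        (
            np.concatenate(([0.0], x2, [1.0])),
            np.concatenate(([rho1], rho, [rho2])),
        )
    )
    return he_curve, table


def recovery_report(
    spec: SynthSpec,
    n_replicates: int,
    stages: Sequence[str] = ("wilson", "rk"),
) -> dict:
    """Monte-Carlo bias/RMSE report for the requested pipeline stages.

    For each replicate a fresh synthetic dataset is generated and reduced;
    the report collects bias, RMSE and the relative errors of the recovered
    parameters.  Deterministic given the spec's seed.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    report: dict = {"n_replicates": n_replicates, "sigma_P": spec.sigma_P, "stages": {}}

    if "wilson" in stages:
        out: dict[float, dict] = {}
        for T, (L12, L21) in spec.wilson_by_T.items():
            rng = spec.rng(stream=int(T * 100))
            est = np.empty((n_replicates, 2))
            for r in range(n_replicates):
                ds = synth_isotherm(spec, T, rng=rng)
                fit = fit_isotherm_barker(ds)
                est[r] = (fit.Lambda12, fit.Lambda21)
            truth = np.array([L12, L21])
            err = est - truth
            rel = np.abs(err) / truth
            out[T] = {
                "truth": truth.tolist(),
                "bias": err.mean(axis=0).tolist(),
                "rmse": np.sqrt((err**2).mean(axis=0)).tolist(),
                "median_rel_error": np.median(rel, axis=0).tolist(),
            }
        report["stages"]["wilson"] = out

    if "rk" in stages and spec.rk_he is not None:
        T = next(iter(spec.density_endpoints), 298.15)
        rng = spec.rng(stream=1_000_000 + int(T * 100))
        n_he = len(spec.rk_he)
        est = np.empty((n_replicates, n_he))
        for r in range(n_replicates):
            he_curve, _ = synth_excess_curves(spec, T, rng=rng)
            fit = fit_redlich_kister(he_curve, n_he)
            est[r] = fit.coefficients
        truth = np.asarray(spec.rk_he, dtype=float)
        err = est - truth
        report["stages"]["rk"] = {
            "T": T,
            "truth": truth.tolist(),
            "bias": err.mean(axis=0).tolist(),
            "rmse": np.sqrt((err**2).mean(axis=0)).tolist(),
        }
    return report
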