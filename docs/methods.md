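# Methods

This note documents the models, numerical choices and design decisions
behind `binmix`, and what the bundled tests do and do not establish.

## Conventions

Subscript 1 is 2-propanol, subscript 2 is 1,8-cineole; isotherm tables are
indexed by x₂ with x₁ = 1 − x₂.  Internally everything is SI (Pa, K,
m³/mol, J/mol) with R = 8.314462618 J mol⁻¹ K⁻¹; conversions to kPa,
cm³/mol or L/mol happen only at I/O boundaries.  Each fit's standard
deviation is s = [Σ(X − X_calc)²/(N − n)]^½ with n the number of adjusted
parameters.

## Pure components

**Antoine correlation.**  ln(P/kPa) = A − B/(T − C), fitted by nonlinear
least squares.  The default objective is ln P: a vapor-pressure table
spanning more than a decade (1.5–23.6 kPa here) fitted in absolute Pa is
dominated by its highest-temperature points, and the ln-P objective is the
one that reproduces the bundled 2-propanol correlation from its source
data (s = 24.5 Pa over ten points, −15.5 Pa residual at 298.15 K; the
shipped constants themselves leave s = 24.8 Pa).  A pressure-unit
objective is available via `objective="pressure"` (it gives s = 17.9 Pa on
the same data).  The 1,8-cineole constants are not part of the bundled
record and are regenerated at load time by refitting its pure-pressure
table (s < 10 Pa).

**Molar volumes** are linearly interpolated in the 278.15–323.15 K table;
extrapolation is permitted 5 K beyond either end and flagged with a
warning, and refused beyond that.

**Virial coefficients.**  B₁₁ = −1810×10⁻⁶ and B₂₂ = −5490×10⁻⁶ m³/mol are
constants evaluated at 325 K — the temperature at which the static
apparatus's manometer and vapor space were thermostatted — and are used
unchanged at every isotherm temperature; only the RT denominator of the
vapor-phase corrections uses the isotherm temperature.  The cross
coefficient uses the cubic Lorenz rule with signed cube roots; for the
study pair B₁₂ = −3320×10⁻⁶ m³/mol and δ₁₂ = 2B₁₂ − B₁₁ − B₂₂ =
+660×10⁻⁶ m³/mol.

## Barker reduction

The fixed point

    P = x₁γ₁P₁⁰R₁ + x₂γ₂P₂⁰R₂,
    R₁ = exp{[(V₁⁰ − B₁₁)(P − P₁⁰) − Pδ₁₂y₂²]/RT},   (R₂ symmetric)
    y₁ = x₁γ₁P₁⁰R₁ / P,

is iterated from R = 1 to |ΔP| < 0.01 Pa (an order below the 13 Pa
pressure reproducibility; 200-iteration cap, never approached at these
conditions — the corrections are ≲0.5% of P).  The outer regression
minimizes unweighted Σ(P_exp − P_calc)² over (Λ₁₂, Λ₂₁) by
Levenberg–Marquardt from the start (0.5, 0.5), which sits inside the
fitted range of both parameters across all ten isotherms; s uses n = 2.
A warning fires if a Λ leaves (0.05, 20).  The signs in the lnγ
expressions are fixed by requiring the Gibbs–Duhem identity and the
reproduction of the tabulated γ values (the typeset forms of such
equations are notoriously ambiguous).

The λ-differences follow from Λ₁₂ = (V₂⁰/V₁⁰)exp[−(λ₁₂−λ₁₁)/RT] (and the
mirrored relation for Λ₂₁) with λ₂₁ = λ₁₂; their near-linear temperature
trends are smoothed by OLS lines, which reproduce the tabulated
"linearly fitted" values within rounding.

## Excess properties and consistency

V^E is computed from each density isotherm using that table's own x₂ = 0
and x₂ = 1 rows as the pure densities, which makes the endpoint identity
exact by construction.  Redlich–Kister fits are linear least squares on
the basis x₁x₂(x₁−x₂)ʲ, j = 0..k−1, interior points only (the endpoint
rows are identically zero and carry no information); three coefficients
for H^E and four for V^E, matching the curvature each property shows.
The equimolar value is A₀/4, a useful cross-check (A₀(V^E)/4 = −0.495
cm³/mol at 298.15 K).

C_p^E is the OLS slope of H^E against T at fixed composition — justified
here because the equimolar H^E rises almost linearly over 288–318 K
(517 → 749 J/mol, slope 7.6 J mol⁻¹ K⁻¹).

The Gibbs–Helmholtz test rebuilds G^E(x, T) from the λ(T) trend lines and
the interpolated molar volumes (so Λ(T) carries both sources of
temperature dependence) and differentiates numerically:
H^E = ∂(G^E/T)/∂(1/T) by central difference with dT = 5 K.  A derivative
step half as large changes the curve by <1%, and in the constant-volume,
constant-λ limit the result matches the closed-form Wilson temperature
derivative.  At 298.15 K the vapor-pressure route peaks at ≈634 J/mol
against the calorimetric ≈600 J/mol — agreement well within the
considerable uncertainty of differentiating vapor-pressure data.
TS^E = H^E − G^E is formed pointwise.

## Cubic equations of state

Peng–Robinson skeleton with Ω_a = 0.457235, Ω_b = 0.077796 and two alpha
functions:

* PRM: √α = 1 + κ_PR(ω)(1−√T_r) − p₁(1−T_r)(0.7−T_r),
  κ_PR = 0.37464 + 1.54226ω − 0.26992ω².  The sign convention of the polar
  term (subtracting p₁·…) is the one that reproduces the measured pure
  vapor pressures with the bundled p₁ values (5860 Pa vs measured 5781 Pa
  for 2-propanol at 298.15 K; the opposite sign gives 8306 Pa).  A
  `mathias_sign` switch preserves the alternative.
* PRSV: √α = 1 + κ(1−√T_r), κ = κ₀ + κ₁(1+√T_r)(0.7−T_r),
  κ₀ = 0.378893 + 1.4897153ω − 0.17131848ω² + 0.0196554ω³.

The Peneloux translation c = (c/b)·b is applied to reported volumes only:
a composition-linear shift cancels identically in the fugacity-equality
conditions, so bubble pressures and vapor compositions are bit-identical
with translation on or off (asserted in the tests), while the translated
liquid volume of 2-propanol moves from 79.6 to 76.9 cm³/mol at 298.15 K —
onto the measured value.

Mixtures: van der Waals one-fluid rules, a = ΣΣxᵢxⱼ(1−kᵢⱼ)√(aᵢaⱼ),
b and c linear, with k₁₂(T) = a + bT + cT² (T in kelvin).  Volume roots
come from the closed-form cubic (`numpy.roots`), smallest real root > B
for liquid, largest for vapor.  Bubble points use successive substitution
on (P, y): Kᵢ = φᵢ^L/φᵢ^V, P ← P·ΣxᵢKᵢ.  The k₁₂ regression minimizes
relative pressure deviations (the isotherm pressures span 71 Pa to
23.6 kPa, so absolute deviations would weight the isotherms absurdly);
an absolute-deviation mode exists.  AAD is (100/N)·Σ|ΔP|/P_exp over all
120 state points (10 isotherms × 12 compositions), with the per-isotherm
breakdown always reported because the averaging set behind a single
published AAD number is rarely stated.

## SAFT

Original Huang–Radosz form, chosen because the bundled parameter set
(m, υ⁰⁰, u⁰/k, κ, ε/k) follows that convention: square-well segments with
v⁰(T) = υ⁰⁰[1 − 0.12exp(−3u⁰/kT)]³, u/k = (u⁰/k)(1 + e/kT), e/k = 10 K
for both compounds, and the 24 Chen–Kreglewski dispersion constants
(bundled as a CSV with citation header).  The effective segment diameter
follows N_A d³ = √2 v⁰.

For mixtures the hard-sphere term is the Boublik/MCSL expression in the
partial packing fractions ζ₀..ζ₃, with chain and association built on the
MCSL pair contact values g_ij; the one-fluid averaging is applied only to
the dispersion energy, where k₁₂ corrects the cross term.  (A fully
one-fluid variant — one-fluid η in every term — was implemented first and
discarded: it misses the dilute-alkanol corner badly and raises the
overall pressure AAD from ~19% to ~24.5% with the bundled k₁₂(T),
inconsistent with the published correlation quality.)

Association: 2B scheme for 2-propanol (one donor + one acceptor,
X_A = X_B), no sites on the ether — so no cross-association, despite the
physical evidence for OH···O complexation; this is a known limitation of
the parameter set, not of the code, and is the main reason SAFT
overpredicts the bubble pressure where the alkanol is dilute.  The site
fraction uses the closed form X = 2/(1 + √(1+4t)), t = x₁ρΔ, written to
avoid subtractive cancellation at low density; a damped
successive-substitution solver (tolerance 10⁻¹²) is kept for generality
and verified against the closed form.

Pressure comes from analytic density derivatives of every term (every ζ is
linear in ρ), verified against numerical differentiation of a_res to
<10⁻⁷.  Fugacity coefficients use closed-form composition derivatives at
fixed (T, ρ), μᵢ^res/RT = a + (Z−1) + ∂a/∂xᵢ − Σxⱼ∂a/∂xⱼ, with a
central-difference mole-number route as an independent check (agreement
<10⁻⁶, typically 10⁻⁸).  The density solver brackets the vapor branch
upward from the ideal-gas packing fraction and takes the highest-density
crossing below η = 0.70 for the liquid.

Excess-volume predictions for all three models are evaluated at
P = 101.325 kPa, the ambient pressure of the density measurements.  Only
SAFT reproduces the negative sign of V^E (−0.56 vs measured −0.50 cm³/mol
at the equimolar point, 298.15 K); both translated cubics predict
≈+0.85 cm³/mol — the sign contrast that makes the volumetric test a
model-discrimination experiment.

## Synthetic data

The generator draws isotherms from the same Barker forward model used in
fitting, with additive Gaussian pressure noise of σ = 13 Pa — the
apparatus's stated reproducibility, and additive because a static
manometer's error is instrument-limited, not proportional.  The default
composition grid copies the twelve abscissae of the 298.15 K isotherm so
synthetic and real datasets are drop-in interchangeable.  Excess-property
curves come from true Redlich–Kister vectors; densities are built by
inverting the excess-volume relation from the pure-density endpoints
(noise σ_ρ = 0.04 kg/m³, the densimeter uncertainty; σ_HE = 5 J/mol,
commensurate with the calorimeter's ~2% at mid-range).  Seeding uses
`numpy` `SeedSequence` streams keyed by temperature, so the full output is
bit-reproducible and independent isotherms get independent streams.

What recovery tests show: with the study's noise level and grid, the
Wilson parameters are recovered with <2% median relative error, i.e. the
printed parameter resolution is supported by the measurement precision.
What they do not show: robustness to composition error (the generator
treats x₂ as exact), to correlated pressure drift, or to the slight
isotherm-to-isotherm drift of the true liquid composition present in real
data — none of which the generator emulates.

## Degenerate inputs and tie-breaks

Barker and RK fits refuse datasets with fewer points than parameters + 1;
the RK design matrix is rank-checked; std_deviation refuses N ≤ n.
Mole-fraction grids must be strictly interior and increasing.  The cubic
saturation solver halves/doubles pressure to escape single-root regions;
bubble solvers flag trivial-root collapse.  Association with κ = 0 forces
X = 1 exactly.

## Known limitations

* No cross-association, no 3B scheme in the shipped configuration (a flag
  exists at the parameter level: any component's κ_AB/ε_AB can be set).
* No dew-point-driven fitting, no flash, no multicomponent (>2) support.
* The virial correction ignores the temperature dependence of B between
  278 and 325 K; this is consistent with how the data were measured
  (vapor space thermostatted at 325 K) but approximate for the coldest
  isotherms.
* The k₁₂ regression objective behind the published quadratic trends is
  unknown; refits land in the same band (±0.02) but not on the same
  coefficients, so the published coefficients are used verbatim when
  scoring the models.
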