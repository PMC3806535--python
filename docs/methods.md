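# Methods

## Photosynthesis core

The package implements the standard Farquhar–von Caemmerer–Berry C3 leaf
model.  Light-limited gross assimilation is Aj = (J/4)·(ci − Γ*)/(ci + 2Γ*)
with J the smaller root of θJ² − (αQ + Jmax)J + αQ·Jmax = 0 (θ = 0 is
handled as the rectangular-hyperbola limit, not an error); Rubisco-limited
gross assimilation is Av = Vcmax·(ci − Γ*)/(ci + Km) with
Km = Kc(1 + [O2]/Ko).  Agross = min(Aj, Av) and Anet = Agross − Rd(T).
Both gross rates are clamped at zero below the compensation point: gross
rates are nonnegative by definition, and the clamp keeps sweeps through
ci < Γ* well defined.  An exact tie Aj = Av (to 1e-9 relative) is labelled
co-limited.  Along any driver, Aj < Av is algebraically equivalent to
J < Jv, which is why the limitation flag and the electron-balance stages
always agree.

The electron demand of Rubisco-limited carboxylation,
Jv = 4Vcmax(ci + 2Γ*)/(ci + Km), equals the electron cost
J(A) = 4A(ci + 2Γ*)/(ci − Γ*) evaluated at Av; this composition identity is
enforced by tests to 1e-10 relative.  J(A) is singular at ci = Γ* and the
code raises a domain error there rather than returning infinities.

Temperatures are Kelvin internally and Celsius at every user-facing
interface; R = 8.314 J mol⁻¹ K⁻¹.  Kinetic constants (Γ*25 = 42.75,
Kc25 = 404.9 µmol mol⁻¹, Ko25 = 278.4 mmol mol⁻¹; Ea = 37 830, 79 430,
36 380 J mol⁻¹; Ea of Vcmax 65 330, Rd 46 390) follow a standard published
Bernacchi-type parameterization and are fully overridable — they are
literature defaults, not fitted values.  Each capacity can follow either a
plain Arrhenius response or the peaked form
k(T) = k25·Arrh(T)·[1 + e^((298.15ΔS−Hd)/(298.15R))]/[1 + e^((TΔS−Hd)/(TR))],
normalized to k25 at 25 °C, with closed-form optimum
Topt = Hd/(ΔS − R·ln(Ea/(Hd − Ea))).  Defaults: Jmax peaked
(Hd = 152 044 J mol⁻¹, ΔS = 495 J mol⁻¹ K⁻¹, giving Topt(J) ≈ 29 °C) and
Vcmax Arrhenius.  The rationale: the electron-balance temperature response
requires an interior optimum of J, while a monotonically rising Jv is what
produces the declining electron excess beyond Topt(J) and the
low-light insensitivity of emission to temperature.  A peaked Vcmax
(e.g. Hd = 149 252, ΔS = 486) is selectable per-parameter to study the
sensitivity of Jv and J − Jv to that choice, which is substantial above
40 °C.

Quantum yield α = 0.3 mol e⁻ per mol absorbed photon and curvature
θ = 0.90 by default.  PAR input is *absorbed* PAR; no absorptance
correction is applied.  No correction is applied for alternative electron
sinks either, so J is a lower-bound estimate of total electron transport.
Rd enters only Anet and never the emission models, since respiration does
not draw on the chloroplastic NADPH budget being partitioned.

## Emission models

**Electron balance.**  Iso = f(ci)·[a·J + b·(J − Jv)], f(ci) =
min(ci/Γ*, 1), floored at zero.  f(ci) multiplies the whole bracket, and
the floor handles the deficit regime (J < Jv at low light / low ci) where
the bracket can go negative — whether real leaves shut emission off
completely there is an open question, so the floor is the conservative
choice.  Units: emission in nmol m⁻² s⁻¹ against electron fluxes in
µmol m⁻² s⁻¹, so a and b (nmol isoprene per µmol e⁻) absorb the 10⁻³
conversion.  Defaults a = 0.3, b = 0.1 were chosen once to give a
standard-condition emission of ~40 nmol m⁻² s⁻¹ and a positive but
declining low-light emission — typical magnitudes for a strong broadleaf
emitter; species-specific values should always be fitted.

**G93.**  Iso = Is·C_L·C_T with C_L = α_L·c_L1·Q/√(1 + α_L²Q²) and
C_T = exp(c_T1(T − Ts)/(R·Ts·T)) / (1 + exp(c_T2(T − T_M)/(R·Ts·T))).
Coefficient defaults are the canonical published values (α_L = 0.0027,
c_L1 = 1.066, c_T1 = 95 000, c_T2 = 230 000 J mol⁻¹, Ts = 303 K,
T_M = 314 K; temperature optimum near 38 °C); Is defaults to
30 nmol m⁻² s⁻¹.  The model has no ci dependence by construction.

**NADPH cost.**  Iso = ε(T)·J·(ci − Γ*)/[6(4.67·ci + 9.33·Γ*)] (converted
to nmol), with ε(T) = ε·exp(k(T − 303.15)) and an optional cap ε·εmax
emulating the capped global-modelling variant (cap disabled by default).
The cost pair (4.67, 9.33) is the canonical published denominator; defaults
ε = 0.02 at 30 °C, k = 0.1 K⁻¹ are literature-scale values exposed in
config.  CO2 modifiers: none (1), f_ci (273/ci) and f_ca (390/ca),
following the common empirical corrections.

**IspS activity.**  A peaked activation/deactivation curve
(Ha = 83 129, Hd = 284 600 J mol⁻¹, ΔS = 886 J mol⁻¹ K⁻¹) rescaled to a
maximum of exactly 1 at its optimum, 45.4 °C with the defaults — inside
the 45–48 °C window reported for the enzyme.  `apply_isps_modulation`
multiplies an emission series elementwise by the activity series; the
product's optimum lands strictly between the two input optima when both
are interior.

**Stoichiometry.**  The MEP-pathway NADPH count per isoprene is kept as an
explicit record (6 for G3P + 5 for pyruvate + 1 further NADPH + 2 reducing
equivalents = 14), with 0.5 NADPH generated per electron; these constants
document the energetic argument rather than entering the emission
equations.

## Fitting

Two-stage, mirroring standard gas-exchange practice: (1) (Vcmax25, Jmax25)
by RSS minimization of modelled vs observed net assimilation — observed Rd
is used per-record when supplied, otherwise the modelled Arrhenius Rd from
the base parameter set (the result records which) — using L-BFGS-B from a
fixed 5-point multistart lattice plus a Nelder-Mead polish (deterministic;
the trace of all starts is returned and the reported optimum is verified
against them).  (2) (a, b) by unweighted OLS of observed isoprene on J
(light design at fixed ci: a + b = slope, b = −intercept/Jv) or on Jv
(ci design at fixed PAR: b = −slope, a = intercept/J + slope).  Records at
or below the compensation point are excluded with a logged count because
the electron-cost expression is singular and the ci gate makes the model
nonlinear there.  Designs are validated (fixed-ci spread < 5 %, ≥ 3 points,
nonzero regressor spread); a fitted b < 0 warns rather than fails.  The
intercept of the light-design regression is an extrapolation far outside
the data, so b is estimated noticeably better from the ci design — the
recovery study therefore pairs a light response (for the capacities, which
need both limitation regimes) with a ci response (for a, b).

r² is 1 − SSres/SStot, may be negative, and is undefined (error) for
zero-variance observations.  Normalization uses the standard condition
T = 30 °C, ci = 273 µmol mol⁻¹, PAR = 1000 µmol m⁻² s⁻¹ (overridable);
normalized curves are invariant to common rescaling of (a, b).

## Response engine

Sweeps evaluate all requested models on a strictly increasing driver grid
(PAR, ci, or temperature) with the other drivers fixed.  Ratios Iso/Agross
and Iso/Anet are emitted as flagged NaN where the denominator is not
positive — never infinities.  Stage segmentation of a PAR sweep locates the
J = Jv crossing by Brent root finding to 0.1 µmol m⁻² s⁻¹ and quantifies
the slope discontinuity of Iso/Agross by one-sided finite differences at
the adjacent grid cells; when Jv ≥ Jmax no crossing exists and the whole
sweep is stage 1.  Temperature optima use the discrete argmax refined by
the parabola through its two neighbours (exact for locally quadratic
series, clamped to the bracketing cells); boundary maxima and all-constant
series are flagged rather than refined.  T × PAR surfaces are normalized to
exactly 1 at the reference cell (default 30 °C / 1000), which must lie on
the grids.  Default grids resolve all features at desk cost: PAR 0–2000
step 10, ci 0–1000 step 5, T 5–50 °C step 0.25.

## Synthetic data

The generator emulates the designs the fitting procedures assume:
light-response sweeps at fixed ci and T, ci sweeps at fixed PAR and T, and
factorial T × PAR grids.  Truth columns come from the photosynthesis core
and the electron-balance model; observations are truth·(1 + ε) with
independent Gaussian ε per channel (default CV 5 %, a realistic cuvette
repeatability), truncated so observed isoprene stays nonnegative.  The
master seed is split into two independent substreams (assimilation,
isoprene).  What it does *not* emulate: instrument drift or autocorrelated
error, stomatal feedback on ci, leaf-to-leaf parameter variation, or any
mismatch between the generating model and the fitted model — so recovery
tests demonstrate internal consistency of the estimation procedures, not
robustness to model misspecification on real leaves.

## Problem sizes and numerical choices

The recovery study uses 100 seeded datasets of n = 20 points per design at
CV = 5 %, and the capacity fit is cross-checked against an exhaustive
200 × 200 grid over the bounds; the noiseless closure check
(generate → fit → simulate) reproduces the generating curves to better than
1e-10 relative in practice, asserted at 1e-6.  Discriminant round-off in
the light-response quadratic is guarded by clipping at zero and by capping
J at min(αQ, Jmax).  All CSV output is UTF-8/LF with '#' unit comments and
the resolved-config hash; identical config + seed reproduces files
byte-for-byte.

## Known limitations

No mesophyll conductance, C4 variant, stomatal coupling, or leaf energy
balance; no DMADP pool dynamics (the electron balance is a steady-state
proxy for pool size); comparator-model constants are literature defaults
rather than refits; the low-light temperature response inherits the
model's known tendency to overstate the influence of the electron deficit
(emission can drop to zero where real leaves still emit).
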