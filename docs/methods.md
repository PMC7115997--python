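# Methods

This note documents the models implemented in `aquaflux`, the defaults
and numerical choices, what the synthetic-data generators do and do not
emulate, and the known limitations. No empirical claim is made here that
the test suite or `scripts/acceptance.py` does not itself compute.

## Unit system

Everything internal is CGS: lengths in cm, times in s, energies in erg
(molar energies in kcal/mol), concentrations in mol/cm³, pressures in
dyn/cm². Rationale: unitary permeabilities (cm³/s), diffusivities
(cm²/s) and membrane permeabilities (cm/s) are universally quoted in CGS
in this field, and keeping them native makes every formula
coefficient-free. Conversions (mM ↔ mol/cm³ is a factor 10⁻⁶, µm/nm ↔
cm) live in `aquaflux.units` and in the I/O layer only; file columns
carry their unit in the name (`time_s`, `c_mM`, `x_um`) so a file can
never be read in the wrong unit silently.

Constants and defaults:

| symbol | value | meaning / why |
|---|---|---|
| v_w | 3.0·10⁻²³ cm³ | one water molecule (18 cm³/mol ÷ N_A); no measured alternative exists |
| z | 2.8·10⁻⁸ cm | water–water spacing in a single file (one water diameter); overridable, recorded in provenance when defaulted |
| V_w | 18 cm³/mol | partial molar volume of water |
| ν₀ | 10¹³ s⁻¹ | universal transition-state attempt frequency |
| R | 1.98720·10⁻³ kcal/(mol·K) | gas constant in the barrier equations |
| T | 298.15 K | default temperature; always a parameter, recorded in provenance when defaulted |

## Hard-sphere chain theory (`singlefile`)

The classical model treats the N-water column as hard spheres: the work
of translocation is taken proportional to pore length, friction per
molecule is γ = kT/D₁, and force balance yields the column velocity and
flux; per unit osmolyte number-density difference this gives
p_f = v_w·D₁/(z·L) and, after substituting the column diffusivity
D_w = D₁/N, the length-free form p_f = D_w·v_w/z². The module computes
every intermediate (work, forces, velocity, flux) so that derivation
consistency can be asserted mechanically.

Assumptions, stated and flagged in docstrings:

* work ∝ L — a hard-sphere idealization. Real channels concentrate their
  resistance at constriction zones and hydrogen-bonding sites, and the
  experimental p_f(N) dependence is exponential, not 1/L. The module
  implements the classical chain verbatim as the reference model and
  labels it the hard-sphere limit; no replacement functional form is
  asserted because none is established.
* the p_f/p_d = N prediction is returned by
  `pf_pd_ratio_prediction` with an explicit warning that it was never
  confirmed experimentally (measured ≈5 for gramicidin A at N = 7,
  ≈13 for AQP1 at N ≈ 8) and cannot be used to infer N.

## Vesicle deflation (`vesicle`)

Forward model: dV/dt = A·P_f·V_w·(c_in − c_out) with conserved internal
osmolyte (c_in·V = c_in,0·V₀) and time-invariant surface area A (the
membrane neither stretches nor buds on the deflation timescale; volume
leaves by dimpling). The closed form is

V(t) = V₀·(c_in,0/c_out)·[1 + W₀(ξ·e^{ξ − k·t})],
ξ = c_Δ/c_in,0, k = A·P_f·V_w·c_out²/(V₀·c_in,0)

with W₀ the principal Lambert W branch. W₀ is used for both shrinking
(argument > 0) and moderate swelling (argument ∈ (−1/e, 0)); continuity
with V(0) = V₀ forces this branch, and for any physical spec
(c_out > 0) the argument never leaves the branch domain — the domain
check exists for defensive completeness. The independent ODE integrator
(LSODA, rtol 10⁻¹⁰) is retained as a cross-oracle and as the engine of
the grid fitting strategy; the two agree to <10⁻⁶ relative across random
parameter sweeps (asserted in the acceptance suite).

τ→P_f conversions: the historical formulas divide r₀/(3·V_w·τ) by an
"effective osmotic concentration". The three divisors found in the
literature are implemented as variants a (c_out), b (c_out − c_in,0) and
c (c_out²/c_in,0); a transcription that lists them as reciprocal factors
is dimensionally inconsistent, and this divisor reading is the only one
producing cm/s. Variant c is the correct small-gradient linearization of
the ODE (relaxation time τ = r₀·c_in,0/(3·P_f·V_w·c_out²), derived by
linearizing around V₀); variant b is biased by exactly
c_out²/(c_in,0·(c_out − c_in,0)) — ≈31× for a 290→300 mM challenge —
and is retained only to quantify that bias. The `improved` variant
replaces the divisor with 2·c_out²/(c_in,0 + c_out), accurate to ~1% in
the tested small-gradient scenarios.

Scattering observable: I = a + b·V + d·V² (a second-order reduction of
Rayleigh–Gans–Debye scattering; the coefficients depend on refractive
indices in a way not modeled here, so calibration is empirical per
dataset). Inversion selects the unique quadratic root inside the
physical volume interval [V_eq, V₀] and refuses ambiguous calibrations.
Intensity traces are treated as normalized to I(0) = 1.

Fitting choices:

* the monoexponential fit is initialized from a trailing-plateau
  asymptote guess and a log-linear decay regression, then refined by
  bounded least squares **on the normalized signal** — raw volumes are
  ~10⁻¹⁵ cm³, below optimizer tolerance floors, and fitting unnormalized
  caused silent non-convergence during development;
* the analytic strategy fits log P_f (positivity without constraints);
* the grid strategy reproduces the simulate-then-match-τ workflow:
  simulate the ODE per candidate P_f, monoexponentially fit each, match
  the experimental τ to the nearest simulated τ_c, and refuse τ outside
  the grid range rather than extrapolate;
* confidence intervals are residual-resampling bootstrap percentiles
  (200 resamples by default, seed mandatory) because no analytic
  uncertainty propagation through the Lambert form is standard;
* r₀ is a required input: the error in P_f is linear in the assumed/true
  radius ratio and nothing in a single scattering trace identifies r₀.

## Unstirred layer (`unstirred`)

C(x) = C_s·exp(−v_t·x/D + a·x³/(3D)), x measured into the hyperosmotic
compartment so v_t > 0 produces near-membrane dilution. The stirring
term +a·x³/(3D) is kept in the transcribed form and treated as purely
empirical (it may be frozen from a no-gradient control scan via
`a_stir_fixed`). Taking logs makes the model linear in
{ln C_s, v_t/D, a/(3D)}, so the fit is exact OLS — no iterative
optimizer, no convergence failure mode; CIs come from the OLS
covariance (C_s by exponentiating the ln-scale interval). Note the
log transform turns multiplicative measurement noise into the additive
noise OLS assumes, which is also how the generator simulates it.

P_f = v_t/(χ·C_osm·V_w) uses the **fitted near-membrane** C_s as C_osm,
not the bulk value: the membrane sees the diluted concentration. χ
defaults to 1 (ideal osmolyte).

Caveat: over a 0–200 µm scan the x and x³ regressors are strongly
collinear, so freely fitting the stirring term inflates the variance of
v_t (~16% single-scan SD at 1% noise vs ~6% with the stirring term
frozen). This is a property of the experiment, not the estimator;
the recovery criteria are therefore statements about the mean over many
seeded scans.

## Energetics (`energetics`)

Hopping rate r = p_f/v_w; transition-state rate r = ν₀·exp(−ΔG‡/RT);
hence p_f = ν₀·v_w·exp(−ΔG‡/RT) and the inversion
ΔG‡ = −RT·ln(p_f/(ν₀·v_w)), a strict inverse pair (asserted to 10⁻¹⁰
on a 0–30 kcal/mol grid). p_f > ν₀·v_w (= 3·10⁻¹⁰ cm³/s at defaults) is
rejected: no process outruns its attempt frequency.
`consistency_gap` packages the check for claimed (p_f, ΔG‡) pairs; a
claimed 6.8·10⁻¹³ cm³/s alongside a 24.1 kcal/mol barrier fails it by
>20 kcal/mol, since that barrier caps p_f at ~6·10⁻²⁸ cm³/s.

Physical bracket for water-filled pores: lower bound 4.6 kcal/mol (bulk
self-diffusion activation), upper bound 4.6 + 10.5 ≈ 15 kcal/mol (add
the vaporization enthalpy for fully de-wetted transfer).

Arrhenius analysis is OLS of ln P_f on 1/T with E_a = −slope·R. The
slope is an activation energy; the field often uses it interchangeably
with ΔG‡, a simplification (it ignores the activation entropy) that the
module documents and does not attempt to refine. With exactly two
temperatures the line is determined and a degenerate (point) CI is
returned rather than refusing the fit.

## Channel census (`census`)

Counts are ensemble averages and stay real-valued. The
silent-channel correction is an explicit opt-in parameter (default 0)
because the silent fraction is channel-specific; the uncorrected
estimator's bias is exactly 1/(1−s) and is asserted in closed form in
the tests. Two-step FCS counting assumes harsh-detergent micelles carry
one labeled protomer each; labeling efficiency below 0.8 triggers a
warning (protomer stoichiometry becomes unreliable), and the
bare-vesicle fraction is exposed explicitly, with both the per-vesicle
and per-proteoliposome conventions reported, because published values do
not always state which was used. Detergent chemistry itself is not
modeled. Slope fits (P_f vs conductance or vs channel density) are OLS
with the intercept reported as the lipid background permeability and a
warning flag when the slope CI spans zero.

## Structure–function regressions (`determinants`)

Unweighted OLS of ln p_f on N or N_H. Unweighted because no fit
procedure or per-point uncertainty is established for these catalogs;
weighting by quality class is available but off by default. Prediction
intervals are ln-scale OLS mean-prediction intervals, exponentiated
(delta method). The N_H = 0 intercept is the hydrogen-bond-free ceiling
(the in-silico nanotube limit, predicted length-invariant because N_H
stays 0). Outlier reports flag |ln residual| > k·SD (default k = 3) and
annotate flagged channels as gating candidates — an annotation slot,
not a conclusion. No experimental catalog ships with the package: the
underlying laboratory values are not tabulated in any machine-readable
source this package may reproduce, so the module is a fit-it-yourself
tool and `docs/example_catalog.tsv` is explicitly synthetic.

## Synthetic data (`synthetic`)

Generators emit (data, truth) pairs; every recovery test consumes
generated data, never hand-edited fixtures. All randomness flows from an
explicit integer seed through `numpy.random.default_rng`; no global
state. The default scenario is a realistic small-gradient bench setup:
100 nm LUVs, 290→300 mM osmotic step, P_f = 0.01 cm/s, 500-point traces
over ~6 relaxation times; 30-point electrode scans over 0–200 µm with
v_t = 10⁻⁴ cm/s and D = 2·10⁻⁵ cm²/s; 6-point temperature series over
5–40 °C. Noise is multiplicative (or additive) Gaussian.

What the generators do **not** emulate: stopped-flow dead time and
mixing artifacts (only a crop option exists on the fitting side),
photon/detector noise statistics, vesicle size polydispersity beyond
discrete mixtures, osmolyte non-ideality, and instrument drift. A green
recovery test therefore establishes estimator correctness under the
stated noise model, not robustness to every laboratory artifact.

## Numerical notes and degenerate inputs

* Lambert W evaluated via `scipy.special.lambertw`, principal branch;
  imaginary residue > 10⁻¹² (relative) is treated as an error.
* ODE: LSODA, rtol 10⁻¹⁰, atol V₀·10⁻¹⁰.
* Constant traces, <4 trace points, <5 profile points, all-equal
  predictors, single catalog points, single temperatures: all rejected
  with typed errors (`FitError`, `DesignError`, `DomainError`) rather
  than returning NaN.
* Grid-strategy τ outside the simulated τ_c range raises a `RangeError`
  naming the range instead of clamping.
* Bootstrap resamples that fail to fit are skipped; if more than ~3/4
  fail the CI itself is declared failed.

## Known limitations

* Inhomogeneous channels (constriction zones, uneven hydrogen-bond
  distribution) are discussed but not modeled; no p_d estimation from
  tracer data.
* No first-principles scattering model; Eq-quadratic calibration only.
* No FCS autocorrelation fitting (particle counts are inputs).
* The single-scan variance of the unstirred-layer fit with a free
  stirring term is large (collinearity); plan replicate scans or a
  control-frozen stirring parameter.
* The silent-channel and bare-vesicle corrections are only as good as
  the independently supplied fractions.
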