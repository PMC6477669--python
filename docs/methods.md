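# Methods

## Coordinates, units, and sign convention

All quantities are in mm, N, s, and MPa; since 1 N/mm² = 1 MPa, engineering
stress needs no conversion factor. Specimens are cylinders (default 40 mm
diameter × 18 mm height, area A₀ = πd²/4 ≈ 1256.64 mm²). Machine records
carry compression-positive displacement and resisting force; conversion to
material coordinates is engineering strain ε = −d/h₀, stretch λ = 1 + ε,
and engineering stress σ = −F/A₀. Internally curves are *signed,
tension-positive* (compression means λ < 1, σ < 0), which lets the
constitutive equation hold with correct signs and keeps the fitter free of
absolute values; `magnitude_view` provides the (compressive strain, |σ|)
plane used in plots. True-stress, barreling, and friction corrections are
out of scope.

## Constitutive model

The surrogates are modeled as incompressible, isotropic, and hyperelastic
with the Yeoh (cubic reduced polynomial) strain energy

ψ(I₁) = c₁(I₁−3) + c₂(I₁−3)² + c₃(I₁−3)³,

where I₁ = Σλᵢ² and, under uniaxial loading with λ₂ = λ₃ = λ^(−1/2),
I₁ = λ² + 2/λ. The stress–stretch relation used for both forward simulation
and fitting is

σ(λ) = 2(λ² − 1/λ)·(c₁ + 2c₂(I₁−3) + 3c₃(I₁−3)²).

Note this expression equals λ·dψ/dλ — the uniaxial **true (Cauchy) stress**
of the Yeoh energy, not the nominal stress dψ/dλ. We adopt it verbatim
because it is the relation the tabulated coefficients were identified with;
the energy–stress consistency test asserts σ(λ) = λ·ψ′(λ) accordingly. With
c₂ = c₃ = 0 the model reduces exactly to neo-Hookean σ = 2c₁(λ² − 1/λ).

The general invariant helper computes I₂ as the sum of λᵢ²λⱼ² over *ordered*
pairs i ≠ j (six terms, 6 at the reference state) rather than the classical
three-term symmetric function; nothing downstream consumes I₂ (the uniaxial
stress depends on I₁ only), so the choice is documentation-visible but
inert. Stretches at or below 10⁻⁶ are rejected to avoid the 1/λ blow-up.
Coefficients carry no sign constraint by default; an optional bounds box
(e.g. non-negativity) is available on the fitter. Rate dependence is handled
by per-rate parameter sets, not a viscoelastic law: the packaged table holds
the healthy control composition at 1.96, 180, and 1800 mm/s plus the
plantar-pain and diabetes surrogates at 1.96 mm/s. (One packaged row's
published rate label reads "mm/min" where every sibling row reads "mm/s";
the verbatim string is preserved alongside a normalized mm/s column.)

## Parameter identification

Fitting minimizes Σᵢ(σ_exp,ᵢ − σ_model(λᵢ))² over (c₁, c₂, c₃). The model
is linear in the coefficients, so the problem has a unique global optimum
for a non-degenerate design; we nevertheless run a derivative-based
multi-start — (0,0,0) plus uniform vectors at magnitudes 10⁻⁴…1 MPa
(log-spaced), plus any user start — through `scipy.optimize.least_squares`
with the analytic (constant) Jacobian, keeping the best SSR and breaking
ties by the smallest ‖c‖₂. Tolerances are 10⁻¹⁴ on cost, step, and
gradient, with at most 10⁴ evaluations. Goodness of fit is
R² = 1 − SS_res/SS_tot about the observed mean, computed between measured
and predicted stresses; R² > 0.95 (strict) flags the coefficients highly
accurate. At least four distinct stretch points are required.

## Cyclic analysis

Records are segmented at displacement peaks (scipy `find_peaks`, minimum
prominence 1 % of maximum displacement so sensor wiggles do not split
cycles); each loop runs trough → peak (loading) and peak → next trough
(unloading). A monotone ramp yields a single loading-only loop with a flag.
The energy dissipation ratio of a loop is

EDR = (A_load − A_unload)/A_load,

with both areas by trapezoidal integration of force over displacement
(N·mm; the ratio is invariant to the linear maps into stress–strain space).
Values within 10⁻⁹ of [0, 1] are clipped; anything farther out raises, since
it indicates broken segmentation. Repeatability over a cycle train follows
the ±10 %-of-maximum-load rule, implemented as peak-to-peak spread of cycle
peak forces ≤ tolerance × overall maximum peak (this is the reading under
which the canonical pass/fail examples behave correctly; a mean-centered
±band twice as wide would pass cases the rule is meant to reject).
Per-cycle deviations from the mean peak are reported under both
normalizations (fraction of maximum and fraction of mean). Idle
warm-up cycles can be dropped via the `skip_cycles` config field (default
0 for synthetic data).

## Surrogate selection

Candidate and reference force–strain curves are linearly resampled onto an
evenly spaced grid over their shared strain span — [max of minima, min of
maxima], 21 points by default; no extrapolation is ever performed. R² is
computed with the reference as the "observed" series (its variance
normalizes the residuals; the opposite convention is not symmetric and the
choice is documented rather than assumed). A candidate is admitted for a
group when R² ≥ 0.8; the best candidate is the argmax, ties broken
lexicographically with a flag. Reference curves are user inputs: the
in vivo literature group curves exist only as published figures and are not
packaged, so the synthetic cohort supplies references for testing.

## Synthetic data generator

The generator emulates the materials-testing protocol: displacement ramps
at a nominal rate (default 1.96 mm/s) to 9 mm on an 18 mm specimen
(λ down to 0.5), sampled at `sampling_rate` (default 100 Hz, a typical
load-frame logging rate), forces from the Yeoh plant times A₀, optional
truncation at a 40 N load cap. Noise is Gaussian on force only (the
displacement encoder is treated as exact), parameterized as a fraction of
peak force, clipped at zero — note the clip makes near-zero forces
upward-biased, a real feature of force-floor clipping that fitting
experiments on noisy *records* inherit. Cyclic records are triangular;
the unloading branch is the loading branch scaled pointwise by (1 − q), so
the analytic EDR equals the prescribed q. The turning point is emitted
twice (loading force, then dropped force at the same displacement), which
makes the trapezoid-rule EDR of each segmented cycle equal q *exactly* —
the duplicated sample spans zero width and adds no area. Cohorts realize
each composition `n_specimens` times with lognormal multiplicative
variability on (c₁, c₂, c₃) (keeps coefficients positive).

What the generator does **not** emulate: macro/microchamber structure and
anisotropy, rate-dependent (viscoelastic) stress contributions, permanent
set or Mullins softening, contact mechanics of the piston–specimen
interface, and machine compliance. Passing tests therefore demonstrate the
correctness of the analysis chain under the stated statistical structure,
not the biofidelity of any physical surrogate.

## Reproducibility and problem sizes

All randomness flows from one root seed split per stage with
`numpy.random.SeedSequence` (generation, cyclic noise, cohort, in that
order); identical spec + seed yields byte-identical CSV output. The
reproduction script uses 50-point noise-free curves spanning λ ∈ [0.55, 1]
for parameter recovery (the span where all tabulated plants are
comfortably identifiable) and single-cycle records at the default sampling
rate for the dissipation round trips; the stochastic-recovery experiment
uses 200-point curves with stress noise at 1 % of peak |σ| over 100 seeds,
applied at the curve level so the clip-at-zero force bias noted above does
not confound the fitter assessment. Monte Carlo under those conditions
puts the mean relative error on c₂ near 3.8 % with negligible bias.

## Known limitations

- Engineering-stress bookkeeping with the true-stress constitutive relation
  mirrors the characterization convention the coefficients come from;
  coefficients are therefore tied to that convention and should not be
  re-exported into solvers expecting nominal-stress Yeoh fits without care.
- The selection stage cannot reproduce published correlation tables whose
  reference curves exist only as figures; it reproduces the *procedure* and
  is validated on synthetic cohorts (plus the published score columns taken
  as precomputed inputs).
- Weighted least squares, simultaneous multi-rate fitting, and parameter
  uncertainty beyond Monte Carlo seeds are not implemented.
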