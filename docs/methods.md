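# Methods

This note documents the models implemented in `ivpk`, the defaults and the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## IV-bolus mammillary models

The central-compartment amount x₁ of a mammillary model with first-order
transfer obeys dx/dt = K x with

    K(2-comp) = [[-(k10+k12), k21], [k12, -k21]]
    K(3-comp) = [[-(k10+k12+k13), k21, k31], [k12, -k21, 0], [k13, 0, -k31]]

and x(0) = (dose, 0, …). Plasma concentration is C(t) = x₁(t)/V1, a sum of
n exponentials whose exponents are the negated eigenvalues of K. All rates
are in 1/h, concentrations in ng/mL, doses in ng, volumes in mL; exponents
are always stored fastest-first, so α is the distribution rate and the last
exponent the terminal elimination rate.

**micro → macro** uses the eigen-decomposition directly: exponents from the
eigenvalues, coefficients from the partial-fraction residues of the central
solution. Repeated (or complex) eigenvalues raise `DegeneracyError`; terms
whose residue is numerically zero are dropped, which makes the k12 = k21 = 0
case reduce cleanly to the mono-exponential C(t) = (dose/V1)e^(−k10 t).

**macro → micro** uses the classical algebra. Two compartments:
V1 = dose/(A+B), k21 = (Aβ + Bα)/(A+B), k10 = αβ/k21,
k12 = α + β − k10 − k21. Three compartments: −k21 and −k31 are the zeros of
the central transfer function (a quadratic in the normalised coefficients),
k10 = αβγ/(k21 k31), and k12, k13 follow from the linear system given by the
trace and second invariant of K. A derived rate ≤ 0 is reported as an
inconsistent parameter set rather than silently clamped. Both directions are
verified against each other (round trip to 1e-8 relative) and against an
independent ODE integration of K in the test suite.

## Weighted fitting

`fit_iv_bolus` minimises WRSS = Σ wᵢ(Cᵢ − Ĉᵢ)² with wᵢ = 1/Cᵢ², i.e.
relative residuals. IV-bolus data span 2–3 orders of magnitude within hours;
with proportional assay error, 1/y² weighting is the maximum-likelihood-ish
choice and keeps the terminal phase from being swamped by the peak.
Numerics:

- parameters are optimised on the log scale (positivity by construction);
- initial values come from curve stripping (log-linear fit of the terminal
  segment, peeled off, repeated for faster phases), plus 10 restarts with
  lognormal jitter (SD 0.3 on the log scale) from a seeded generator —
  deterministic given the `seed` argument;
- the Levenberg–Marquardt solver runs per start and the best WRSS wins;
- fitted exponents closer than a factor 1.1 trigger an over-parameterisation
  warning suggesting one fewer compartment;
- BLQ points are excluded from fitting; at least 2n+1 quantifiable points
  are required for n compartments.

Diagnostics: df = n − 2·(compartments), AIC = n ln(WRSS/n) + 2p, and the
weighted R² about the weighted mean. The AIC convention matters: values are
comparable only within this package, not with software using other
conventions. WRSS = 0 yields AIC = −∞ with a warning.

## Model selection

The two- vs three-compartment decision uses the extra-sum-of-squares F-test
at a configurable α (default 0.05), with the critical value computed from
the F distribution at run time. `compare_models` reports per-subject tests
(the recommended basis) and additionally a pooled test on the across-subject
mean WRSS at the common df — a convention some studies use for a single
cohort-level verdict; it is provided for that workflow. Under the null, the
test's empirical type-I error is checked by simulation in the test suite.

## Derived parameters

From a micro/macro pair: Vss = V1(1 + k12/k21 [+ k13/k31]), Cl = V1·k10,
t½(dist) = ln2/fastest exponent, t½(elim) = ln2/slowest exponent,
depth = k10/k12, capacity = k12/k21, fc = (slowest exponent)/k10. Half-lives
and fc deliberately take the exponents from the macro form so they can be
computed from reported summary constants even when those are means across
subjects; note that ratios of means are not means of ratios, so population
descriptors should be computed per subject and then averaged
(`population_summary` does exactly this when given per-subject results).

## Non-compartmental analysis

Linear-trapezoid AUC from the first to the last quantifiable sample
(second-order accurate; verified against closed-form integrals). Interior
BLQ samples are dropped; trailing BLQ samples truncate AUC_last. No C(0)
back-extrapolation by default — AUC_last is reported as observed — with an
optional bolus extension using C(0) = ΣA from a fitted macro model. Cmax is
the largest quantifiable concentration, ties broken by earliest time (for a
true IV bolus the first sample is always Cmax since the model curve is
strictly decreasing).

## Calibration

Weighted least squares (statsmodels WLS) of the analyte/IS response ratio on
nominal concentration with weights 1/x^k; k ∈ {0, 1, 2} covers the standard
bioanalytical options and k = 2 is the default. Replicate standards enter
as individual points. The reported r² is the weighted coefficient of
determination. Back-calculation inverts the line and flags results outside
[LLOQ, ULOQ] (inclusive); a d-fold dilution multiplies the reportable
maximum by d once dilution integrity has been shown.

## Total-error validation

For each nominal level of a p-series × n-replicate run, the one-way
random-effects ANOVA gives MSW and MSB; σ̂²_within = MSW and
σ̂²_between = max(0, (MSB − MSW)/n) (standard zero-truncated estimator; for
unbalanced cells n is replaced by the method-of-moments n₀ =
(N − Σnᵢ²/N)/(p−1)). Repeatability RSD uses σ̂_within, intermediate
precision uses √(σ̂²_within + σ̂²_between).

The β-expectation tolerance interval on relative error follows Mee's
construction: with R = σ̂²_B/σ̂²_W, B² = (R+1)/(nR+1) and Satterthwaite
degrees of freedom ν = (R+1)²/[(R+1/n)²/(p−1) + (1−1/n)/(pn)],

    bias ± t_{(1+β)/2, ν} · √(1 + 1/(pnB²)) · s_IP.

β defaults to 0.95. A single-series run falls back to the Student
prediction interval mean ± t·s·√(1+1/n) and is flagged. The Monte-Carlo
expected coverage of the interval is verified in the test suite.
The accuracy profile declares the method valid iff every level's interval
lies inside the ±acceptance limits (default ±20%, boundaries inclusive — the
regulatory reading of "within"). The risk of an out-of-acceptance result is
the tail mass of a location-scale Student variable (bias, s_IP, ν) outside
the limits; a Monte-Carlo cross-check of the same quantity appears in the
tests. Exact tolerance-interval algorithms differ slightly between
implementations; Mee's method is the documented choice here.

Matrix factors are peak-area ratios (post-extraction spike over neat), the
IS-normalised MF their quotient, summarised by mean and CV% across lots.
Dilution integrity reports per-replicate deviations with an
all-replicates-within-limit criterion by default (mean-based optional).
Stability and ion-ratio utilities are simple threshold/CV bookkeeping.

## Synthetic-data generator

The generator encodes the emulated study conditions: subjects P1–P3 at
9.45/9.04/8.85 kg; 0.3 mg/kg IV bolus of a 1.2 mg/mL solution (injected
volume = weight × dose/concentration); sampling at 5, 10, 20, 30, 45, 60,
90 min, 2, 4, 8 h (a variant schedule ends at 6.5 h for an early-exit
subject); disposition truth given by the typical two-compartment macro
constants A = 542.53, α = 3.71 h⁻¹, B = 168.95, β = 0.34 h⁻¹.

Measurement error is C_obs = C_true(1 + ε_prop) + ε_add with Gaussian ε; the
default proportional CV is 10% with no additive term. This is a synthetic
choice, not an estimate of any particular dataset: proportional error is the
structure that motivates 1/y² fitting weights, and 10% is a realistic
magnitude for a validated LC-MS/MS assay near its working range. Values
falling below the LLOQ (default 0.5 ng/mL) or driven negative (clamped to a
configurable floor) are flagged BLQ, retained in files, and excluded from
fits by default.

Validation runs are simulated as measured = nominal(1 + overall_bias +
series_effect + residual) with the series effect shared within a series.
Defaults: 3 series × 5 replicates at levels {0.5, 1.5, 15, 50} ng/mL,
between-series SD 3%, within-series CV 4%, overall bias −2% — magnitudes
typical of a passing assay validation (biases of a few %, intermediate
precision under ~8%).

What the generator does not emulate: inter-subject variability in the rate
constants (all simulated animals share the disposition truth; only dose and
noise differ), chromatographic artefacts (carry-over, interferences, peak
integration), extraction recovery, metabolite kinetics, and any
concentration dependence of the assay CV. Passing tests therefore show that
the estimators recover the parameters of data satisfying the stated model —
not that any real study satisfies it.

## Problem sizes in the test and acceptance runs

Simulation-based checks use: 200 replicate fits for parameter recovery
(median relative bias within ±10% at proportional CV 10%), 2000 simulated
runs for tolerance-interval coverage (within 2 points of β), 2000 nested
linear fits for the F-test type-I error (within [3%, 7%] at α = 0.05), and
400 paired calibrations for the weighted-vs-unweighted comparison. These
sizes give Monte-Carlo error comfortably below the asserted tolerances
while keeping the default run fast.

## Known limitations

- Only linear (first-order) elimination; no absorption phase, no
  Michaelis–Menten kinetics, no mixed-effects pooling across subjects.
- Nearly equal exponents make the macro↔micro conversions ill-conditioned;
  the code raises/warns rather than returning silently imprecise values.
- The pooled mean-WRSS F-test treats the cohort mean as a single fit; it is
  provided to mirror a published workflow, and the per-subject tests should
  be preferred.
- β-expectation intervals assume the one-way random model with Gaussian
  components; heavy-tailed assay error will under-cover.
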