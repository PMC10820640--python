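# ivpk

Compartmental pharmacokinetics and total-error bioanalytical validation for
small intravenous-bolus studies — the kind of exploratory animal PK study
where a drug (here, cannabidiol in piglets) is injected IV, plasma is
sampled densely over hours, concentrations are measured by a validated
LC-MS/MS assay, and the disposition is summarised by a two- or
three-compartment mammillary model.

The package is a library: you use it from Python (see `examples/`), not
from a shell.

## What it computes

**Disposition modelling.** After an IV bolus the plasma concentration of a
drug following a mammillary compartment model is a sum of decaying
exponentials,

    C(t) = A e^(-αt) + B e^(-βt) [+ C e^(-γt)],

whose exponents are the negated eigenvalues of the rate matrix built from
the micro constants k10, k12, k21 (k13, k31) and whose coefficients follow
from C(0) = dose/V1. `ivpk` converts between the macro (A, α, B, β, …) and
micro forms in both directions, fits the macro form to observed profiles by
weighted least squares (weights 1/y², minimising the weighted residual sum
of squares WRSS), and decides between the two- and three-compartment models
with the extra-sum-of-squares F-test

    F = [(WRSS₂ − WRSS₃)/(df₂ − df₃)] / (WRSS₃/df₃).

Derived descriptors: Vss = V1(1 + k12/k21 [+ k13/k31]), Cl = V1·k10,
half-lives ln2/α and ln2/β, depth k10/k12, capacity k12/k21 and the central
fraction fc = β/k10. Non-compartmental Cmax/Tmax and linear-trapezoid
AUC_last with dose normalisation are included.

**Assay validation.** Total-error method validation per the accuracy-profile
approach: at each nominal level of a p-series × n-replicate validation run,
relative bias, repeatability and intermediate-precision RSD (one-way
random-effects variance components), a β-expectation tolerance interval
(Mee's construction with Satterthwaite degrees of freedom) and the risk of
a future result falling outside the ±acceptance limits. Plus 1/x²-weighted
linear calibration with back-calculation, IS-normalised matrix factors,
dilution integrity, ion-ratio CV and stability checks.

**Synthetic data.** A generator reproduces the structure of the emulated
study — three ~9 kg piglets, 0.3 mg/kg IV bolus of a 1.2 mg/mL solution,
sampling from 5 min to 8 h, bi-exponential decay with proportional error —
and of the validation design (3 series × 5 replicates × 4 levels), so every
analysis step can be exercised end to end.

## Worked example

```sh
python examples/fit_and_select.py
```

simulates the three-subject study, fits both candidate models and prints
(abridged):

```
Nested F-test (pooled): F = 0.45 vs critical 6.94 -> keep the reduced (two-compartment) model

Per-subject two-compartment results:
  P1: k10 1.12/h, k12 1.52/h, k21 0.93/h, V1 3935 mL | Cl 4409 mL/h, Vss 10353 mL, t1/2 dist 0.21 h, t1/2 elim 2.16 h, fc 0.29
  ...
```

The F statistic below its critical value says the third compartment is not
statistically justified. In the retained two-compartment model, k12 > k10 >
k21 (depth < 1, capacity > 1) describes a drug that distributes into
peripheral tissue faster than it is eliminated and returns slowly; fc ≈ 0.3
means roughly two thirds of the body load sits outside plasma during the
terminal phase, which decays with a ~2 h half-life.

`examples/validation_report.py`, `examples/calibration_workflow.py` and
`examples/dosing_and_simulation.py` walk through the assay-validation,
calibration and dosing/simulation capabilities the same way.

## Layout

- `src/ivpk/synthetic.py` — study generator and dosing arithmetic
- `src/ivpk/calibration.py` — weighted calibration and back-calculation
- `src/ivpk/validation.py` — total-error validation statistics
- `src/ivpk/nca.py` — non-compartmental summaries
- `src/ivpk/compartmental.py` — models, fitting, macro↔micro, derived PK
- `src/ivpk/selection.py` — F-test, AIC, weighted R², model comparison
- `src/ivpk/io.py` — CSV/JSON boundary
- `docs/methods.md` — models, assumptions, defaults and limitations
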