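# Methods

This note records the models, the parameters that matter, the synthetic
data the analyses run on, and the numerical and design choices made
where the procedure was genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Models and assumptions

All learners operate trial by trial on an internal estimate of the
object's mass, expressed relative to the reference object (1% of body
mass), so the perturbation *f* is 1 for the standard object, 0.7/1.0/1.3
in the three-mass protocol, and 0 on zero-force trials.

**Single-rate model (SRM).** `x ← α x + β e`, `e = f − x`. α ∈ [0, 1]
is the fraction of state retained per trial absent error; β ∈ [0, 1]
the fraction of the error added to the state. Under constant *f* the
error is exactly geometric with ratio (α − β) toward the asymptote
(1 − α)f / (1 − α + β); the suite checks this closed form to 1e−10 over
1,000 trials, and it implies an exponential time constant
t = −1/ln(α − β) trials.

**Dual-rate model (DRM).** Two states with separate (α, β) pairs share
the error and sum to the output. States are labeled by learning rate
(state 2 = fast, β₂ ≥ β₁), enforced by relabeling after fitting to
remove the label-switching ambiguity. When the two pairs coincide the
model is trajectory-identical to an SRM with (α, 2β) — a property test.

**Multiple-context model (MCSRM).** A 16-element state vector over
object orientations spaced 22.5° apart (covering (−180°, 180°]). The
context-selection vector is 1 at the current orientation and decays
with circular lag L to an offset *d* at 180°. The exact normalization
of the published tuning function is not printed, so it is implemented
as an affine-rescaled Gaussian,

    c(L) = d + (1 − d) · (N(L) − N(180)) / (N(0) − N(180)),  N(L) = exp(−L²/2σ²),

which satisfies both printed anchors (c(0) = 1, c(180) = d) exactly for
every σ and d; the σ → ∞ limit is handled analytically. A 10-parameter
variant replaces the Gaussian with 8 free symmetric lag weights
(lag 0 fixed at 1). Both the read-out (`x = c·z`) and the credit
assignment (`z ← α z + β e c`) use the same vector.

**Compliance-dependent error.** In context models the observed error is
`e_cm = g · k · (f − x)` with compliance *k* (cm per unit mass error)
depending on orientation and on the sign of the error (*k*⁺ when
*f* > *x*, *k*⁻ otherwise), and a free gain *g*. *k* is calibrated at
five orientations {0, −45, −90, −135, 180}°; at intermediate grid
orientations it is circularly linearly interpolated (the minimal
assumption, since probes occur at ±22.5° off the calibrated angles).
The default profile used throughout the synthetic analyses is the
declared unit profile (*k*⁺ = *k*⁻ = 1 everywhere, *g* = 1); the
calibration fixture uses a synthetic, declared non-unit profile because
the original calibration values were never published as numbers.

**Error drive (open choice).** The published equations are ambiguous
about whether the state update consumes the cm-valued error or the
mass-unit discrepancy. The default here is `error_drive='mass_units'`
(the update uses *f* − *x*; the compliance only shapes the
observation). This keeps state units as mass estimate, reduces exactly
to the SRM under unit compliance, and makes the compliance calibration
well-posed — the compliances then enter the predicted displacement
linearly and carry the full output scale with *g* fixed at 1, so no
k·β degeneracy arises. The alternative (`'cm_units'`) is implemented
behind the same interface; under it β and k are identified only up to a
product.

**Trial modes.** Zero-force trials set *f* = 0, so de-adaptation is
error-driven with the same β. Error-clamp trials report the error
*f* − *x* (that is what the clamp measures) but update with zero error
and full retention decay, `x ← α x` — the standard state-space
treatment, exposed as `clamp_update='zero_error' | 'frozen'`. A
passive-decay de-adaptation variant (retention-only on zero-force
trials) exists as a flag but is used by no main pipeline.

## Schedules

Each experimental protocol is built deterministically from a seed;
wherever the protocol says "random" (clamp positions, orientation or
mass orders) the placement is drawn from a seeded generator, so a
schedule is a pure function of (experiment, group, seed). Within a
block, trials strictly alternate CW/CCW rotations. Specifics worth
recording:

* Single-context: 48 familiarization zero-force trials (generated,
  flagged, excluded from fitting) + 320 main trials; the 16 error
  clamps occupy one seeded slot per 8-trial bin of the final 128
  exposure trials, with bins alternately assigned CW and CCW parity so
  every seed yields the printed 8/8 split.
* Multi-context de-adaptation: 64 exposure trials, then 15 blocks of
  2 clamps + 8 zero-force probes + 2 clamps + 18 re-exposures; probe
  orientations appear once per cycle in a seeded permutation (3
  cycles).
* Dual-context: 11 cycles of paired 24-trial blocks at 180°/0°; first
  and last cycles zero-force; exposure blocks carry 4 seeded clamps,
  never block-initial (the analyses read block-initial exposure
  errors).
* Five-context: 2 pre + 5 exposure + 2 post cycles, orientations
  permuted per cycle with the constraint that consecutive blocks always
  change orientation (the binning analysis is defined on orientation
  *changes*).
* Calibration: 3 cycles of 30 exposure + 20 zero-force trials per
  orientation; counts configurable, since only the fitted compliance
  matters downstream.

## Object dynamics

The peak-force normalizer assumes a minimum-jerk 40° rotation in 0.4 s
(the required movement time); subjects' actual within-trial kinematics
were never published, and any smooth rest-to-rest profile serves, since
the adaptation ratio divides two forces computed from the same
kinematics. Angle convention: 0° along +y, positive CCW, angles stored
in (−180°, 180°]. Mass fractions convert to kilograms through a
canonical 70 kg body mass.

## Fitting

The model's absolute error output is fit to the mean-across-subjects
peak-displacement series over all non-clamp trials by bounded nonlinear
least squares (`scipy.optimize.least_squares`, trust-region reflective)
with seeded Latin-hypercube multi-start (default 20 starts; bounds
α, β, d, free weights ∈ [0, 1], σ ∈ [1°, 180°], k ∈ (0, 10],
g ∈ [0.5, 2]). Multiple series may share one parameter vector
(concurrent two-group fits). Divergent parameter regions (unstable
state growth) are mapped to a large finite residual so the optimizer
retreats from them. The gain *g* is refit as a free parameter whenever
a compliance profile is in play, unless explicitly fixed.

`BIC = n ln σ²ₑ + k ln n`, with ΔBIC > 4.6 (Bayes factor 10) as strong
evidence. The source text's remark that ΔBIC approximates *half* the
log Bayes factor is inconsistent with its own 4.6 ↔ BF 10 equivalence
(which implies ΔBIC = 2 ln BF); the 4.6 threshold is taken as
authoritative and the inconsistency is noted here rather than resolved.
A fit with exactly zero residual variance returns −∞ with a warning.

The exponential time constant is fit as y(n) = a + b·exp(−n/t) (offset
plus single exponential — the only form consistent with a single rate
and a nonzero asymptote, the published rendering being a figure
placeholder); on any geometric series with ratio r it returns
t = −1/ln r exactly, and constant or non-decaying series are flagged
unidentifiable.

Bootstrap confidence intervals resample subjects with replacement
(1,000 resamples by default), deduplicating repeated multisets up to a
retry cap and accepting duplicates with a warning beyond it, refit the
resample mean series, and report 2.5/97.5 percentiles. Everything is
seeded and bit-reproducible.

**Compliance calibration.** The modified SRM (state update in mass
units, observation scaled by k) makes the 10 compliances enter the
predicted displacement linearly, so they are profiled out in closed
form per (orientation, sign) group and only (α, β) are searched
nonlinearly — a variable-projection fit that is fast and immune to the
12-dimensional multi-start problem. *g* is fixed at 1 here (this *is*
the calibration), which pins the k scale; the convention is recorded in
the result metadata.

## Synthetic cohorts

The generator stands in for the unavailable human data. Per subject it
perturbs the generative α and β multiplicatively (lognormal, default
5% CV, clipped to [0, 1]), simulates the model over the schedule, and
emits per trial: on non-clamp trials the peak displacement
|e| + Gaussian noise (default σ = 0.15 cm, the order of the published
pre-exposure variability), truncated at zero because displacement
magnitudes cannot be negative; on clamp trials the subject peak force,
equal to the model's adaptation ratio times the peak object force with
5% multiplicative noise. All draws flow from one seed.

What it does *not* emulate: within-trial kinematic variability,
reaction times or movement-duration failures, trial repeats, learning
of the compliance itself, or any structured (autocorrelated,
signal-dependent) noise. Passing tests therefore show that the
pipeline recovers the truth under the assumed noise model, not that
real data satisfy that model. Two consequences of the noise model are
worth naming because the validation suites respect them:

* The zero-truncation puts a small positive floor (≈ σ/√(2π) ≈ 0.06 cm)
  under trials whose true error is near zero. The single-context
  *model-selection* suite therefore analyzes cohorts exactly as the
  original pipeline does — subtract the final-8 pre-exposure baseline
  and divide by the series maximum before fitting — which removes the
  floor; without that step a flexible dual-rate fit can absorb the
  floor as a spurious slow state. The *parameter-recovery* suite fits
  the raw mean series instead, since its question is whether the fitter
  returns the generative parameters for the observable the generator
  actually produces.
* Between-subject rate heterogeneity makes the cohort mean a mixture of
  exponentials, which is genuinely not single-rate. The recovery and
  model-selection suites are therefore run at their stated conditions —
  8 subjects, observation noise 0.15 cm — with heterogeneity zero;
  heterogeneity is exercised by the bootstrap and fixture tests.

## Dual-rate diagnostics

Two protocol simulations score the dual-rate signatures of a DRM
parameterization. *Spontaneous recovery*: 250 adaptation trials
(asymptotic for all parameter sets considered), counter-adaptation
(f = −1) until the net state crosses zero, then 100 error-clamp trials;
the score is the maximum net state during the clamp. *Savings*: the
same washout, then re-exposure; the score is the error drop over the
first 5 re-exposure trials minus the naive drop. Because a discrete
trial generically oversteps the zero crossing, the state pair is
linearly interpolated between the bracketing trials so the scored phase
starts at net state exactly zero — single-rate parameterizations then
score exactly 0 rather than inheriting an overshoot artifact, and
fast/slow parameterizations show genuine rebound and savings. Washout
uses counter-adaptation rather than error-driven decay to zero-force,
because the latter drives *both* states to zero and separates nothing.

## Problem sizes and runtime choices

Noise-free self-consistency fits use the full protocols with 20 starts
(50 for the dual-rate refit, whose 4-parameter landscape is flatter).
The stochastic suites use the stated sizes — 100 cohorts for recovery
medians, 50 for BIC consistency, 8 subjects each — with 4 (SRM) and 8
(DRM) multi-starts inside the loops; multi-start count is an optimizer
setting, not a study condition, and noise-free recovery verifies that
these landscapes are found reliably from few starts. Bootstrap tests
use reduced resample counts; the production default remains 1,000.

## Known limitations

* The tuning-function normalization and the exponential form are
  reconstructions from printed anchor conditions, exact at the anchors
  but not guaranteed to match the original code elsewhere.
* The compliance profile used in synthetic work is declared, not
  estimated from data; analyses involving compliance are therefore
  self-consistency demonstrations.
* Fits use the mean series across subjects (individual series are too
  noisy, per the original design); per-subject fitting is supported for
  the exponential time constants only.
* No likelihood-based inference: selection is BIC-from-residuals under
  an implicit iid Gaussian error model, as in the original analysis.
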