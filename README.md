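# ssadapt

State-space models of trial-by-trial motor adaptation to **familiar
object dynamics**, for researchers in sensorimotor learning who want a
tested, reproducible implementation of single-rate, dual-rate and
multiple-context learners together with the experimental protocols,
fitting machinery and synthetic cohorts needed to exercise them.

## The science

Subjects rotate a virtual hammer-like object — a point mass *m* on a
rigid rod of length *r* = 8 cm — through 40° while keeping the grasp
point still. The object loads the hand with a torque τ = *m r*²θ̈, a
tangential force *F*ₜ = *m r*θ̈ and a centripetal force *F*꜀ = *m r*θ̇²;
the handle-frame force is the rod-frame force rotated by the rod angle.
Performance on each trial is the peak handle displacement (cm); on
error-clamp trials the anticipatory force is measured instead and
normalized by the peak force the object itself would have produced,
giving a dimensionless **adaptation ratio** (1 = full compensation).

Trial-by-trial learning is modeled with state-space learners whose state
*x* is an internal estimate of the object's mass:

* **SRM** (single-rate): `x(n+1) = α x(n) + β e(n)`, `e = f − x`, with
  retention constant α and learning rate β; *f* is the relative object
  mass (0 on zero-force trials).
* **DRM** (dual-rate): two such states with separate (α₁, β₁) and
  (α₂, β₂) share the error and sum to the output — the fast/slow
  architecture that explains spontaneous recovery and savings in novel
  force-field learning.
* **MCSRM** (multiple-context single-rate): a 16-element state vector
  **z** over visual-orientation contexts spaced 22.5° apart. A Gaussian
  context-selection vector **c**(θ; σ, d) — 1 at the current
  orientation, decaying to an offset *d* at ±180° — weights both the
  read-out `x = c·z` and the credit assignment
  `z ← α z + β e c`. The observed error is the mass error scaled by an
  orientation- and sign-dependent arm compliance *k* and gain *g*
  (units cm).

Models are fit to mean peak-displacement series by bounded nonlinear
least squares with Latin-hypercube multi-start, and compared with
`BIC = n ln σ²ₑ + k ln n`; a BIC difference above 4.6 (Bayes factor 10)
counts as strong evidence. The central scientific claim the package
reproduces: adaptation to *familiar* dynamics is governed by a
**single-rate, context-dependent** process — the dual-rate model's
extra parameters are not justified, adaptation and de-adaptation share
one time constant, and the fitted dual-rate solution shows neither
spontaneous recovery nor savings.

Because the original trial series are not public, the package ships a
first-class synthetic-cohort generator (`ssadapt.synthetic_data`) that
simulates subjects from the published best-fit parameters with
observation noise, and every analysis is validated by parameter
recovery on such cohorts.

## Worked example

```python
import ssadapt as sa
from ssadapt.analysis import normalize_exp1

sched, cohort, truth = sa.make_fixture("exp1_srm")   # 8 synthetic subjects
y = normalize_exp1(cohort.mean_series(), sched)

fit_srm = sa.fit_model(y, sched, "srm", n_starts=20, seed=1)
fit_drm = sa.fit_model(y, sched, "drm", n_starts=20, seed=1)
print(fit_srm.params, fit_srm.r_squared)
print(sa.select_model(fit_srm, fit_drm))
```

Output (abridged):

```
{'alpha': 0.9530, 'beta': 0.2096}  0.8810
{'delta_bic': 11.4, 'favored': 'srm', 'strong_evidence': True}
```

The recovered rates sit next to the generative truth (α = 0.9513,
β = 0.2150), and the dual-rate model's two extra parameters are
penalized away — BIC prefers the single-rate account of data that were
in fact produced by a single-rate process. Fitting a single exponential
to each subject's exposure and post-exposure phases gives matching time
constants (3.4 ± 0.6 vs 3.2 ± 0.9 trials on this cohort), the
single-rate signature.

The numbered scripts under `analysis/` walk through the full study:
schedule construction (`01`), the single-context SRM/DRM comparison
(`02`), Gaussian-tuned generalization and the 4- vs 10-parameter tuning
comparison (`03`), adaptation versus object mass (`04`), dual- and
five-context switching (`05`), and the parameter-recovery /
model-selection validation (`06`). Each writes its tables to
`results/`.

A thin CLI mirrors the library:

```bash
ssadapt schedule --experiment exp1 --seed 1 --out sched.json
ssadapt synth --fixture exp1_srm --out cohort.csv
ssadapt fit --model srm --series cohort.csv --schedule sched.json --out fit.json
```

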