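"""Synthetic per-subject cohorts with the statistical structure the
analysis assumes.

The raw trial series of the original study are not deposited, so every
downstream stage (fitting, model selection, bootstrap, figure-analog
analyses) is exercised on generated cohorts instead.  A cohort is built
by perturbing the generative model's rate constants per subject
(multiplicative lognormal heterogeneity), simulating the model over the
schedule, and adding zero-truncated Gaussian observation noise to the
peak displacements.  Error-clamp trials yield a subject peak force equal
to the model's adaptation ratio times the peak force the object itself
would have produced, with multiplicative noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import ObjectSpec, peak_object_force
from .models import (
    ComplianceProfile,
    DRMParams,
    GaussianTuning,
    MCSRMParams,
    SRMParams,
    simulate,
    unit_compliance,
    REFERENCE_MASS_FRAC,
)
from .schedules import Schedule, build_schedule

#: Canonical body mass used to convert mass fractions to kilograms.
DEFAULT_BODY_MASS_KG = 70.0

#: Published single-context SRM rates used as generative truth in fixtures.
EXP1_SRM_TRUTH = SRMParams(retention=0.9513, learning_rate=0.2150)
#: Published context-model parameters used as generative truth in fixtures.
MCSRM4_TRUTH = MCSRMParams(0.9811, 0.0451, GaussianTuning(sigma_deg=26.3, offset=0.09))
#: Published dual-rate parameters (slow state first).
EXP1_DRM_TRUTH = DRMParams(
    retention_slow=0.9808, learning_slow=0.0139,
    retention_fast=0.9453, learning_fast=0.2053,
)


@dataclass(frozen=True)
class GenerativeSpec:
    """Ground truth plus noise structure for a synthetic cohort."""

    model_kind: str
    params: SRMParams | DRMParams | MCSRMParams
    compliance: ComplianceProfile | None = None
    observation_noise_sd: float = 0.15  # cm, per trial
    subject_heterogeneity_sd: float = 0.05  # relative SD on alpha, beta
    n_subjects: int = 8
    seed: int = 0
    clamp_force_noise_sd: float = 0.05  # fraction of peak object force
    body_mass_kg: float = DEFAULT_BODY_MASS_KG

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        for sd in (self.observation_noise_sd, self.subject_heterogeneity_sd, self.clamp_force_noise_sd):
            if sd < 0:
                raise ValueError("noise SDs must be nonnegative")


@dataclass
class CohortSeries:
    """Per-subject observations aligned to one schedule.

    ``displacement`` is (n_subjects, n_trials) peak displacement in cm,
    NaN on error-clamp trials; ``clamp_force`` is peak force in newtons,
    NaN off clamp trials.
    """

    schedule: Schedule
    displacement: np.ndarray
    clamp_force: np.ndarray
    subject_params: list = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return self.displacement.shape[0]

    def mean_series(self) -> np.ndarray:
        """Mean peak displacement across subjects (NaN on clamp trials)."""
        return _nanmean_cols(self.displacement)

    def mean_clamp_force(self) -> np.ndarray:
        return _nanmean_cols(self.clamp_force)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in range(self.n_subjects):
            for t in self.schedule.trials:
                rows.append(
                    {
                        "subject_id": s,
                        "trial": t.index,
                        "mode": t.mode,
                        "orientation_deg": t.orientation_deg,
                        "peak_displacement_cm": self.displacement[s, t.index],
                        "clamp_force_n": self.clamp_force[s, t.index],
                    }
                )
        return pd.DataFrame(rows)


def _nanmean_cols(arr: np.ndarray) -> np.ndarray:
    """Column nanmean that returns NaN (silently) for all-NaN columns."""
    mask = np.isfinite(arr)
    counts = mask.sum(axis=0)
    sums = np.where(mask, arr, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def _perturb_rates(params, factor_a: float, factor_b: float):
    clip = lambda v: float(np.clip(v, 0.0, 1.0))
    if isinstance(params, SRMParams):
        return SRMParams(clip(params.retention * factor_a), clip(params.learning_rate * factor_b))
    if isinstance(params, DRMParams):
        return DRMParams(
            clip(params.retention_slow * factor_a), clip(params.learning_slow * factor_b),
            clip(params.retention_fast * factor_a), clip(params.learning_fast * factor_b),
        )
    if isinstance(params, MCSRMParams):
        return MCSRMParams(clip(params.retention * factor_a), clip(params.learning_rate * factor_b), params.tuning)
    raise TypeError(f"unsupported params {type(params)!r}")


def generate_cohort(schedule: Schedule, spec: GenerativeSpec) -> CohortSeries:
    """Simulate a cohort of subjects over a schedule, deterministically
    per seed."""
    rng = np.random.default_rng(spec.seed)
    n = len(schedule)
    modes = schedule.modes()
    clamp = modes == "error_clamp"
    compliance = spec.compliance
    if spec.model_kind.startswith("mcsrm") and compliance is None:
        compliance = unit_compliance()

    # peak object force per distinct mass (same canonical kinematics for all)
    peak_force = {}
    for t in schedule.trials:
        if t.mass_frac_bm not in peak_force:
            obj = ObjectSpec(mass_kg=t.mass_frac_bm * spec.body_mass_kg)
            peak_force[t.mass_frac_bm] = peak_object_force(obj)
    masses = np.array([t.mass_frac_bm for t in schedule.trials])
    pf = np.array([peak_force[m] for m in masses])

    disp = np.full((spec.n_subjects, n), np.nan)
    force = np.full((spec.n_subjects, n), np.nan)
    subject_params = []
    cv = spec.subject_heterogeneity_sd
    for s in range(spec.n_subjects):
        if cv > 0:
            fa, fb = np.exp(rng.normal(0.0, cv, size=2))
        else:
            fa = fb = 1.0
        p_s = _perturb_rates(spec.params, fa, fb)
        subject_params.append(p_s)
        ts = simulate(spec.model_kind, schedule, p_s, compliance=compliance)
        # displacement on non-clamp trials: |e| plus truncated noise
        noise = rng.normal(0.0, spec.observation_noise_sd, size=n) if spec.observation_noise_sd > 0 else np.zeros(n)
        d = np.clip(ts.abs_error + noise, 0.0, None)
        disp[s, ~clamp] = d[~clamp]
        # clamp trials: subject peak force = adaptation ratio x object peak force
        ratio = np.where(np.isfinite(ts.adaptation_ratio), ts.adaptation_ratio, 0.0)
        fnoise = rng.normal(0.0, spec.clamp_force_noise_sd, size=n) if spec.clamp_force_noise_sd > 0 else np.zeros(n)
        force[s, clamp] = (ratio * pf * (1.0 + fnoise))[clamp]
    return CohortSeries(schedule=schedule, displacement=disp, clamp_force=force, subject_params=subject_params)


_FIXTURES = {
    # name: (experiment, group, schedule seed, cohort seed, n_subjects)
    "exp1_srm": ("exp1", None, 11, 211, 8),
    "exp2_mcsrm": ("exp2", 1, 12, 212, 12),
    "exp4_mcsrm": ("exp4", None, 14, 214, 8),
    "exp5_mcsrm": ("exp5", None, 15, 215, 8),
    "expS1_compliance": ("expS1", None, 16, 216, 12),
}

#: Synthetic, declared calibration truth for the expS1 fixture (the real
#: calibration values were never published as numbers).
SYNTHETIC_S1_COMPLIANCE = ComplianceProfile(
    k_plus=(1.2, 1.0, 0.8, 1.0, 1.4),
    k_minus=(0.9, 1.1, 1.0, 0.8, 1.2),
    gain=1.0,
)


def make_fixture(name: str, seed: int | None = None):
    """Canonical seeded fixture: (schedule, cohort, truth record).

    Ground-truth parameters are the published best-fit values; the
    compliance in the expS1 fixture is a synthetic declared profile.
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    exp, group, sched_seed, cohort_seed, n_subjects = _FIXTURES[name]
    if seed is not None:
        sched_seed, cohort_seed = seed, seed + 1000
    schedule = build_schedule(exp, seed=sched_seed, group=group)
    if name == "exp1_srm":
        spec = GenerativeSpec("srm", EXP1_SRM_TRUTH, n_subjects=n_subjects, seed=cohort_seed)
    elif name == "expS1_compliance":
        spec = GenerativeSpec(
            "srm", EXP1_SRM_TRUTH, compliance=SYNTHETIC_S1_COMPLIANCE,
            n_subjects=n_subjects, seed=cohort_seed,
        )
    else:
        spec = GenerativeSpec(
            "mcsrm4", MCSRM4_TRUTH, compliance=unit_compliance(),
            n_subjects=n_subjects, seed=cohort_seed,
        )
    if name == "expS1_compliance":
        # observations carry the compliance-scaled SRM error
        cohort = _generate_compliance_cohort(schedule, spec)
    else:
        cohort = generate_cohort(schedule, spec)
    truth = {
        "fixture": name,
        "model_kind": spec.model_kind,
        "schedule_seed": sched_seed,
        "cohort_seed": cohort_seed,
        "n_subjects": n_subjects,
        "params": _params_record(spec.params),
        "observation_noise_sd": spec.observation_noise_sd,
        "subject_heterogeneity_sd": spec.subject_heterogeneity_sd,
    }
    if name == "expS1_compliance":
        truth["compliance"] = {
            "k_plus": list(SYNTHETIC_S1_COMPLIANCE.k_plus),
            "k_minus": list(SYNTHETIC_S1_COMPLIANCE.k_minus),
            "gain": SYNTHETIC_S1_COMPLIANCE.gain,
        }
    return schedule, cohort, truth


def _params_record(params) -> dict:
    if isinstance(params, SRMParams):
        return {"model": "SRM", "alpha": params.retention, "beta": params.learning_rate}
    if isinstance(params, DRMParams):
        return {
            "model": "DRM",
            "alpha1": params.retention_slow, "beta1": params.learning_slow,
            "alpha2": params.retention_fast, "beta2": params.learning_fast,
        }
    rec = {"model": "MCSRM4" if isinstance(params.tuning, GaussianTuning) else "MCSRM10",
           "alpha": params.retention, "beta": params.learning_rate}
    if isinstance(params.tuning, GaussianTuning):
        rec.update(sigma_deg=params.tuning.sigma_deg, offset=params.tuning.offset)
    else:
        rec.update(weights=list(params.tuning.weights))
    return rec


def _generate_compliance_cohort(schedule: Schedule, spec: GenerativeSpec) -> CohortSeries:
    """Cohort for the calibration experiment: the observed displacement is
    the compliance-scaled SRM error (mass-unit state update)."""
    rng = np.random.default_rng(spec.seed)
    n = len(schedule)
    modes = schedule.modes()
    clamp = modes == "error_clamp"
    prof = spec.compliance
    disp = np.full((spec.n_subjects, n), np.nan)
    force = np.full((spec.n_subjects, n), np.nan)
    subject_params = []
    from .models import _trial_f  # single source for the f convention

    for s in range(spec.n_subjects):
        if spec.subject_heterogeneity_sd > 0:
            fa, fb = np.exp(rng.normal(0.0, spec.subject_heterogeneity_sd, size=2))
        else:
            fa = fb = 1.0
        p_s = _perturb_rates(spec.params, fa, fb)
        subject_params.append(p_s)
        x = 0.0
        noise = rng.normal(0.0, spec.observation_noise_sd, size=n) if spec.observation_noise_sd > 0 else np.zeros(n)
        for i, t in enumerate(schedule.trials):
            f = _trial_f(t)
            diff = f - x
            k = prof.k_at(t.orientation_deg, positive_error=diff > 0)
            if not clamp[i]:
                disp[s, i] = max(abs(prof.gain * k * diff) + noise[i], 0.0)
                x = p_s.retention * x + p_s.learning_rate * diff
            else:
                x = p_s.retention * x
    return CohortSeries(schedule=schedule, displacement=disp, clamp_force=force, subject_params=subject_params)
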