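"""State-space learners for trial-by-trial adaptation to object dynamics.

Three model families describe how an internal estimate of object mass is
updated from trial errors:

* SRM — single-rate model.  One state ``x`` (the mass estimate), updated
  as ``x <- alpha*x + beta*e`` with error ``e = f - x``, where ``f`` is
  the (relative) object mass, 0 on zero-force trials.
* DRM — dual-rate model.  Two states with separate retention and learning
  rates; their sum is the net mass estimate.
* MCSRM — multiple-context single-rate model.  A 16-element state vector
  ``z`` holds one mass estimate per visual-orientation context (22.5-degree
  spacing).  A context-selection vector ``c`` — a Gaussian tuned to the
  current orientation, value 1 at the current context decaying to an
  offset ``d`` at +-180 degrees — weights both the read-out
  (``x = c . z``) and the credit assignment (``z <- alpha*z + beta*e*c``).
  The observed error is in cm of handle displacement and is the mass
  error scaled by an orientation- and sign-dependent arm compliance ``k``
  and a gain ``g``.

Error-clamp trials measure anticipatory force without kinematic error;
the default update applies pure retention (``e = 0``) on those trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .schedules import Schedule, Trial, wrap_deg, GRID_STEP_DEG, FIVE_ORIENTATIONS

#: The 16 context orientations covering (-180, 180] at 22.5-degree spacing.
ORIENT_GRID = np.round(np.arange(-157.5, 180.0 + 1e-9, GRID_STEP_DEG), 4)
N_CONTEXTS = 16

#: Mass fraction of body mass that defines relative mass f = 1.
REFERENCE_MASS_FRAC = 0.01

MODEL_KINDS = ("srm", "drm", "mcsrm4", "mcsrm10")


def grid_index(orientation_deg: float) -> int:
    """Index of an on-grid orientation in ORIENT_GRID (off-grid rejected)."""
    theta = wrap_deg(orientation_deg)
    idx = (theta - ORIENT_GRID[0]) / GRID_STEP_DEG
    if abs(idx - round(idx)) > 1e-9:
        raise ValueError(f"orientation {orientation_deg} is off the 22.5-degree grid")
    return int(round(idx)) % N_CONTEXTS


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class SRMParams:
    retention: float  # alpha
    learning_rate: float  # beta

    def __post_init__(self) -> None:
        if not (0.0 <= self.retention <= 1.0 and 0.0 <= self.learning_rate <= 1.0):
            raise ValueError("SRM parameters must lie in [0, 1]")


@dataclass(frozen=True)
class DRMParams:
    retention_slow: float  # alpha_1
    learning_slow: float  # beta_1
    retention_fast: float  # alpha_2
    learning_fast: float  # beta_2

    def __post_init__(self) -> None:
        for v in (self.retention_slow, self.learning_slow, self.retention_fast, self.learning_fast):
            if not 0.0 <= v <= 1.0:
                raise ValueError("DRM parameters must lie in [0, 1]")

    def sorted_by_rate(self) -> "DRMParams":
        """Relabel so the fast state carries the larger learning rate."""
        if self.learning_fast >= self.learning_slow:
            return self
        return DRMParams(
            retention_slow=self.retention_fast,
            learning_slow=self.learning_fast,
            retention_fast=self.retention_slow,
            learning_fast=self.learning_slow,
        )


@dataclass(frozen=True)
class GaussianTuning:
    """Two-parameter context tuning: Gaussian width sigma and offset d."""

    sigma_deg: float
    offset: float

    def __post_init__(self) -> None:
        if self.sigma_deg <= 0:
            raise ValueError("sigma_deg must be positive")
        if not 0.0 <= self.offset <= 1.0:
            raise ValueError("offset must lie in [0, 1]")


@dataclass(frozen=True)
class FreeTuning:
    """Eight free symmetric weights for lags 22.5..180 deg (lag 0 fixed at 1)."""

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.weights) != 8:
            raise ValueError("FreeTuning requires 8 weights (lags 22.5..180 deg)")
        if any(not 0.0 <= w <= 1.0 for w in self.weights):
            raise ValueError("tuning weights must lie in [0, 1]")


@dataclass(frozen=True)
class MCSRMParams:
    retention: float
    learning_rate: float
    tuning: GaussianTuning | FreeTuning

    def __post_init__(self) -> None:
        if not (0.0 <= self.retention <= 1.0 and 0.0 <= self.learning_rate <= 1.0):
            raise ValueError("MCSRM rate parameters must lie in [0, 1]")

    @property
    def kind(self) -> str:
        return "mcsrm4" if isinstance(self.tuning, GaussianTuning) else "mcsrm10"


@dataclass(frozen=True)
class ComplianceProfile:
    """Arm compliance (cm of displacement per unit mass error) at the five
    calibrated orientations, split by error sign, plus an overall gain."""

    orientations: tuple[float, ...] = FIVE_ORIENTATIONS
    k_plus: tuple[float, ...] = (1.0,) * 5
    k_minus: tuple[float, ...] = (1.0,) * 5
    gain: float = 1.0

    def __post_init__(self) -> None:
        if len(self.k_plus) != len(self.orientations) or len(self.k_minus) != len(self.orientations):
            raise ValueError("one k per calibrated orientation")
        if any(k <= 0 for k in self.k_plus) or any(k <= 0 for k in self.k_minus):
            raise ValueError("compliances must be positive")
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    def k_at(self, orientation_deg: float, positive_error: bool) -> float:
        """Compliance at any grid orientation, circularly interpolated
        between the calibrated angles."""
        ks = np.asarray(self.k_plus if positive_error else self.k_minus, dtype=float)
        cal = np.asarray([wrap_deg(o) for o in self.orientations], dtype=float)
        theta = wrap_deg(orientation_deg) % 360.0
        cal360 = cal % 360.0
        order = np.argsort(cal360)
        angles = cal360[order]
        vals = ks[order]
        # closed circle: append first point + 360
        angles = np.append(angles, angles[0] + 360.0)
        vals = np.append(vals, vals[0])
        if theta < angles[0]:
            theta += 360.0
        j = int(np.searchsorted(angles, theta, side="right") - 1)
        span = angles[j + 1] - angles[j]
        w = 0.0 if span == 0 else (theta - angles[j]) / span
        return float((1 - w) * vals[j] + w * vals[j + 1])


def unit_compliance() -> ComplianceProfile:
    """The declared default profile: k+ = k- = 1 everywhere, g = 1."""
    return ComplianceProfile()


# ---------------------------------------------------------------------------
# context tuning


def tuning_vector(current_orientation_deg: float, tuning: GaussianTuning | FreeTuning) -> np.ndarray:
    """Context-selection vector for the 16 orientation contexts.

    For Gaussian tuning the weight at circular lag L (degrees) is

        c(L) = d + (1 - d) * (N(L) - N(180)) / (N(0) - N(180)),

    with N a zero-mean Gaussian of width sigma, so c(0) = 1 and
    c(180) = d exactly.  For free tuning the weight is looked up by
    absolute lag.
    """
    i0 = grid_index(current_orientation_deg)
    lags = np.abs(
        np.array([wrap_deg(ORIENT_GRID[i] - ORIENT_GRID[i0]) for i in range(N_CONTEXTS)])
    )
    lags[lags > 180.0] -= 360.0  # defensive; wrap_deg already bounds to 180
    if isinstance(tuning, FreeTuning):
        table = {0.0: 1.0}
        for k, w in enumerate(tuning.weights, start=1):
            table[round(k * GRID_STEP_DEG, 4)] = w
        return np.array([table[round(abs(l), 4)] for l in lags])
    sigma, d = tuning.sigma_deg, tuning.offset
    n = np.exp(-(lags**2) / (2.0 * sigma**2))
    n180 = np.exp(-(180.0**2) / (2.0 * sigma**2))
    denom = 1.0 - n180
    if denom < 1e-12:
        # sigma -> infinity limit of the affine-rescaled Gaussian
        shape = (180.0**2 - lags**2) / 180.0**2
    else:
        shape = (n - n180) / denom
    return d + (1.0 - d) * shape


# ---------------------------------------------------------------------------
# single steps


def _trial_f(trial: Trial) -> float:
    """Relative object mass driving the error (0 on zero-force trials)."""
    if trial.mode == "zero_force":
        return 0.0
    return trial.mass_frac_bm / REFERENCE_MASS_FRAC


def compliance_error(f: float, x: float, orientation_deg: float, profile: ComplianceProfile) -> float:
    """Displacement error in cm: g * k * (f - x), with k chosen by the
    sign of the mass error (k+ for under-, k- for over-estimation)."""
    diff = f - x
    k = profile.k_at(orientation_deg, positive_error=diff > 0)
    return profile.gain * k * diff


def step_srm(x: float, trial: Trial, params: SRMParams, clamp_update: str = "zero_error"):
    """One SRM update; returns (x_next, e).  On error-clamp trials the
    reported e is f - x but the state update uses e = 0 (retention only),
    or leaves the state frozen when clamp_update='frozen'."""
    f = _trial_f(trial)
    e = f - x
    if trial.mode == "error_clamp":
        x_next = x if clamp_update == "frozen" else params.retention * x
    else:
        x_next = params.retention * x + params.learning_rate * e
    return x_next, e


def step_drm(x1: float, x2: float, trial: Trial, params: DRMParams, clamp_update: str = "zero_error"):
    """One DRM update; returns (x1_next, x2_next, e) with e = f - (x1+x2)."""
    f = _trial_f(trial)
    e = f - (x1 + x2)
    if trial.mode == "error_clamp":
        if clamp_update == "frozen":
            return x1, x2, e
        return params.retention_slow * x1, params.retention_fast * x2, e
    x1n = params.retention_slow * x1 + params.learning_slow * e
    x2n = params.retention_fast * x2 + params.learning_fast * e
    return x1n, x2n, e


def step_mcsrm(
    z: np.ndarray,
    trial: Trial,
    params: MCSRMParams,
    compliance: ComplianceProfile,
    clamp_update: str = "zero_error",
    error_drive: str = "mass_units",
):
    """One MCSRM update; returns (z_next, e_cm, x_net).

    The net state is the tuning-weighted sum of context states; the
    observed error is the compliance-scaled mass error (cm).  By default
    the update is driven by the mass-unit error (f - x_net), so with unit
    compliance the model reduces exactly to the SRM on single-orientation
    schedules; `error_drive='cm_units'` drives it with the cm error
    instead.
    """
    c = tuning_vector(trial.orientation_deg, params.tuning)
    x_net = float(c @ z)
    f = _trial_f(trial)
    e_cm = compliance_error(f, x_net, trial.orientation_deg, compliance)
    if trial.mode == "error_clamp":
        z_next = z.copy() if clamp_update == "frozen" else params.retention * z
    else:
        drive = (f - x_net) if error_drive == "mass_units" else e_cm
        z_next = params.retention * z + params.learning_rate * drive * c
    return z_next, e_cm, x_net


# ---------------------------------------------------------------------------
# whole-schedule simulation


@dataclass
class TrialSeries:
    """Per-trial model outputs aligned to a schedule."""

    trial: np.ndarray
    mode: np.ndarray
    orientation_deg: np.ndarray
    f: np.ndarray
    x_net: np.ndarray
    error: np.ndarray
    abs_error: np.ndarray
    adaptation_ratio: np.ndarray  # x/f, nan where f == 0

    def __len__(self) -> int:
        return len(self.trial)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": self.trial,
                "mode": self.mode,
                "orientation_deg": self.orientation_deg,
                "f": self.f,
                "x_net": self.x_net,
                "error": self.error,
                "abs_error": self.abs_error,
                "adaptation_ratio": self.adaptation_ratio,
            }
        )


def _series_from(schedule: Schedule, f, x, e) -> TrialSeries:
    f = np.asarray(f, dtype=float)
    x = np.asarray(x, dtype=float)
    e = np.asarray(e, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(f > 0, x / np.where(f > 0, f, 1.0), np.nan)
    return TrialSeries(
        trial=np.arange(len(schedule)),
        mode=schedule.modes(),
        orientation_deg=schedule.orientations(),
        f=f,
        x_net=x,
        error=e,
        abs_error=np.abs(e),
        adaptation_ratio=ratio,
    )


def simulate(
    model_kind: str,
    schedule: Schedule,
    params,
    compliance: ComplianceProfile | None = None,
    initial_state: float | np.ndarray = 0.0,
    clamp_update: str = "zero_error",
    error_drive: str = "mass_units",
) -> TrialSeries:
    """Deterministically step a model over every trial of a schedule.

    For the context models `compliance` is required and errors are in cm;
    for SRM/DRM errors are dimensionless mass errors.  `x_net` always
    reports the net mass estimate before the trial's update.
    """
    kind = model_kind.lower()
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    n = len(schedule)
    fs = np.empty(n)
    xs = np.empty(n)
    es = np.empty(n)

    if kind == "srm":
        x = float(initial_state)
        for i, t in enumerate(schedule.trials):
            fs[i] = _trial_f(t)
            xs[i] = x
            x, es[i] = step_srm(x, t, params, clamp_update)
        return _series_from(schedule, fs, xs, es)

    if kind == "drm":
        if np.isscalar(initial_state):
            x1 = x2 = float(initial_state) / 2.0
        else:
            x1, x2 = (float(v) for v in initial_state)
        for i, t in enumerate(schedule.trials):
            fs[i] = _trial_f(t)
            xs[i] = x1 + x2
            x1, x2, es[i] = step_drm(x1, x2, t, params, clamp_update)
        return _series_from(schedule, fs, xs, es)

    # MCSRM
    if compliance is None:
        raise ValueError("MCSRM simulation requires a compliance profile")
    if np.isscalar(initial_state):
        z = np.full(N_CONTEXTS, float(initial_state))
    else:
        z = np.asarray(initial_state, dtype=float).copy()
        if z.shape != (N_CONTEXTS,):
            raise ValueError(f"initial state must have {N_CONTEXTS} elements")
    alpha, beta = params.retention, params.learning_rate
    # cache per-orientation tuning vectors and compliances
    c_cache: dict[float, np.ndarray] = {}
    kp_cache: dict[float, float] = {}
    km_cache: dict[float, float] = {}
    for t in schedule.trials:
        th = t.orientation_deg
        if th not in c_cache:
            c_cache[th] = tuning_vector(th, params.tuning)
            kp_cache[th] = compliance.k_at(th, True)
            km_cache[th] = compliance.k_at(th, False)
    g = compliance.gain
    for i, t in enumerate(schedule.trials):
        th = t.orientation_deg
        c = c_cache[th]
        x = float(c @ z)
        f = _trial_f(t)
        diff = f - x
        k = kp_cache[th] if diff > 0 else km_cache[th]
        e_cm = g * k * diff
        fs[i], xs[i], es[i] = f, x, e_cm
        if t.mode == "error_clamp":
            if clamp_update != "frozen":
                z = alpha * z
        else:
            drive = diff if error_drive == "mass_units" else e_cm
            z = alpha * z + beta * drive * c
    return _series_from(schedule, fs, xs, es)


# ---------------------------------------------------------------------------
# dual-rate diagnostics


def _const_schedule(mode: str, n: int, mass_frac: float = REFERENCE_MASS_FRAC) -> list[Trial]:
    return [
        Trial(i, mode, 0.0, "CW" if i % 2 == 0 else "CCW", mass_frac, "diag", 0)
        for i in range(n)
    ]


def _drm_run(params: DRMParams, x1: float, x2: float, f_seq):
    """Iterate the DRM over a sequence of (f, is_clamp) pairs."""
    a1, b1 = params.retention_slow, params.learning_slow
    a2, b2 = params.retention_fast, params.learning_fast
    xs, es = [], []
    for f, clamp in f_seq:
        x = x1 + x2
        e = f - x
        xs.append(x)
        es.append(e)
        if clamp:
            x1, x2 = a1 * x1, a2 * x2
        else:
            x1, x2 = a1 * x1 + b1 * e, a2 * x2 + b2 * e
    return np.array(xs), np.array(es), x1, x2


def diagnose_drm(
    params: DRMParams,
    protocol: str,
    n_adapt: int = 250,
    n_clamp: int = 100,
    max_counter: int = 1000,
) -> float:
    """Score the two dual-rate signatures for a DRM parameterization.

    spontaneous_recovery: adapt to f = 1, counter-adapt with f = -1 until
    the net state first crosses zero, then run error-clamp trials; the
    score is the maximum net state during the clamp phase (rebound above
    zero indicates spontaneous recovery).

    savings: adapt to f = 1, wash out by counter-adaptation (f = -1)
    until the net state first returns to zero, re-expose to f = 1; the
    score is the error drop over the first 5 re-exposure trials minus the
    same drop during naive learning (positive means faster relearning).
    Error-driven decay alone (f = 0) approaches zero without separating
    the states, so counter-adaptation is the discriminating washout.
    """
    if protocol == "spontaneous_recovery":
        _, _, x1, x2 = _drm_run(params, 0.0, 0.0, [(1.0, False)] * n_adapt)
        x1, x2 = _counter_adapt_to_zero(params, x1, x2, max_counter)
        xs, _, _, _ = _drm_run(params, x1, x2, [(0.0, True)] * n_clamp)
        return float(np.max(xs))
    if protocol == "savings":
        _, e_naive, x1, x2 = _drm_run(params, 0.0, 0.0, [(1.0, False)] * n_adapt)
        naive_drop = float(e_naive[0] - e_naive[4])
        x1, x2 = _counter_adapt_to_zero(params, x1, x2, max_counter)
        _, e_re, _, _ = _drm_run(params, x1, x2, [(1.0, False)] * 5)
        re_drop = float(e_re[0] - e_re[4])
        return re_drop - naive_drop
    raise ValueError(f"unknown protocol {protocol!r}")


def _counter_adapt_to_zero(params: DRMParams, x1: float, x2: float, max_counter: int):
    """Counter-adapt (f = -1) until the net state crosses zero, then
    interpolate the state pair between the bracketing trials so the next
    phase starts at net state exactly 0.  A discrete trial generically
    oversteps the crossing; without the interpolation the score would mix
    residual adaptation into the rebound/savings measure."""
    for _ in range(max_counter):
        if x1 + x2 <= 0:
            break
        e = -1.0 - (x1 + x2)
        x1n = params.retention_slow * x1 + params.learning_slow * e
        x2n = params.retention_fast * x2 + params.learning_fast * e
        if x1n + x2n <= 0:
            pre, post = x1 + x2, x1n + x2n
            lam = pre / (pre - post) if pre != post else 1.0
            return x1 + lam * (x1n - x1), x2 + lam * (x2n - x2)
        x1, x2 = x1n, x2n
    return x1, x2
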