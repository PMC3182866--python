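"""Model fitting, model selection and bootstrap machinery.

Models are fit by bounded nonlinear least squares: the model's absolute
error output is matched to the observed peak-displacement trial series
(mean across subjects) over all non-clamp trials, with seeded
Latin-hypercube multi-start to avoid local minima.  Model selection uses
the Bayesian Information Criterion computed from the residual variance,

    BIC = n ln(sigma_e^2) + k ln(n),

with a difference of 4.6 (Bayes factor 10) taken as strong evidence.
Bootstrap confidence intervals resample subjects with replacement and
refit the mean series of each resample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from . import models
from .models import (
    ComplianceProfile,
    DRMParams,
    FreeTuning,
    GaussianTuning,
    MCSRMParams,
    SRMParams,
    simulate,
    unit_compliance,
)
from .schedules import Schedule

#: Strong-evidence threshold: BIC difference equivalent to Bayes factor 10.
BIC_STRONG_EVIDENCE = 4.6

DEFAULT_N_STARTS = 20

_BOUNDS = {
    "srm": ([0.0, 0.0], [1.0, 1.0]),
    "drm": ([0.0] * 4, [1.0] * 4),
    "mcsrm4": ([0.0, 0.0, 1.0, 0.0], [1.0, 1.0, 180.0, 1.0]),
    "mcsrm10": ([0.0] * 10, [1.0] * 10),
}
_GAIN_BOUNDS = (0.5, 2.0)
_N_PARAMS = {"srm": 2, "drm": 4, "mcsrm4": 4, "mcsrm10": 10}
_PARAM_NAMES = {
    "srm": ["alpha", "beta"],
    "drm": ["alpha1", "beta1", "alpha2", "beta2"],
    "mcsrm4": ["alpha", "beta", "sigma_deg", "offset"],
    "mcsrm10": ["alpha", "beta"] + [f"w{i}" for i in range(1, 9)],
}


@dataclass
class FitResult:
    model_kind: str
    params: dict
    residual_variance: float
    r_squared: float
    bic: float
    n_trials: int
    n_params: int
    n_starts: int
    converged: bool
    cost: float
    bootstrap_ci: dict | None = None
    metadata: dict = field(default_factory=dict)

    def params_object(self):
        return _decode(self.model_kind, np.array([self.params[k] for k in _PARAM_NAMES[self.model_kind]]))

    def to_dict(self) -> dict:
        out = {
            "model_kind": self.model_kind,
            "params": self.params,
            "residual_variance": self.residual_variance,
            "r_squared": self.r_squared,
            "bic": self.bic,
            "n_trials": self.n_trials,
            "n_params": self.n_params,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "cost": self.cost,
            "metadata": self.metadata,
        }
        if self.bootstrap_ci is not None:
            out["bootstrap_ci"] = self.bootstrap_ci
        return out


def _decode(model_kind: str, theta: np.ndarray):
    if model_kind == "srm":
        return SRMParams(retention=theta[0], learning_rate=theta[1])
    if model_kind == "drm":
        return DRMParams(*theta).sorted_by_rate()
    if model_kind == "mcsrm4":
        return MCSRMParams(theta[0], theta[1], GaussianTuning(theta[2], theta[3]))
    if model_kind == "mcsrm10":
        return MCSRMParams(theta[0], theta[1], FreeTuning(tuple(theta[2:10])))
    raise ValueError(f"unknown model kind {model_kind!r}")


def _fit_mask(schedule: Schedule, observed: np.ndarray) -> np.ndarray:
    """Trials entering the least squares: displacement exists only on
    non-clamp trials, and familiarization trials are excluded."""
    modes = schedule.modes()
    fam = np.array([t.familiarization for t in schedule.trials])
    return (modes != "error_clamp") & ~fam & np.isfinite(observed)


def fit_model(
    series_list: Sequence[np.ndarray] | np.ndarray,
    schedules: Sequence[Schedule] | Schedule,
    model_kind: str,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
    fixed_compliance: ComplianceProfile | None = None,
    fit_gain: bool = True,
    clamp_update: str = "zero_error",
    error_drive: str = "mass_units",
    bounds: tuple | None = None,
) -> FitResult:
    """Fit one model to one or more aligned mean displacement series.

    Multiple (series, schedule) pairs share one parameter vector and are
    fit concurrently (summed squared residuals).  For context models a
    compliance profile is required; its gain g is refit as an extra free
    parameter unless ``fit_gain=False``.
    """
    kind = model_kind.lower()
    if kind not in _BOUNDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    if isinstance(schedules, Schedule):
        schedules = [schedules]
        series_list = [np.asarray(series_list, dtype=float)]
    else:
        series_list = [np.asarray(s, dtype=float) for s in series_list]
    if len(series_list) != len(schedules):
        raise ValueError("series/schedule count mismatch")
    for y, sch in zip(series_list, schedules):
        if len(y) != len(sch):
            raise ValueError("series not aligned with schedule")
        if np.any(np.isinf(y)):
            raise ValueError("non-finite series values")

    is_context = kind in ("mcsrm4", "mcsrm10")
    if is_context and fixed_compliance is None:
        raise ValueError("context models require a compliance profile")
    gain_free = is_context and fit_gain

    lb, ub = bounds if bounds is not None else _BOUNDS[kind]
    lb, ub = list(lb), list(ub)
    if gain_free:
        lb, ub = lb + [_GAIN_BOUNDS[0]], ub + [_GAIN_BOUNDS[1]]
    lb, ub = np.array(lb), np.array(ub)
    if np.any(lb >= ub):
        raise ValueError("infeasible bounds")

    masks = [_fit_mask(sch, y) for sch, y in zip(schedules, series_list)]
    y_obs = np.concatenate([y[m] for y, m in zip(series_list, masks)])

    def residuals(theta: np.ndarray) -> np.ndarray:
        core = theta[:-1] if gain_free else theta
        p = _decode(kind, core)
        comp = fixed_compliance
        if gain_free:
            comp = ComplianceProfile(
                orientations=fixed_compliance.orientations,
                k_plus=fixed_compliance.k_plus,
                k_minus=fixed_compliance.k_minus,
                gain=float(theta[-1]),
            )
        pred = []
        with np.errstate(over="ignore", invalid="ignore"):
            for sch, m in zip(schedules, masks):
                ts = simulate(kind, sch, p, compliance=comp, clamp_update=clamp_update, error_drive=error_drive)
                pred.append(ts.abs_error[m])
        out = np.concatenate(pred) - y_obs
        # unstable parameter regions (divergent state) get a large finite cost
        return np.clip(np.nan_to_num(out, nan=1e3, posinf=1e3, neginf=-1e3), -1e3, 1e3)

    sampler = qmc.LatinHypercube(d=len(lb), seed=seed)
    starts = qmc.scale(sampler.random(n_starts), lb, ub)
    best = None
    n_ok = 0
    for x0 in starts:
        try:
            sol = least_squares(
                residuals, x0, bounds=(lb, ub), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000,
            )
        except Exception:
            continue
        n_ok += 1
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimizer starts failed")

    theta = best.x
    core = theta[:-1] if gain_free else theta
    p_obj = _decode(kind, core)
    # re-encode (DRM may have been relabeled fast/slow)
    values = _encode(kind, p_obj)
    params = dict(zip(_PARAM_NAMES[kind], values))
    if gain_free:
        params["gain"] = float(theta[-1])

    res = residuals(theta)
    n = len(y_obs)
    ss_res = float(res @ res)
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    sigma2 = ss_res / n
    # a (numerically) constant series has no variance to explain
    tiny = 1e-12 * n * max(float(np.max(np.abs(y_obs)))**2, 1e-300)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > tiny else 0.0
    k = _N_PARAMS[kind] + (1 if gain_free else 0)
    return FitResult(
        model_kind=kind,
        params=params,
        residual_variance=sigma2,
        r_squared=r2,
        bic=bic(sigma2, k, n),
        n_trials=n,
        n_params=k,
        n_starts=n_ok,
        converged=bool(best.status > 0),
        cost=float(best.cost),
        metadata={"clamp_update": clamp_update, "error_drive": error_drive},
    )


def _encode(model_kind: str, p) -> list[float]:
    if model_kind == "srm":
        return [p.retention, p.learning_rate]
    if model_kind == "drm":
        return [p.retention_slow, p.learning_slow, p.retention_fast, p.learning_fast]
    if model_kind == "mcsrm4":
        return [p.retention, p.learning_rate, p.tuning.sigma_deg, p.tuning.offset]
    return [p.retention, p.learning_rate, *p.tuning.weights]


def bic(residual_variance: float, n_params: int, n_trials: int) -> float:
    """BIC = n ln(sigma_e^2) + k ln(n)."""
    if n_trials <= n_params:
        raise ValueError("need more trials than parameters")
    if residual_variance <= 0:
        warnings.warn("zero residual variance; BIC is -inf", RuntimeWarning)
        return -np.inf
    return float(n_trials * np.log(residual_variance) + n_params * np.log(n_trials))


def select_model(fit_a: FitResult, fit_b: FitResult, threshold: float = BIC_STRONG_EVIDENCE) -> dict:
    """Compare two fits of the same series by BIC difference."""
    if fit_a.n_trials != fit_b.n_trials:
        raise ValueError("fits are not on the same series (n_trials differ)")
    delta = abs(fit_a.bic - fit_b.bic)
    favored = fit_a if fit_a.bic <= fit_b.bic else fit_b
    return {
        "delta_bic": float(delta),
        "favored": favored.model_kind,
        "strong_evidence": bool(delta > threshold),
        "bic_a": fit_a.bic,
        "bic_b": fit_b.bic,
        "threshold": threshold,
    }


def bootstrap_ci(
    cohort,
    model_kind: str,
    n_boot: int = 1000,
    seed: int = 0,
    n_starts: int = 5,
    unique_resamples: bool = True,
    max_retry_factor: int = 10,
    **fit_kwargs,
) -> dict:
    """Subject-level bootstrap 95% CIs for one model's parameters.

    Draws seeded with-replacement resamples of subjects (re-drawing
    duplicated multisets up to a retry cap when ``unique_resamples``),
    refits the mean series of each resample, and returns 2.5/97.5
    percentiles per parameter.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    disp = np.asarray(cohort.displacement, dtype=float)
    n_subj = disp.shape[0]
    if n_subj < 2:
        raise ValueError("bootstrap requires at least 2 subjects")
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    resamples: list[np.ndarray] = []
    attempts = 0
    cap = max_retry_factor * n_boot
    while len(resamples) < n_boot and attempts < cap:
        draw = rng.integers(0, n_subj, size=n_subj)
        key = tuple(sorted(draw.tolist()))
        attempts += 1
        if unique_resamples and key in seen:
            continue
        seen.add(key)
        resamples.append(draw)
    if len(resamples) < n_boot:
        warnings.warn("could not draw enough unique resamples; accepting duplicates", RuntimeWarning)
        while len(resamples) < n_boot:
            resamples.append(rng.integers(0, n_subj, size=n_subj))

    finite = np.isfinite(disp)
    estimates: dict[str, list[float]] = {}
    for i, draw in enumerate(resamples):
        sub, mask = disp[draw], finite[draw]
        counts = mask.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean_series = np.where(
                counts > 0,
                np.where(mask, sub, 0.0).sum(axis=0) / np.maximum(counts, 1),
                np.nan,
            )
        fit = fit_model(mean_series, cohort.schedule, model_kind, n_starts=n_starts,
                        seed=seed + 1 + i, **fit_kwargs)
        for name, val in fit.params.items():
            estimates.setdefault(name, []).append(val)
    return {
        name: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for name, v in estimates.items()
    }


# ---------------------------------------------------------------------------
# exponential time constants


@dataclass
class ExpFit:
    """Single exponential with offset: y(n) = a + b exp(-n / t)."""

    asymptote: float
    amplitude: float
    time_constant_trials: float
    identifiable: bool
    r_squared: float


def fit_exponential(series: np.ndarray, phase_window: tuple[int, int] | None = None) -> ExpFit:
    """Least-squares single-exponential fit over a window of trials.

    ``n`` counts trials from the start of the window.  A constant or
    non-decaying series leaves t unidentifiable and is flagged.
    """
    y = np.asarray(series, dtype=float)
    if phase_window is not None:
        y = y[phase_window[0]:phase_window[1]]
    y = y[np.isfinite(y)]
    if len(y) < 4:
        raise ValueError("window must contain at least 4 finite values")
    n = np.arange(len(y), dtype=float)
    scale = max(np.ptp(y), 1e-12)

    t_lo, t_hi = 1e-2, 1e5

    def resid(theta):
        a, b, t = theta
        return a + b * np.exp(-n / t) - y

    best = None
    for t0 in (1.0, 3.0, 10.0, 30.0, 100.0):
        x0 = [y[-1], y[0] - y[-1], t0]
        sol = least_squares(
            resid, x0,
            bounds=([-np.inf, -np.inf, t_lo], [np.inf, np.inf, t_hi]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    a, b, t = best.x
    ss_res = 2 * best.cost
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    identifiable = abs(b) > 1e-8 * scale and t_lo * 1.01 < t < t_hi * 0.99
    return ExpFit(
        asymptote=float(a),
        amplitude=float(b),
        time_constant_trials=float(t),
        identifiable=bool(identifiable),
        r_squared=float(r2),
    )


# ---------------------------------------------------------------------------
# compliance calibration (adapt/de-adapt cycles at five orientations)


def _compliance_groups(schedule: Schedule, alpha: float, beta: float):
    """Simulate the modified SRM (state in mass units) over the schedule
    and return, per trial, |f - x| plus the (orientation, sign) group."""
    x = 0.0
    m = np.empty(len(schedule))
    keys = []
    for i, t in enumerate(schedule.trials):
        f = models._trial_f(t)
        diff = f - x
        m[i] = abs(diff)
        keys.append((t.orientation_deg, diff > 0))
        if t.mode == "error_clamp":
            x = alpha * x
        else:
            x = alpha * x + beta * diff
    return m, keys


def fit_compliance(
    series: np.ndarray,
    schedule: Schedule,
    seed: int = 0,
    n_starts: int = DEFAULT_N_STARTS,
) -> tuple[ComplianceProfile, SRMParams, FitResult]:
    """Jointly fit SRM rates and the 10-value compliance profile to a
    calibration series (adapt/de-adapt cycles at the five orientations).

    The state update is driven by the mass-unit error, so the compliances
    enter the predicted displacement linearly and are profiled out in
    closed form for each (alpha, beta); only the two rates are optimized
    nonlinearly.  The gain g is fixed at 1 here (this is the
    calibration), which pins the k scale; the convention is recorded in
    the result metadata.
    """
    y = np.asarray(series, dtype=float)
    if len(y) != len(schedule):
        raise ValueError("series not aligned with schedule")
    oris = sorted(set(t.orientation_deg for t in schedule.trials))
    required = set(models.FIVE_ORIENTATIONS)
    if not required.issubset(set(oris)):
        raise ValueError("calibration schedule must cover all five orientations")
    mask = _fit_mask(schedule, y)
    y_fit = y[mask]

    def solve_k(alpha, beta):
        m, keys = _compliance_groups(schedule, alpha, beta)
        m, keys = m[mask], [k for k, keep in zip(keys, mask) if keep]
        khat: dict[tuple, float] = {}
        pred = np.zeros_like(y_fit)
        groups: dict[tuple, list[int]] = {}
        for i, key in enumerate(keys):
            groups.setdefault(key, []).append(i)
        for key, idx in groups.items():
            idx = np.array(idx)
            mm = m[idx]
            denom = float(mm @ mm)
            k = float(mm @ y_fit[idx] / denom) if denom > 0 else 1.0
            k = min(max(k, 1e-6), 10.0)
            khat[key] = k
            pred[idx] = k * mm
        return khat, pred

    def cost(theta):
        _, pred = solve_k(*theta)
        r = pred - y_fit
        return float(r @ r)

    sampler = qmc.LatinHypercube(d=2, seed=seed)
    starts = qmc.scale(sampler.random(n_starts), [0.0, 0.0], [1.0, 1.0])
    best_theta, best_cost = None, np.inf
    for x0 in starts:
        sol = least_squares(
            lambda th: solve_k(*th)[1] - y_fit, x0,
            bounds=([0.0, 0.0], [1.0, 1.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if 2 * sol.cost < best_cost:
            best_cost, best_theta = 2 * sol.cost, sol.x
    alpha, beta = best_theta
    khat, pred = solve_k(alpha, beta)

    def pick(sign: bool) -> tuple[float, ...]:
        return tuple(khat.get((o, sign), 1.0) for o in models.FIVE_ORIENTATIONS)

    profile = ComplianceProfile(k_plus=pick(True), k_minus=pick(False), gain=1.0)
    srm = SRMParams(retention=float(alpha), learning_rate=float(beta))
    n = len(y_fit)
    ss_res = float(np.sum((pred - y_fit) ** 2))
    ss_tot = float(np.sum((y_fit - y_fit.mean()) ** 2))
    sigma2 = ss_res / n
    k_free = 12
    result = FitResult(
        model_kind="srm+compliance",
        params={"alpha": float(alpha), "beta": float(beta),
                **{f"k_plus_{o:g}": v for o, v in zip(models.FIVE_ORIENTATIONS, profile.k_plus)},
                **{f"k_minus_{o:g}": v for o, v in zip(models.FIVE_ORIENTATIONS, profile.k_minus)}},
        residual_variance=sigma2,
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0,
        bic=bic(sigma2, k_free, n) if sigma2 > 0 else -np.inf,
        n_trials=n,
        n_params=k_free,
        n_starts=n_starts,
        converged=True,
        cost=ss_res / 2,
        metadata={
            "scale_convention": "g fixed at 1; state update driven by mass-unit error, "
            "so k is cm per unit relative-mass error and carries the full output scale",
        },
    )
    return profile, srm, result
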