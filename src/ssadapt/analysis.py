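"""Derived measures: series normalization, generalization curves,
adaptation ratios, mass slopes and orientation-change binning.

These reproduce the figure-level analyses of the study: the normalized
single-context learning curve, the composite multi-context de-adaptation
series with half-Gaussian generalization fits, adaptation-versus-mass
slopes at training and transfer orientations, and the binning of
multi-context blocks by the absolute orientation change from the
previous block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dynamics import ObjectSpec, RotationProfile, peak_object_force
from .models import TrialSeries, REFERENCE_MASS_FRAC
from .schedules import Schedule, wrap_deg
from .synthetic_data import CohortSeries, DEFAULT_BODY_MASS_KG


def circular_abs_diff(a: float, b: float) -> float:
    """Absolute circular difference between two angles, in [0, 180]."""
    return abs(wrap_deg(a - b))


# ---------------------------------------------------------------------------
# Experiment 1 normalization


def normalize_exp1(mean_series: np.ndarray, schedule: Schedule, baseline: str = "final8") -> np.ndarray:
    """Two-anchor normalization of the single-context mean series.

    Subtracts the mean over the final 8 pre-exposure trials (or the whole
    pre-exposure phase with ``baseline='whole_pre'``) and divides by the
    maximum over all main-experiment trials, so the output baseline is 0
    and its maximum exactly 1.  Affine transforms of the input map to the
    same output.
    """
    y = np.asarray(mean_series, dtype=float)
    if len(y) != len(schedule):
        raise ValueError("series not aligned with schedule")
    labels = np.array([t.phase_label for t in schedule.trials])
    fam = np.array([t.familiarization for t in schedule.trials])
    pre_idx = np.where(labels == "pre")[0]
    if len(pre_idx) == 0:
        raise ValueError("schedule has no pre-exposure phase")
    if baseline == "final8":
        base_idx = pre_idx[-8:]
    elif baseline == "whole_pre":
        base_idx = pre_idx
    else:
        raise ValueError("baseline must be 'final8' or 'whole_pre'")
    base = np.nanmean(y[base_idx])
    shifted = y - base
    main_vals = shifted[~fam]
    peak = np.nanmax(main_vals)
    if not peak > 0:
        raise ValueError("zero range after baseline subtraction")
    return shifted / peak


# ---------------------------------------------------------------------------
# Experiment 2 composite and generalization curve


@dataclass
class HalfGaussianFit:
    """err(L) = offset + amplitude * exp(-L^2 / (2 width^2)), L >= 0."""

    width_deg: float
    offset: float
    amplitude: float
    degenerate: bool


@dataclass
class GeneralizationCurve:
    relative_orientation_deg: np.ndarray
    deadaptation_error_cm: np.ndarray
    reexposure_error_cm: np.ndarray
    deadaptation_fit: HalfGaussianFit
    reexposure_fit: HalfGaussianFit


_WIDTH_MAX = 1000.0


def fit_half_gaussian(rel_deg: np.ndarray, err: np.ndarray) -> HalfGaussianFit:
    """Bounded least-squares half-Gaussian fit (peak pinned at 0 deg)."""
    rel = np.asarray(rel_deg, dtype=float)
    y = np.asarray(err, dtype=float)

    def resid(theta):
        w, off, amp = theta
        return off + amp * np.exp(-(rel**2) / (2 * w**2)) - y

    best = None
    for w0 in (10.0, 30.0, 90.0):
        sol = least_squares(
            resid, [w0, float(np.min(y)), float(np.ptp(y)) or 1e-6],
            bounds=([1.0, -np.inf, 0.0], [_WIDTH_MAX, np.inf, np.inf]),
            xtol=1e-13, ftol=1e-13,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    w, off, amp = best.x
    scale = max(float(np.max(np.abs(y))), 1e-12)
    # a flat profile leaves the width unconstrained (amplitude ~ 0 or the
    # width pushed to its bound)
    degenerate = bool(w >= 0.999 * _WIDTH_MAX or amp < 1e-6 * scale)
    return HalfGaussianFit(
        width_deg=float(w), offset=float(off), amplitude=float(amp),
        degenerate=degenerate,
    )


def _block_layout(schedule: Schedule):
    """De-adaptation block structure of the multi-context schedule:
    {block_id: (probe_orientation, trial indices)}."""
    blocks: dict[int, list[int]] = {}
    for t in schedule.trials:
        if t.block_id >= 1:
            blocks.setdefault(t.block_id, []).append(t.index)
    out = {}
    for b, idx in blocks.items():
        probes = [schedule.trials[i].orientation_deg for i in idx if schedule.trials[i].mode == "zero_force"]
        out[b] = (probes[0], idx)
    return out


def composite_exp2(cohort: CohortSeries, schedule: Schedule | None = None):
    """Composite series plus generalization curve for the multi-context
    de-adaptation experiment.

    The three repeats at each probe orientation are averaged within
    subject, then across subjects; composite blocks are ordered by
    descending relative orientation (180 -> 0).  De-adaptation and
    re-exposure errors are means over the first 4 zero-force and first 4
    re-exposure trials of each composite block.
    """
    if schedule is None:
        schedule = cohort.schedule
    if schedule.experiment_id != "exp2":
        raise ValueError("composite_exp2 requires an exp2 schedule")
    training = {1: 0.0, 2: 180.0}[schedule.group]
    layout = _block_layout(schedule)
    by_rel: dict[float, list[list[int]]] = {}
    for b, (probe, idx) in sorted(layout.items()):
        rel = round(circular_abs_diff(probe, training), 4)
        by_rel.setdefault(rel, []).append(idx)
    for rel, reps in by_rel.items():
        if len(reps) != 3:
            raise ValueError(f"probe at relative orientation {rel} has {len(reps)} repeats, expected 3")

    disp = cohort.displacement
    rels = sorted(by_rel, reverse=True)  # 180 -> 0
    composite_rows = []
    dead_err, reexp_err = [], []
    modes = schedule.modes()
    for rel in rels:
        reps = by_rel[rel]
        # within-subject average across the 3 repeats, position by position
        block_subj = np.stack([
            np.stack([disp[:, i] for i in idx], axis=1) for idx in reps
        ])  # (3, n_subj, 30)
        with warnings.catch_warnings():
            # clamp positions are NaN for every subject by construction
            warnings.simplefilter("ignore", RuntimeWarning)
            within = np.nanmean(block_subj, axis=0)  # (n_subj, 30)
            across = np.nanmean(within, axis=0)  # (30,)
        block_modes = [modes[i] for i in reps[0]]
        zf_pos = [j for j, m in enumerate(block_modes) if m == "zero_force"]
        re_pos = [j for j, m in enumerate(block_modes) if m == "exposure"]
        dead_err.append(float(np.nanmean(across[zf_pos[:4]])))
        reexp_err.append(float(np.nanmean(across[re_pos[:4]])))
        for j, v in enumerate(across):
            composite_rows.append({
                "relative_orientation_deg": rel,
                "position": j,
                "mode": block_modes[j],
                "mean_displacement_cm": v,
            })
    rel_arr = np.array(rels)
    curve = GeneralizationCurve(
        relative_orientation_deg=rel_arr,
        deadaptation_error_cm=np.array(dead_err),
        reexposure_error_cm=np.array(reexp_err),
        deadaptation_fit=fit_half_gaussian(rel_arr, np.array(dead_err)),
        reexposure_fit=fit_half_gaussian(rel_arr, np.array(reexp_err)),
    )
    return pd.DataFrame(composite_rows), curve


# ---------------------------------------------------------------------------
# adaptation ratio and mass slopes


def adaptation_from_clamp(
    clamp_force_n: float,
    object_spec: ObjectSpec,
    profile: RotationProfile | None = None,
) -> float:
    """Dimensionless adaptation: subject peak force over the peak force
    the object would have produced (1 = full compensation)."""
    denom = peak_object_force(object_spec, profile)
    if denom <= 0:
        raise ValueError("zero peak object force")
    return float(clamp_force_n) / denom


def mass_slopes(
    cohort: CohortSeries,
    schedule: Schedule | None = None,
    body_mass_kg: float = DEFAULT_BODY_MASS_KG,
    training_deg: float = 0.0,
    transfer_deg: float = -90.0,
) -> dict:
    """Per-subject OLS slopes of relative adaptation versus relative mass.

    Adaptation on each clamp trial is expressed relative to the 1% body
    mass reference object, so perfect adaptation maps mass fractions
    0.7/1.0/1.3 % to relative adaptations 0.7/1.0/1.3 and the training
    slope of an ideal adapter is 1.
    """
    if schedule is None:
        schedule = cohort.schedule
    masses = sorted(set(t.mass_frac_bm for t in schedule.trials))
    if len(masses) < 2:
        raise ValueError("need at least 2 masses")
    ref = peak_object_force(ObjectSpec(mass_kg=REFERENCE_MASS_FRAC * body_mass_kg))
    rel_mass = np.array(masses) / REFERENCE_MASS_FRAC
    n_subj = cohort.n_subjects
    slopes = {"training": np.empty(n_subj), "transfer": np.empty(n_subj)}
    means = {"training": [], "transfer": []}
    for role, theta in (("training", training_deg), ("transfer", transfer_deg)):
        per_mass = []
        for m in masses:
            idx = [
                t.index for t in schedule.trials
                if t.mode == "error_clamp" and t.mass_frac_bm == m
                and t.orientation_deg == wrap_deg(theta)
            ]
            if not idx:
                raise ValueError(f"no clamp trials at {theta} deg for mass {m}")
            per_mass.append(np.nanmean(cohort.clamp_force[:, idx], axis=1) / ref)
        per_mass = np.stack(per_mass, axis=1)  # (n_subj, n_mass)
        means[role] = per_mass.mean(axis=0).tolist()
        for s in range(n_subj):
            slopes[role][s] = np.polyfit(rel_mass, per_mass[s], 1)[0]
    return {
        "relative_mass": rel_mass.tolist(),
        "training_slopes": slopes["training"].tolist(),
        "transfer_slopes": slopes["transfer"].tolist(),
        "training_slope_mean": float(slopes["training"].mean()),
        "transfer_slope_mean": float(slopes["transfer"].mean()),
        "training_adaptation_mean": means["training"],
        "transfer_adaptation_mean": means["transfer"],
    }


# ---------------------------------------------------------------------------
# Experiment 5 binning


@dataclass
class BinnedBlocks:
    """Block measures grouped by |orientation change| from the previous
    block: the 45-degree bin versus changes of 90 degrees or more."""

    initial_adaptation: dict
    final_adaptation: dict
    trajectory: dict  # bin -> mean 16-trial displacement trajectory
    block_bins: list  # (block_id, |delta|, bin label)


def bin_exp5(data, schedule: Schedule | None = None, body_mass_kg: float = DEFAULT_BODY_MASS_KG) -> BinnedBlocks:
    """Bin exposure blocks by absolute orientation change versus the
    previous block (45 vs 90+); the first exposure cycle is excluded.

    ``data`` may be a model TrialSeries (adaptation read from the model's
    adaptation ratio) or a CohortSeries (adaptation from clamp forces).
    """
    if schedule is None:
        if not isinstance(data, CohortSeries):
            raise ValueError("schedule required for TrialSeries input")
        schedule = data.schedule
    if schedule.experiment_id != "exp5":
        raise ValueError("bin_exp5 requires an exp5 schedule")

    # exposure blocks in order
    blocks: dict[int, list[int]] = {}
    for t in schedule.trials:
        if t.phase_label == "exposure":
            blocks.setdefault(t.block_id, []).append(t.index)
    order = sorted(blocks)
    if isinstance(data, CohortSeries):
        ref = peak_object_force(ObjectSpec(mass_kg=REFERENCE_MASS_FRAC * body_mass_kg))
        adapt_tr = data.mean_clamp_force() / ref
        disp_tr = data.mean_series()
    else:
        adapt_tr = np.where(np.isfinite(data.adaptation_ratio), data.adaptation_ratio, np.nan)
        disp_tr = data.abs_error

    init_bins: dict[str, list[float]] = {"45": [], "90+": []}
    final_bins: dict[str, list[float]] = {"45": [], "90+": []}
    traj_bins: dict[str, list[np.ndarray]] = {"45": [], "90+": []}
    block_bins = []
    for prev_b, b in zip(order[:-1], order[1:]):
        pos = order.index(b)
        if pos < 5:  # first exposure cycle excluded
            continue
        theta_prev = schedule.trials[blocks[prev_b][0]].orientation_deg
        theta = schedule.trials[blocks[b][0]].orientation_deg
        delta = circular_abs_diff(theta, theta_prev)
        if delta == 0:
            continue
        label = "45" if delta == 45.0 else "90+"
        idx = blocks[b]
        clamps = [i for i in idx if schedule.trials[i].mode == "error_clamp"]
        expos = [i for i in idx if schedule.trials[i].mode == "exposure"]
        init_bins[label].append(float(np.nanmean(adapt_tr[clamps[:2]])))
        final_bins[label].append(float(np.nanmean(adapt_tr[clamps[-2:]])))
        traj_bins[label].append(disp_tr[expos])
        block_bins.append((b, delta, label))
    return BinnedBlocks(
        initial_adaptation={k: float(np.mean(v)) for k, v in init_bins.items() if v},
        final_adaptation={k: float(np.mean(v)) for k, v in final_bins.items() if v},
        trajectory={k: np.mean(np.stack(v), axis=0) for k, v in traj_bins.items() if v},
        block_bins=block_bins,
    )
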