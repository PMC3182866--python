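"""Figure-level analyses: normalization anchors, composite generalization
curves, adaptation ratios, mass slopes and orientation-change binning."""

import numpy as np
import pytest

import ssadapt as sa
from ssadapt import analysis as an
from ssadapt import synthetic_data as sd
from ssadapt.dynamics import ObjectSpec, RotationProfile, minimum_jerk_profile, peak_object_force
from ssadapt.synthetic_data import CohortSeries


@pytest.fixture(scope="module")
def exp1_sched():
    return sa.build_schedule("exp1", seed=11)


@pytest.fixture(scope="module")
def noisefree_exp2_cohort():
    sched = sa.build_schedule("exp2", seed=12, group=1)
    spec = sa.GenerativeSpec(
        "mcsrm4", sd.MCSRM4_TRUTH, compliance=sa.unit_compliance(),
        n_subjects=3, seed=5, observation_noise_sd=0.0,
        subject_heterogeneity_sd=0.0, clamp_force_noise_sd=0.0,
    )
    return sa.generate_cohort(sched, spec)


# ---------------------------------------------------------------------------
# normalization


def test_normalize_anchors(exp1_sched, srm_truth):
    spec = sa.GenerativeSpec("srm", srm_truth, n_subjects=8, seed=3)
    cohort = sa.generate_cohort(exp1_sched, spec)
    norm = an.normalize_exp1(cohort.mean_series(), exp1_sched)
    labels = np.array([t.phase_label for t in exp1_sched.trials])
    pre_final8 = np.where(labels == "pre")[0][-8:]
    assert np.nanmean(norm[pre_final8]) == pytest.approx(0.0, abs=1e-12)
    fam = np.array([t.familiarization for t in exp1_sched.trials])
    assert np.nanmax(norm[~fam]) == pytest.approx(1.0)


def test_normalize_idempotent_and_affine_invariant(exp1_sched, srm_truth):
    spec = sa.GenerativeSpec("srm", srm_truth, n_subjects=8, seed=4)
    y = sa.generate_cohort(exp1_sched, spec).mean_series()
    norm = an.normalize_exp1(y, exp1_sched)
    np.testing.assert_allclose(
        an.normalize_exp1(norm, exp1_sched), norm, atol=1e-12, equal_nan=True
    )
    np.testing.assert_allclose(
        an.normalize_exp1(3.7 * y + 0.9, exp1_sched), norm, atol=1e-10, equal_nan=True
    )


def test_normalize_rejects_constant_series(exp1_sched):
    with pytest.raises(ValueError):
        an.normalize_exp1(np.full(len(exp1_sched), 0.5), exp1_sched)


def test_normalize_whole_pre_variant(exp1_sched, srm_truth):
    spec = sa.GenerativeSpec("srm", srm_truth, n_subjects=8, seed=5)
    y = sa.generate_cohort(exp1_sched, spec).mean_series()
    norm = an.normalize_exp1(y, exp1_sched, baseline="whole_pre")
    labels = np.array([t.phase_label for t in exp1_sched.trials])
    pre = np.where(labels == "pre")[0]
    assert np.nanmean(norm[pre]) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# composite generalization


def test_composite_curve_shape(noisefree_exp2_cohort):
    comp_df, curve = an.composite_exp2(noisefree_exp2_cohort)
    rels = curve.relative_orientation_deg
    assert list(rels) == [180.0, 90.0, 45.0, 22.5, 0.0]  # descending order
    dead = dict(zip(rels, curve.deadaptation_error_cm))
    # transfer is maximal at the training orientation, near the offset floor far away
    assert dead[0.0] == max(dead.values())
    assert dead[180.0] < 0.3 * dead[0.0]
    assert dead[22.5] > dead[45.0] > dead[90.0]
    reexp = dict(zip(rels, curve.reexposure_error_cm))
    assert reexp[0.0] == max(reexp.values())
    # composite has one 30-trial block per probe
    assert len(comp_df) == 5 * 30
    assert not curve.deadaptation_fit.degenerate
    assert 5.0 < curve.deadaptation_fit.width_deg < 180.0


def test_composite_matches_model_simulation(noisefree_exp2_cohort):
    # noise-free cohort: composite equals the model's own composite exactly
    sched = noisefree_exp2_cohort.schedule
    ts = sa.simulate("mcsrm4", sched, sd.MCSRM4_TRUTH, compliance=sa.unit_compliance())
    clamp = sched.modes() == "error_clamp"
    model_disp = np.where(clamp, np.nan, ts.abs_error)[None, :]
    model_cohort = CohortSeries(
        schedule=sched, displacement=model_disp, clamp_force=np.full_like(model_disp, np.nan)
    )
    _, c_model = an.composite_exp2(model_cohort)
    _, c_cohort = an.composite_exp2(noisefree_exp2_cohort)
    np.testing.assert_allclose(
        c_cohort.deadaptation_error_cm, c_model.deadaptation_error_cm, atol=1e-12
    )


def test_flat_generalization_degenerate_fit():
    fit = an.fit_half_gaussian(np.array([0.0, 22.5, 45.0, 90.0, 180.0]), np.full(5, 0.4))
    assert fit.degenerate


def test_composite_requires_exp2(exp1_sched):
    cohort = CohortSeries(
        schedule=exp1_sched,
        displacement=np.ones((2, len(exp1_sched))),
        clamp_force=np.full((2, len(exp1_sched)), np.nan),
    )
    with pytest.raises(ValueError):
        an.composite_exp2(cohort)


# ---------------------------------------------------------------------------
# adaptation ratio


def test_adaptation_from_clamp_values():
    obj = ObjectSpec(mass_kg=0.7)
    pf = peak_object_force(obj)
    assert an.adaptation_from_clamp(pf, obj) == pytest.approx(1.0)
    assert an.adaptation_from_clamp(0.0, obj) == 0.0


def test_adaptation_ratio_invariant_to_shared_kinematic_scaling():
    # same profile in numerator convention and denominator: ratio unchanged
    obj = ObjectSpec(mass_kg=0.7)
    slow = minimum_jerk_profile(40.0, 0.8, 801)
    fast = minimum_jerk_profile(40.0, 0.4, 801)
    for prof in (slow, fast):
        force = 0.6 * peak_object_force(obj, prof)
        assert an.adaptation_from_clamp(force, obj, prof) == pytest.approx(0.6)


def test_adaptation_from_clamp_zero_object_force():
    n = 9
    still = RotationProfile(np.linspace(0, 1, n), np.zeros(n), np.zeros(n), np.zeros(n))
    with pytest.raises(ValueError):
        an.adaptation_from_clamp(1.0, ObjectSpec(0.7), still)


# ---------------------------------------------------------------------------
# mass slopes


def _manual_exp3_cohort(transfer_fraction: float):
    """Cohort whose clamp forces encode a known adaptation level:
    full compensation at the training orientation, a fixed fraction of it
    at the transfer orientation."""
    sched = sa.build_schedule("exp3", seed=4)
    n = len(sched)
    disp = np.full((2, n), np.nan)
    force = np.full((2, n), np.nan)
    body = sd.DEFAULT_BODY_MASS_KG
    for t in sched.trials:
        if t.mode != "error_clamp":
            disp[:, t.index] = 0.1
            continue
        own = peak_object_force(ObjectSpec(mass_kg=t.mass_frac_bm * body))
        frac = 1.0 if t.orientation_deg == 0.0 else transfer_fraction
        force[:, t.index] = frac * own
    return CohortSeries(schedule=sched, displacement=disp, clamp_force=force)


def test_perfect_adaptation_training_slope_is_one():
    cohort = _manual_exp3_cohort(transfer_fraction=1.0)
    res = an.mass_slopes(cohort)
    assert res["training_slope_mean"] == pytest.approx(1.0, rel=1e-9)
    assert res["transfer_slope_mean"] == pytest.approx(1.0, rel=1e-9)


def test_zero_transfer_slope_is_zero():
    cohort = _manual_exp3_cohort(transfer_fraction=0.0)
    res = an.mass_slopes(cohort)
    assert res["transfer_slope_mean"] == pytest.approx(0.0, abs=1e-12)


def test_model_training_slope_exceeds_transfer_slope():
    sched = sa.build_schedule("exp3", seed=4)
    spec = sa.GenerativeSpec(
        "mcsrm4", sd.MCSRM4_TRUTH, compliance=sa.unit_compliance(),
        n_subjects=2, seed=6, observation_noise_sd=0.0,
        subject_heterogeneity_sd=0.0, clamp_force_noise_sd=0.0,
    )
    cohort = sa.generate_cohort(sched, spec)
    res = an.mass_slopes(cohort)
    assert res["training_slope_mean"] > res["transfer_slope_mean"] > 0.0


def test_mass_slopes_needs_multiple_masses(exp1_sched):
    cohort = CohortSeries(
        schedule=exp1_sched,
        displacement=np.ones((2, len(exp1_sched))),
        clamp_force=np.ones((2, len(exp1_sched))),
    )
    with pytest.raises(ValueError):
        an.mass_slopes(cohort)


# ---------------------------------------------------------------------------
# orientation-change binning


def test_circular_difference_wraps():
    assert an.circular_abs_diff(180.0, 0.0) == 180.0
    assert an.circular_abs_diff(-135.0, 180.0) == 45.0
    assert an.circular_abs_diff(0.0, -45.0) == 45.0
    assert an.circular_abs_diff(157.5, -157.5) == 45.0


def test_bin_assignment_is_exhaustive_and_disjoint():
    sched = sa.build_schedule("exp5", seed=15)
    ts = sa.simulate("mcsrm4", sched, sd.MCSRM4_TRUTH, compliance=sa.unit_compliance())
    binned = an.bin_exp5(ts, sched)
    # 20 eligible blocks (cycles 2-5), each in exactly one bin
    assert len(binned.block_bins) == 20
    for _, delta, label in binned.block_bins:
        assert delta in (45.0, 90.0, 135.0, 180.0)
        assert label == ("45" if delta == 45.0 else "90+")


def test_model_bin_pattern_matches_predictions():
    # higher initial adaptation after a 45-degree change; equal final adaptation
    sched = sa.build_schedule("exp5", seed=15)
    ts = sa.simulate("mcsrm4", sched, sd.MCSRM4_TRUTH, compliance=sa.unit_compliance())
    binned = an.bin_exp5(ts, sched)
    assert binned.initial_adaptation["45"] > binned.initial_adaptation["90+"] + 0.05
    assert binned.final_adaptation["45"] == pytest.approx(binned.final_adaptation["90+"], abs=0.05)
    # displacement trajectory starts lower in the 45-degree bin
    assert binned.trajectory["45"][0] < binned.trajectory["90+"][0]


def test_bin_exp5_cohort_input_matches_model():
    sched = sa.build_schedule("exp5", seed=15)
    spec = sa.GenerativeSpec(
        "mcsrm4", sd.MCSRM4_TRUTH, compliance=sa.unit_compliance(),
        n_subjects=2, seed=8, observation_noise_sd=0.0,
        subject_heterogeneity_sd=0.0, clamp_force_noise_sd=0.0,
    )
    cohort = sa.generate_cohort(sched, spec)
    from_cohort = an.bin_exp5(cohort)
    ts = sa.simulate("mcsrm4", sched, sd.MCSRM4_TRUTH, compliance=sa.unit_compliance())
    from_model = an.bin_exp5(ts, sched)
    for label in ("45", "90+"):
        assert from_cohort.initial_adaptation[label] == pytest.approx(
            from_model.initial_adaptation[label], abs=1e-9
        )


def test_bin_exp5_rejects_wrong_experiment(exp1_sched):
    ts = sa.simulate("srm", exp1_sched, sa.SRMParams(0.95, 0.2))
    with pytest.raises(ValueError):
        an.bin_exp5(ts, exp1_sched)
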