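"""Generator contracts: schedules, stance curves, cohorts, ground truth."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from insolegait.synthetic import (
    default_profiles,
    generate_cohort,
    generate_stride_schedule,
    generate_subject,
    noise_free,
    synth_stance_curve,
)
from tests.conftest import exact_profile


class TestStrideSchedule:
    def test_zero_variance_schedule_is_exactly_nominal(self):
        sch = generate_stride_schedule(exact_profile(), seed=0)
        assert np.allclose(np.diff(sch.left_fs), 1.10)
        assert np.allclose(sch.right_fs[:-1] - sch.left_fs[:-1], 0.55)
        assert np.allclose(sch.left_to - sch.left_fs[:-1], 0.72)  # stance
        assert np.allclose(sch.phase_deg, 180.0)

    def test_same_seed_gives_identical_schedule(self):
        prof = default_profiles()["PD"]
        a = generate_stride_schedule(prof, seed=42)
        b = generate_stride_schedule(prof, seed=42)
        for x, y in ((a.left_fs, b.left_fs), (a.right_to, b.right_to)):
            np.testing.assert_array_equal(x, y)

    def test_infeasible_profile_rejected(self):
        with pytest.raises(ValueError, match="swing >= stride"):
            generate_stride_schedule(
                exact_profile(swing_time_mean_s=(1.2, 1.2)), seed=0
            )
        with pytest.raises(ValueError, match="double support"):
            # phase 140 puts the right strike before the right swing ends
            generate_stride_schedule(
                exact_profile(phase_offset_deg=140.0, swing_time_mean_s=(0.43, 0.43)),
                seed=0,
            )

    def test_phase_noise_sd_is_recovered(self):
        prof = noise_free(
            default_profiles()["YC"],
            phase_sd_deg=5.0,
            duration_s=250 * 1.125 + 3,
        )
        sch = generate_stride_schedule(prof, seed=3)
        assert sch.n_strides >= 240
        realized_sd = np.std(sch.phase_deg, ddof=1)
        assert abs(realized_sd - 5.0) < 0.2 * 5.0

    def test_ground_truth_matches_schedule_exactly(self):
        left, right, truth = generate_subject(default_profiles()["AMC"], seed=5)
        sch = truth.schedule
        np.testing.assert_array_equal(truth.stride_s["left"], np.diff(sch.left_fs))
        np.testing.assert_array_equal(truth.stance_s["left"], sch.left_to - sch.left_fs[:-1])
        np.testing.assert_array_equal(truth.swing_s["right"], sch.right_fs[1:] - sch.right_to)
        assert np.all(np.diff(sch.left_fs) > 0)
        assert np.all(np.diff(sch.right_fs) > 0)
        assert set(truth.turn_stride_idx) <= set(range(sch.n_strides))


class TestStanceCurve:
    def test_template_extrema_sit_at_requested_fractions(self):
        curve = synth_stance_curve(0.70, (0.26, 0.46, 0.74), (1.0, 0.6, 1.1), 100.0)
        n = curve.size
        assert n == 70
        interior = np.arange(1, n - 1)
        is_max = (curve[interior] > curve[interior - 1]) & (curve[interior] >= curve[interior + 1])
        is_min = (curve[interior] < curve[interior - 1]) & (curve[interior] <= curve[interior + 1])
        maxima = interior[is_max]
        minima = interior[is_min]
        assert maxima.size == 2 and minima.size == 1
        assert abs(maxima[0] - 0.26 * (n - 1)) <= 1
        assert abs(minima[0] - 0.46 * (n - 1)) <= 1
        assert abs(maxima[1] - 0.74 * (n - 1)) <= 1
        # magnitudes within 1 %
        assert abs(curve[maxima[0]] - 1.0) < 0.01
        assert abs(curve[minima[0]] - 0.6) < 0.01 * 0.6
        assert abs(curve[maxima[1]] - 1.1) < 0.01 * 1.1
        assert curve[0] == 0.0 and curve[-1] == 0.0

    def test_flat_peaks_rejected(self):
        with pytest.raises(ValueError, match="mid-stance"):
            synth_stance_curve(0.7, (0.26, 0.46, 0.74), (1.0, 1.0, 1.0), 100.0)

    def test_too_short_stance_rejected(self):
        with pytest.raises(ValueError, match="5 samples"):
            synth_stance_curve(0.03, (0.26, 0.46, 0.74), (1.0, 0.6, 1.1), 100.0)

    @given(
        f1=st.floats(0.15, 0.35),
        gap1=st.floats(0.08, 0.25),
        gap2=st.floats(0.08, 0.25),
        p1=st.floats(0.5, 1.5),
        vfrac=st.floats(0.2, 0.9),
        p2=st.floats(0.5, 1.5),
        dur=st.floats(0.4, 1.2),
    )
    def test_curve_invariants_hold_for_any_valid_input(
        self, f1, gap1, gap2, p1, vfrac, p2, dur
    ):
        f2, f3 = f1 + gap1, f1 + gap1 + gap2
        if f3 >= 0.95:
            return
        v = vfrac * min(p1, p2)
        curve = synth_stance_curve(dur, (f1, f2, f3), (p1, v, p2), 100.0)
        assert curve.sum() > 0
        assert np.all(curve >= 0)
        assert curve[0] == 0.0 and curve[-1] == 0.0
        interior = np.arange(1, curve.size - 1)
        strict_max = (curve[interior] > curve[interior - 1]) & (
            curve[interior] >= curve[interior + 1]
        )
        assert 1 <= strict_max.sum() <= 2  # two unless grid merges close knots


class TestCohort:
    def test_default_cohort_has_39_subjects_78_series(self):
        profiles = {g: replace(p, duration_s=20.0) for g, p in default_profiles().items()}
        cohort = generate_cohort(profiles=profiles, seed=0)
        assert len(cohort.subjects) == 39
        assert sum(len(v) for v in cohort.series.values()) == 39 * 2
        groups = [s.group_label for s in cohort.subjects]
        assert groups.count("YC") == 16
        assert groups.count("AMC") == 12
        assert groups.count("PD") == 11

    def test_cohort_without_pd_has_no_clinical_fields(self):
        profiles = {g: replace(p, duration_s=15.0) for g, p in default_profiles().items()}
        cohort = generate_cohort(n_yc=2, n_amc=2, n_pd=0, profiles=profiles, seed=1)
        assert all(s.clinical is None for s in cohort.subjects)
        assert all("updrs_iii" not in row for row in cohort.manifest_rows())

    def test_cohort_generation_is_deterministic(self):
        profiles = {g: replace(p, duration_s=15.0) for g, p in default_profiles().items()}
        a = generate_cohort(n_yc=2, n_amc=2, n_pd=2, profiles=profiles, seed=9)
        b = generate_cohort(n_yc=2, n_amc=2, n_pd=2, profiles=profiles, seed=9)
        for sid in a.series:
            np.testing.assert_array_equal(
                a.series[sid][0].samples, b.series[sid][0].samples
            )
        assert [s.age_years for s in a.subjects] == [s.age_years for s in b.subjects]

    def test_doubled_double_support_sd_raises_downstream_dst_cv(self):
        """PD-like double-support noise must dominate the extracted DST CV."""
        import warnings

        from insolegait.events import detect_contacts, moving_average, remove_outlier_strides
        from insolegait.kinematics import stride_intervals, coefficient_of_variation

        def dst_cv(profile, seed):
            left, right, _ = generate_subject(profile, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ev_l = remove_outlier_strides(detect_contacts(moving_average(left)))
                ev_r = remove_outlier_strides(detect_contacts(moving_average(right)))
                return coefficient_of_variation(stride_intervals(ev_l, ev_r).dst_s)

        control = replace(default_profiles()["YC"], duration_s=120.0)
        doubled = replace(control, double_support_sd_s=2 * control.double_support_sd_s)
        wins = sum(
            dst_cv(doubled, seed) > dst_cv(control, seed) for seed in range(20)
        )
        assert wins >= 18  # >= 90 % of replicates
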