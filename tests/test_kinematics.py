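"""Kinematic parameters: intervals, CV, GA, phase, cadence, assembly."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from insolegait.core import GRFSeries
from insolegait.events import GaitEvents
from insolegait.kinematics import (
    KINEMATIC_COLUMNS,
    cadence,
    coefficient_of_variation,
    gait_asymmetry,
    kinematic_features,
    phase_series,
    phase_stats,
    spatial_estimates,
    stride_intervals,
)
from insolegait.synthetic import default_profiles


def _events(fs, to, side="left"):
    return GaitEvents(side, np.asarray(fs, float), np.asarray(to, float), 100.0)


def _alternating_events(n=12, stride=1.10, swing=0.385, offset=0.0):
    fs = offset + stride * np.arange(n)
    to = fs + (stride - swing)
    return fs, to


class TestStrideIntervals:
    def test_symmetric_zero_variance_geometry(self):
        """stride 1.10 s, swing 0.385 s -> stance 0.715 s, DST 0.330 s."""
        fs_l, to_l = _alternating_events()
        fs_r, to_r = _alternating_events(offset=0.55)
        iv = stride_intervals(_events(fs_l, to_l), _events(fs_r, to_r, "right"))
        np.testing.assert_allclose(iv.stance_s["left"], 0.715)
        np.testing.assert_allclose(iv.swing_s["left"], 0.385)
        np.testing.assert_allclose(iv.dst_s, 2 * (0.715 - 0.550), atol=1e-12)

    def test_detected_interval_means_within_one_sample_of_truth(self, noisy_subject):
        iv = stride_intervals(noisy_subject["events_left"], noisy_subject["events_right"])
        truth = noisy_subject["truth"]
        keep = np.ones(truth.stride_s["left"].size, bool)
        for i in truth.turn_stride_idx:
            keep[i] = False
            if i + 1 < keep.size:
                keep[i + 1] = False
        for q, tv in (("stride_s", truth.stride_s), ("stance_s", truth.stance_s),
                      ("swing_s", truth.swing_s)):
            got = float(np.median(getattr(iv, q)["left"]))
            want = float(np.median(tv["left"][keep]))
            assert abs(got - want) <= 0.01 + 1e-9, q
        assert abs(np.median(iv.dst_s) - np.median(truth.dst_s[keep])) <= 0.015

    def test_one_foot_entirely_invalid_is_an_error(self):
        fs_l, to_l = _alternating_events()
        fs_r, to_r = _alternating_events(offset=0.55)
        left = _events(fs_l, to_l)
        left.valid[:] = False
        with pytest.raises(ValueError, match="valid strides"):
            stride_intervals(left, _events(fs_r, to_r, "right"))


class TestCoefficientOfVariation:
    def test_constant_values_have_zero_cv(self):
        assert coefficient_of_variation([2.0, 2.0, 2.0]) == 0.0

    def test_hand_computed_example(self):
        assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(70.7107, abs=1e-4)

    @given(st.floats(0.1, 100.0))
    def test_scale_invariance(self, c):
        base = np.array([1.0, 2.0, 4.0, 5.5])
        assert coefficient_of_variation(c * base) == pytest.approx(
            coefficient_of_variation(base), rel=1e-9
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            coefficient_of_variation([1.0])
        with pytest.raises(ValueError, match="zero mean"):
            coefficient_of_variation([-1.0, 1.0])


class TestGaitAsymmetry:
    def test_equal_swings_give_zero(self):
        assert gait_asymmetry(0.38, 0.38) == 0.0

    def test_hand_computed_example(self):
        assert gait_asymmetry(0.37, 0.38) == pytest.approx(2.6668, abs=1e-4)

    @given(st.floats(0.05, 2.0), st.floats(0.05, 2.0))
    def test_symmetry_in_arguments(self, a, b):
        assert gait_asymmetry(a, b) == pytest.approx(gait_asymmetry(b, a), rel=1e-12)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            gait_asymmetry(0.0, 0.4)


class TestPhase:
    def test_perfect_alternation_gives_180_everywhere(self, exact_subject):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps = phase_series(exact_subject["events_left"], exact_subject["events_right"])
        np.testing.assert_allclose(ps.phases_deg, 180.0, atol=1e-9)

    def test_formula_on_hand_values(self):
        # reference strikes at 0 and 1.2, contralateral at 0.5 -> 150 deg
        fs_l = np.array([0.0, 1.2, 2.4, 3.6])
        to_l = fs_l + 0.75
        fs_r = np.array([0.5, 1.7, 2.9, 4.1])
        to_r = fs_r + 0.70  # shorter right stance -> longer right swing? no:
        # swing_l = 0.45, swing_r = 0.50 -> right leg is the reference
        left = _events(fs_l, to_l)
        right = _events(fs_r, to_r, "right")
        ps = phase_series(left, right)
        assert ps.reference_side == "right"
        # left strikes at 1.2 inside right stride [0.5, 1.7): phi = 360*0.7/1.2
        np.testing.assert_allclose(ps.phases_deg, 360.0 * 0.7 / 1.2)

    def test_stride_without_interior_strike_is_skipped(self):
        fs_l = np.array([0.0, 1.2, 2.4, 3.6, 4.8])
        to_l = fs_l + 0.8
        left = _events(fs_l, to_l)
        fs_r = np.array([0.6, 1.8, 4.2])  # missing strike inside [2.4, 3.6)
        to_r = fs_r + 0.8
        right = _events(fs_r, to_r, "right")
        right_swings = fs_r[1:] - to_r[:-1]
        assert right_swings.min() > 0.4  # right is reference (longer swing)
        ps = phase_series(left, right)
        assert ps.n_skipped >= 1

    def test_phase_stats_identities(self):
        ps_obj = type("P", (), {})()
        from insolegait.kinematics import PhaseSeries

        phases = PhaseSeries(
            phases_deg=np.array([170.0, 190.0] * 5),
            reference_side="left",
            t_long=np.arange(10.0),
            t_short=np.arange(10.0) + 0.5,
        )
        st_ = phase_stats(phases)
        assert st_.phi_mean_deg == pytest.approx(180.0)
        assert st_.phi_deviation == pytest.approx(100.0 * 10.0 / 180.0, abs=1e-4)
        assert st_.phi_deviation_deg == pytest.approx(10.0)
        assert st_.pci == pytest.approx(st_.phi_cv + st_.phi_deviation, abs=1e-12)
        in_degrees = phase_stats(phases, convention="degrees")
        assert in_degrees.pci == pytest.approx(in_degrees.phi_cv + 10.0, abs=1e-12)

    def test_all_180_gives_zero_deviation_and_pci(self):
        from insolegait.kinematics import PhaseSeries

        phases = PhaseSeries(
            phases_deg=np.full(8, 180.0),
            reference_side="left",
            t_long=np.arange(8.0),
            t_short=np.arange(8.0) + 0.5,
        )
        st_ = phase_stats(phases)
        assert (st_.phi_mean_deg, st_.phi_cv, st_.phi_deviation, st_.pci) == (180.0, 0, 0, 0)


class TestCadence:
    def test_pure_sinusoid_peak_recovered(self):
        t = np.arange(300 * 100) / 100.0
        x = 1.0 + 0.5 * np.sin(2 * np.pi * 1.75 * t)
        f = cadence(GRFSeries(x, 100.0, "left"))
        assert f == pytest.approx(1.75, abs=1.0 / 300.0 + 1e-9)

    def test_zero_variance_gait_cadence_is_step_rate(self, exact_subject):
        f = cadence(exact_subject["total"])
        # stride 1.10 s -> two steps per stride -> 1.818 Hz
        assert f == pytest.approx(2.0 / 1.10, abs=1.0 / exact_subject["total"].duration_s + 1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cadence(GRFSeries(np.ones(100 * 40), 100.0, "left"))


class TestSpatialEstimates:
    def test_worked_example_values(self):
        speed, step = spatial_estimates(524.5, 300.0, 377.3)
        assert speed == pytest.approx(1.2577, abs=1e-4)
        assert step == pytest.approx(0.7194, abs=1e-4)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            spatial_estimates(500, 300.0, 0.0)


class TestAssembly:
    def test_feature_set_has_exactly_28_named_fields(self, noisy_subject):
        feats = kinematic_features(
            noisy_subject["events_left"],
            noisy_subject["events_right"],
            noisy_subject["total"],
            distance_m=noisy_subject["truth"].distance_m,
        )
        aux = {"phi deviation [deg]"}
        assert [k for k in feats if k not in aux] == KINEMATIC_COLUMNS
        assert len(KINEMATIC_COLUMNS) == 28

    def test_zero_variance_subject_has_zero_cvs_ga_pci(self, exact_subject):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            feats = kinematic_features(
                exact_subject["events_left"],
                exact_subject["events_right"],
                exact_subject["total"],
                distance_m=exact_subject["truth"].distance_m,
            )
        for name in [c for c in KINEMATIC_COLUMNS if c.endswith("CV")] + ["GA", "PCI"]:
            assert feats[name] == pytest.approx(0.0, abs=1e-9), name

    def test_pst_pswt_sum_to_100(self, noisy_subject):
        feats = kinematic_features(
            noisy_subject["events_left"],
            noisy_subject["events_right"],
            noisy_subject["total"],
            distance_m=noisy_subject["truth"].distance_m,
        )
        assert feats["R PST [%]"] + feats["R PSWT [%]"] == pytest.approx(100.0, abs=0.5)
        assert feats["L PST [%]"] + feats["L PSWT [%]"] == pytest.approx(100.0, abs=0.5)

    def test_ga_and_pci_invariant_under_side_relabeling(self, noisy_subject):
        from dataclasses import replace as dc_replace

        el, er = noisy_subject["events_left"], noisy_subject["events_right"]
        feats = kinematic_features(el, er, noisy_subject["total"],
                                   distance_m=noisy_subject["truth"].distance_m)
        swapped = kinematic_features(
            dc_replace(er, side="left"),
            dc_replace(el, side="right"),
            noisy_subject["total"],
            distance_m=noisy_subject["truth"].distance_m,
        )
        assert swapped["GA"] == pytest.approx(feats["GA"], rel=1e-9)
        assert swapped["PCI"] == pytest.approx(feats["PCI"], rel=1e-9)

    def test_group_medians_recover_generator_nominals(self):
        """Timing means extracted from a YC cohort stay within 10 % of truth."""
        import warnings as w

        from insolegait.pipeline import extract_cohort_features
        from insolegait.synthetic import generate_cohort
        from dataclasses import replace as dc_replace

        profiles = {g: dc_replace(p, duration_s=120.0)
                    for g, p in default_profiles().items()}
        nominal = profiles["YC"]
        meds = []
        for seed in range(5):
            with w.catch_warnings():
                w.simplefilter("ignore")
                cohort = generate_cohort(n_yc=4, n_amc=0, n_pd=0,
                                         profiles=profiles, seed=seed)
                feats = extract_cohort_features(cohort)
            meds.append(feats.median(numeric_only=True))
        med = sum(meds) / len(meds)
        cycle = nominal.cycle_time_s
        checks = {
            "R stride time [s]": cycle,
            "L stride time [s]": cycle,
            "L swing time [s]": nominal.swing_time_mean_s[0],
            "R swing time [s]": nominal.swing_time_mean_s[1],
            "L stance time [s]": cycle - nominal.swing_time_mean_s[0],
            "Cadence [strides/s]": 2.0 / cycle,
            "Step length [m]": nominal.step_length_m,
            "phi [deg]": nominal.phase_offset_deg,
            "DST [s]": sum(nominal.nominal_double_support_s),
        }
        for name, want in checks.items():
            assert abs(med[name] - want) <= 0.10 * want, (name, med[name], want)
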