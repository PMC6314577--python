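import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tcdasym.hemodynamics import (
    InvalidIndexError,
    InvalidSampleError,
    Segment,
    Side,
    VelocitySample,
    asymmetry_index,
    compute_mv,
    compute_pi,
    index_sensitivity_grid,
    mca_index,
    mean_mca_index,
    patient_profile,
    segment_from_depth,
)

# strategies for the valid region mv > 10*pi
valid_mv = st.floats(min_value=20.0, max_value=150.0)
valid_pi = st.floats(min_value=0.0, max_value=1.5)
positive = st.floats(min_value=1e-3, max_value=1e6)


class TestComputeMv:
    @pytest.mark.parametrize(
        "psv, edv, expected",
        [(50, 50, 50.0), (90, 45, 60.0), (60, 0, 20.0)],
    )
    def test_examples(self, psv, edv, expected):
        assert compute_mv(psv, edv) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("psv, edv", [(40, 45), (-1, -2), (10, -1)])
    def test_corrupted_sample_rejected(self, psv, edv):
        with pytest.raises(InvalidSampleError):
            compute_mv(psv, edv)

    @given(edv=st.floats(0, 200), delta=st.floats(0, 200))
    def test_bracketed_by_edv_and_psv(self, edv, delta):
        psv = edv + delta
        mv = compute_mv(psv, edv)
        assert edv - 1e-9 <= mv <= psv + 1e-9


class TestComputePi:
    @pytest.mark.parametrize(
        "psv, edv, expected",
        [(50, 50, 0.0), (90, 45, 0.75), (60, 0, 3.0)],
    )
    def test_examples(self, psv, edv, expected):
        assert compute_pi(psv, edv) == pytest.approx(expected, rel=1e-12)

    def test_zero_mv_undefined(self):
        with pytest.raises(InvalidIndexError):
            compute_pi(0, 0)

    @given(edv=st.floats(0.1, 200), delta=st.floats(0, 200))
    def test_recomposition_identity(self, edv, delta):
        # PI * MV == PSV - EDV exactly, by construction
        psv = edv + delta
        assert compute_pi(psv, edv) * compute_mv(psv, edv) == pytest.approx(
            psv - edv, abs=1e-9
        )


class TestSegmentFromDepth:
    @pytest.mark.parametrize(
        "depth, expected",
        [
            (60, Segment.M1),
            (58, Segment.M1),
            (68, Segment.M1),
            (44, Segment.M2),
            (56, Segment.M2),
            (50, Segment.M2),
            (57, Segment.OUT_OF_WINDOW),  # gap between the printed windows
            (43.9, Segment.OUT_OF_WINDOW),
            (68.1, Segment.OUT_OF_WINDOW),
            (30, Segment.OUT_OF_WINDOW),
        ],
    )
    def test_windows(self, depth, expected):
        assert segment_from_depth(depth) is expected

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(InvalidSampleError):
            segment_from_depth(0)


class TestMcaIndex:
    @pytest.mark.parametrize(
        "mv, pi, expected",
        [
            (50, 0.0, 100.0),
            (50, 1.0, 150.0),  # 100*60/40
            (56, 0.87, 100 * 64.7 / 47.3),  # group-median inputs
        ],
    )
    def test_examples(self, mv, pi, expected):
        assert mca_index(mv, pi) == pytest.approx(expected, rel=1e-6)

    def test_table2_median_inputs_do_not_commute(self):
        # medians do not pass through the nonlinear formula: the index of
        # the medians (136.79) differs from the median index
        assert mca_index(56, 0.87) == pytest.approx(136.79, abs=0.005)

    def test_denominator_guard(self):
        with pytest.raises(InvalidIndexError):
            mca_index(10, 1.0)  # mv == 10*pi
        with pytest.raises(InvalidIndexError):
            mca_index(5, 1.0)

    @given(mv=valid_mv, pi=valid_pi, k=st.floats(0.01, 100))
    def test_scale_invariance(self, mv, pi, k):
        assert mca_index(k * mv, k * pi) == pytest.approx(
            mca_index(mv, pi), rel=1e-9
        )

    @given(mv=valid_mv, pi=st.floats(0.01, 1.5))
    def test_exceeds_100_when_pulsatile(self, mv, pi):
        assert mca_index(mv, pi) > 100.0

    @given(mv=valid_mv, pi=st.floats(0.01, 1.5), dmv=st.floats(0.1, 10))
    def test_decreasing_in_mv(self, mv, pi, dmv):
        # pi bounded away from 0: at pi ~ 1e-88 both values round to 100.0
        assert mca_index(mv + dmv, pi) < mca_index(mv, pi)

    @given(mv=valid_mv, pi=st.floats(0, 1.0), dpi=st.floats(0.01, 0.5))
    def test_increasing_in_pi(self, mv, pi, dpi):
        assert mca_index(mv, pi + dpi) > mca_index(mv, pi)


class TestMeanMcaIndex:
    @pytest.mark.parametrize(
        "p, d, expected",
        [(140, 140, 140.0), (150, 130, 140.0), (136.79, 141.94, 139.365)],
    )
    def test_examples(self, p, d, expected):
        assert mean_mca_index(p, d) == pytest.approx(expected, rel=1e-9)


class TestAsymmetryIndex:
    def test_perfect_symmetry(self):
        assert asymmetry_index(137, 137) == 0.0

    def test_hand_example(self):
        assert asymmetry_index(150, 130) == pytest.approx(200 * 20 / 280, rel=1e-9)
        assert asymmetry_index(150, 130) == pytest.approx(14.2857, abs=1e-4)

    def test_literal_convention_is_one_quarter(self):
        assert asymmetry_index(150, 130, convention="literal") == pytest.approx(
            asymmetry_index(150, 130) / 4.0, rel=1e-12
        )

    def test_unknown_convention(self):
        with pytest.raises(ValueError):
            asymmetry_index(1, 2, convention="bogus")

    @pytest.mark.parametrize("r, l", [(0, 1), (1, 0), (-1, 2)])
    def test_nonpositive_rejected(self, r, l):
        with pytest.raises(InvalidSampleError):
            asymmetry_index(r, l)

    @given(a=positive, b=positive)
    def test_symmetric_and_bounded(self, a, b):
        v = asymmetry_index(a, b)
        assert v == asymmetry_index(b, a)
        assert 0.0 <= v < 200.0
        assert (v == 0.0) == (a == b)

    @given(a=positive, b=positive, k=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, a, b, k):
        assert asymmetry_index(k * a, k * b) == pytest.approx(
            asymmetry_index(a, b), rel=1e-9, abs=1e-9
        )


class TestPatientProfile:
    def test_hand_computed_chain(self, four_sample_patient):
        p = patient_profile(four_sample_patient)
        assert p.complete and not p.invalid
        # right: MV1=60 PI1=0.75, MV2=56 PI2=0.75
        assert p.rt_proximal_index == pytest.approx(100 * 67.5 / 52.5, rel=1e-9)
        assert p.rt_distal_index == pytest.approx(100 * 63.5 / 48.5, rel=1e-9)
        # left: MV1=55 PI1=6/11, MV2=52 PI2=15/26
        assert p.lt_proximal_index == pytest.approx(66500 / 545, rel=1e-9)
        assert p.lt_distal_index == pytest.approx(75100 / 601, rel=1e-9)
        r_mean = (100 * 67.5 / 52.5 + 100 * 63.5 / 48.5) / 2
        l_mean = (66500 / 545 + 75100 / 601) / 2
        assert p.rt_mean_index == pytest.approx(r_mean, rel=1e-9)
        assert p.overall_asym == pytest.approx(
            200 * abs(r_mean - l_mean) / (r_mean + l_mean), rel=1e-9
        )
        assert p.overall_asym == pytest.approx(4.9450, abs=5e-4)

    def test_mv_and_pi_asymmetries(self, four_sample_patient):
        p = patient_profile(four_sample_patient)
        assert p.proximal_mv_asym == pytest.approx(200 * 5 / 115, rel=1e-9)
        assert p.distal_mv_asym == pytest.approx(200 * 4 / 108, rel=1e-9)
        # overall uses per-side means of proximal and distal MV: 58 vs 53.5
        assert p.overall_mv_asym == pytest.approx(200 * 4.5 / 111.5, rel=1e-9)
        pi_r = (0.75 + 0.75) / 2
        pi_l = (30 / 55 + 30 / 52) / 2
        assert p.overall_pi_asym == pytest.approx(
            200 * abs(pi_r - pi_l) / (pi_r + pi_l), rel=1e-9
        )

    def test_symmetric_inputs_zero_asymmetry(self, symmetric_patient):
        p = patient_profile(symmetric_patient)
        for name in (
            "proximal_asym", "distal_asym", "overall_asym",
            "proximal_mv_asym", "distal_mv_asym", "overall_mv_asym",
            "proximal_pi_asym", "distal_pi_asym", "overall_pi_asym",
        ):
            assert getattr(p, name) == 0.0

    def test_missing_segment_marks_incomplete(self, four_sample_patient):
        without_left_m1 = [
            s for s in four_sample_patient
            if not (s.side is Side.LEFT and s.segment is Segment.M1)
        ]
        p = patient_profile(without_left_m1)
        assert not p.complete
        assert p.incomplete_reasons == ["no left proximal window"]

    def test_multi_depth_aggregation_averages_mv_and_pi(self, four_sample_patient):
        extra = four_sample_patient + [
            VelocitySample(psv=100, edv=40, depth=62, side=Side.RIGHT)
        ]
        p = patient_profile(extra)
        # right M1: mean of MV(90,45)=60 and MV(100,40)=60, PI mean of .75 and 1.0
        assert p.right.mv == pytest.approx(60.0)
        assert p.right.pi == pytest.approx((0.75 + 1.0) / 2)

    def test_out_of_window_samples_ignored(self, four_sample_patient):
        noise = four_sample_patient + [
            VelocitySample(psv=200, edv=100, depth=57, side=Side.RIGHT)
        ]
        a = patient_profile(four_sample_patient)
        b = patient_profile(noise)
        assert b.rt_proximal_index == pytest.approx(a.rt_proximal_index)

    def test_invalid_index_flagged_not_dropped(self):
        # right M1 has mv <= 10*pi -> its index and everything derived from
        # it is flagged, but left-side indices survive
        samples = [
            VelocitySample(psv=30, edv=1, depth=60, side=Side.RIGHT),  # pi huge
            VelocitySample(psv=84, edv=42, depth=50, side=Side.RIGHT),
            VelocitySample(psv=75, edv=45, depth=60, side=Side.LEFT),
            VelocitySample(psv=72, edv=42, depth=50, side=Side.LEFT),
        ]
        p = patient_profile(samples)
        assert p.complete
        assert "rt_proximal_index" in p.invalid
        assert math.isnan(p.rt_proximal_index)
        assert "rt_mean_index" in p.invalid and "overall_asym" in p.invalid
        assert not math.isnan(p.lt_mean_index)
        # MV/PI asymmetries do not depend on the index and stay defined
        assert not math.isnan(p.overall_mv_asym)


class TestSensitivityGrid:
    def test_examples(self):
        grid = index_sensitivity_grid([50], [0.8, 5.0], [1, 10])
        cell = grid[0, 0, 0]
        assert cell["index"] == pytest.approx(100 * 50.8 / 49.2, rel=1e-9)
        assert grid[0, 0, 1]["index"] == pytest.approx(100 * 58 / 42, rel=1e-9)
        undefined = grid[0, 1, 1]  # mv=50, pi=5, k=10 -> denominator 0
        assert not undefined["defined"] and math.isnan(undefined["index"])

    def test_larger_multiplier_spreads_differences(self, rng):
        # state 1: lower mv, higher pi; state 2: higher mv, lower pi
        for _ in range(50):
            mv1, mv2 = sorted(rng.uniform(40, 80, 2))
            pi2, pi1 = sorted(rng.uniform(0.5, 1.2, 2))
            grid = index_sensitivity_grid([mv1, mv2], [pi1, pi2], [1, 10])
            d1 = abs(grid[0, 0, 0]["index"] - grid[1, 1, 0]["index"])
            d10 = abs(grid[0, 0, 1]["index"] - grid[1, 1, 1]["index"])
            assert d10 > d1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidSampleError):
            index_sensitivity_grid([0], [0.5], [10])
        with pytest.raises(InvalidSampleError):
            index_sensitivity_grid([50], [-0.1], [10])
        with pytest.raises(InvalidSampleError):
            index_sensitivity_grid([50], [0.5], [0])


class TestVelocitySample:
    def test_validation(self):
        with pytest.raises(InvalidSampleError):
            VelocitySample(psv=40, edv=50, depth=60, side=Side.RIGHT)
        with pytest.raises(InvalidSampleError):
            VelocitySample(psv=50, edv=40, depth=0, side=Side.RIGHT)

    def test_derived_properties(self):
        s = VelocitySample(psv=90, edv=45, depth=60, side=Side.RIGHT)
        assert s.mv == 60.0 and s.pi == 0.75 and s.segment is Segment.M1
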