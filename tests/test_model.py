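"""Deterministic drive-map behaviour: pairing probabilities, the frequency
recurrence, threshold location and bistable trajectories."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egidrive import (
    DegenerateModelError,
    DriveParams,
    NoThresholdError,
    closed_form_threshold,
    delta_x,
    find_threshold,
    iterate_trajectory,
    mating_probabilities,
    next_frequency,
)


class TestDriveParams:
    def test_defaults_are_neutral(self):
        p = DriveParams()
        assert (p.F, p.c, p.w1, p.w2, p.w3) == (1, 1, 1, 1, 1)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(F=0), dict(F=-1), dict(c=0), dict(w1=-0.1), dict(c=2, w1=3)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DriveParams(**kwargs)


class TestMatingProbabilities:
    def test_symmetric_point_propensity(self):
        d = mating_probabilities(0.5, DriveParams(), mode="propensity")
        assert d.p_egi_egi == pytest.approx(0.25)
        assert d.p_egi_wt + d.p_wt_egi == pytest.approx(0.5)
        assert d.p_wt_wt == pytest.approx(0.25)
        assert d.z is None

    def test_uniform_weights_give_quarter_each(self):
        d = mating_probabilities(0.5, DriveParams(), mode="preference")
        assert d.as_tuple() == pytest.approx((0.25, 0.25, 0.25, 0.25))
        assert d.z == pytest.approx(1.0)

    def test_weighted_example_hand_computed(self):
        # z = 2*0.36 + (1+1)*0.24 + 0.16 = 1.36; p_ee = 0.72/1.36
        d = mating_probabilities(0.6, DriveParams(w1=2.0), mode="preference")
        assert d.z == pytest.approx(1.36)
        assert d.p_egi_egi == pytest.approx(0.72 / 1.36)

    def test_mode_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mating_probabilities(0.5, DriveParams(w1=2.0), mode="propensity")
        with pytest.raises(ValueError):
            mating_probabilities(0.5, DriveParams(c=2.0), mode="preference")

    def test_zero_normalizer_is_degenerate(self):
        # the wt x wt weight is implicitly 1, so z vanishes only where every
        # term with nonzero weight has zero frequency
        with pytest.raises(DegenerateModelError):
            mating_probabilities(1.0, DriveParams(w1=0, w2=0, w3=0), mode="preference")

    def test_propensity_warns_beyond_unit_effective_frequency(self):
        with pytest.warns(RuntimeWarning):
            mating_probabilities(0.9, DriveParams(c=1.5), mode="propensity")

    @given(
        x=st.floats(0, 1),
        w1=st.floats(0, 10),
        w2=st.floats(0, 10),
        w3=st.floats(0, 10),
    )
    @settings(max_examples=200, derandomize=True)
    def test_preference_probabilities_sum_to_one(self, x, w1, w2, w3):
        params = DriveParams(w1=w1, w2=w2, w3=w3)
        try:
            d = mating_probabilities(x, params, mode="preference")
        except DegenerateModelError:
            return
        assert d.total == pytest.approx(1.0, abs=1e-12)
        assert all(0 <= p <= 1 for p in d.as_tuple())


class TestNextFrequency:
    @pytest.mark.parametrize(
        "x, params, expected",
        [
            (0.5, DriveParams(), 0.5),
            (0.4, DriveParams(), 0.16 / 0.52),
            (0.5, DriveParams(F=108.1 / 78.6), (108.1 / 78.6) / (108.1 / 78.6 + 1)),
        ],
    )
    def test_hand_computed_values(self, x, params, expected):
        assert next_frequency(x, params) == pytest.approx(expected, abs=1e-12)

    def test_boundaries_are_fixed_points(self):
        params = DriveParams(F=2.0)
        assert next_frequency(0.0, params) == 0.0
        assert next_frequency(1.0, params) == 1.0

    def test_degenerate_denominator(self):
        # reachable only in preference mode with w1 = 0 at x = 1
        with pytest.raises(DegenerateModelError):
            next_frequency(1.0, DriveParams(w1=0.0))

    def test_array_input(self):
        xs = np.array([0.0, 0.4, 0.5, 1.0])
        out = next_frequency(xs, DriveParams())
        assert out.shape == xs.shape
        assert out[2] == pytest.approx(0.5)


class TestDeltaX:
    def test_equilibrium_and_boundary_zeros(self):
        assert delta_x(0.5, DriveParams()) == 0.0
        assert delta_x(0.0, DriveParams(F=3.0, w1=2.0)) == 0.0

    def test_hand_computed_value(self):
        assert delta_x(0.4, DriveParams()) == pytest.approx(0.16 / 0.52 - 0.4, abs=1e-12)

    def test_sign_structure_around_threshold(self):
        params = DriveParams(F=1.5, w1=0.8)
        xstar = 1.0 / (1.0 + 1.5 * 0.8)
        grid = np.linspace(1e-3, 1 - 1e-3, 1000)
        d = delta_x(grid, params)
        assert np.all(d[grid < xstar - 1e-9] < 0)
        assert np.all(d[grid > xstar + 1e-9] > 0)


class TestFindThreshold:
    def test_symmetric_underdominance(self):
        assert find_threshold(DriveParams()) == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize(
        "F, w1, reported_pct",
        [
            (108.1 / 78.6, 1.0, 42),
            (57.5 / 78.6, 1.0, 58),
            (108.1 / 78.6, 17 / 15, 39),
        ],
    )
    def test_measured_component_thresholds(self, F, w1, reported_pct):
        thr = find_threshold(DriveParams(F=F, w1=w1))
        assert round(100 * thr) == reported_pct

    @given(
        logF=st.floats(-2.3, 2.3),
        logw=st.floats(-2.3, 2.3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_agrees_with_closed_form(self, logF, logw):
        F, w1 = float(np.exp(logF)), float(np.exp(logw))
        thr = find_threshold(DriveParams(F=F, w1=w1))
        assert thr == pytest.approx(closed_form_threshold(F, w1), abs=1e-9)

    def test_strictly_decreasing_in_F_and_w1(self):
        grid = np.logspace(-1, 1, 9)
        thr_F = [find_threshold(DriveParams(F=F)) for F in grid]
        thr_w = [find_threshold(DriveParams(w1=w)) for w in grid]
        assert np.all(np.diff(thr_F) < 0)
        assert np.all(np.diff(thr_w) < 0)

    def test_no_interior_crossing_raises(self):
        with pytest.raises(NoThresholdError):
            find_threshold(DriveParams(w1=0.0))


class TestIterateTrajectory:
    def test_bistability_around_symmetric_threshold(self):
        up = iterate_trajectory(0.6, DriveParams())
        down = iterate_trajectory(0.4, DriveParams())
        assert up.outcome == "fixation"
        assert down.outcome == "loss"
        assert np.all(np.diff(up.frequencies) > 0)
        assert np.all(np.diff(down.frequencies) < 0)

    def test_exact_fixed_point_is_equilibrium(self):
        t = iterate_trajectory(0.5, DriveParams())
        assert t.outcome == "equilibrium"
        assert t.frequencies == (0.5,)

    def test_first_element_is_x0_and_range_invariant(self):
        t = iterate_trajectory(0.73, DriveParams(F=1.4))
        assert t.frequencies[0] == 0.73
        assert all(0 <= x <= 1 for x in t.frequencies)

    @pytest.mark.parametrize("F, w1", [(1.0, 1.0), (1.4, 1.0), (0.8, 2.5)])
    def test_bistable_about_computed_threshold(self, F, w1):
        params = DriveParams(F=F, w1=w1)
        xstar = find_threshold(params)
        assert iterate_trajectory(min(xstar + 0.02, 0.99), params).outcome == "fixation"
        assert iterate_trajectory(max(xstar - 0.02, 0.01), params).outcome == "loss"
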