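"""Mate-choice and quadrant statistics, each checked against hand
computation or an independent enumeration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from egidrive import (
    AssayRecord,
    DriveParams,
    MatingCountTable,
    chi_squared_uniform,
    delta_x,
    empirical_p_value,
    estimate_preferences,
    fisher_exact_2x2,
    mating_probabilities,
    quadrant_assign,
    two_proportion_z_test,
)

from oracles import fisher_exact_enumeration


def table(ee, ew, we, ww):
    return MatingCountTable(n_ee=ee, n_ew=ew, n_we=we, n_ww=ww)


class TestChiSquaredUniform:
    def test_exact_uniformity_is_zero(self):
        assert chi_squared_uniform(table(25, 25, 25, 25)) == 0.0

    def test_relabeling_invariance(self):
        a = chi_squared_uniform(table(5, 9, 2, 14))
        b = chi_squared_uniform(table(14, 2, 9, 5))
        assert a == b

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_uniform(table(0, 0, 0, 0))


class TestEmpiricalPValue:
    def test_zero_statistic_gives_p_one(self):
        assert empirical_p_value(0.0, n=90, n_sims=1000, seed=0) == 1.0

    def test_floor_at_inverse_sims(self):
        # a statistic far beyond anything the null produces
        p = empirical_p_value(63.2, n=90, n_sims=20_000, seed=0)
        assert p == pytest.approx(1 / 20_001)

    def test_median_statistic_gives_half(self):
        rng = np.random.default_rng(5)
        sims = rng.multinomial(90, [0.25] * 4, size=20_000)
        stats = ((sims - 22.5) ** 2).sum(axis=1) / 22.5
        med = float(np.median(stats))
        p = empirical_p_value(med, n=90, n_sims=20_000, seed=99)
        assert p == pytest.approx(0.5, abs=0.02)

    def test_converges_to_analytic_chi2_tail(self):
        # large n: the multinomial Pearson statistic is chi2 with 3 df
        n_sims = 100_000
        for stat in (2.0, 6.0, 12.0):
            p = empirical_p_value(stat, n=1000, n_sims=n_sims, seed=31)
            analytic = sps.chi2.sf(stat, df=3)
            mc_se = np.sqrt(analytic * (1 - analytic) / n_sims)
            assert abs(p - analytic) < 3 * mc_se + 2e-3


class TestFisherExact:
    def test_perfect_diagonal_greater(self):
        # only one of C(10,5) margin-fixed tables is this extreme
        from math import comb

        p = fisher_exact_2x2(table(5, 0, 0, 5), alternative="greater")
        assert p == pytest.approx(1 / comb(10, 5))

    def test_two_by_two_singleton_two_sided(self):
        assert fisher_exact_2x2(table(1, 0, 0, 1)) == pytest.approx(1.0)

    def test_transpose_symmetry_greater(self):
        t1, t2 = table(7, 2, 3, 9), table(7, 3, 2, 9)
        assert fisher_exact_2x2(t1, "greater") == pytest.approx(
            fisher_exact_2x2(t2, "greater")
        )

    def test_zero_margin_degenerate(self):
        with pytest.warns(RuntimeWarning):
            assert fisher_exact_2x2(table(0, 0, 3, 5)) == 1.0

    @given(
        ee=st.integers(0, 12),
        ew=st.integers(0, 12),
        we=st.integers(0, 12),
        ww=st.integers(0, 12),
        alt=st.sampled_from(["two_sided", "greater", "less"]),
    )
    @settings(max_examples=150, derandomize=True)
    def test_matches_exact_enumeration(self, ee, ew, we, ww, alt):
        t = table(ee, ew, we, ww)
        arr = t.as_array()
        if arr.sum() == 0 or 0 in arr.sum(0) or 0 in arr.sum(1):
            return
        expected = float(fisher_exact_enumeration(ee, ew, we, ww, alt))
        assert fisher_exact_2x2(t, alt) == pytest.approx(expected, abs=1e-9)


class TestEstimatePreferences:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((17, 54, 4, 15), (17 / 15, 54 / 15, 4 / 15)),
            ((52, 21, 9, 7), (52 / 7, 3.0, 9 / 7)),
            ((8, 8, 8, 8), (1.0, 1.0, 1.0)),
        ],
    )
    def test_count_ratios(self, cells, expected):
        assert estimate_preferences(table(*cells)) == pytest.approx(expected)

    def test_zero_reference_cell_rejected(self):
        with pytest.raises(ValueError, match="pseudocount"):
            estimate_preferences(table(5, 3, 2, 0))

    def test_mle_self_consistency_at_half(self):
        # plugging the estimated weights back into the pairing model at
        # x = 0.5 must reproduce the observed cell frequencies exactly
        t = table(17, 54, 4, 15)
        w1, w2, w3 = estimate_preferences(t)
        d = mating_probabilities(0.5, DriveParams(w1=w1, w2=w2, w3=w3))
        obs = np.array([t.n_ee, t.n_ew, t.n_we, t.n_ww]) / t.total
        assert d.as_tuple() == pytest.approx(tuple(obs), abs=1e-12)


def record_at(x0, dx, total_start=40, total_off=1000):
    se = round(x0 * total_start)
    x1 = x0 + dx
    oe = round(x1 * total_off)
    return AssayRecord(se, total_start - se, oe, total_off - oe)


class TestQuadrants:
    def test_tie_and_corner_assignment(self):
        records = [
            record_at(0.2, -0.05),  # C: below split, decline
            record_at(0.8, +0.05),  # B: above split, spread
            record_at(0.2, +0.05),  # A
            record_at(0.8, -0.05),  # D
            record_at(0.5, +0.05),  # x0 == split counts as right: B
            record_at(0.2, 0.0),    # dx == 0 counts as non-positive: C
        ]
        q = quadrant_assign(records, split_x=0.5)
        assert (q.a, q.b, q.c, q.d) == (1, 2, 2, 1)
        assert q.n_classified == 6

    def test_deterministic_model_points_all_drive_consistent(self):
        params = DriveParams()
        records = [
            record_at(x0, delta_x(float(x0), params), total_off=10**6)
            for x0 in np.arange(0.05, 0.96, 0.05)
        ]
        q = quadrant_assign(records, split_x=0.5)
        # the exact-equilibrium point (x0 = 0.5, dx = 0) ties into D by the
        # deterministic tie rule; every other point is drive-consistent
        assert q.a == 0 and q.d == 1
        assert q.n_drive_consistent == len(records) - 1

    def test_unclassifiable_records_skipped(self):
        records = [record_at(0.2, -0.05), AssayRecord(20, 20, 0, 0)]
        q = quadrant_assign(records, split_x=0.5)
        assert q.n_classified == 1


class TestTwoProportionZ:
    def test_equal_proportions_give_zero(self):
        z, p = two_proportion_z_test(3, 10, 6, 20)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # pooled p = 0.7, se = sqrt(0.21 * 0.2)
        z, p = two_proportion_z_test(9, 10, 5, 10)
        assert z == pytest.approx(0.4 / np.sqrt(0.042), abs=1e-9)
        assert p == pytest.approx(0.0509, abs=5e-4)

    def test_extreme_contrast(self):
        z, p = two_proportion_z_test(10, 10, 0, 10)
        assert z == pytest.approx(1.0 / np.sqrt(0.25 * 0.2), abs=1e-9)
        assert p < 1e-3

    def test_degenerate_pooled_proportion(self):
        with pytest.warns(RuntimeWarning):
            z, p = two_proportion_z_test(0, 10, 0, 10)
        assert (z, p) == (0.0, 1.0)
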