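"""Spread/greek classification, VAF shapes, Fisher 2x3 and BH oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fieldmap import mutation_classes as mc
from fieldmap.synthetic_organ import neutral_vaf_sample

from conftest import make_mutation_table


class TestSpreadClass:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (1, "private"),
            (2, "regional_2_10"),
            (10, "regional_2_10"),
            (11, "regional_11_20"),
            (15, "regional_11_20"),
            (20, "regional_11_20"),
            (21, "widespread_21_30"),
            (30, "widespread_21_30"),
            (31, "widespread_gt30"),
            (37, "widespread_gt30"),
        ],
    )
    def test_bins(self, n, expected):
        presence = [True] * n + [False] * (40 - n)
        assert mc.spread_class(presence) == expected

    def test_absent_everywhere_is_error(self):
        with pytest.raises(ValueError, match="absent"):
            mc.spread_class([False] * 5)


class TestAssignGreek:
    def test_private_low_vaf_is_alpha(self):
        v = np.zeros(37)
        v[3] = 0.05
        assert mc.assign_greek(v) == "alpha"

    def test_expanded_low_vaf_is_beta(self):
        v = np.zeros(37)
        v[:6] = 0.08
        assert mc.assign_greek(v) == "beta"

    def test_expanded_clonal_vaf_is_gamma(self):
        v = np.zeros(37)
        v[:25] = 0.35
        assert mc.assign_greek(v) == "gamma"

    def test_two_fields_below_cluster_minimum_is_alpha(self):
        v = np.zeros(37)
        v[:2] = 0.3
        assert mc.assign_greek(v) == "alpha"


class TestVafShape:
    def test_neutral_sample_right_skewed(self):
        rng = np.random.default_rng(0)
        v = neutral_vaf_sample(1000, rng)
        assert mc.vaf_shape(v) == "right_skewed"

    def test_clonal_mode_binomial(self):
        rng = np.random.default_rng(1)
        v = stats.truncnorm.rvs(-11, 5, loc=0.35, scale=0.03, size=1000,
                                random_state=rng)
        assert mc.vaf_shape(v) == "binomial_clonal"

    def test_uniform_sample(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0.55, 0.95, size=300)
        assert mc.vaf_shape(v) == "uniform"

    def test_below_n_min_indeterminate(self):
        assert mc.vaf_shape([0.1, 0.2, 0.3, 0.4, 0.5]) == "indeterminate"


def _fisher_oracle(table: np.ndarray) -> float:
    """Independent brute-force 2x3 Fisher p by rational-arithmetic enumeration."""
    t = np.asarray(table, dtype=int)
    r1, r2 = t.sum(axis=1)
    c = t.sum(axis=0)
    n = t.sum()

    def prob(a, b, cc):
        num = (
            math.comb(c[0], a) * math.comb(c[1], b) * math.comb(c[2], cc)
        )
        return num / math.comb(n, r1)

    p_obs = prob(t[0, 0], t[0, 1], t[0, 2])
    total = 0.0
    for a in range(c[0] + 1):
        for b in range(c[1] + 1):
            cc = r1 - a - b
            if 0 <= cc <= c[2]:
                p = prob(a, b, cc)
                if p <= p_obs * (1 + 1e-12):
                    total += p
    return min(1.0, total)


class TestGroupDistribution:
    def test_homogeneous_table_p_one(self):
        assert mc.group_distribution_test([[5, 5, 5], [5, 5, 5]]) == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            t = rng.integers(0, 12, size=(2, 3))
            if t.sum() == 0:
                continue
            p = mc.group_distribution_test(t)
            assert p == pytest.approx(_fisher_oracle(t), abs=1e-12)

    def test_extreme_table(self):
        t = [[10, 0, 0], [0, 10, 10]]
        assert mc.group_distribution_test(t) == pytest.approx(
            _fisher_oracle(np.array(t)), abs=1e-12
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mc.group_distribution_test([[1, 2, -1], [0, 1, 2]])

    def test_monte_carlo_close_to_exact(self):
        t = [[30, 20, 10], [10, 20, 30]]
        exact = mc.group_distribution_test(t)
        mc_p = mc.group_distribution_test(t, max_enumeration=10, seed=1)
        assert mc_p == pytest.approx(exact, abs=0.01)

    def test_monte_carlo_seeded_reproducible(self):
        t = [[30, 20, 10], [10, 20, 30]]
        a = mc.group_distribution_test(t, max_enumeration=10, seed=5)
        b = mc.group_distribution_test(t, max_enumeration=10, seed=5)
        assert a == b


def _bh_oracle(p):
    """Step-up BH computed directly from its defining formula."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, m * p[i] / rank_from_top)
        q[i] = running
    return q


class TestBH:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            mc.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-15
        )

    def test_single_and_ties(self):
        assert mc.bh_fdr([0.5]) == pytest.approx([0.5])
        np.testing.assert_allclose(mc.bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_against_oracle_many_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(mc.bh_fdr(p), _bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_property_monotone_in_p(self, pvals):
        q = mc.bh_fdr(pvals)
        p = np.asarray(pvals)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= p - 1e-12) & (q <= 1 + 1e-12)).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mc.bh_fdr([0.5, 1.5])


class TestClassification:
    def test_order_invariance(self, small_organ):
        t = small_organ.mutations
        base = mc.classify_mutations(t)
        rng = np.random.default_rng(0)
        rows = rng.permutation(t.meta.index)
        cols = list(rng.permutation(t.vaf.columns))
        shuffled = type(t)(t.meta.loc[rows], t.vaf.loc[rows, cols])
        perm = mc.classify_mutations(shuffled)
        pd.testing.assert_frame_equal(
            base.table.sort_index(), perm.table.sort_index()
        )

    def test_greek_recovery_on_planted_truth(self, small_organ):
        a = mc.classify_mutations(small_organ.mutations)
        truth = small_organ.truth.mutations["greek_class"]
        assert (a.table["greek_class"] == truth).mean() >= 0.99

    def test_counts_sum_to_total(self, small_organ):
        a = mc.classify_mutations(small_organ.mutations)
        assert a.class_counts().sum() == small_organ.mutations.n_mutations
        assert a.spread_counts().sum() == small_organ.mutations.n_mutations


class TestDrivers:
    def test_all_and_none(self, tiny_field_map):
        vaf = pd.DataFrame(
            [[0.1, 0, 0, 0], [0, 0.2, 0, 0]],
            index=["m0", "m1"],
            columns=tiny_field_map.field_ids,
        )
        t = make_mutation_table(vaf)
        a = mc.classify_mutations(t)
        allhit = mc.driver_proportions(a, t, ["GENE0", "GENE1"])
        assert allhit["alpha"] == 1.0
        nohit = mc.driver_proportions(a, t, [])
        assert nohit["alpha"] == 0.0

    def test_planted_gamma_enrichment(self, small_organ):
        a = mc.classify_mutations(small_organ.mutations)
        props = mc.driver_proportions(
            a, small_organ.mutations, small_organ.truth.driver_genes
        )
        assert props["gamma"] > props["alpha"]

    def test_empty_assignment_rejected(self, tiny_field_map):
        vaf = pd.DataFrame(
            [[0.1, 0, 0, 0]], index=["m0"], columns=tiny_field_map.field_ids
        )
        t = make_mutation_table(vaf)
        a = mc.classify_mutations(t)
        empty = mc.ClassAssignment(a.table.iloc[:0], 0.01, 0.2, 3)
        with pytest.raises(ValueError, match="empty"):
            mc.driver_proportions(empty, t, ["X"])
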