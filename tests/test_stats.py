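from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slowwave.stats import (
    aggregate_by_area,
    bh_adjust,
    normalize_by_subject,
    rank_core_nodes,
    ranksum_p,
    wilcoxon_matrix,
)


def enumeration_ranksum_p(x, y):
    """Independent oracle: exact two-sided rank-sum p by full enumeration."""
    pooled = np.r_[x, y]
    n1 = len(x)
    ranks = pooled.argsort().argsort() + 1.0
    w_obs = ranks[:n1].sum()
    ws = np.array([ranks[list(idx)].sum() for idx in combinations(range(len(pooled)), n1)])
    return min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))


def stepup_bh(p):
    """Independent oracle: BH step-up with an explicit reverse cummin."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for k in range(m - 1, -1, -1):
        i = order[k]
        prev = min(prev, p[i] * m / (k + 1))
        adj[i] = prev
    return adj


class TestAggregation:
    def test_median_of_channels(self, geometry):
        chans = geometry.area_channels("M")[:3]
        values = dict(zip(chans, [1.0, 2.0, 3.0]))
        out = aggregate_by_area(values, geometry)
        assert out["M"] == 2.0

    def test_single_channel_area(self, geometry):
        ch = geometry.area_channels("V")[0]
        assert aggregate_by_area({ch: 7.5}, geometry) == {"V": 7.5}

    def test_durations_pooled_before_median(self, geometry):
        chans = geometry.area_channels("R")[:2]
        values = {chans[0]: np.array([1.0, 2.0, 3.0]), chans[1]: np.array([10.0])}
        out = aggregate_by_area(values, geometry)
        # pooled convention: median of [1,2,3,10], not median of medians
        assert out["R"] == pytest.approx(np.median([1.0, 2.0, 3.0, 10.0]))

    def test_excluded_channels_contribute_nothing(self, geometry):
        chans = geometry.area_channels("M")[:2]
        values = dict(zip(chans, [1.0, 100.0]))
        out = aggregate_by_area(values, geometry, excluded={chans[1]})
        assert out["M"] == 1.0


class TestNormalization:
    def test_constant_areas_normalize_to_one(self):
        df = normalize_by_subject({"s": {a: 2.0 for a in "MSPRV"}})
        np.testing.assert_allclose(df["value"], 1.0)

    def test_two_area_example(self):
        df = normalize_by_subject({"s": {"A": 1.0, "B": 3.0}})
        assert sorted(df["value"]) == [0.5, 1.5]

    def test_mean_identity_holds_exactly(self):
        rng = np.random.default_rng(0)
        summary = {
            f"s{i}": {a: float(v) for a, v in zip("MSPRV", rng.uniform(0.1, 5, 5))}
            for i in range(6)
        }
        df = normalize_by_subject(summary)
        for _, g in df.groupby("subject"):
            assert g["value"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_negative_factor_allowed_for_slopes(self):
        df = normalize_by_subject({"s": {"A": -1.0, "B": -3.0}})
        assert df["value"].mean() == pytest.approx(1.0)


class TestRankSum:
    def test_identical_groups_p_one(self):
        assert ranksum_p([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_fully_separated_small_groups(self):
        # the most extreme of C(6,3)=20 orderings, doubled
        assert ranksum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_path_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for n1 in (2, 4, 6):
            for n2 in (3, 5, 6):
                for _ in range(10):
                    x, y = rng.normal(size=n1), rng.normal(size=n2)
                    assert ranksum_p(x, y) == pytest.approx(
                        enumeration_ranksum_p(x, y), abs=1e-12
                    )

    def test_matrix_structure(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(size=8) for k in "ABCD"}
        pm = wilcoxon_matrix(groups)
        np.testing.assert_allclose(pm.p_raw, pm.p_raw.T)
        off = ~np.eye(4, dtype=bool)
        assert np.all(pm.p_adj[off] >= pm.p_raw[off] - 1e-15)

    def test_small_groups_marked_undefined(self):
        pm = wilcoxon_matrix({"A": [1.0], "B": [1.0, 2.0, 3.0], "C": [2.0, 3.0, 4.0]})
        ia = pm.labels.index("A")
        assert np.isnan(pm.p_raw[ia, 1]) and np.isnan(pm.p_adj[ia, 2])
        assert np.isfinite(pm.p_raw[1, 2])


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust([0.5]), [0.5])

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            p = rng.random(int(rng.integers(1, 60)))
            np.testing.assert_allclose(bh_adjust(p), stepup_bh(p), rtol=1e-12, atol=1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms())
    def test_permutation_equivariance(self, p, rnd):
        p = np.asarray(p)
        perm = np.arange(len(p))
        rnd.shuffle(perm)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), rtol=1e-12)


class TestCoreNodes:
    def test_all_pairs_significant(self):
        n = 5
        p_adj = np.full((n, n), 0.001)
        pm_labels = [str(i) for i in range(n)]
        from slowwave.stats import PMatrix

        pm = PMatrix(labels=pm_labels, p_raw=p_adj.copy(), p_adj=p_adj)
        rep = rank_core_nodes(pm)
        assert all(rep.counts[l] == 4 for l in pm_labels)
        assert rep.top3 == ["0", "1", "2"]   # deterministic tie-break

    def test_no_significant_pairs(self):
        from slowwave.stats import PMatrix

        n = 4
        pm = PMatrix(labels=list("abcd"), p_raw=np.ones((n, n)), p_adj=np.ones((n, n)))
        rep = rank_core_nodes(pm)
        assert rep.no_core_nodes

    def test_planted_shifted_group_wins(self):
        rng = np.random.default_rng(4)
        groups = {f"g{i}": rng.normal(0, 0.1, 10) for i in range(6)}
        for i in (0, 1, 2):
            groups[f"g{i}"] = rng.normal(3.0, 0.1, 10)
        pm = wilcoxon_matrix(groups)
        rep = rank_core_nodes(pm)
        assert set(rep.top3) <= {"g0", "g1", "g2"}


def test_fdr_control_under_global_null():
    """Fraction of adjusted-significant pairs under the null stays below alpha."""
    rng = np.random.default_rng(5)
    sig = 0
    total = 0
    for _ in range(60):
        groups = {k: rng.normal(size=11) for k in "ABCDE"}
        pm = wilcoxon_matrix(groups)
        sig += len(pm.significant_pairs())
        total += 10
    assert sig / total <= 0.05 + 0.02
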