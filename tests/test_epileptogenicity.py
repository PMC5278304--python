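"""Seizure likelihood, rank-sum/FDR kernels, epileptogenic-set delineation."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ictonet import (
    EscapeTimeEnsemble,
    bh_fdr,
    clustering_coefficient,
    delineate_epileptogenic_set,
    likelihood_profile,
    node_strength,
    wilcoxon_ranksum,
)


def make_ensemble(tau, t_max):
    tau = np.asarray(tau, dtype=float)
    return EscapeTimeEnsemble(tau=tau, censored=(tau >= t_max), t_max=t_max)


def exact_ranksum_p(x, y):
    """Enumeration oracle: two-sided p of the rank-sum statistic over all
    C(n, n1) assignments of the pooled ranks."""
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    # midranks for ties
    order = np.sort(pooled)
    rank_of = {}
    for v in np.unique(order):
        where = np.flatnonzero(order == v) + 1
        rank_of[v] = where.mean()
    ranks = np.array([rank_of[v] for v in pooled])
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * (n - n1) / 2
    count = total = 0
    for comb in combinations(range(n), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestLikelihoodProfile:
    def test_reciprocal_of_mean_escape_time(self):
        ens = make_ensemble([[2.0, 2.0], [4.0, 4.0]], t_max=10.0)
        prof = likelihood_profile(ens)
        np.testing.assert_allclose(prof.mean_tau, [2.0, 4.0])
        np.testing.assert_allclose(prof.likelihood, [0.5, 0.25])

    def test_identical_rows_equal_likelihood(self):
        ens = make_ensemble(np.full((4, 5), 3.0), t_max=10.0)
        prof = likelihood_profile(ens)
        assert np.unique(prof.likelihood).size == 1

    def test_censored_row_flagged_and_bounded(self):
        tau = np.vstack([np.full(10, 1000.0), np.full(10, 100.0)])
        prof = likelihood_profile(make_ensemble(tau, t_max=1000.0))
        np.testing.assert_allclose(prof.likelihood, [0.001, 0.01])
        assert prof.all_censored.tolist() == [True, False]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_ranking_preserved(self, seed):
        rng = np.random.default_rng(seed)
        tau = rng.uniform(1.0, 99.0, size=(6, 8))
        prof = likelihood_profile(make_ensemble(tau, t_max=100.0))
        assert np.argmin(prof.mean_tau) == np.argmax(prof.likelihood)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            likelihood_profile(make_ensemble(np.zeros((0, 0)), t_max=1.0))


class TestWilcoxonRanksum:
    def test_extreme_separation_small_samples_exact(self):
        assert wilcoxon_ranksum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        assert wilcoxon_ranksum([1.0, 2.0], [1.0, 2.0]) == 1.0

    def test_all_tied_p_one(self):
        assert wilcoxon_ranksum(np.full(50, 7.0), np.full(80, 7.0)) == 1.0

    @pytest.mark.parametrize("n1,n2", [(3, 5), (5, 5), (6, 8)])
    def test_matches_enumeration_oracle(self, n1, n2, rng):
        for _ in range(5):
            x = rng.standard_normal(n1)
            y = rng.standard_normal(n2) + 0.7
            assert wilcoxon_ranksum(x, y) == pytest.approx(
                exact_ranksum_p(x, y), abs=1e-12)

    def test_asymptotic_agrees_with_exact_on_null_decisions(self, rng):
        """Forcing the large-sample path on samples where the exact path is
        available must give the same accept/reject call nearly always."""
        from scipy.stats import mannwhitneyu
        agree = 0
        trials = 200
        for _ in range(trials):
            x, y = rng.standard_normal(8), rng.standard_normal(8)
            p_exact = wilcoxon_ranksum(x, y)
            p_asym = mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic").pvalue
            agree += (p_exact < 0.05) == (p_asym < 0.05)
        assert agree / trials >= 0.95

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([], [1.0])


class TestBhFdr:
    def test_step_up_by_hand(self):
        mask = bh_fdr([0.01, 0.02, 0.2], q=0.05)
        assert mask.tolist() == [True, True, False]

    def test_all_tiny_all_rejected(self):
        assert bh_fdr(np.full(10, 0.001)).all()

    def test_all_large_none_rejected(self):
        assert not bh_fdr(np.full(10, 0.9)).any()

    def test_empty_input_empty_mask(self):
        assert bh_fdr([]).size == 0

    def test_matches_manual_step_up_on_random_vectors(self, rng):
        for _ in range(50):
            m = rng.integers(1, 30)
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3.0)
            mask = bh_fdr(p, q=0.05)
            order = np.argsort(p)
            ps = p[order]
            below = np.flatnonzero(ps <= (np.arange(1, m + 1) * 0.05 / m))
            expected = np.zeros(m, bool)
            if below.size:
                expected[order[:below[-1] + 1]] = True
            np.testing.assert_array_equal(mask, expected)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])


class TestDelineateEpileptogenicSet:
    def test_iid_nodes_keep_nearly_everyone(self, rng):
        sizes = []
        for _ in range(100):
            tau = rng.gamma(4.0, 25.0, size=(5, 60))
            sizes.append(delineate_epileptogenic_set(
                make_ensemble(np.clip(tau, 1e-3, 1e4), t_max=1e4)).size)
        assert np.mean(sizes) >= 0.9 * 5

    def test_planted_fast_node_isolated(self, rng):
        hits = 0
        repeats = 20
        for _ in range(repeats):
            tau = rng.gamma(4.0, 25.0, size=(9, 200))
            planted = int(rng.integers(9))
            tau[planted] *= 0.5
            found = delineate_epileptogenic_set(
                make_ensemble(np.clip(tau, 1e-3, 1e4), t_max=1e4))
            hits += found.tolist() == [planted]
        assert hits >= 0.9 * repeats

    def test_reference_node_always_included(self, rng):
        tau = rng.uniform(10, 20, size=(2, 30))
        found = delineate_epileptogenic_set(make_ensemble(tau, t_max=100.0))
        assert int(np.argmin(tau.mean(axis=1))) in found

    def test_opposite_convention_flag(self, rng):
        tau = rng.gamma(4.0, 25.0, size=(6, 100))
        tau[2] *= 0.4
        ens = make_ensemble(np.clip(tau, 1e-3, 1e4), t_max=1e4)
        default = set(delineate_epileptogenic_set(ens).tolist())
        opposite = set(delineate_epileptogenic_set(
            ens, include_rejected=True).tolist())
        assert default & opposite == {2}
        assert default | opposite == set(range(6))

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            delineate_epileptogenic_set(
                make_ensemble(np.ones((1, 10)), t_max=10.0))


class TestGraphMetrics:
    def test_complete_graph(self):
        w = 0.4
        C = np.full((5, 5), w)
        np.fill_diagonal(C, 0.0)
        np.testing.assert_allclose(node_strength(C), 4 * w)
        np.testing.assert_allclose(clustering_coefficient(C), 1.0)

    def test_star_graph_has_no_triangles(self):
        C = np.zeros((5, 5))
        C[0, 1:] = C[1:, 0] = 0.8
        np.testing.assert_allclose(clustering_coefficient(C), 0.0)

    def test_clustering_matches_triangle_enumeration(self, rng):
        n = 6
        W = rng.uniform(0, 1, size=(n, n))
        W = np.triu(W, 1)
        W[W < 0.3] = 0.0          # some missing edges
        W = W + W.T
        got = clustering_coefficient(W)
        Wn = W / W.max()
        expected = np.zeros(n)
        for i in range(n):
            ks = np.flatnonzero(W[i] > 0)
            deg = ks.size
            if deg < 2:
                continue
            tot = 0.0
            for a in range(deg):
                for b in range(a + 1, deg):
                    j, k = ks[a], ks[b]
                    if W[j, k] > 0:
                        tot += (Wn[i, j] * Wn[i, k] * Wn[j, k]) ** (1 / 3)
            expected[i] = 2 * tot / (deg * (deg - 1))
        np.testing.assert_allclose(got, expected, atol=1e-12)
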