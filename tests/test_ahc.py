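import itertools

import numpy as np
import pytest
from scipy.cluster import hierarchy

from mrahc.ahc import build_merge_path, cluster_ivw_mean, pairwise_distance
from mrahc.summary_data import OutcomeCorrelation, compute_ratio_estimates

from conftest import make_ratios, random_ratios


class TestClusterIVW:
    def test_equal_weight_mean(self):
        r = make_ratios([[0.0, 0.0], [2.0, 4.0]])
        cl = cluster_ivw_mean([0, 1], r)
        np.testing.assert_allclose(cl.ivw_mean, [1.0, 2.0])

    def test_weighted_mean_by_hand(self):
        # weights 3 and 1 -> mean = (3*0 + 1*4) / 4 = 1
        r = make_ratios([[0.0], [4.0]], v2=[[1 / 3], [1.0]])
        cl = cluster_ivw_mean([0, 1], r)
        assert cl.ivw_mean[0] == pytest.approx(1.0)
        # IVW variance is 1 / sum of weights
        assert 1.0 / cl.weight_sums[0] == pytest.approx(0.25)

    def test_singleton_is_identity(self, rng):
        r = random_ratios(rng)
        cl = cluster_ivw_mean([3], r)
        np.testing.assert_allclose(cl.ivw_mean, r.beta_hat[3])
        np.testing.assert_allclose(cl.weight_sums, r.weights[3])

    def test_empty_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_ivw_mean([], random_ratios(rng))

    def test_incremental_equals_from_scratch(self, rng):
        """Merging clusters adds their summaries exactly."""
        r = random_ratios(rng, J=6)
        a = cluster_ivw_mean([0, 1], r)
        b = cluster_ivw_mean([2, 3, 4], r)
        merged = cluster_ivw_mean([0, 1, 2, 3, 4], r)
        np.testing.assert_allclose(a.weight_sums + b.weight_sums, merged.weight_sums)
        np.testing.assert_allclose(a.cross_weight + b.cross_weight, merged.cross_weight)


class TestPairwiseDistance:
    def test_identical_means_give_zero(self):
        r = make_ratios([[1.0, 2.0], [1.0, 2.0]])
        d = pairwise_distance(cluster_ivw_mean([0], r), cluster_ivw_mean([1], r), r)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_single_outcome_reduces_to_wald(self, rng):
        """For P=1 singletons the distance is (b1-b2)^2 / (v1^2+v2^2)."""
        b1, b2, v1, v2 = 0.3, -0.6, 0.5, 1.2
        r = make_ratios([[b1], [b2]], v2=[[v1], [v2]])
        d = pairwise_distance(cluster_ivw_mean([0], r), cluster_ivw_mean([1], r), r)
        assert d == pytest.approx((b1 - b2) ** 2 / (v1 + v2), rel=1e-12)

    def test_two_outcome_hand_computation(self):
        # unit variances, independent outcomes: Omega = diag(2, 2),
        # difference (1, 1) -> D = 1/2 + 1/2 = 1
        r = make_ratios([[0.0, 0.0], [1.0, 1.0]])
        d = pairwise_distance(cluster_ivw_mean([0], r), cluster_ivw_mean([1], r), r)
        assert d == pytest.approx(1.0, rel=1e-12)

    def test_symmetry_and_nonnegativity(self, rng):
        rho = OutcomeCorrelation.exchangeable(2, 0.4)
        r = random_ratios(rng, J=8, rho=rho)
        a = cluster_ivw_mean([0, 1, 2], r)
        b = cluster_ivw_mean([3, 4], r)
        assert pairwise_distance(a, b, r) == pytest.approx(pairwise_distance(b, a, r))
        assert pairwise_distance(a, b, r) >= 0

    def test_omega_diagonal_identity_under_correlation(self, rng):
        """The Omega diagonal must equal 1/W_k + 1/W_l even with rho != I;
        checked against a direct element-by-element evaluation."""
        rho = OutcomeCorrelation.exchangeable(3, 0.5)
        r = random_ratios(rng, J=7, P=3, rho=rho)
        a = cluster_ivw_mean([0, 1, 2], r)
        b = cluster_ivw_mean([3, 4, 5, 6], r)
        # direct formula: rho_ir / (W_i W_r) * sum_j sqrt(w_ji w_jr), per cluster
        def omega(members_k, members_l):
            out = np.zeros((3, 3))
            for members in (members_k, members_l):
                w = r.weights[np.asarray(members)]
                W = w.sum(axis=0)
                sw = np.sqrt(w)
                out += rho.rho * (sw.T @ sw) / np.outer(W, W)
            return out

        om = omega([0, 1, 2], [3, 4, 5, 6])
        np.testing.assert_allclose(
            np.diag(om), 1.0 / a.weight_sums + 1.0 / b.weight_sums, rtol=1e-12
        )
        # and the engine's distance agrees with the direct quadratic form
        d = a.ivw_mean - b.ivw_mean
        expected = float(d @ np.linalg.solve(om, d))
        assert pairwise_distance(a, b, r, rho) == pytest.approx(expected, rel=1e-10)

    def test_overlapping_clusters_rejected(self, rng):
        r = random_ratios(rng)
        with pytest.raises(ValueError):
            pairwise_distance(cluster_ivw_mean([0, 1], r), cluster_ivw_mean([1, 2], r), r)


def _total_within_distance(groups, ratios):
    """Sum of within-group Wald dispersions (cluster Q with unit structure)."""
    total = 0.0
    for g in groups:
        if len(g) < 2:
            continue
        cl = cluster_ivw_mean(g, ratios)
        dev = ratios.beta_hat[np.asarray(list(g))] - cl.ivw_mean
        w = ratios.weights[np.asarray(list(g))]
        total += float((dev**2 * w).sum())
    return total


def _three_partitions(items):
    """All partitions of items into exactly 3 non-empty groups."""
    for labels in itertools.product(range(3), repeat=len(items)):
        if set(labels) != {0, 1, 2}:
            continue
        if labels.index(0) < labels.index(1) < labels.index(2):  # canonical order
            groups = [[], [], []]
            for item, lab in zip(items, labels):
                groups[lab].append(item)
            yield groups


class TestMergePath:
    def test_first_merge_joins_closest(self):
        r = make_ratios([[0.0], [0.01], [10.0]])
        path = build_merge_path(r)
        assert sorted(map(sorted, path.partition_at(2))) == [[0, 1], [2]]

    def test_ties_break_deterministically(self):
        r = make_ratios([[1.0], [1.0], [1.0], [1.0]])
        path = build_merge_path(r)
        # all distances are zero: the lowest-index pair merges first
        assert sorted(map(sorted, path.partition_at(3))) == [[0, 1], [2], [3]]

    def test_partition_structure(self, rng):
        r = random_ratios(rng, J=9)
        path = build_merge_path(r)
        for k in range(1, 10):
            part = path.partition_at(k)
            assert len(part) == k
            assert sorted(j for g in part for j in g) == list(range(9))
        # consecutive partitions differ by exactly one merge
        for k in range(2, 10):
            prev = {tuple(g) for g in path.partition_at(k)}
            nxt = {tuple(g) for g in path.partition_at(k - 1)}
            gone = prev - nxt
            new = nxt - prev
            assert len(gone) == 2 and len(new) == 1
            (a, b), (c,) = sorted(gone, key=len), new
            assert sorted(list(gone)[0] + list(gone)[1]) == sorted(c)

    def test_merge_distances_reproducible(self, rng):
        r = random_ratios(rng, J=7)
        path = build_merge_path(r)
        for f, _, _, dist in path.merges:
            k_before = 7 - f + 1
            prev = {tuple(g) for g in path.partition_at(k_before)}
            nxt = {tuple(g) for g in path.partition_at(k_before - 1)}
            a, b = sorted(prev - nxt, key=lambda g: g[0])
            d = pairwise_distance(cluster_ivw_mean(a, r), cluster_ivw_mean(b, r), r)
            assert d == pytest.approx(dist, rel=1e-9)

    def test_three_group_instance_recovered_and_optimal(self, figure2_toy):
        """Well-separated {0,1}, {2,3,4}, {5}: the K=3 level recovers the
        groups, and brute-force enumeration confirms they minimize the total
        within-group Wald dispersion among all 3-partitions."""
        r = compute_ratio_estimates(figure2_toy)
        path = build_merge_path(r)
        got = sorted(map(sorted, path.partition_at(3)))
        assert got == [[0, 1], [2, 3, 4], [5]]
        best = min(_three_partitions(range(6)), key=lambda g: _total_within_distance(g, r))
        assert sorted(map(sorted, best)) == got

    def test_single_variant_rejected(self):
        with pytest.raises(ValueError):
            build_merge_path(make_ratios([[1.0]]))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_single_outcome_matches_weighted_ward_oracle(self, seed):
        """For P=1 the path must coincide with classic Ward clustering of
        weighted scalars.  Oracle: replicate each point proportionally to its
        integer weight and run reference Ward linkage; replicas first merge
        at distance zero, after which the path is the weighted-point path."""
        rng = np.random.default_rng(seed)
        J = rng.integers(5, 12)
        beta = rng.normal(0, 2, size=J)
        w_int = rng.integers(1, 5, size=J)
        r = make_ratios(beta[:, None], v2=(1.0 / w_int)[:, None])
        path = build_merge_path(r)

        replicated = np.repeat(beta, w_int)[:, None]
        owner = np.repeat(np.arange(J), w_int)
        Z = hierarchy.linkage(replicated, method="ward")
        n_rep = replicated.shape[0]
        for k in range(1, J):  # k distinct clusters among the original points
            labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
            oracle = {}
            for j in range(J):
                lab = labels[owner == j]
                assert len(set(lab)) == 1  # replicas stay together
                oracle.setdefault(lab[0], []).append(j)
            oracle_part = sorted(sorted(g) for g in oracle.values())
            got = sorted(map(sorted, path.partition_at(k)))
            assert got == oracle_part
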