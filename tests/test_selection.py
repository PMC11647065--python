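import math

import numpy as np
import pytest
from scipy import stats

from mrahc.ahc import build_merge_path, cluster_ivw_mean
from mrahc.selection import (
    cochran_q,
    downward_testing,
    individual_q,
    iterate_outlier_removal,
    zeta_threshold,
)
from mrahc.summary_data import OutcomeCorrelation, compute_ratio_estimates

from conftest import make_ratios, random_ratios


class TestZeta:
    def test_forced_values(self):
        assert zeta_threshold(math.e**10) == pytest.approx(0.01, rel=1e-12)
        assert zeta_threshold(math.e**2) == pytest.approx(0.05, rel=1e-12)

    def test_applied_effective_sample_size(self):
        # a typical binary-outcome effective sample size
        assert zeta_threshold(193_440) == pytest.approx(0.1 / math.log(193_440), rel=1e-12)
        assert zeta_threshold(193_440) == pytest.approx(0.008215, abs=5e-7)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            zeta_threshold(1.0)
        with pytest.raises(ValueError):
            zeta_threshold(0.5)


def _scalar_cochran(beta, v2):
    """Independent textbook implementation of the scalar Cochran Q."""
    w = 1.0 / np.asarray(v2)
    mean = np.sum(w * beta) / np.sum(w)
    return float(np.sum(w * (np.asarray(beta) - mean) ** 2))


class TestCochranQ:
    def test_singleton_passes_by_convention(self, rng):
        res = cochran_q([2], random_ratios(rng))
        assert (res.q, res.df, res.p_value) == (0.0, 0, 1.0)
        assert res.passes

    def test_single_outcome_hand_value(self):
        r = make_ratios([[0.0], [1.0]])
        res = cochran_q([0, 1], r)
        assert res.q == pytest.approx(0.5)
        assert res.df == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_single_outcome_equals_textbook(self, seed):
        rng = np.random.default_rng(seed)
        beta = rng.normal(size=7)
        v2 = rng.uniform(0.2, 2.0, size=7)
        r = make_ratios(beta[:, None], v2[:, None])
        assert cochran_q(range(7), r).q == pytest.approx(_scalar_cochran(beta, v2), rel=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_independent_outcomes_decompose(self, seed):
        """With rho = 0 the multi-outcome Q is exactly the sum of the
        per-outcome scalar Q statistics, with df = P (|S| - 1)."""
        rng = np.random.default_rng(seed)
        r = random_ratios(rng, J=6, P=3)
        res = cochran_q(range(6), r)
        per_outcome = sum(
            _scalar_cochran(r.beta_hat[:, p], r.v2[:, p]) for p in range(3)
        )
        assert res.q == pytest.approx(per_outcome, rel=1e-10)
        assert res.df == 3 * 5

    def test_correlated_outcomes_change_q(self, rng):
        r0 = random_ratios(rng, J=5, P=2)
        rho = OutcomeCorrelation.exchangeable(2, 0.6)
        r1 = make_ratios(r0.beta_hat, r0.v2, rho)
        assert cochran_q(range(5), r1).q != pytest.approx(cochran_q(range(5), r0).q)


class TestIndividualQ:
    def test_zero_when_at_cluster_mean(self):
        r = make_ratios([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        cl = cluster_ivw_mean([0, 1, 2], r)
        assert individual_q(1, cl, r).q == pytest.approx(0.0, abs=1e-12)

    def test_single_outcome_chi1_tail(self):
        # deviation 2 with unit variance: Q = 4, p = P(chi2_1 > 4);
        # the near-zero-variance companion pins the IVW mean at 0
        r2 = make_ratios([[0.0], [2.0]], v2=[[1e-12], [1.0]])
        cl2 = cluster_ivw_mean([0, 1], r2)
        res2 = individual_q(1, cl2, r2)
        assert res2.q == pytest.approx(4.0, rel=1e-6)
        assert res2.p_value == pytest.approx(stats.chi2.sf(4, 1), rel=1e-6)
        assert res2.p_value == pytest.approx(0.0455, abs=2e-4)

    def test_two_outcome_closed_form_tail(self):
        # standardized deviations (1, 1) under rho = 0: Q = 2, p = e^{-1}
        r = make_ratios([[0.0, 0.0], [1.0, 1.0]], v2=[[1e-12, 1e-12], [1.0, 1.0]])
        cl = cluster_ivw_mean([0, 1], r)
        res = individual_q(1, cl, r)
        assert res.q == pytest.approx(2.0, rel=1e-6)
        assert res.p_value == pytest.approx(math.exp(-1), rel=1e-5)

    def test_contributions_sum_to_cluster_q(self, rng):
        r = random_ratios(rng, J=6, P=2, rho=OutcomeCorrelation.exchangeable(2, 0.3))
        members = [0, 1, 2, 3, 4, 5]
        cl = cluster_ivw_mean(members, r)
        total = sum(individual_q(j, cl, r).q for j in members)
        assert total == pytest.approx(cochran_q(members, r).q, rel=1e-10)

    def test_non_member_rejected(self, rng):
        r = random_ratios(rng)
        cl = cluster_ivw_mean([0, 1], r)
        with pytest.raises(ValueError):
            individual_q(5, cl, r)


class TestDownwardTesting:
    def test_homogeneous_data_selects_one_cluster(self, rng):
        beta = 0.3 + 0.001 * rng.normal(size=(10, 2))
        r = make_ratios(beta, v2=np.full((10, 2), 0.04))
        sel = downward_testing(build_merge_path(r), r, n=1e5)
        assert sel.selected_level == 1
        assert sel.n_clusters == 1

    def test_two_separated_groups(self, rng):
        beta = np.r_[np.zeros(6), np.full(6, 5.0)][:, None] + 0.01 * rng.normal(size=(12, 1))
        r = make_ratios(beta, v2=np.full((12, 1), 0.01))
        sel = downward_testing(build_merge_path(r), r, n=1e5)
        assert sel.selected_level == 2
        assert sorted(map(sorted, sel.partition)) == [list(range(6)), list(range(6, 12))]

    def test_three_groups_with_singleton(self, figure2_toy):
        r = compute_ratio_estimates(figure2_toy)
        sel = downward_testing(build_merge_path(r), r, n=math.e**10)
        assert sel.selected_level == 3
        assert sorted(map(sorted, sel.partition)) == [[0, 1], [2, 3, 4], [5]]
        assert all(q.passes for q in sel.per_cluster_q)

    def test_requires_threshold(self, rng):
        r = random_ratios(rng)
        with pytest.raises(ValueError):
            downward_testing(build_merge_path(r), r)


class TestOutlierRemoval:
    def test_no_outliers_matches_plain_selection(self, rng):
        beta = 0.2 + 0.001 * rng.normal(size=(8, 2))
        r = make_ratios(beta, v2=np.full((8, 2), 0.04))
        robust = iterate_outlier_removal(r, n=1e5)
        plain = downward_testing(build_merge_path(r), r, n=1e5)
        assert robust.iterations == 1
        assert robust.outliers_removed == set()
        assert sorted(map(sorted, robust.partition)) == sorted(map(sorted, plain.partition))

    def test_displaced_variant_is_junked(self, rng):
        beta = 0.5 + 0.02 * rng.normal(size=(15, 1))
        beta[7] += 10 * 0.2  # 10 SDs away from the rest
        r = make_ratios(beta, v2=np.full((15, 1), 0.04))
        sel = iterate_outlier_removal(r, n=1e5)
        assert 7 in sel.outliers_removed
        assert sel.n_clusters == 1
        assert sorted(sel.partition[0]) == [j for j in range(15) if j != 7]

    def test_final_clusters_free_of_outliers(self, rng):
        r = random_ratios(rng, J=20, P=2)
        sel = iterate_outlier_removal(r, n=1e5, min_cluster_size=1)
        for members in sel.partition:
            cl = cluster_ivw_mean(members, r)
            for j in members:
                if len(members) > 1:
                    assert individual_q(j, cl, r).p_value >= 0.05

    def test_idempotent_on_own_output(self, rng):
        beta = np.r_[np.zeros(10), np.full(10, 3.0)][:, None] + 0.05 * rng.normal(size=(20, 1))
        r = make_ratios(beta, v2=np.full((20, 1), 0.01))
        first = iterate_outlier_removal(r, n=1e5)
        kept = sorted(set(range(20)) - first.outliers_removed)
        again = iterate_outlier_removal(r.subset(kept), n=1e5)
        assert again.outliers_removed == set()
        relabeled = sorted(
            sorted(kept[j] for j in members) for members in again.partition
        )
        assert relabeled == sorted(map(sorted, first.partition))

    def test_small_clusters_reassigned_to_junk(self):
        # two tight groups of 5 and one isolated pair: with min_cluster_size=4
        # the pair is junked, with 1 it is kept as a cluster
        beta = np.r_[np.zeros(5), np.full(5, 4.0), [10.0, 10.01]][:, None]
        r = make_ratios(beta, v2=np.full((12, 1), 0.01))
        strictly = iterate_outlier_removal(r, n=1e5, min_cluster_size=4)
        assert strictly.n_clusters == 2
        assert strictly.outliers_removed == {10, 11}
        lenient = iterate_outlier_removal(r, n=1e5, min_cluster_size=1)
        assert lenient.n_clusters == 3
        assert lenient.outliers_removed == set()
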