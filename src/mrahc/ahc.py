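"""Ward-style agglomerative merge path on inverse-variance weighted ratio estimates.

Starting from J singleton clusters, the two clusters with the smallest
weighted squared Euclidean distance are merged repeatedly until one
super-cluster remains.  The distance between clusters S_k and S_l is the
Wald statistic for equality of their cluster-specific causal effects,

    D(S_k, S_l) = d' Omega^{-1} d,     d = beta_IVW(S_k) - beta_IVW(S_l),

where beta_IVW(S) is the per-outcome inverse-variance weighted mean of the
member ratio estimates, and Omega is the covariance of the difference of the
two IVW means.  With per-outcome weight sums W_Sp = sum_{j in S} w_jp and
outcome correlation rho, the (i, r) entry of Omega is

    rho_ir / (W_ki W_kr) * sum_{j in S_k} sqrt(w_ji w_jr)
  + rho_ir / (W_li W_lr) * sum_{j in S_l} sqrt(w_ji w_jr)

(note sqrt(w_ji w_jr) = gamma_hat_j^2 / (se_ji se_jr)).  Its diagonal equals
1/W_ki + 1/W_li, the usual sum of IVW variances, which is asserted at run
time.  Merging the closest pair therefore merges the two clusters whose
effects are hardest to distinguish statistically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .summary_data import OutcomeCorrelation, RatioEstimateSet

__all__ = ["Cluster", "MergePath", "cluster_ivw_mean", "pairwise_distance", "build_merge_path"]

#: Relative tolerance within which two candidate merge distances count as tied.
TIE_RTOL = 1e-12

#: Condition number beyond which Omega is treated as numerically singular.
_COND_MAX = 1e12


@dataclass(frozen=True)
class Cluster:
    """A cluster of variants with its IVW summary statistics.

    ``ivw_mean[p]`` is the inverse-variance weighted mean of the member ratio
    estimates for outcome p; ``weight_sums[p]`` is the corresponding weight
    total W_Sp (so the IVW variance is 1/W_Sp).  ``cross_weight`` holds the
    P x P matrix with entries sum_j sqrt(w_ji w_jr), needed for the
    off-diagonal covariance terms under correlated outcomes.
    """

    member_indices: frozenset[int]
    ivw_mean: np.ndarray
    weight_sums: np.ndarray
    cross_weight: np.ndarray

    @property
    def size(self) -> int:
        return len(self.member_indices)


def cluster_ivw_mean(members: Sequence[int] | frozenset[int], ratios: RatioEstimateSet) -> Cluster:
    """Build the :class:`Cluster` summary for a set of variant indices."""
    idx = np.asarray(sorted(members), dtype=int)
    if idx.size == 0:
        raise ValueError("cluster must contain at least one variant")
    w = ratios.weights[idx]  # (m, P)
    sw = np.sqrt(w)
    W = w.sum(axis=0)
    mean = (ratios.beta_hat[idx] * w).sum(axis=0) / W
    cross = sw.T @ sw  # (P, P) with [i, r] = sum_j sqrt(w_ji w_jr)
    return Cluster(
        member_indices=frozenset(int(i) for i in idx),
        ivw_mean=mean,
        weight_sums=W,
        cross_weight=cross,
    )


def _omega(k: Cluster, l: Cluster, rho: np.ndarray) -> np.ndarray:
    Wk = k.weight_sums
    Wl = l.weight_sums
    om = rho * (k.cross_weight / np.outer(Wk, Wk) + l.cross_weight / np.outer(Wl, Wl))
    # Diagonal identity: both cross_weight diagonals are the weight sums.
    expected = 1.0 / Wk + 1.0 / Wl
    if not np.allclose(np.diag(om), expected, rtol=1e-8):
        raise AssertionError("Omega diagonal does not equal the sum of IVW variances")
    return om


def pairwise_distance(
    k: Cluster, l: Cluster, ratios: RatioEstimateSet, rho: OutcomeCorrelation | None = None
) -> float:
    """Weighted squared Euclidean (Wald) distance between two disjoint clusters."""
    if k.member_indices & l.member_indices:
        raise ValueError("clusters must be disjoint")
    if rho is None:
        rho = ratios.rho
    om = _omega(k, l, rho.rho)
    cond = np.linalg.cond(om)
    if not np.isfinite(cond) or cond > _COND_MAX:
        raise np.linalg.LinAlgError(
            f"singular between-cluster covariance Omega (condition number {cond:.3e})"
        )
    d = k.ivw_mean - l.ivw_mean
    return float(d @ np.linalg.solve(om, d))


@dataclass
class MergePath:
    """The full merge sequence from J singletons down to one cluster.

    ``merges[f]`` records the f-th merge as
    ``(level, (cluster_id_a, cluster_id_b), new_cluster_id, distance)``;
    ``partitions[K]`` gives the partition with exactly K clusters as a list
    of sorted member-index lists (keys J down to 1).
    """

    merges: list[tuple[int, tuple[int, int], int, float]]
    partitions: dict[int, list[list[int]]]
    n_variants: int

    def partition_at(self, k: int) -> list[list[int]]:
        return self.partitions[k]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_variants": self.n_variants,
                "merges": [
                    {"level": f, "pair": list(pair), "new_id": nid, "distance": d}
                    for f, pair, nid, d in self.merges
                ],
            },
            indent=2,
        )

    def to_table(self):
        """Dendrogram table: one row per (level, cluster)."""
        import pandas as pd

        rows = []
        dist_by_level = {self.n_variants - f: d for f, _, _, d in self.merges}
        for k in sorted(self.partitions, reverse=True):
            for cid, members in enumerate(self.partitions[k]):
                rows.append(
                    {
                        "n_clusters": k,
                        "cluster_id": cid,
                        "members": ",".join(map(str, members)),
                        "merge_distance": dist_by_level.get(k, np.nan),
                    }
                )
        return pd.DataFrame(rows)


def build_merge_path(
    ratios: RatioEstimateSet, rho: OutcomeCorrelation | None = None
) -> MergePath:
    """Run the agglomerative merging step and return the full path.

    Distances between untouched clusters do not change across merges, so a
    running distance matrix is kept and only the merged cluster's row is
    recomputed (batched P x P solves).  Ties within relative tolerance
    ``TIE_RTOL`` are broken toward the pair whose member-index union has the
    smallest (min, max) — a platform-independent deterministic rule.
    """
    J = ratios.n_variants
    if J < 2:
        raise ValueError("at least two variants are required for clustering")
    if rho is None:
        rho = ratios.rho
    rho_m = rho.rho

    w = ratios.weights  # (J, P)
    sw = np.sqrt(w)
    # Per-cluster running summaries, indexed by position in the active list.
    A = sw[:, :, None] * sw[:, None, :]  # cross-weight matrices (K, P, P)
    W = w.copy()  # weight sums (K, P)
    S = ratios.beta_hat * w  # weighted sums (K, P)
    members: list[list[int]] = [[j] for j in range(J)]
    ids = list(range(J))
    next_id = J

    def dists_from(a_new, W_new, S_new):
        """Distances from one cluster summary to every active cluster."""
        om = rho_m[None] * (
            (a_new / np.outer(W_new, W_new))[None] + A / (W[:, :, None] * W[:, None, :])
        )
        diag = np.einsum("kpp->kp", om)
        if not np.allclose(diag, 1.0 / W_new[None, :] + 1.0 / W, rtol=1e-8):
            raise AssertionError("Omega diagonal does not equal the sum of IVW variances")
        d = (S_new / W_new)[None, :] - S / W
        try:
            sol = np.linalg.solve(om, d[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular between-cluster covariance Omega "
                f"(max condition number {np.max(np.linalg.cond(om)):.3e})"
            ) from err
        return np.einsum("kp,kp->k", d, sol)

    # Full initial distance matrix (rows computed in batch).
    D = np.full((J, J), np.inf)
    for i in range(J):
        row = dists_from(A[i], W[i], S[i])
        D[i] = row
        D[i, i] = np.inf

    merges: list[tuple[int, tuple[int, int], int, float]] = []
    partitions: dict[int, list[list[int]]] = {J: [list(m) for m in members]}

    for step in range(1, J):
        dmin = D.min()
        tol = TIE_RTOL * max(1.0, abs(dmin))
        ti, tj = np.nonzero(D <= dmin + tol)
        cand = [(int(a), int(b)) for a, b in zip(ti, tj) if a < b]
        a, b = min(
            cand,
            key=lambda ab: (
                min(members[ab[0]] + members[ab[1]]),
                max(members[ab[0]] + members[ab[1]]),
            ),
        )

        a_new = A[a] + A[b]
        w_new = W[a] + W[b]
        s_new = S[a] + S[b]
        m_new = sorted(members[a] + members[b])
        id_a, id_b = ids[a], ids[b]

        keep = [k for k in range(len(ids)) if k not in (a, b)]
        A = np.concatenate([A[keep], a_new[None]], axis=0)
        W = np.concatenate([W[keep], w_new[None]], axis=0)
        S = np.concatenate([S[keep], s_new[None]], axis=0)
        members = [members[k] for k in keep] + [m_new]
        ids = [ids[k] for k in keep] + [next_id]

        D = D[np.ix_(keep, keep)]
        if keep:
            new_row = dists_from(A[-1], W[-1], S[-1])[:-1]
            D = np.pad(D, ((0, 1), (0, 1)), constant_values=np.inf)
            D[-1, :-1] = new_row
            D[:-1, -1] = new_row
        else:
            D = np.full((1, 1), np.inf)

        merges.append((step, (id_a, id_b), next_id, float(dmin)))
        partitions[J - step] = [list(m) for m in members]
        next_id += 1

    return MergePath(merges=merges, partitions=partitions, n_variants=J)
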