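"""Downward testing along the merge path and iterated outlier removal.

The merge path is retraced from the single super-cluster toward singletons.
Each cluster's heterogeneity is assessed with a multi-outcome Cochran Q
statistic: a cluster whose Q falls below its threshold is accepted, a
rejecting cluster is split into the two subclusters it was merged from and
the test recurses.  The threshold p-value is zeta = 0.1 / ln(n), which
shrinks slowly with the sample size n and yields a consistent selection
procedure; the number of accepted clusters is K_opt.

Because the Q covariance matrix Phi is block-diagonal across outcome pairs
with diagonal blocks per variant, the quadratic form decomposes exactly into
per-variant contributions:

    Q(S) = sum_{j in S} (beta_j - beta_IVW)' Sigma_j^{-1} (beta_j - beta_IVW),

where Sigma_j is variant j's P x P ratio covariance.  A single variant's
term, with the cluster mean held fixed, is its individual Q statistic; it is
approximately chi-squared with P degrees of freedom, and members with an
individual-Q p-value below 5% are treated as outliers.  Outliers are removed
and the whole procedure (path building + downward testing) reruns on the
remaining variants until no outlier is flagged; everything removed ends up
in the junk cluster.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ahc import Cluster, MergePath, build_merge_path, cluster_ivw_mean
from .summary_data import OutcomeCorrelation, RatioEstimateSet

logger = logging.getLogger(__name__)

__all__ = [
    "QResult",
    "SelectionResult",
    "zeta_threshold",
    "cochran_q",
    "individual_q",
    "downward_testing",
    "iterate_outlier_removal",
    "DEFAULT_OUTLIER_P",
    "DEFAULT_MAX_ITER",
    "DEFAULT_MIN_CLUSTER_SIZE",
]

DEFAULT_OUTLIER_P = 0.05
DEFAULT_MAX_ITER = 25
#: Detected clusters smaller than this are reassigned to the junk cluster
#: after the outlier loop: a handful of stray variants that happen to sit
#: together is weak evidence of a distinct causal pathway, and cluster-specific
#: IVW estimation with so few instruments is unreliable anyway.
DEFAULT_MIN_CLUSTER_SIZE = 6


@dataclass(frozen=True)
class QResult:
    """A Cochran Q test for one cluster (or one variant).

    ``threshold`` is the (1 - zeta) chi-squared quantile on ``df`` degrees of
    freedom; the cluster passes when ``q < threshold``.  Singletons have
    q = 0, df = 0 and pass by convention.
    """

    q: float
    df: int
    p_value: float
    threshold: float

    @property
    def passes(self) -> bool:
        return self.df == 0 or self.q < self.threshold


@dataclass
class SelectionResult:
    """Final partition after downward testing (and optional outlier loop)."""

    partition: list[list[int]]
    selected_level: int
    per_cluster_q: list[QResult]
    outliers_removed: set[int]
    iterations: int
    zeta: float

    @property
    def n_clusters(self) -> int:
        return len(self.partition)

    def labels(self, n_variants: int) -> np.ndarray:
        """Per-variant cluster labels; junk (removed) variants get -1."""
        lab = np.full(n_variants, -1, dtype=int)
        for cid, members in enumerate(self.partition):
            lab[members] = cid
        return lab

    def to_frame(self, ratios: RatioEstimateSet, rho: OutcomeCorrelation | None = None) -> pd.DataFrame:
        """Per-variant assignment table with individual Q diagnostics."""
        rho = rho or ratios.rho
        n = ratios.n_variants
        lab = self.labels(n)
        iq = np.full(n, np.nan)
        ip = np.full(n, np.nan)
        for members in self.partition:
            cl = cluster_ivw_mean(members, ratios)
            for j in members:
                r = individual_q(j, cl, ratios, rho)
                iq[j], ip[j] = r.q, r.p_value
        return pd.DataFrame(
            {
                "variant_id": ratios.variant_ids,
                "cluster_id": lab,
                "individual_q": iq,
                "individual_p": ip,
                "is_junk": lab == -1,
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected_level": self.selected_level,
                "n_clusters": self.n_clusters,
                "zeta": self.zeta,
                "iterations": self.iterations,
                "partition": self.partition,
                "outliers_removed": sorted(self.outliers_removed),
                "per_cluster_q": [
                    {"q": r.q, "df": r.df, "p_value": r.p_value, "threshold": r.threshold}
                    for r in self.per_cluster_q
                ],
            },
            indent=2,
        )


def zeta_threshold(n: float) -> float:
    """Threshold p-value zeta = 0.1 / ln(n) for the Q and Wald tests.

    Natural logarithm; n should comfortably exceed e so that zeta < 0.1.
    """
    if n <= 1:
        raise ValueError("sample size n must exceed 1")
    zeta = 0.1 / math.log(n)
    if zeta >= 1:
        raise ValueError(f"n={n} gives a threshold p-value >= 1; supply a larger sample size")
    return zeta


def _deviation_q(dev: np.ndarray, prec: np.ndarray) -> float:
    """Quadratic form sum_j dev_j' prec_j dev_j for stacked (m, P) deviations."""
    return float(np.einsum("jp,jpq,jq->", dev, prec, dev))


def cochran_q(
    members,
    ratios: RatioEstimateSet,
    rho: OutcomeCorrelation | None = None,
    zeta: float = 0.05,
) -> QResult:
    """Multi-outcome Cochran Q statistic for one cluster.

    Deviations of each member's ratio-estimate vector from the cluster's
    per-outcome IVW mean are combined in a quadratic form weighted by the
    inverse per-variant covariances.  df = P * (|S| - 1); for P = 1 this is
    the classic Cochran statistic  sum_j w_j (beta_j - beta_IVW)^2.
    """
    idx = np.asarray(sorted(members), dtype=int)
    if idx.size == 0:
        raise ValueError("cluster must contain at least one variant")
    rho = rho or ratios.rho
    p = ratios.n_outcomes
    df = p * (idx.size - 1)
    if idx.size == 1:
        return QResult(q=0.0, df=0, p_value=1.0, threshold=0.0)
    cl = cluster_ivw_mean(idx, ratios)
    dev = ratios.beta_hat[idx] - cl.ivw_mean[None, :]
    rho_inv = np.linalg.inv(rho.rho)
    if not np.all(np.isfinite(rho_inv)):
        raise np.linalg.LinAlgError("singular Phi: outcome correlation matrix is not invertible")
    s = np.sqrt(ratios.weights[idx])
    prec = rho_inv[None, :, :] * s[:, :, None] * s[:, None, :]
    q = _deviation_q(dev, prec)
    return QResult(
        q=q,
        df=df,
        p_value=float(stats.chi2.sf(q, df)),
        threshold=float(stats.chi2.ppf(1 - zeta, df)),
    )


def individual_q(
    variant_index: int,
    cluster: Cluster,
    ratios: RatioEstimateSet,
    rho: OutcomeCorrelation | None = None,
) -> QResult:
    """One variant's contribution to its cluster's Q, against chi2(P).

    The cluster IVW mean is held fixed, so the contributions of all members
    sum to the cluster Q statistic.
    """
    if variant_index not in cluster.member_indices:
        raise ValueError(f"variant {variant_index} is not a member of the cluster")
    rho = rho or ratios.rho
    p = ratios.n_outcomes
    dev = ratios.beta_hat[variant_index] - cluster.ivw_mean
    rho_inv = np.linalg.inv(rho.rho)
    s = np.sqrt(ratios.weights[variant_index])
    prec = rho_inv * np.outer(s, s)
    q = float(dev @ prec @ dev)
    return QResult(
        q=q,
        df=p,
        p_value=float(stats.chi2.sf(q, p)),
        threshold=float(stats.chi2.ppf(0.95, p)),
    )


def downward_testing(
    path: MergePath,
    ratios: RatioEstimateSet,
    rho: OutcomeCorrelation | None = None,
    n: float | None = None,
    zeta: float | None = None,
) -> SelectionResult:
    """Retrace the merge path from the single super-cluster toward singletons.

    Either the sample size ``n`` (from which zeta = 0.1/ln(n)) or an explicit
    ``zeta`` must be supplied.

    The descent is recursive on the dendrogram: a cluster whose Q statistic
    falls below its threshold is accepted and frozen; a rejecting cluster is
    split into the two subclusters it was merged from and each is tested in
    turn.  Singletons pass by convention, so the recursion terminates.  (The
    alternative reading — testing every cluster of a common dendrogram level
    and stopping at the first level where all pass — splits already-passing
    clusters as a side effect whenever a few outlying variants deep in one
    branch force further descent, which fragments genuine clusters and
    destroys selection consistency as precision grows; the recursive reading
    does not.)
    """
    if zeta is None:
        if n is None:
            raise ValueError("supply either n or zeta")
        zeta = zeta_threshold(n)
    rho = rho or ratios.rho
    J = path.n_variants
    p = ratios.n_outcomes
    rho_inv = np.linalg.inv(rho.rho)
    s = np.sqrt(ratios.weights)
    prec = rho_inv[None, :, :] * s[:, :, None] * s[:, None, :]  # (J, P, P)

    # chi2 thresholds for all possible dfs, computed lazily.
    thresh_cache: dict[int, float] = {}

    def threshold(df: int) -> float:
        if df not in thresh_cache:
            thresh_cache[df] = float(stats.chi2.ppf(1 - zeta, df))
        return thresh_cache[df]

    def q_test(idx: np.ndarray) -> QResult:
        if idx.size == 1:
            return QResult(q=0.0, df=0, p_value=1.0, threshold=0.0)
        w = ratios.weights[idx]
        mean = (ratios.beta_hat[idx] * w).sum(axis=0) / w.sum(axis=0)
        dev = ratios.beta_hat[idx] - mean[None, :]
        q = _deviation_q(dev, prec[idx])
        df = p * (idx.size - 1)
        return QResult(
            q=q, df=df, p_value=float(stats.chi2.sf(q, df)), threshold=threshold(df)
        )

    children = {new_id: pair for _, pair, new_id, _ in path.merges}
    members_of: dict[int, list[int]] = {j: [j] for j in range(J)}
    for _, (a, b), new_id, _ in path.merges:
        members_of[new_id] = members_of[a] + members_of[b]
    root = path.merges[-1][2]

    accepted: list[tuple[list[int], QResult]] = []
    stack = [root]
    while stack:
        node = stack.pop()
        idx = np.asarray(sorted(members_of[node]), dtype=int)
        res = q_test(idx)
        logger.debug(
            "downward testing node %d (size %d): Q=%.3f vs T=%.3f",
            node,
            idx.size,
            res.q,
            res.threshold,
        )
        if res.passes:
            accepted.append((idx.tolist(), res))
        else:
            stack.extend(children[node])
    accepted.sort(key=lambda item: item[0][0])
    return SelectionResult(
        partition=[m for m, _ in accepted],
        selected_level=len(accepted),
        per_cluster_q=[r for _, r in accepted],
        outliers_removed=set(),
        iterations=1,
        zeta=zeta,
    )


def iterate_outlier_removal(
    ratios: RatioEstimateSet,
    rho: OutcomeCorrelation | None = None,
    n: float | None = None,
    zeta: float | None = None,
    outlier_p: float = DEFAULT_OUTLIER_P,
    max_iter: int = DEFAULT_MAX_ITER,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> SelectionResult:
    """Outlier-robust selection: cluster, flag individual-Q outliers, rerun.

    Each round builds the merge path on the remaining variants, selects a
    partition by downward testing, and flags every member whose individual-Q
    p-value falls below ``outlier_p``.  Flagged variants are removed and the
    round repeats until none is flagged (or ``max_iter`` rounds).  Removed
    variants form the junk cluster; indices in the returned result refer to
    the original variant ordering.

    After convergence, detected clusters with fewer than ``min_cluster_size``
    members are reassigned to the junk cluster as well (set
    ``min_cluster_size=1`` to keep every cluster, however small).
    """
    if ratios.n_variants < 2:
        raise ValueError("at least two variants are required")
    rho = rho or ratios.rho
    active = np.arange(ratios.n_variants)
    removed: set[int] = set()

    last: SelectionResult | None = None
    for it in range(1, max_iter + 1):
        if active.size < 2:
            raise RuntimeError("no non-junk variants remain after outlier removal")
        sub = ratios.subset(active)
        path = build_merge_path(sub, rho)
        sel = downward_testing(path, sub, rho, n=n, zeta=zeta)
        outliers_local: list[int] = []
        for members in sel.partition:
            if len(members) == 1:
                continue
            cl = cluster_ivw_mean(members, sub)
            dev = sub.beta_hat[members] - cl.ivw_mean[None, :]
            rho_inv = np.linalg.inv(rho.rho)
            s = np.sqrt(sub.weights[members])
            prec = rho_inv[None, :, :] * s[:, :, None] * s[:, None, :]
            qs = np.einsum("jp,jpq,jq->j", dev, prec, dev)
            ps = stats.chi2.sf(qs, sub.n_outcomes)
            outliers_local.extend(int(members[i]) for i in np.flatnonzero(ps < outlier_p))
        last = SelectionResult(
            partition=[[int(active[j]) for j in members] for members in sel.partition],
            selected_level=sel.selected_level,
            per_cluster_q=sel.per_cluster_q,
            outliers_removed=set(removed),
            iterations=it,
            zeta=sel.zeta,
        )
        if not outliers_local:
            return _junk_small_clusters(last, min_cluster_size)
        removed.update(int(active[j]) for j in outliers_local)
        mask = np.ones(active.size, dtype=bool)
        mask[outliers_local] = False
        active = active[mask]
    logger.warning("outlier removal hit max_iter=%d before converging", max_iter)
    assert last is not None
    last.outliers_removed = set(removed)
    return _junk_small_clusters(last, min_cluster_size)


def _junk_small_clusters(sel: SelectionResult, min_size: int) -> SelectionResult:
    """Reassign clusters smaller than ``min_size`` to the junk cluster."""
    if min_size <= 1:
        return sel
    keep = [i for i, m in enumerate(sel.partition) if len(m) >= min_size]
    if not keep or len(keep) == len(sel.partition):
        if not keep:
            logger.warning(
                "all %d detected clusters fall below min_cluster_size=%d; keeping them",
                len(sel.partition),
                min_size,
            )
        return sel
    junked = {j for i, m in enumerate(sel.partition) if i not in keep for j in m}
    sel.partition = [sel.partition[i] for i in keep]
    sel.per_cluster_q = [sel.per_cluster_q[i] for i in keep]
    sel.outliers_removed = sel.outliers_removed | junked
    return sel
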