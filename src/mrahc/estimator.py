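"""Scikit-learn style front end for the full clustering pipeline."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .post_inference import assemble_report, estimate_clusters, test_null_cluster
from .selection import (
    DEFAULT_MAX_ITER,
    DEFAULT_MIN_CLUSTER_SIZE,
    DEFAULT_OUTLIER_P,
    downward_testing,
    iterate_outlier_removal,
    zeta_threshold,
)
from .ahc import build_merge_path
from .summary_data import (
    OutcomeCorrelation,
    RatioEstimateSet,
    compute_ratio_estimates,
    harmonize_orientation,
    variants_from_frame,
)

__all__ = ["MRAHC"]


class MRAHC(BaseEstimator, ClusterMixin):
    """Agglomerative clustering of genetic variants in summary-data MR.

    Groups variants by the similarity of their ratio (variant-specific
    causal) estimates using Ward-style merging under a Wald distance,
    selects the number of clusters by downward Cochran-Q testing at the
    threshold p-value zeta = 0.1/ln(n), and (optionally) iterates
    individual-Q outlier removal, sending outliers to a junk cluster.

    Parameters
    ----------
    n : float, optional
        Sample size driving the selection threshold (use the smallest
        outcome sample, or an effective sample size for binary outcomes).
        Exactly one of ``n`` and ``zeta`` must be set by fit time.
    zeta : float, optional
        Explicit threshold p-value, overriding ``n``.
    rho : array-like (P, P) or OutcomeCorrelation, optional
        Outcome correlation matrix; identity (uncorrelated) by default.
    robust : bool, default True
        Run the iterated outlier-removal extension.
    outlier_p : float, default 0.05
        Individual-Q p-value below which a cluster member is an outlier.
    max_iter : int, default 25
        Cap on outlier-removal rounds.
    min_cluster_size : int, default 4
        Detected clusters smaller than this are reassigned to the junk
        cluster (robust mode only); set to 1 to keep every cluster.

    Attributes
    ----------
    labels_ : ndarray (J,)
        Cluster label per variant; junk variants get -1.
    n_clusters_ : int
        Number of substantive clusters detected.
    selection_ : SelectionResult
        Partition, per-cluster Q statistics and outlier bookkeeping.
    estimates_ : list of ClusterEstimate
        Per-cluster IVW effects with null labels and I^2 diagnostics.
    merge_path_ : MergePath
        The dendrogram built on the variants kept in the final round.
    report_ : dict
        Machine-readable run summary.

    Examples
    --------
    >>> from mrahc.simulate import design_by_name, generate_dataset
    >>> variants, truth = generate_dataset(design_by_name("P2_K4_rho0"))
    >>> model = MRAHC(n=1e5).fit(variants)
    >>> model.n_clusters_  # doctest: +SKIP
    4
    """

    def __init__(
        self,
        n: float | None = None,
        zeta: float | None = None,
        rho=None,
        robust: bool = True,
        outlier_p: float = DEFAULT_OUTLIER_P,
        max_iter: int = DEFAULT_MAX_ITER,
        min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    ):
        self.n = n
        self.zeta = zeta
        self.rho = rho
        self.robust = robust
        self.outlier_p = outlier_p
        self.max_iter = max_iter
        self.min_cluster_size = min_cluster_size

    # ------------------------------------------------------------------
    def _resolve_rho(self, p: int) -> OutcomeCorrelation:
        if self.rho is None:
            return OutcomeCorrelation.identity(p)
        if isinstance(self.rho, OutcomeCorrelation):
            return self.rho
        return OutcomeCorrelation(np.asarray(self.rho, dtype=float))

    def _as_ratios(self, X) -> RatioEstimateSet:
        if isinstance(X, RatioEstimateSet):
            return X
        if isinstance(X, pd.DataFrame):
            variants = variants_from_frame(X)
        elif isinstance(X, (list, tuple)):
            variants = list(X)
        else:
            raise TypeError(
                "X must be a RatioEstimateSet, a list of VariantSummary, or a wide "
                "summary-statistics DataFrame"
            )
        variants = harmonize_orientation(variants)
        return compute_ratio_estimates(variants, self._resolve_rho(variants[0].n_outcomes))

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        """Cluster the variants.

        ``X`` may be a :class:`RatioEstimateSet`, a list of
        :class:`VariantSummary`, or a wide DataFrame with columns ``SNP``,
        ``gamma_hat``, ``se_gamma``, ``Gamma_hat_p`` / ``se_Gamma_p``.
        """
        if self.n is None and self.zeta is None:
            raise ValueError("set either n (sample size) or zeta (threshold p-value)")
        ratios = self._as_ratios(X)
        rho = ratios.rho
        zeta = self.zeta if self.zeta is not None else zeta_threshold(self.n)

        if self.robust:
            selection = iterate_outlier_removal(
                ratios,
                rho,
                zeta=zeta,
                outlier_p=self.outlier_p,
                max_iter=self.max_iter,
                min_cluster_size=self.min_cluster_size,
            )
            kept = sorted(set(range(ratios.n_variants)) - selection.outliers_removed)
            self.merge_path_ = build_merge_path(ratios.subset(kept), rho)
        else:
            self.merge_path_ = build_merge_path(ratios, rho)
            selection = downward_testing(self.merge_path_, ratios, rho, zeta=zeta)

        estimates = estimate_clusters(selection, ratios, rho)
        for e in estimates:
            test_null_cluster(e, ratios, zeta=zeta, rho=rho)

        self.ratios_ = ratios
        self.zeta_ = zeta
        self.selection_ = selection
        self.estimates_ = estimates
        self.labels_ = selection.labels(ratios.n_variants)
        self.n_clusters_ = selection.n_clusters
        self.report_ = assemble_report(
            selection,
            estimates,
            ratios,
            config={
                "n": self.n,
                "zeta": zeta,
                "robust": self.robust,
                "outlier_p": self.outlier_p,
                "max_iter": self.max_iter,
                "min_cluster_size": self.min_cluster_size,
            },
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
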