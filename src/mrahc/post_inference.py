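"""Post-clustering inference: IVW effect estimates, null-cluster Wald tests,
heterogeneity diagnostics, and report assembly.

Each substantive cluster's causal effect per outcome is the inverse-variance
weighted mean of its members' ratio estimates, with standard error
(sum of weights)^{-1/2}.  A joint Wald test of the P-dimensional estimate
against zero, at the same zeta = 0.1/ln(n) level used for selection,
labels null clusters.  Within-cluster overdispersion is summarized by
I^2 = max(0, (Q - df)/Q); where it is non-zero, multiplicative
overdispersion-adjusted standard errors (se * sqrt(max(1, Q/df))) are
reported alongside as a diagnostic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ahc import cluster_ivw_mean
from .selection import QResult, SelectionResult, cochran_q, zeta_threshold
from .summary_data import OutcomeCorrelation, RatioEstimateSet

__all__ = ["ClusterEstimate", "estimate_clusters", "test_null_cluster", "assemble_report"]

_Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class ClusterEstimate:
    """Causal-effect estimate for one substantive cluster."""

    cluster_id: int
    members: list[int]
    estimate: np.ndarray  # (P,) IVW estimates
    se: np.ndarray  # (P,) = 1/sqrt(W_Sp)
    ci_low: np.ndarray
    ci_high: np.ndarray
    q: QResult
    i_squared: float
    wald_p: float = float("nan")  # joint test against zero
    wald_p_per_outcome: np.ndarray | None = None
    is_null: bool | None = None
    se_overdispersed: np.ndarray | None = None

    @property
    def n_variants(self) -> int:
        return len(self.members)

    def odds_ratios(self) -> dict[str, np.ndarray]:
        """Estimates and CI bounds on the odds-ratio scale (binary outcomes)."""
        return {
            "or": np.exp(self.estimate),
            "or_ci_low": np.exp(self.ci_low),
            "or_ci_high": np.exp(self.ci_high),
        }


def _ivw_cov(members: Sequence[int], ratios: RatioEstimateSet, rho: OutcomeCorrelation) -> np.ndarray:
    """P x P covariance of the cluster IVW estimate (the single-cluster term
    of the between-cluster distance covariance)."""
    cl = cluster_ivw_mean(members, ratios)
    W = cl.weight_sums
    return rho.rho * cl.cross_weight / np.outer(W, W)


def estimate_clusters(
    selection: SelectionResult,
    ratios: RatioEstimateSet,
    rho: OutcomeCorrelation | None = None,
) -> list[ClusterEstimate]:
    """IVW estimates with heterogeneity diagnostics for every cluster."""
    rho = rho or ratios.rho
    out: list[ClusterEstimate] = []
    for cid, members in enumerate(selection.partition):
        cl = cluster_ivw_mean(members, ratios)
        se = 1.0 / np.sqrt(cl.weight_sums)
        q = cochran_q(members, ratios, rho, zeta=selection.zeta)
        i2 = max(0.0, (q.q - q.df) / q.q) if q.q > 0 else 0.0
        z = cl.ivw_mean / se
        est = ClusterEstimate(
            cluster_id=cid,
            members=list(members),
            estimate=cl.ivw_mean,
            se=se,
            ci_low=cl.ivw_mean - _Z95 * se,
            ci_high=cl.ivw_mean + _Z95 * se,
            q=q,
            i_squared=i2,
            wald_p_per_outcome=2 * stats.norm.sf(np.abs(z)),
        )
        if q.df > 0:
            est.se_overdispersed = se * np.sqrt(max(1.0, q.q / q.df))
        out.append(est)
    return out


def test_null_cluster(
    est: ClusterEstimate,
    ratios: RatioEstimateSet,
    n: float | None = None,
    zeta: float | None = None,
    rho: OutcomeCorrelation | None = None,
) -> ClusterEstimate:
    """Joint Wald test of a zero causal-effect vector, at level zeta.

    The statistic  estimate' V^{-1} estimate  is compared against chi2(P),
    where V is the IVW covariance of the cluster estimate (diagonal 1/W_Sp,
    off-diagonals induced by the outcome correlation).  The cluster is
    labelled null when the test fails to reject.
    """
    if zeta is None:
        if n is None:
            raise ValueError("supply either n or zeta")
        zeta = zeta_threshold(n)
    rho = rho or ratios.rho
    V = _ivw_cov(est.members, ratios, rho)
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(f"singular IVW covariance (condition number {cond:.3e})")
    wald = float(est.estimate @ np.linalg.solve(V, est.estimate))
    p = ratios.n_outcomes
    est.wald_p = float(stats.chi2.sf(wald, p))
    est.is_null = est.wald_p >= zeta
    return est


test_null_cluster.__test__ = False  # not a pytest test, despite the name


def estimates_frame(estimates: Sequence[ClusterEstimate]) -> pd.DataFrame:
    """Long-format per-(cluster, outcome) estimate table."""
    rows = []
    for e in estimates:
        ors = e.odds_ratios()
        for p in range(len(e.estimate)):
            rows.append(
                {
                    "cluster_id": e.cluster_id,
                    "outcome": p + 1,
                    "n_variants": e.n_variants,
                    "estimate": e.estimate[p],
                    "se": e.se[p],
                    "ci_low": e.ci_low[p],
                    "ci_high": e.ci_high[p],
                    "or": ors["or"][p],
                    "or_ci_low": ors["or_ci_low"][p],
                    "or_ci_high": ors["or_ci_high"][p],
                    "se_overdispersed": (
                        e.se_overdispersed[p] if e.se_overdispersed is not None else np.nan
                    ),
                    "q": e.q.q,
                    "q_df": e.q.df,
                    "q_p": e.q.p_value,
                    "i_squared": e.i_squared,
                    "wald_p_joint": e.wald_p,
                    "wald_p_outcome": (
                        e.wald_p_per_outcome[p] if e.wald_p_per_outcome is not None else np.nan
                    ),
                    "is_null": e.is_null,
                }
            )
    return pd.DataFrame(rows)


def assemble_report(
    selection: SelectionResult,
    estimates: Sequence[ClusterEstimate],
    ratios: RatioEstimateSet,
    config: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Machine-readable summary of a full run.

    Contains the selected partition, per-cluster estimates on both the raw
    and odds-ratio scales, heterogeneity and null/junk labels, the
    thresholds used, package version, and a hash of the input ratio
    estimates for provenance.
    """
    from . import __version__

    digest = hashlib.sha256(
        np.ascontiguousarray(ratios.beta_hat).tobytes()
        + np.ascontiguousarray(ratios.v2).tobytes()
    ).hexdigest()
    clusters = []
    for e in estimates:
        ors = e.odds_ratios()
        clusters.append(
            {
                "cluster_id": e.cluster_id,
                "n_variants": e.n_variants,
                "variant_ids": [ratios.variant_ids[j] for j in e.members],
                "estimate": e.estimate.tolist(),
                "se": e.se.tolist(),
                "ci_low": e.ci_low.tolist(),
                "ci_high": e.ci_high.tolist(),
                "odds_ratio": ors["or"].tolist(),
                "odds_ratio_ci": [ors["or_ci_low"].tolist(), ors["or_ci_high"].tolist()],
                "q": e.q.q,
                "q_df": e.q.df,
                "q_p_value": e.q.p_value,
                "i_squared": e.i_squared,
                "wald_p_joint": e.wald_p,
                "wald_p_per_outcome": (
                    e.wald_p_per_outcome.tolist() if e.wald_p_per_outcome is not None else None
                ),
                "is_null": e.is_null,
            }
        )
    junk_ids = sorted(selection.outliers_removed)
    report = {
        "k_opt": selection.n_clusters,
        "n_variants": ratios.n_variants,
        "n_outcomes": ratios.n_outcomes,
        "zeta": selection.zeta,
        "iterations": selection.iterations,
        "clusters": clusters,
        "junk_cluster": {
            "n_variants": len(junk_ids),
            "variant_ids": [ratios.variant_ids[j] for j in junk_ids],
        },
        "version": __version__,
        "input_sha256": digest,
        "config": config or {},
    }
    return report


def report_text(report: dict[str, Any]) -> str:
    """Human-readable rendering of :func:`assemble_report` output."""
    lines = [
        f"MR-AHC report (v{report['version']})",
        f"  variants: {report['n_variants']}   outcomes: {report['n_outcomes']}",
        f"  threshold p-value zeta: {report['zeta']:.5g}   outlier iterations: {report['iterations']}",
        f"  substantive clusters: {report['k_opt']}   junk variants: {report['junk_cluster']['n_variants']}",
    ]
    for c in report["clusters"]:
        flags = []
        if c["is_null"]:
            flags.append("NULL")
        if c["i_squared"] > 0:
            flags.append(f"I2={c['i_squared']:.2f}")
        est = ", ".join(
            f"{e:+.3f} (se {s:.3f})" for e, s in zip(c["estimate"], c["se"])
        )
        lines.append(
            f"  cluster {c['cluster_id']}: {c['n_variants']} variants; estimates [{est}]"
            + (f"  [{' ,'.join(flags)}]" if flags else "")
        )
    return "\n".join(lines)


def to_json(report: dict[str, Any]) -> str:
    return json.dumps(report, indent=2)
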