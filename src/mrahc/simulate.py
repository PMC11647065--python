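"""Monte Carlo generator and evaluation harness for multi-outcome MR clustering.

Datasets are simulated directly at the summary-statistic (reduced-form)
level: each variant j has a true instrument strength gamma_j and a true
ratio-effect vector beta_j (shared by its cluster, or idiosyncratic for junk
variants), so its outcome associations are Gamma_jp = beta_jp * gamma_j.
Observed statistics add Gaussian GWAS noise:

    gamma_hat_j  ~ N(gamma_j, se_gamma^2)
    Gamma_hat_j. ~ MVN(Gamma_j., S rho S),   S = diag(se_Gamma_j.)

with the reported standard errors equal to the generating values.  This is
exactly the sampling model the clustering method assumes, and nothing
individual-level is needed because the method consumes only summary data.

The default scenario battery mirrors a 2x2x3 factorial: P in {2, 3}
outcomes, K_true in {1, 4} substantive clusters, and outcome correlation
rho in {0, 0.2, 0.7}; every design has J = 100 variants of which 10 are
junk.  In the K = 4 designs one cluster represents a correlated-pleiotropy
pathway (its effect vector arises through variant-confounder effects rather
than a true causal path, although at the summary level it behaves like any
other cluster) and one cluster sits at the origin; the K = 1 designs have a
single all-zero effect row, making the only substantive cluster a null
cluster.  Analyses inside the Monte Carlo loop always treat the outcome
correlation as zero, the realistic default when no estimate of it is
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import rand_score

from .post_inference import ClusterEstimate, estimate_clusters, test_null_cluster
from .selection import (
    DEFAULT_MAX_ITER,
    DEFAULT_MIN_CLUSTER_SIZE,
    DEFAULT_OUTLIER_P,
    SelectionResult,
    iterate_outlier_removal,
)
from .summary_data import OutcomeCorrelation, RatioEstimateSet, VariantSummary, compute_ratio_estimates

__all__ = [
    "SimulationDesign",
    "TruthRecord",
    "MetricsSummary",
    "generate_dataset",
    "default_designs",
    "design_by_name",
    "design_from_file",
    "run_monte_carlo",
    "clustering_metrics",
]

# -- fixed, versioned generator constants ----------------------------------
# True cluster effect rows for the four-cluster designs.  Centers are well
# separated relative to the ratio-estimate standard errors below, with the
# first row the correlated-pleiotropy pathway and the last sitting at the
# origin (a null pattern).
_EFFECTS_K4 = {
    2: np.array([[0.4, 0.5], [-0.5, 0.4], [0.5, -0.4], [0.0, 0.0]]),
    3: np.array([[0.4, 0.5, 0.4], [-0.5, 0.4, -0.4], [0.5, -0.4, 0.3], [0.0, 0.0, 0.0]]),
}
#: Default instrument-strength range (per-allele exposure effects).
_GAMMA_RANGE = (0.3, 0.5)
#: Default outcome-association standard-error scale.
_SE_SCALE = 0.07
#: Relative spread of per-variant outcome standard errors around se_scale.
_SE_JITTER = (0.75, 1.25)
#: Exposure-association standard error as a fraction of se_scale (the
#: instrument GWAS is typically much larger than the outcome GWAS).
_SE_GAMMA_FRAC = 0.25
#: Spread of junk variants' idiosyncratic ratio effects.
_JUNK_SD = 0.4
#: Nominal sample size driving the selection threshold zeta = 0.1/ln(n).
_N_NOMINAL = 3e5


@dataclass(frozen=True)
class SimulationDesign:
    """Generative parameters for one Monte Carlo scenario."""

    name: str
    P: int
    K_true: int
    cluster_sizes: tuple[int, ...]
    effect_matrix: np.ndarray  # (K_true, P)
    rho: OutcomeCorrelation
    J: int = 100
    n_junk: int = 10
    pleiotropy_cluster: int | None = None
    junk_alpha_sd: float = _JUNK_SD
    gamma_range: tuple[float, float] = _GAMMA_RANGE
    se_scale: float = _SE_SCALE
    n_nominal: float = _N_NOMINAL
    seed: int = 0

    def __post_init__(self) -> None:
        eff = np.atleast_2d(np.asarray(self.effect_matrix, dtype=float))
        object.__setattr__(self, "effect_matrix", eff)
        object.__setattr__(self, "cluster_sizes", tuple(int(s) for s in self.cluster_sizes))
        if eff.shape != (self.K_true, self.P):
            raise ValueError(f"effect_matrix must have shape ({self.K_true}, {self.P})")
        if sum(self.cluster_sizes) != self.J - self.n_junk:
            raise ValueError("cluster sizes must sum to J - n_junk")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("every cluster must have at least one variant")
        if self.K_true > 1 and len({tuple(r) for r in eff.round(12)}) != self.K_true:
            raise ValueError("effect rows must be distinct when K_true > 1")
        if self.rho.p != self.P:
            raise ValueError("rho dimension does not match P")
        if not (0 < self.gamma_range[0] <= self.gamma_range[1]):
            raise ValueError("gamma_range must be positive and ordered")
        if self.se_scale <= 0 or self.junk_alpha_sd <= 0:
            raise ValueError("scale parameters must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth labels and effects for a simulated dataset."""

    true_cluster: np.ndarray  # (J,) labels 0..K-1, junk = -1
    true_beta: np.ndarray  # (J, P)

    @property
    def junk_mask(self) -> np.ndarray:
        return self.true_cluster == -1


def generate_dataset(
    design: SimulationDesign, rng: np.random.Generator | None = None
) -> tuple[list[VariantSummary], TruthRecord]:
    """Draw one summary-statistic dataset from a design."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(design.seed))
    J, P = design.J, design.P

    labels = np.empty(J, dtype=int)
    pos = 0
    for k, size in enumerate(design.cluster_sizes):
        labels[pos : pos + size] = k
        pos += size
    labels[pos:] = -1  # junk

    true_beta = np.empty((J, P))
    for k in range(design.K_true):
        true_beta[labels == k] = design.effect_matrix[k]
    n_junk = int(np.sum(labels == -1))
    true_beta[labels == -1] = rng.normal(0.0, design.junk_alpha_sd, size=(n_junk, P))

    gamma = rng.uniform(*design.gamma_range, size=J)
    se_gamma = np.full(J, _SE_GAMMA_FRAC * design.se_scale)
    gamma_hat = rng.normal(gamma, se_gamma)

    se_Gamma = design.se_scale * rng.uniform(*_SE_JITTER, size=(J, P))
    Gamma = true_beta * gamma[:, None]
    chol = np.linalg.cholesky(design.rho.rho)
    noise = rng.standard_normal(size=(J, P)) @ chol.T
    Gamma_hat = Gamma + se_Gamma * noise

    variants = [
        VariantSummary(
            variant_id=f"snp_{j + 1}",
            gamma_hat=float(gamma_hat[j]),
            se_gamma=float(se_gamma[j]),
            Gamma_hat=Gamma_hat[j],
            se_Gamma=se_Gamma[j],
        )
        for j in range(J)
    ]
    return variants, TruthRecord(true_cluster=labels, true_beta=true_beta)


def default_designs() -> list[SimulationDesign]:
    """The 12 built-in scenarios: P in {2,3} x K in {1,4} x rho in {0,0.2,0.7}."""
    designs = []
    for P in (2, 3):
        for K in (4, 1):
            for r in (0.0, 0.2, 0.7):
                name = f"P{P}_K{K}_rho{r:g}"
                if K == 4:
                    sizes = (30, 30, 15, 15)
                    eff = _EFFECTS_K4[P]
                    pleio = 0
                else:
                    sizes = (90,)
                    eff = np.zeros((1, P))
                    pleio = None
                designs.append(
                    SimulationDesign(
                        name=name,
                        P=P,
                        K_true=K,
                        cluster_sizes=sizes,
                        effect_matrix=eff,
                        rho=OutcomeCorrelation.exchangeable(P, r),
                        pleiotropy_cluster=pleio,
                    )
                )
    return designs


def design_by_name(name: str) -> SimulationDesign:
    for d in default_designs():
        if d.name == name:
            return d
    known = ", ".join(d.name for d in default_designs())
    raise KeyError(f"unknown design {name!r}; built-in designs: {known}")


def design_from_file(path) -> SimulationDesign:
    """Load a design from a YAML or JSON mapping.

    Recognized keys mirror :class:`SimulationDesign`; ``rho`` may be a
    scalar (exchangeable correlation) or a full matrix.  Unspecified fields
    fall back to the calibrated defaults.
    """
    import yaml

    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict):
        raise ValueError(f"{path}: expected a mapping of design fields")
    P = int(spec.get("P", 2))
    rho_val = spec.get("rho", 0.0)
    if isinstance(rho_val, (int, float)):
        rho = OutcomeCorrelation.exchangeable(P, float(rho_val))
    else:
        rho = OutcomeCorrelation(np.asarray(rho_val, dtype=float))
    K = int(spec.get("K_true", 1))
    J = int(spec.get("J", 100))
    n_junk = int(spec.get("n_junk", 10))
    sizes = tuple(spec.get("cluster_sizes", (J - n_junk,) if K == 1 else ()))
    eff = np.asarray(spec.get("effect_matrix", np.zeros((K, P))), dtype=float)
    kwargs = {
        k: spec[k]
        for k in ("pleiotropy_cluster", "junk_alpha_sd", "se_scale", "n_nominal", "seed")
        if k in spec
    }
    if "gamma_range" in spec:
        kwargs["gamma_range"] = tuple(spec["gamma_range"])
    return SimulationDesign(
        name=str(spec.get("name", "custom")),
        P=P,
        K_true=K,
        cluster_sizes=sizes,
        effect_matrix=eff,
        rho=rho,
        J=J,
        n_junk=n_junk,
        **kwargs,
    )


def clustering_metrics(
    truth: TruthRecord,
    selection: SelectionResult,
    estimates: Sequence[ClusterEstimate],
    ratios: RatioEstimateSet | None = None,
) -> dict[str, float]:
    """Evaluation metrics for one replication.

    - ``n_clusters``: detected substantive clusters.
    - ``rand``: pairwise-agreement Rand index over true non-junk variants,
      with junk-assigned variants forming one extra detected label.
    - ``n_junk`` / ``correct_junk``: detected junk count and its overlap with
      the true junk set.
    - ``mae`` / ``mse``: mean (squared) absolute error of the assigned
      cluster's IVW estimate against each non-junk variant's true effect,
      averaged over variants and outcomes; variants assigned to junk
      contribute their own ratio estimate.
    - ``freq_null``: 1.0 when exactly one substantive cluster is detected
      and its joint Wald test labels it null.
    """
    J = truth.true_cluster.shape[0]
    labels_pred = np.full(J, -1, dtype=int)
    for cid, members in enumerate(selection.partition):
        labels_pred[members] = cid

    non_junk = ~truth.junk_mask
    rand = rand_score(truth.true_cluster[non_junk], labels_pred[non_junk])

    detected_junk = set(selection.outliers_removed)
    true_junk = set(np.flatnonzero(truth.junk_mask))

    est_by_cluster = {e.cluster_id: e.estimate for e in estimates}
    errs = []
    for j in np.flatnonzero(non_junk):
        cid = labels_pred[j]
        if cid >= 0:
            assigned = est_by_cluster[cid]
        elif ratios is not None:
            assigned = ratios.beta_hat[j]  # junk-assigned: the variant's own estimate
        else:
            raise ValueError("ratios must be supplied when variants are junk-assigned")
        errs.append(np.abs(assigned - truth.true_beta[j]))
    abs_err = np.vstack(errs)

    is_null_single = float(
        len(selection.partition) == 1
        and estimates
        and bool(estimates[0].is_null)
    )
    return {
        "n_clusters": float(len(selection.partition)),
        "rand": float(rand),
        "n_junk": float(len(detected_junk)),
        "correct_junk": float(len(detected_junk & true_junk)),
        "mae": float(abs_err.mean()),
        "mse": float((abs_err**2).mean()),
        "freq_null": is_null_single,
    }


@dataclass
class MetricsSummary:
    """Aggregated Monte Carlo metrics."""

    design: str
    n_reps: int
    seed: int
    per_rep: pd.DataFrame
    mean: pd.Series = field(init=False)
    median: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.mean = self.per_rep.mean()
        self.median = self.per_rep.median()


def run_monte_carlo(
    design: SimulationDesign,
    n_reps: int,
    seed: int | None = None,
    outlier_p: float = DEFAULT_OUTLIER_P,
    max_iter: int = DEFAULT_MAX_ITER,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    analysis_rho: OutcomeCorrelation | None = None,
) -> MetricsSummary:
    """Replicate generate -> cluster -> evaluate and aggregate the metrics.

    The analysis always runs the outlier-robust procedure.  ``analysis_rho``
    defaults to the identity, i.e. the outcome correlation is treated as
    zero regardless of the generating value.  Replication r uses an
    independent substream spawned from (seed, r), so any single replication
    is reproducible in isolation.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if seed is None:
        seed = design.seed
    if analysis_rho is None:
        analysis_rho = OutcomeCorrelation.identity(design.P)

    rows = []
    for rep in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(rep,)))
        variants, truth = generate_dataset(design, rng)
        ratios = compute_ratio_estimates(variants, analysis_rho)
        selection = iterate_outlier_removal(
            ratios,
            analysis_rho,
            n=design.n_nominal,
            outlier_p=outlier_p,
            max_iter=max_iter,
            min_cluster_size=min_cluster_size,
        )
        estimates = estimate_clusters(selection, ratios, analysis_rho)
        for e in estimates:
            test_null_cluster(e, ratios, n=design.n_nominal, rho=analysis_rho)
        m = clustering_metrics(truth, selection, estimates, ratios)
        m["rep"] = rep
        rows.append(m)
    per_rep = pd.DataFrame(rows).set_index("rep")
    return MetricsSummary(design=design.name, n_reps=n_reps, seed=seed, per_rep=per_rep)
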