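"""Ingestion and harmonization of GWAS summary statistics for multi-outcome MR.

A two-sample (or multi-sample) summary-data Mendelian randomization analysis
starts from per-variant association estimates: the variant-exposure effect
``gamma_hat`` with its standard error, and for each of the P outcomes the
variant-outcome effect ``Gamma_hat`` with its standard error.  The
variant-specific causal ("ratio") estimate for outcome p is

    beta_hat_jp = Gamma_hat_jp / gamma_hat_j,

with first-order variance  v_jp^2 = se(Gamma_hat_jp)^2 / gamma_hat_j^2
(the exposure-side uncertainty is ignored at first order, the usual NOME
approximation).  When outcome GWAS samples overlap or the outcome traits are
phenotypically correlated, the P ratio estimates of one variant are
correlated; a constant P x P outcome correlation matrix ``rho`` induces the
per-variant covariance

    Sigma_j[i, r] = rho_ir * v_ji * v_jr.

This module turns raw summary tables into a :class:`RatioEstimateSet`, the
in-memory container consumed by the clustering engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantSummary",
    "OutcomeCorrelation",
    "RatioEstimateSet",
    "harmonize_orientation",
    "compute_ratio_estimates",
    "effective_sample_size",
    "read_gwas_table",
    "merge_gwas_tables",
    "variants_from_frame",
    "variants_to_frame",
    "ratio_frame",
]

#: Complementary DNA bases, used for strand flips during allele harmonization.
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class VariantSummary:
    """Harmonized summary statistics for one genetic variant.

    Parameters
    ----------
    variant_id : str
        Variant identifier (typically an rsID).
    gamma_hat : float
        Variant-exposure association estimate, in exposure units per
        effect-allele copy.
    se_gamma : float
        Standard error of ``gamma_hat``; must be positive.
    Gamma_hat : ndarray of shape (P,)
        Variant-outcome association estimates, one entry per outcome.
    se_Gamma : ndarray of shape (P,)
        Standard errors of ``Gamma_hat``; all positive.
    effect_allele, other_allele : str, optional
        Alleles the estimates are oriented to; retained for provenance.
    """

    variant_id: str
    gamma_hat: float
    se_gamma: float
    Gamma_hat: np.ndarray
    se_Gamma: np.ndarray
    effect_allele: str | None = None
    other_allele: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "Gamma_hat", np.atleast_1d(np.asarray(self.Gamma_hat, dtype=float)))
        object.__setattr__(self, "se_Gamma", np.atleast_1d(np.asarray(self.se_Gamma, dtype=float)))
        if self.Gamma_hat.shape != self.se_Gamma.shape:
            raise ValueError(
                f"variant {self.variant_id!r}: Gamma_hat and se_Gamma shapes differ "
                f"({self.Gamma_hat.shape} vs {self.se_Gamma.shape})"
            )
        if not np.isfinite(self.gamma_hat):
            raise ValueError(f"variant {self.variant_id!r}: non-finite gamma_hat")
        if not (self.se_gamma > 0 and np.isfinite(self.se_gamma)):
            raise ValueError(f"variant {self.variant_id!r}: se_gamma must be positive and finite")
        if not np.all(np.isfinite(self.Gamma_hat)):
            raise ValueError(f"variant {self.variant_id!r}: non-finite Gamma_hat")
        if not np.all((self.se_Gamma > 0) & np.isfinite(self.se_Gamma)):
            raise ValueError(f"variant {self.variant_id!r}: se_Gamma must be positive and finite")

    @property
    def n_outcomes(self) -> int:
        return self.Gamma_hat.shape[0]


@dataclass(frozen=True)
class OutcomeCorrelation:
    """Constant P x P correlation matrix of the outcome association errors.

    The correlation between ``Gamma_hat_ji`` and ``Gamma_hat_jr`` is assumed
    constant across variants j.  It is non-zero only when outcome GWAS
    samples overlap and the traits are phenotypically correlated; treating it
    as zero is a safe default in most applied settings.
    """

    rho: np.ndarray

    def __post_init__(self) -> None:
        rho = np.atleast_2d(np.asarray(self.rho, dtype=float))
        if rho.shape[0] != rho.shape[1]:
            raise ValueError("rho must be square")
        if not np.allclose(rho, rho.T, atol=1e-12):
            raise ValueError("rho must be symmetric")
        if not np.allclose(np.diag(rho), 1.0, atol=1e-12):
            raise ValueError("rho must have unit diagonal")
        if np.any(np.abs(rho) > 1 + 1e-12):
            raise ValueError("rho entries must lie in [-1, 1]")
        eigvals = np.linalg.eigvalsh(rho)
        if eigvals.min() < -1e-10:
            raise ValueError("rho must be positive semi-definite")
        object.__setattr__(self, "rho", rho)

    @classmethod
    def identity(cls, p: int) -> "OutcomeCorrelation":
        return cls(np.eye(p))

    @classmethod
    def exchangeable(cls, p: int, r: float) -> "OutcomeCorrelation":
        """All off-diagonal correlations equal to ``r``."""
        rho = np.full((p, p), float(r))
        np.fill_diagonal(rho, 1.0)
        return cls(rho)

    @property
    def p(self) -> int:
        return self.rho.shape[0]


@dataclass
class RatioEstimateSet:
    """Per-variant ratio estimates with their covariance structure.

    Attributes
    ----------
    beta_hat : ndarray (J, P)
        Ratio estimates ``Gamma_hat / gamma_hat``.
    v2 : ndarray (J, P)
        First-order ratio-estimate variances ``se(Gamma_hat)^2 / gamma_hat^2``.
    weights : ndarray (J, P)
        Inverse-variance weights ``1 / v2``.
    rho : OutcomeCorrelation
        Outcome correlation used to build per-variant covariances.
    variant_ids : list of str
    gamma_hat, se_gamma : ndarray (J,)
        Retained exposure-side statistics (diagnostics only; the first-order
        variance does not use ``se_gamma``).
    """

    beta_hat: np.ndarray
    v2: np.ndarray
    rho: OutcomeCorrelation
    variant_ids: list[str]
    gamma_hat: np.ndarray
    se_gamma: np.ndarray
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.beta_hat = np.atleast_2d(np.asarray(self.beta_hat, dtype=float))
        self.v2 = np.atleast_2d(np.asarray(self.v2, dtype=float))
        if self.beta_hat.shape != self.v2.shape:
            raise ValueError("beta_hat and v2 shapes differ")
        if np.any(self.v2 <= 0):
            raise ValueError("ratio-estimate variances must be positive")
        if self.rho.p != self.beta_hat.shape[1]:
            raise ValueError("rho dimension does not match number of outcomes")
        if len(self.variant_ids) != self.beta_hat.shape[0]:
            raise ValueError("variant_ids length does not match beta_hat rows")
        self.weights = 1.0 / self.v2

    @property
    def n_variants(self) -> int:
        return self.beta_hat.shape[0]

    @property
    def n_outcomes(self) -> int:
        return self.beta_hat.shape[1]

    def variant_cov(self, j: int) -> np.ndarray:
        """P x P covariance matrix Sigma_j of variant j's ratio estimates."""
        v = np.sqrt(self.v2[j])
        return self.rho.rho * np.outer(v, v)

    def variant_cov_all(self) -> np.ndarray:
        """(J, P, P) stack of per-variant covariance matrices."""
        v = np.sqrt(self.v2)
        return self.rho.rho[None, :, :] * v[:, :, None] * v[:, None, :]

    def precision_all(self) -> np.ndarray:
        """(J, P, P) stack of per-variant inverse covariances.

        Sigma_j = diag(v_j) rho diag(v_j), hence
        Sigma_j^{-1} = diag(1/v_j) rho^{-1} diag(1/v_j).
        """
        rho_inv = np.linalg.inv(self.rho.rho)
        s = np.sqrt(self.weights)
        return rho_inv[None, :, :] * s[:, :, None] * s[:, None, :]

    def subset(self, indices: Sequence[int]) -> "RatioEstimateSet":
        idx = np.asarray(list(indices), dtype=int)
        return RatioEstimateSet(
            beta_hat=self.beta_hat[idx],
            v2=self.v2[idx],
            rho=self.rho,
            variant_ids=[self.variant_ids[i] for i in idx],
            gamma_hat=self.gamma_hat[idx],
            se_gamma=self.se_gamma[idx],
        )


def harmonize_orientation(variants: Iterable[VariantSummary]) -> list[VariantSummary]:
    """Orient every variant in the direction of increasing the exposure.

    Variants with a negative exposure association have the signs of
    ``gamma_hat`` and all outcome associations flipped (equivalent to
    swapping effect and other alleles); standard errors are unchanged.
    A variant with ``gamma_hat == 0`` has no defined ratio estimate and is
    rejected.
    """
    out: list[VariantSummary] = []
    for v in variants:
        if v.gamma_hat == 0:
            raise ValueError(
                f"variant {v.variant_id!r} has gamma_hat == 0; its ratio estimate is undefined"
            )
        if v.gamma_hat > 0:
            out.append(v)
        else:
            out.append(
                replace(
                    v,
                    gamma_hat=-v.gamma_hat,
                    Gamma_hat=-v.Gamma_hat,
                    effect_allele=v.other_allele,
                    other_allele=v.effect_allele,
                )
            )
    return out


def compute_ratio_estimates(
    variants: Sequence[VariantSummary],
    rho: OutcomeCorrelation | None = None,
) -> RatioEstimateSet:
    """Form the ratio-estimate set ``{beta_hat_j, Sigma_j}`` from harmonized variants.

    Parameters
    ----------
    variants : sequence of VariantSummary
        Must already be harmonized (``gamma_hat > 0``).
    rho : OutcomeCorrelation, optional
        Outcome correlation; defaults to the identity (uncorrelated outcome
        samples).
    """
    if len(variants) == 0:
        raise ValueError("no variants supplied")
    p = variants[0].n_outcomes
    for v in variants:
        if v.n_outcomes != p:
            raise ValueError(f"variant {v.variant_id!r}: expected {p} outcomes, got {v.n_outcomes}")
        if v.gamma_hat <= 0:
            raise ValueError(
                f"variant {v.variant_id!r}: gamma_hat <= 0; call harmonize_orientation first"
            )
    if rho is None:
        rho = OutcomeCorrelation.identity(p)

    gamma = np.array([v.gamma_hat for v in variants])
    se_gamma = np.array([v.se_gamma for v in variants])
    Gamma = np.vstack([v.Gamma_hat for v in variants])
    se_Gamma = np.vstack([v.se_Gamma for v in variants])

    beta_hat = Gamma / gamma[:, None]
    v2 = se_Gamma**2 / gamma[:, None] ** 2
    return RatioEstimateSet(
        beta_hat=beta_hat,
        v2=v2,
        rho=rho,
        variant_ids=[v.variant_id for v in variants],
        gamma_hat=gamma,
        se_gamma=se_gamma,
    )


def effective_sample_size(n_cases: float, n_controls: float) -> float:
    """Effective sample size of a case-control GWAS, 4 / (1/cases + 1/controls).

    Equals the total sample size for a balanced study and shrinks as the
    case:control ratio becomes unbalanced.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("case and control counts must both be >= 1")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


# ---------------------------------------------------------------------------
# Tab-separated GWAS table I/O


def read_gwas_table(path, label: str | None = None) -> pd.DataFrame:
    """Read a tab-separated GWAS summary table.

    Required columns: ``SNP``, ``beta``, ``se``; ``effect_allele`` and
    ``other_allele`` are used for harmonization when present.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str})
    missing = {"SNP", "beta", "se"} - set(df.columns)
    if missing:
        raise ValueError(f"{label or path}: missing required column(s) {sorted(missing)}")
    if df["SNP"].duplicated().any():
        dups = df.loc[df["SNP"].duplicated(), "SNP"].tolist()[:5]
        raise ValueError(f"{label or path}: duplicated SNP id(s), e.g. {dups}")
    bad_se = ~(df["se"] > 0)
    if bad_se.any():
        row = int(np.flatnonzero(bad_se)[0])
        raise ValueError(f"{label or path}: non-positive se at line {row + 2} (SNP {df['SNP'].iloc[row]})")
    return df


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def merge_gwas_tables(
    exposure: pd.DataFrame,
    outcomes: Sequence[pd.DataFrame],
    outcome_names: Sequence[str] | None = None,
    strict: bool = False,
) -> list[VariantSummary]:
    """Merge exposure and outcome GWAS tables into harmonized variants.

    Only variants present in every table are retained (a logged count reports
    drops).  Allele mismatches between exposure and outcome are resolved by
    the swap rule (outcome alleles reversed -> flip the outcome beta sign)
    and, failing that, by strand complement; palindromic (A/T, C/G) variants
    are ambiguous under strand flips and are dropped when ``strict`` is set.
    Finally all variants are oriented toward increasing exposure.
    """
    if outcome_names is None:
        outcome_names = [f"outcome_{i + 1}" for i in range(len(outcomes))]
    have_alleles = "effect_allele" in exposure.columns and "other_allele" in exposure.columns

    exp = exposure.set_index("SNP")
    outs = [o.set_index("SNP") for o in outcomes]
    shared = exp.index
    for o in outs:
        shared = shared.intersection(o.index)
    n_dropped = len(exp.index) - len(shared)
    if n_dropped:
        logger.info("dropped %d variant(s) missing from at least one outcome table", n_dropped)

    variants: list[VariantSummary] = []
    n_ambiguous = 0
    for snp in shared:
        g = float(exp.loc[snp, "beta"])
        seg = float(exp.loc[snp, "se"])
        ea = str(exp.loc[snp, "effect_allele"]).upper() if have_alleles else None
        oa = str(exp.loc[snp, "other_allele"]).upper() if have_alleles else None
        Gammas: list[float] = []
        ses: list[float] = []
        ok = True
        for name, o in zip(outcome_names, outs):
            b = float(o.loc[snp, "beta"])
            s = float(o.loc[snp, "se"])
            if have_alleles and "effect_allele" in o.columns and "other_allele" in o.columns:
                ea_o = str(o.loc[snp, "effect_allele"]).upper()
                oa_o = str(o.loc[snp, "other_allele"]).upper()
                if (ea_o, oa_o) == (ea, oa):
                    pass
                elif (ea_o, oa_o) == (oa, ea):
                    b = -b  # effect measured on the other allele
                elif (_COMPLEMENT.get(ea_o), _COMPLEMENT.get(oa_o)) == (ea, oa):
                    pass  # opposite strand, same orientation
                elif (_COMPLEMENT.get(ea_o), _COMPLEMENT.get(oa_o)) == (oa, ea):
                    b = -b
                else:
                    logger.warning("variant %s: alleles irreconcilable with %s; dropped", snp, name)
                    ok = False
                    break
                if strict and _is_palindromic(ea_o, oa_o):
                    logger.warning("variant %s: palindromic alleles ambiguous under --strict; dropped", snp)
                    n_ambiguous += 1
                    ok = False
                    break
            Gammas.append(b)
            ses.append(s)
        if not ok:
            continue
        variants.append(
            VariantSummary(
                variant_id=str(snp),
                gamma_hat=g,
                se_gamma=seg,
                Gamma_hat=np.array(Gammas),
                se_Gamma=np.array(ses),
                effect_allele=ea,
                other_allele=oa,
            )
        )
    if n_ambiguous:
        logger.info("dropped %d palindromic variant(s) under strict harmonization", n_ambiguous)
    return harmonize_orientation(variants)


def variants_from_frame(df: pd.DataFrame, n_outcomes: int | None = None) -> list[VariantSummary]:
    """Build variants from a combined wide table.

    Expected columns: ``SNP``, ``gamma_hat``, ``se_gamma`` and per-outcome
    pairs ``Gamma_hat_1 .. Gamma_hat_P``, ``se_Gamma_1 .. se_Gamma_P``.
    """
    if n_outcomes is None:
        n_outcomes = sum(c.startswith("Gamma_hat_") for c in df.columns)
    if n_outcomes < 1:
        raise ValueError("no Gamma_hat_<p> columns found")
    required = ["SNP", "gamma_hat", "se_gamma"]
    for p in range(1, n_outcomes + 1):
        required += [f"Gamma_hat_{p}", f"se_Gamma_{p}"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"missing required column(s) {sorted(missing)}")
    variants = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        variants.append(
            VariantSummary(
                variant_id=str(d["SNP"]),
                gamma_hat=float(d["gamma_hat"]),
                se_gamma=float(d["se_gamma"]),
                Gamma_hat=np.array([d[f"Gamma_hat_{p}"] for p in range(1, n_outcomes + 1)], dtype=float),
                se_Gamma=np.array([d[f"se_Gamma_{p}"] for p in range(1, n_outcomes + 1)], dtype=float),
                effect_allele=d.get("effect_allele"),
                other_allele=d.get("other_allele"),
            )
        )
    return variants


def variants_to_frame(variants: Sequence[VariantSummary]) -> pd.DataFrame:
    """Inverse of :func:`variants_from_frame`: one wide row per variant."""
    if not variants:
        raise ValueError("no variants supplied")
    p = variants[0].n_outcomes
    rows = []
    for v in variants:
        d = {"SNP": v.variant_id, "gamma_hat": v.gamma_hat, "se_gamma": v.se_gamma}
        for i in range(p):
            d[f"Gamma_hat_{i + 1}"] = v.Gamma_hat[i]
            d[f"se_Gamma_{i + 1}"] = v.se_Gamma[i]
        rows.append(d)
    return pd.DataFrame(rows)


def ratio_frame(ratios: RatioEstimateSet) -> pd.DataFrame:
    """Harmonized combined table with ratio estimates and their variances."""
    data: dict[str, np.ndarray | list] = {"SNP": list(ratios.variant_ids)}
    data["gamma_hat"] = ratios.gamma_hat
    data["se_gamma"] = ratios.se_gamma
    for p in range(ratios.n_outcomes):
        data[f"beta_hat_{p + 1}"] = ratios.beta_hat[:, p]
        data[f"v2_{p + 1}"] = ratios.v2[:, p]
    return pd.DataFrame(data)
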