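import numpy as np
import pytest

from mrahc.summary_data import OutcomeCorrelation, RatioEstimateSet, VariantSummary


def make_ratios(beta, v2=None, rho=None, gamma=None):
    """Build a RatioEstimateSet directly from ratio estimates and variances."""
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    if beta.shape[0] == 1 and beta.shape[1] > 1 and v2 is None:
        beta = beta.T  # single-outcome convenience: row vector of variants
    J, P = beta.shape
    v2 = np.ones_like(beta) if v2 is None else np.atleast_2d(np.asarray(v2, dtype=float))
    if v2.shape != beta.shape:
        v2 = np.broadcast_to(v2, beta.shape).copy()
    rho = rho if rho is not None else OutcomeCorrelation.identity(P)
    gamma = np.ones(J) if gamma is None else np.asarray(gamma, dtype=float)
    return RatioEstimateSet(
        beta_hat=beta,
        v2=v2,
        rho=rho,
        variant_ids=[f"v{j}" for j in range(J)],
        gamma_hat=gamma,
        se_gamma=np.full(J, 0.01),
    )


def random_ratios(rng, J=8, P=2, rho=None):
    """A generic random instance for property checks."""
    beta = rng.normal(0, 1, size=(J, P))
    v2 = rng.uniform(0.2, 2.0, size=(J, P))
    return make_ratios(beta, v2, rho)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def figure2_toy():
    """Six single-outcome estimates forming groups {0,1}, {2,3,4}, {5}.

    Group separations are large relative to the standard errors, so the
    three-cluster partition is unambiguous.
    """
    variants = [
        VariantSummary(f"v{i}", 1.0, 0.01, np.array([b]), np.array([0.03]))
        for i, b in enumerate([0.0, 0.02, 0.5, 0.52, 0.48, 1.5])
    ]
    return variants
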