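import math

import pytest

from enrichopt.design import PriorSpec, StageOneParams, TrialConfig
from enrichopt.simulate import RuleMapPolicy


@pytest.fixture(scope="session")
def we_cfg() -> TrialConfig:
    """Reference trial configuration: n=700, sigma=1, alpha=0.05, lambda=0.3."""
    return TrialConfig(n=700, sigma=1.0, alpha=0.05, lambda_pop=0.3, mode="enrichment")


@pytest.fixture(scope="session")
def we_prior() -> PriorSpec:
    """Reference prior: mean (0.1, 0), covariance [[0.1, 0.05], [0.05, 0.1]]."""
    s = math.sqrt(0.1)
    return PriorSpec(mu1=0.1, mu2=0.0, psi1=s, psi2=s, rho=0.5)


@pytest.fixture(scope="session")
def we_a1() -> StageOneParams:
    """Reference first-stage design: s1=0.5, r1=0.4, w1=0.4."""
    return StageOneParams(s1=0.5, r1_1=0.4, w1_1=0.4)


@pytest.fixture(scope="session")
def we_rule_map(we_cfg, we_prior, we_a1) -> RuleMapPolicy:
    """Precomputed interim-optimal adaptation rule for the reference design.

    Session-scoped: building the map dominates simulation cost, and the
    FWER, power-monotonicity and benchmark comparisons all reuse it.
    """
    return RuleMapPolicy.build(we_a1, we_prior, we_cfg, n_grid=13, tol=1e-3)
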