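"""Prior/posterior machinery and expected-utility computation.

The utility of a completed trial is

    U = lambda * 1(reject H01 globally) + (1 - lambda) * 1(reject H02 globally),

weighting each rejection by the population prevalence of its subgroup.  With
a bivariate normal prior on the treatment effects and normal sampling laws,
every expected utility in this package reduces to rejection probabilities of
a bivariate normal vector of Z-statistics over the union-of-rectangles
rejection region of the closed test.  These are computed exactly from
bivariate-normal orthant probabilities rather than by nested quadrature over
theta — the normal-normal structure makes this exact, fast and precise.
Monte-Carlo counterparts exist for the backward-induction stage-1 search and
as independent oracles in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.stats import norm

from ._bvn import bvn_upper
from .design import (
    Mode,
    PriorSpec,
    StageOneParams,
    StageSummary,
    StageTwoParams,
    TestResult,
    TrialConfig,
    coupled_stage_two,
)
from .testing import ConditionalErrors

__all__ = [
    "PosteriorSpec",
    "PredictiveSpec",
    "Thresholds",
    "utility",
    "posterior_update",
    "predictive_stage2",
    "rejection_probabilities",
    "conditional_expected_utility",
    "expected_utility_single_stage",
    "expected_utility_two_stage_mc",
]


@dataclass(frozen=True)
class PosteriorSpec:
    """Bivariate normal posterior of (theta1, theta2) after stage 1."""

    m1: float
    m2: float
    V11: float
    V22: float
    V12: float = 0.0

    def __post_init__(self):
        if self.V11 < 0 or self.V22 < 0:
            raise ValueError("posterior variances must be non-negative")
        if self.V12**2 > self.V11 * self.V22 * (1 + 1e-12) + 1e-300:
            raise ValueError("posterior covariance not positive semidefinite")

    @property
    def mean(self):
        return np.array([self.m1, self.m2])

    @property
    def cov(self):
        return np.array([[self.V11, self.V12], [self.V12, self.V22]])

    @classmethod
    def from_prior(cls, prior: PriorSpec) -> "PosteriorSpec":
        c = prior.rho * prior.psi1 * prior.psi2
        return cls(prior.mu1, prior.mu2, prior.psi1**2, prior.psi2**2, c)


@dataclass(frozen=True)
class PredictiveSpec:
    """Predictive law of the stage-2 Z-values given the interim posterior.

    Marginalizing ``Zj_2 | theta ~ N(cj theta_j, 1)`` over the posterior
    gives a bivariate normal with ``var >= 1`` (the sampling-noise floor).
    """

    mean1: float
    mean2: float
    var1: float
    var2: float
    cov: float = 0.0

    def __post_init__(self):
        if self.var1 < 1.0 - 1e-9 or self.var2 < 1.0 - 1e-9:
            raise ValueError("predictive variances cannot fall below 1")
        if self.cov**2 > self.var1 * self.var2 * (1 + 1e-12):
            raise ValueError("predictive covariance not positive semidefinite")


@dataclass(frozen=True)
class Thresholds:
    """Critical values (z-scale) of the active final test.

    ``b1``/``b2`` for the individual tests, ``d1``/``d2`` for the weighted
    Bonferroni intersection components (``None`` in umbrella mode).  A
    ``+inf`` entry means that component can never reject.
    """

    b1: float
    b2: float
    d1: Optional[float] = None
    d2: Optional[float] = None


def utility(result: TestResult, lambda_pop: float) -> float:
    """Realized utility of a trial outcome."""
    return lambda_pop * float(result.reject_H01_global) + (
        1.0 - lambda_pop
    ) * float(result.reject_H02_global)


def posterior_update(
    prior: PriorSpec,
    stage1: StageSummary,
    a1: StageOneParams,
    cfg: TrialConfig,
) -> PosteriorSpec:
    """Conjugate bivariate-normal update given stage-1 estimates.

    The likelihood contributes independent terms
    ``theta_hat_j ~ N(theta_j, 4 sigma^2 / (r_j s1 n))`` for each sampled
    subgroup; an unsampled subgroup (prevalence 0, estimate ``None``)
    contributes nothing.  The covariance-form update
    ``V = Psi - Psi_J (Psi_JJ + D_J)^-1 Psi_J'`` is used so that degenerate
    (point-mass) priors are handled without inverting Psi.
    """
    mu = prior.mean
    Psi = prior.cov

    rs = [a1.r1_1, a1.r2_1]
    ests = [stage1.theta_hat_1, stage1.theta_hat_2]
    active = [j for j in range(2) if rs[j] > 0 and ests[j] is not None]
    if not active:
        return PosteriorSpec.from_prior(prior)

    d = np.array(
        [4.0 * cfg.sigma**2 / (rs[j] * a1.s1 * cfg.n) for j in active]
    )
    theta_hat = np.array([ests[j] for j in active])
    Psi_aJ = Psi[:, active]
    K = Psi[np.ix_(active, active)] + np.diag(d)
    gain = Psi_aJ @ np.linalg.inv(K)
    m = mu + gain @ (theta_hat - mu[active])
    V = Psi - gain @ Psi_aJ.T
    # Clamp tiny negative round-off on the diagonal.
    V11 = max(V[0, 0], 0.0)
    V22 = max(V[1, 1], 0.0)
    V12 = float(np.clip(V[0, 1], -math.sqrt(V11 * V22), math.sqrt(V11 * V22)))
    return PosteriorSpec(float(m[0]), float(m[1]), V11, V22, V12)


def predictive_stage2(
    post: PosteriorSpec,
    a2: StageTwoParams,
    a1: StageOneParams,
    cfg: TrialConfig,
) -> PredictiveSpec:
    """Predictive moments of the stage-2 Z-values under the posterior.

    With ``cj = sqrt(r_j_2 s2 n) / (2 sigma)``: mean ``cj mj``, variance
    ``1 + cj^2 Vjj``, covariance ``c1 c2 V12``; ``cj = 0`` for a dropped
    subgroup (its "Z" is pure noise and never consulted).
    """
    s2 = 1.0 - a1.s1
    if s2 <= 0:
        raise ValueError("stage-2 fraction must be positive (s1 < 1)")
    c1 = math.sqrt(a2.r1_2 * s2 * cfg.n) / (2.0 * cfg.sigma)
    c2 = math.sqrt(a2.r2_2 * s2 * cfg.n) / (2.0 * cfg.sigma)
    return PredictiveSpec(
        mean1=c1 * post.m1,
        mean2=c2 * post.m2,
        var1=1.0 + c1**2 * post.V11,
        var2=1.0 + c2**2 * post.V22,
        cov=c1 * c2 * post.V12,
    )


def rejection_probabilities(
    pred: PredictiveSpec, thresholds: Thresholds, mode: Mode
) -> Tuple[float, float]:
    """Global rejection probabilities under a bivariate normal Z-law.

    Enrichment: H01 is rejected globally iff ``Z1 > b1`` and
    (``Z1 > d1`` or ``Z2 > d2``), i.e. the union
    ``{Z1 > max(b1, d1)} ∪ {Z1 > b1, Z2 > d2}``, whose probability is
    assembled from univariate tails and bivariate upper-orthant
    probabilities (inclusion-exclusion).  Umbrella: univariate tails only.
    All probabilities are clipped to [0, 1].
    """
    m1, m2 = pred.mean1, pred.mean2
    v1, v2, cv = pred.var1, pred.var2, pred.cov
    s1d, s2d = math.sqrt(v1), math.sqrt(v2)

    def tail1(x):
        return float(norm.sf((x - m1) / s1d)) if np.isfinite(x) else (1.0 if x == -math.inf else 0.0)

    def tail2(x):
        return float(norm.sf((x - m2) / s2d)) if np.isfinite(x) else (1.0 if x == -math.inf else 0.0)

    if mode is Mode.UMBRELLA:
        return (
            float(np.clip(tail1(thresholds.b1), 0, 1)),
            float(np.clip(tail2(thresholds.b2), 0, 1)),
        )

    b1, b2 = thresholds.b1, thresholds.b2
    d1 = thresholds.d1 if thresholds.d1 is not None else math.inf
    d2 = thresholds.d2 if thresholds.d2 is not None else math.inf

    def joint(x, y):
        return float(bvn_upper(x, y, m1, m2, v1, v2, cv))

    m1d = max(b1, d1)
    p_rej1 = tail1(m1d) + joint(b1, d2) - joint(m1d, d2)
    m2d = max(b2, d2)
    p_rej2 = tail2(m2d) + joint(d1, b2) - joint(d1, m2d)
    return (
        float(np.clip(p_rej1, 0.0, 1.0)),
        float(np.clip(p_rej2, 0.0, 1.0)),
    )


def _thresholds_from_ce(
    ce: ConditionalErrors, a2: StageTwoParams, mode: Mode
) -> Thresholds:
    """Critical values of the conditional-error final tests under a2."""

    def isf(p):
        if p <= 0:
            return math.inf
        if p >= 1:
            return -math.inf
        return float(norm.isf(p))

    dropped1 = a2.r1_2 <= 0.0
    dropped2 = a2.r1_2 >= 1.0
    b1 = math.inf if dropped1 else isf(ce.A1)
    b2 = math.inf if dropped2 else isf(ce.A2)
    if mode is Mode.UMBRELLA:
        return Thresholds(b1=b1, b2=b2)
    if ce.A12 is None:
        raise ValueError("enrichment mode requires A12")
    w1 = 0.0 if dropped1 else (1.0 if dropped2 else a2.w1_2)
    w2 = 1.0 - w1
    d1 = math.inf if dropped1 else isf(w1 * ce.A12)
    d2 = math.inf if dropped2 else isf(w2 * ce.A12)
    return Thresholds(b1=b1, b2=b2, d1=d1, d2=d2)


def conditional_expected_utility(
    a2: StageTwoParams,
    a1: StageOneParams,
    interim,
    prior: PriorSpec,
    cfg: TrialConfig,
) -> float:
    """Conditional expected utility W2 of continuing with parameters a2.

    Averages the utility over the predictive law of the stage-2 Z-values
    (posterior of theta given stage-1 data, then sampling noise), with the
    conditional-error thresholds fixed at the interim.  ``interim`` must
    carry ``ce`` (ConditionalErrors) and ``post`` (PosteriorSpec).
    """
    if interim.ce is None:
        raise ValueError("interim state lacks conditional error rates")
    post = interim.post
    if post is None:
        raise ValueError("interim state lacks a posterior")
    pred = predictive_stage2(post, a2, a1, cfg)
    thr = _thresholds_from_ce(interim.ce, a2, cfg.mode)
    p1, p2 = rejection_probabilities(pred, thr, cfg.mode)
    lam = cfg.lambda_pop
    return lam * p1 + (1.0 - lam) * p2


def expected_utility_single_stage(
    a: Tuple[float, float], prior: PriorSpec, cfg: TrialConfig
) -> float:
    """Closed-form Bayes expected utility of a single-stage design (r1, w1).

    Under the prior predictive law the single-stage Z-values are bivariate
    normal with ``mean_j = c_j mu_j``, ``var_j = 1 + c_j^2 psi_j^2``,
    ``cov = c1 c2 rho psi1 psi2`` where ``c_j = sqrt(r_j n) / (2 sigma)``;
    rejection probabilities use thresholds ``Phi^-1(1 - alpha)`` and
    ``Phi^-1(1 - w_j alpha)``.  Boundary prevalences force the weights and
    drop the unsampled subgroup's hypothesis.
    """
    r1, w1 = a
    if not 0 <= r1 <= 1:
        raise ValueError(f"r1 must be in [0, 1], got {r1}")
    r2 = 1.0 - r1
    c1 = math.sqrt(r1 * cfg.n) / (2.0 * cfg.sigma)
    c2 = math.sqrt(r2 * cfg.n) / (2.0 * cfg.sigma)
    pred = PredictiveSpec(
        mean1=c1 * prior.mu1,
        mean2=c2 * prior.mu2,
        var1=1.0 + c1**2 * prior.psi1**2,
        var2=1.0 + c2**2 * prior.psi2**2,
        cov=c1 * c2 * prior.rho * prior.psi1 * prior.psi2,
    )
    alpha = cfg.alpha

    def isf(p):
        if p <= 0:
            return math.inf
        if p >= 1:
            return -math.inf
        return float(norm.isf(p))

    dropped1, dropped2 = r1 <= 0.0, r1 >= 1.0
    b1 = math.inf if dropped1 else isf(alpha)
    b2 = math.inf if dropped2 else isf(alpha)
    if cfg.mode is Mode.UMBRELLA:
        thr = Thresholds(b1=b1, b2=b2)
    else:
        w1e = 0.0 if dropped1 else (1.0 if dropped2 else w1)
        d1 = math.inf if dropped1 else isf(w1e * alpha)
        d2 = math.inf if dropped2 else isf((1.0 - w1e) * alpha)
        thr = Thresholds(b1=b1, b2=b2, d1=d1, d2=d2)
    p1, p2 = rejection_probabilities(pred, thr, cfg.mode)
    lam = cfg.lambda_pop
    return lam * p1 + (1.0 - lam) * p2


def expected_utility_two_stage_mc(
    a1: StageOneParams,
    prior: PriorSpec,
    cfg: TrialConfig,
    n_sims: int = 1000,
    seed: int = 0,
    interim_options: Optional[dict] = None,
    _base: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> Tuple[float, float]:
    """Monte-Carlo Bayes expected utility of first-stage parameters a1.

    For each replicate: draw theta from the prior, draw stage-1 estimates,
    build the interim state and take the *optimized* conditional expected
    utility (backward induction: the interim decision is assumed optimal).
    Returns ``(estimate, standard error)``.

    ``_base`` optionally supplies common random numbers — a pair of (2, B)
    standard-normal arrays for the prior draw and the sampling noise —
    shared across candidate designs to sharpen comparisons.

    ``s1 = 1`` has no second stage: the replicate utility is the closed-form
    single-stage expected utility of ``(r1_1, w1_1)`` (no interim decision
    remains, so the MC average degenerates to the deterministic value).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if a1.s1 >= 1.0:
        val = expected_utility_single_stage((a1.r1_1, a1.w1_1), prior, cfg)
        return val, 0.0

    from .optimize import interim_state_from_estimates, optimize_interim

    if _base is None:
        rng = np.random.default_rng(seed)
        u = rng.standard_normal((2, n_sims))
        e = rng.standard_normal((2, n_sims))
    else:
        u, e = _base
        n_sims = u.shape[1]

    L = np.linalg.cholesky(prior.cov + 1e-15 * np.eye(2))
    theta = prior.mean[:, None] + L @ u
    rs = np.array([a1.r1_1, a1.r2_1])
    opts = interim_options or {}

    vals = np.empty(n_sims)
    for b in range(n_sims):
        ests = [None, None]
        for j in range(2):
            if rs[j] > 0:
                sd = math.sqrt(4.0 * cfg.sigma**2 / (rs[j] * a1.s1 * cfg.n))
                ests[j] = float(theta[j, b] + sd * e[j, b])
        summary = StageSummary(ests[0], ests[1], stage=1)
        state = interim_state_from_estimates(summary, a1, prior, cfg)
        res = optimize_interim(a1, state, prior, cfg, **opts)
        vals[b] = res.value

    est = float(vals.mean())
    se = float(vals.std(ddof=1) / math.sqrt(n_sims)) if n_sims > 1 else 0.0
    return est, se
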