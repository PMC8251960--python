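"""Posterior machinery and expected utilities against independent oracles."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from enrichopt.bayes import (
    PosteriorSpec,
    PredictiveSpec,
    Thresholds,
    conditional_expected_utility,
    expected_utility_single_stage,
    expected_utility_two_stage_mc,
    posterior_update,
    predictive_stage2,
    rejection_probabilities,
    utility,
)
from enrichopt.design import (
    Mode,
    PriorSpec,
    StageOneParams,
    StageSummary,
    StageTwoParams,
    TestResult,
    TrialConfig,
)
from enrichopt.optimize import interim_state_from_estimates


def _mc_single_stage_utility(a, prior, cfg, n, rng):
    """Independent oracle: simulate whole single-stage trials."""
    r1, w1 = a
    theta = rng.multivariate_normal(prior.mean, prior.cov, size=n)
    c1 = math.sqrt(r1 * cfg.n) / (2 * cfg.sigma)
    c2 = math.sqrt((1 - r1) * cfg.n) / (2 * cfg.sigma)
    z1 = c1 * theta[:, 0] + rng.standard_normal(n)
    z2 = c2 * theta[:, 1] + rng.standard_normal(n)
    q = norm.isf(cfg.alpha)
    loc1, loc2 = z1 >= q, z2 >= q
    if cfg.mode is Mode.UMBRELLA:
        g1, g2 = loc1, loc2
    else:
        t1 = norm.isf(w1 * cfg.alpha) if w1 > 0 else np.inf
        t2 = norm.isf((1 - w1) * cfg.alpha) if w1 < 1 else np.inf
        inter = (z1 >= t1) | (z2 >= t2)
        g1, g2 = loc1 & inter, loc2 & inter
    u = cfg.lambda_pop * g1 + (1 - cfg.lambda_pop) * g2
    return u.mean(), u.std(ddof=1) / math.sqrt(n)


class TestUtility:
    @pytest.mark.parametrize(
        "g1,g2,lam,expected",
        [
            (True, False, 0.3, 0.3),
            (False, True, 0.3, 0.7),
            (True, True, 0.42, 1.0),
            (False, False, 0.42, 0.0),
        ],
    )
    def test_prevalence_weighted_indicator(self, g1, g2, lam, expected):
        res = TestResult(g1, g2, g1, g2, True if (g1 or g2) else False)
        assert utility(res, lam) == pytest.approx(expected, abs=1e-15)


class TestPosteriorUpdate:
    def test_no_information_returns_prior(self, we_prior, we_cfg):
        a1 = StageOneParams(s1=1e-12, r1_1=0.4, w1_1=0.4)
        post = posterior_update(
            we_prior, StageSummary(0.4, 0.1), a1, we_cfg
        )
        assert post.m1 == pytest.approx(we_prior.mu1, abs=1e-6)
        assert post.V11 == pytest.approx(we_prior.psi1**2, abs=1e-6)

    def test_independent_prior_factorizes(self, we_cfg):
        prior = PriorSpec(0.1, -0.05, 0.2, 0.3, rho=0.0)
        a1 = StageOneParams(s1=0.5, r1_1=0.4, w1_1=0.4)
        post = posterior_update(prior, StageSummary(0.3, 0.1), a1, we_cfg)
        assert post.V12 == pytest.approx(0.0, abs=1e-14)
        # Margin matches the scalar normal-normal update.
        v = 4 * we_cfg.sigma**2 / (0.4 * 0.5 * we_cfg.n)
        m = (prior.mu1 / prior.psi1**2 + 0.3 / v) / (1 / prior.psi1**2 + 1 / v)
        assert post.m1 == pytest.approx(m, abs=1e-12)

    def test_quadrature_oracle_reference_interim(self, we_prior, we_cfg, we_a1):
        # 2-d numerical integration of prior x likelihood on a dense grid.
        est = (0.442, 0.033)
        post = posterior_update(we_prior, StageSummary(*est), we_a1, we_cfg)
        g = np.linspace(-1.2, 1.6, 701)
        t1, t2 = np.meshgrid(g, g, indexing="ij")
        pts = np.stack([t1.ravel(), t2.ravel()], axis=1)
        pri = multivariate_normal(we_prior.mean, we_prior.cov).pdf(pts)
        lik = norm.pdf(est[0], pts[:, 0], math.sqrt(4 / 140)) * norm.pdf(
            est[1], pts[:, 1], math.sqrt(4 / 210)
        )
        w = pri * lik
        w /= w.sum()
        m1 = float(w @ pts[:, 0])
        m2 = float(w @ pts[:, 1])
        v11 = float(w @ (pts[:, 0] - m1) ** 2)
        v12 = float(w @ ((pts[:, 0] - m1) * (pts[:, 1] - m2)))
        assert post.m1 == pytest.approx(m1, abs=1e-6)
        assert post.m2 == pytest.approx(m2, abs=1e-6)
        assert post.V11 == pytest.approx(v11, abs=1e-6)
        assert post.V12 == pytest.approx(v12, abs=1e-6)

    def test_unsampled_subgroup_contributes_no_likelihood(self, we_prior, we_cfg):
        a1 = StageOneParams(s1=0.5, r1_1=1.0, w1_1=1.0)
        post = posterior_update(we_prior, StageSummary(0.4, None), a1, we_cfg)
        # theta_2 is updated only through the prior correlation.
        a1b = StageOneParams(s1=0.5, r1_1=0.4, w1_1=0.4)
        post_b = posterior_update(we_prior, StageSummary(0.4, 0.4), a1b, we_cfg)
        assert post.V22 > post_b.V22


class TestPredictiveStage2:
    def test_point_mass_posterior_pure_noise(self, we_a1, we_cfg):
        post = PosteriorSpec(0.2, 0.1, 0.0, 0.0, 0.0)
        pred = predictive_stage2(post, StageTwoParams(0.5, 0.5), we_a1, we_cfg)
        assert pred.var1 == pytest.approx(1.0, abs=1e-12)
        assert pred.cov == pytest.approx(0.0, abs=1e-12)

    def test_dropped_subgroup(self, we_a1, we_cfg):
        post = PosteriorSpec(0.2, 0.1, 0.02, 0.02, 0.01)
        pred = predictive_stage2(post, StageTwoParams(0.0, 0.0), we_a1, we_cfg)
        assert pred.mean1 == 0.0 and pred.var1 == 1.0 and pred.cov == 0.0

    def test_monte_carlo_oracle_reference_interim(self, we_prior, we_cfg, we_a1):
        state = interim_state_from_estimates(
            StageSummary(0.442, 0.033), we_a1, we_prior, we_cfg
        )
        a2 = StageTwoParams(0.314, 0.953)
        pred = predictive_stage2(state.post, a2, we_a1, we_cfg)
        rng = np.random.default_rng(3)
        n = 400_000
        theta = rng.multivariate_normal(state.post.mean, state.post.cov, size=n)
        c1 = math.sqrt(a2.r1_2 * 0.5 * we_cfg.n) / 2
        c2 = math.sqrt(a2.r2_2 * 0.5 * we_cfg.n) / 2
        z1 = c1 * theta[:, 0] + rng.standard_normal(n)
        z2 = c2 * theta[:, 1] + rng.standard_normal(n)
        assert pred.mean1 == pytest.approx(z1.mean(), abs=3 * z1.std() / math.sqrt(n))
        assert pred.mean2 == pytest.approx(z2.mean(), abs=3 * z2.std() / math.sqrt(n))
        assert pred.var1 == pytest.approx(z1.var(), rel=0.02)
        assert pred.cov == pytest.approx(np.cov(z1, z2)[0, 1], abs=0.02)


class TestRejectionProbabilities:
    def test_nested_thresholds_reduce_to_univariate(self):
        pred = PredictiveSpec(0.5, 0.0, 1.0, 1.0, 0.0)
        thr = Thresholds(b1=1.0, b2=np.inf, d1=0.5, d2=np.inf)
        p1, p2 = rejection_probabilities(pred, thr, Mode.ENRICHMENT)
        assert p1 == pytest.approx(float(norm.sf(1.0 - 0.5)), abs=1e-10)
        assert p2 == 0.0

    def test_all_infinite_thresholds(self):
        pred = PredictiveSpec(0.0, 0.0, 1.0, 1.0, 0.0)
        thr = Thresholds(b1=np.inf, b2=np.inf, d1=np.inf, d2=np.inf)
        assert rejection_probabilities(pred, thr, Mode.ENRICHMENT) == (0.0, 0.0)

    def test_correlated_monte_carlo_oracle(self):
        pred = PredictiveSpec(0.0, 0.0, 1.0, 1.0, 0.5)
        thr = Thresholds(b1=1.0, b2=1.0, d1=2.0, d2=0.5)
        p1, p2 = rejection_probabilities(pred, thr, Mode.ENRICHMENT)
        rng = np.random.default_rng(9)
        n = 2_000_000
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=n)
        rej1 = (z[:, 0] > 1.0) & ((z[:, 0] > 2.0) | (z[:, 1] > 0.5))
        rej2 = (z[:, 1] > 1.0) & ((z[:, 0] > 2.0) | (z[:, 1] > 0.5))
        for p, hits in ((p1, rej1), (p2, rej2)):
            mc = hits.mean()
            se = math.sqrt(mc * (1 - mc) / n)
            assert abs(p - mc) < 3 * se


class TestSingleStageExpectedUtility:
    def test_null_point_prior_bounded_by_alpha(self, we_cfg):
        prior = PriorSpec(0.0, 0.0, 0.0, 0.0)
        val = expected_utility_single_stage((0.4, 0.5), prior, we_cfg)
        assert val <= we_cfg.alpha + 1e-10

    def test_certain_rejection_limit(self, we_cfg):
        prior = PriorSpec(3.0, 3.0, 1e-6, 1e-6)
        val = expected_utility_single_stage((0.5, 0.5), prior, we_cfg)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_monte_carlo_oracle(self, we_cfg):
        prior = PriorSpec(0.1, 0.0, 0.2, 0.2, rho=0.5)
        val = expected_utility_single_stage((0.3, 0.5), prior, we_cfg)
        rng = np.random.default_rng(13)
        mc, se = _mc_single_stage_utility((0.3, 0.5), prior, we_cfg, 200_000, rng)
        assert abs(val - mc) < 3 * se

    def test_umbrella_rho_invariance(self):
        cfg = TrialConfig(n=700, lambda_pop=0.3, mode="umbrella")
        vals = [
            expected_utility_single_stage(
                (0.4, 0.5), PriorSpec(0.1, 0.0, 0.2, 0.2, rho), cfg
            )
            for rho in (-0.8, 0.0, 0.8)
        ]
        assert max(vals) - min(vals) <= 1e-10

    def test_enrichment_never_beats_umbrella(self, we_prior):
        enr = TrialConfig(n=700, lambda_pop=0.3, mode="enrichment")
        umb = TrialConfig(n=700, lambda_pop=0.3, mode="umbrella")
        for r1, w1 in [(0.3, 0.5), (0.5, 0.2), (0.7, 0.9)]:
            assert expected_utility_single_stage(
                (r1, w1), we_prior, enr
            ) <= expected_utility_single_stage((r1, w1), we_prior, umb) + 1e-12


class TestConditionalExpectedUtility:
    def test_null_posterior_bounded_by_alpha(self, we_a1, we_cfg, we_prior):
        from enrichopt.optimize import InterimState
        from enrichopt.testing import conditional_errors

        ce = conditional_errors(0.0, 0.0, we_a1, we_cfg)
        state = InterimState(0.0, 0.0, ce, PosteriorSpec(0, 0, 0, 0, 0))
        w2 = conditional_expected_utility(
            StageTwoParams(0.4, 0.4), we_a1, state, we_prior, we_cfg
        )
        # With theta = 0 for sure, the rejection chance is the conditional
        # error budget; the utility mixes two rates bounded by A1 and A2.
        assert w2 <= max(ce.A1, ce.A2, ce.A12) + 1e-10

    def test_monte_carlo_oracle_reference_interim(self, we_prior, we_cfg, we_a1):
        state = interim_state_from_estimates(
            StageSummary(0.442, 0.033), we_a1, we_prior, we_cfg
        )
        a2 = StageTwoParams(0.314, 0.953)
        w2 = conditional_expected_utility(a2, we_a1, state, we_prior, we_cfg)
        rng = np.random.default_rng(29)
        n = 400_000
        theta = rng.multivariate_normal(state.post.mean, state.post.cov, size=n)
        c1 = math.sqrt(a2.r1_2 * 0.5 * we_cfg.n) / 2
        c2 = math.sqrt(a2.r2_2 * 0.5 * we_cfg.n) / 2
        z1 = c1 * theta[:, 0] + rng.standard_normal(n)
        z2 = c2 * theta[:, 1] + rng.standard_normal(n)
        ce = state.ce
        loc1 = z1 > norm.isf(ce.A1)
        loc2 = z2 > norm.isf(ce.A2)
        inter = (z1 > norm.isf(a2.w1_2 * ce.A12)) | (z2 > norm.isf(a2.w2_2 * ce.A12))
        u = we_cfg.lambda_pop * (loc1 & inter) + (1 - we_cfg.lambda_pop) * (loc2 & inter)
        se = u.std(ddof=1) / math.sqrt(n)
        assert abs(w2 - u.mean()) < 3 * se

    def test_continuous_in_stage_two_parameters(self, we_prior, we_cfg, we_a1):
        state = interim_state_from_estimates(
            StageSummary(0.3, 0.1), we_a1, we_prior, we_cfg
        )
        base = conditional_expected_utility(
            StageTwoParams(0.4, 0.5), we_a1, state, we_prior, we_cfg
        )
        for dr, dw in [(1e-5, 0), (0, 1e-5), (-1e-5, 1e-5)]:
            v = conditional_expected_utility(
                StageTwoParams(0.4 + dr, 0.5 + dw), we_a1, state, we_prior, we_cfg
            )
            assert abs(v - base) < 1e-3


class TestOracleGrid:
    def test_closed_forms_match_mc_on_random_grid(self, we_cfg):
        # 10 random parameter points, each checked against a trial-level
        # Monte-Carlo oracle within 3 standard errors.
        rng = np.random.default_rng(101)
        for _ in range(10):
            prior = PriorSpec(
                mu1=float(rng.uniform(-0.1, 0.3)),
                mu2=float(rng.uniform(-0.1, 0.3)),
                psi1=float(rng.uniform(0.05, 0.4)),
                psi2=float(rng.uniform(0.05, 0.4)),
                rho=float(rng.uniform(-0.8, 0.8)),
            )
            r1 = float(rng.uniform(0.1, 0.9))
            w1 = float(rng.uniform(0.0, 1.0))
            val = expected_utility_single_stage((r1, w1), prior, we_cfg)
            mc, se = _mc_single_stage_utility((r1, w1), prior, we_cfg, 100_000, rng)
            assert abs(val - mc) < 3 * max(se, 1e-5)


class TestTwoStageMc:
    def test_deterministic_given_seed(self, we_prior, we_cfg, we_a1):
        opts = {"starts": [[we_a1.r1_1, we_a1.w1_1]], "tol": 1e-3}
        a = expected_utility_two_stage_mc(
            we_a1, we_prior, we_cfg, n_sims=30, seed=4, interim_options=opts
        )
        b = expected_utility_two_stage_mc(
            we_a1, we_prior, we_cfg, n_sims=30, seed=4, interim_options=opts
        )
        assert a == b
        assert 0.0 <= a[0] <= 1.0
        assert a[1] > 0

    def test_degenerates_to_single_stage_without_interim(self, we_prior, we_cfg):
        a1 = StageOneParams(s1=1.0, r1_1=0.4, w1_1=0.4)
        est, se = expected_utility_two_stage_mc(a1, we_prior, we_cfg, n_sims=10, seed=0)
        assert est == pytest.approx(
            expected_utility_single_stage((0.4, 0.4), we_prior, we_cfg), abs=1e-12
        )
        assert se == 0.0
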