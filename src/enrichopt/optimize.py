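"""Design optimization: single-stage, interim decision, and stage-1 search.

Three layers, following the backward-induction principle:

1. ``optimize_single_stage`` — maximize the closed-form Bayes expected
   utility over (r1, w1) (umbrella: r1 only) by a coarse grid plus local
   derivative-free refinement.
2. ``optimize_interim`` — at the interim, maximize the conditional expected
   utility W2 over the second-stage parameters (r1_2, w1_2) with a
   Hooke-Jeeves pattern search, multi-started because the utility surface
   can be multimodal near the weight boundaries.
3. ``optimize_stage1`` — Monte-Carlo backward induction over a grid of
   candidate first-stage parameters, assuming the interim decision will be
   optimal, with common random numbers across candidates.

``adaptation_rule_map`` tabulates the optimal interim decision over a grid
of stage-1 Z-value pairs, the form in which adaptation rules are inspected
(and in which the simulator consumes them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._bvn import bvn_upper
from .bayes import (
    PosteriorSpec,
    conditional_expected_utility,
    expected_utility_single_stage,
    expected_utility_two_stage_mc,
    posterior_update,
)
from .design import (
    Mode,
    PriorSpec,
    StageOneParams,
    StageSummary,
    StageTwoParams,
    TrialConfig,
    coupled_stage_two,
    z_statistic,
)
from .testing import ConditionalErrors, conditional_errors

__all__ = [
    "InterimState",
    "OptimResult",
    "interim_state_from_estimates",
    "interim_state_from_z",
    "pattern_search",
    "optimize_single_stage",
    "optimize_interim",
    "optimize_stage1",
    "adaptation_rule_map",
    "UNSTABLE_UTILITY_THRESHOLD",
]

#: Below this maximum conditional expected utility the interim optimization
#: is flagged unstable (essentially no rejection chance remains) and the
#: no-adaptation parameters are returned.
UNSTABLE_UTILITY_THRESHOLD = 0.01


@dataclass(frozen=True)
class InterimState:
    """Everything the interim decision depends on.

    Stage-1 Z-values (``None`` for an unsampled subgroup), the conditional
    error rates computed with the stage-1 weights, and the posterior of the
    treatment effects given the stage-1 estimates.
    """

    z1_1: Optional[float]
    z2_1: Optional[float]
    ce: ConditionalErrors
    post: PosteriorSpec


@dataclass(frozen=True)
class OptimResult:
    """Outcome of one optimization run."""

    params: dict
    value: float
    gain: Optional[float] = None
    se: Optional[float] = None
    stable: bool = True
    n_evals: int = 0

    def stage_two(self) -> StageTwoParams:
        return coupled_stage_two(
            self.params["r1_2"], self.params.get("w1_2", 0.5)
        )


def interim_state_from_estimates(
    stage1: StageSummary,
    a1: StageOneParams,
    prior: PriorSpec,
    cfg: TrialConfig,
) -> InterimState:
    """Build the interim state from stage-1 effect estimates."""
    z1 = (
        z_statistic(stage1.theta_hat_1, a1.r1_1, a1.s1, cfg)
        if a1.r1_1 > 0 and stage1.theta_hat_1 is not None
        else None
    )
    z2 = (
        z_statistic(stage1.theta_hat_2, a1.r2_1, a1.s1, cfg)
        if a1.r1_1 < 1 and stage1.theta_hat_2 is not None
        else None
    )
    ce = conditional_errors(z1, z2, a1, cfg)
    post = posterior_update(prior, stage1, a1, cfg)
    return InterimState(z1_1=z1, z2_1=z2, ce=ce, post=post)


def interim_state_from_z(
    z1: Optional[float],
    z2: Optional[float],
    a1: StageOneParams,
    prior: PriorSpec,
    cfg: TrialConfig,
) -> InterimState:
    """Build the interim state from stage-1 Z-values (estimates implied)."""
    est1 = est2 = None
    if z1 is not None:
        est1 = 2.0 * cfg.sigma * z1 / math.sqrt(a1.r1_1 * a1.s1 * cfg.n)
    if z2 is not None:
        est2 = 2.0 * cfg.sigma * z2 / math.sqrt(a1.r2_1 * a1.s1 * cfg.n)
    return interim_state_from_estimates(
        StageSummary(est1, est2, stage=1), a1, prior, cfg
    )


def pattern_search(
    f: Callable[[np.ndarray], float],
    x0: Sequence[float],
    bounds: Sequence[Tuple[float, float]],
    step0: float = 0.25,
    tol: float = 1e-4,
    shrink: float = 0.5,
    max_evals: int = 10000,
) -> Tuple[np.ndarray, float, int]:
    """Hooke-Jeeves pattern search maximizing ``f`` on a box.

    Exploratory coordinate moves around the base point, followed by a
    pattern (acceleration) move when the exploration improves; the step is
    halved on failure and the search stops when it falls below ``tol``.
    Iterates are clipped to the box.  Returns (argmax, value, n_evals).
    """
    lo = np.array([b[0] for b in bounds], float)
    hi = np.array([b[1] for b in bounds], float)
    x = np.clip(np.asarray(x0, float), lo, hi)
    n_evals = 0

    def ev(p):
        nonlocal n_evals
        n_evals += 1
        return f(p)

    fx = ev(x)
    step = step0
    while step >= tol and n_evals < max_evals:
        # Exploratory move around x.
        xe, fe = x.copy(), fx
        for i in range(len(x)):
            for d in (step, -step):
                trial = xe.copy()
                trial[i] = min(max(trial[i] + d, lo[i]), hi[i])
                if trial[i] == xe[i]:
                    continue
                ft = ev(trial)
                if ft > fe:
                    xe, fe = trial, ft
                    break
        if fe > fx:
            # Pattern move: extrapolate along the successful direction.
            while n_evals < max_evals:
                xp = np.clip(xe + (xe - x), lo, hi)
                x, fx = xe, fe
                if np.allclose(xp, xe):
                    break
                fp = ev(xp)
                if fp > fx:
                    xe, fe = xp, fp
                else:
                    break
        else:
            step *= shrink
    return x, fx, n_evals


def _single_stage_grid(
    prior: PriorSpec, cfg: TrialConfig, step: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized closed-form utility on a (r1, w1) grid."""
    r = np.arange(0.0, 1.0 + step / 2, step)
    if cfg.mode is Mode.UMBRELLA:
        w = np.array([0.5])
    else:
        w = np.arange(0.0, 1.0 + step / 2, step)
    R, W = np.meshgrid(r, w, indexing="ij")
    # Boundary coupling.
    W = np.where(R >= 1.0, 1.0, np.where(R <= 0.0, 0.0, W))

    c1 = np.sqrt(R * cfg.n) / (2.0 * cfg.sigma)
    c2 = np.sqrt((1.0 - R) * cfg.n) / (2.0 * cfg.sigma)
    m1, m2 = c1 * prior.mu1, c2 * prior.mu2
    v1 = 1.0 + c1**2 * prior.psi1**2
    v2 = 1.0 + c2**2 * prior.psi2**2
    cv = c1 * c2 * prior.rho * prior.psi1 * prior.psi2
    alpha = cfg.alpha
    q = norm.isf(alpha)

    def isf(p):
        with np.errstate(divide="ignore"):
            return np.where(p > 0, norm.isf(np.clip(p, 1e-300, 1)), np.inf)

    b1 = np.where(R <= 0, np.inf, q)
    b2 = np.where(R >= 1, np.inf, q)
    if cfg.mode is Mode.UMBRELLA:
        p1 = np.where(R <= 0, 0.0, norm.sf((b1 - m1) / np.sqrt(v1)))
        p2 = np.where(R >= 1, 0.0, norm.sf((b2 - m2) / np.sqrt(v2)))
    else:
        d1 = np.where(R <= 0, np.inf, isf(W * alpha))
        d2 = np.where(R >= 1, np.inf, isf((1.0 - W) * alpha))
        md1 = np.maximum(b1, d1)
        md2 = np.maximum(b2, d2)
        p1 = (
            norm.sf((md1 - m1) / np.sqrt(v1))
            + bvn_upper(b1, d2, m1, m2, v1, v2, cv)
            - bvn_upper(md1, d2, m1, m2, v1, v2, cv)
        )
        p2 = (
            norm.sf((md2 - m2) / np.sqrt(v2))
            + bvn_upper(d1, b2, m1, m2, v1, v2, cv)
            - bvn_upper(d1, md2, m1, m2, v1, v2, cv)
        )
    lam = cfg.lambda_pop
    U = lam * np.clip(p1, 0, 1) + (1 - lam) * np.clip(p2, 0, 1)
    return R, W, U


def optimize_single_stage(
    prior: PriorSpec,
    cfg: TrialConfig,
    grid_step: float = 0.01,
    refine: bool = True,
    tol: float = 1e-5,
) -> OptimResult:
    """Bayes-optimal single-stage design over (r1, w1) (umbrella: r1).

    Coarse vectorized grid (default step 0.01) followed by Hooke-Jeeves
    refinement from the best grid point; boundary designs r1 in {0, 1} are
    evaluated with the forced weights.
    """
    R, W, U = _single_stage_grid(prior, cfg, grid_step)
    idx = np.unravel_index(np.argmax(U), U.shape)
    r_best, w_best, u_best = float(R[idx]), float(W[idx]), float(U[idx])
    n_evals = U.size

    umbrella = cfg.mode is Mode.UMBRELLA
    if refine:
        if umbrella:
            def f(x):
                return expected_utility_single_stage((x[0], 1.0 if x[0] >= 1 else (0.0 if x[0] <= 0 else 0.5)), prior, cfg)

            x, val, ne = pattern_search(
                f, [r_best], [(0.0, 1.0)], step0=grid_step, tol=tol
            )
            r_best, u_best = float(x[0]), val
        else:
            def f(x):
                r, w = x
                if r >= 1:
                    w = 1.0
                elif r <= 0:
                    w = 0.0
                return expected_utility_single_stage((r, w), prior, cfg)

            x, val, ne = pattern_search(
                f, [r_best, w_best], [(0.0, 1.0)] * 2, step0=grid_step, tol=tol
            )
            r_best, w_best, u_best = float(x[0]), float(x[1]), val
        n_evals += ne

    if r_best >= 1:
        w_best = 1.0
    elif r_best <= 0:
        w_best = 0.0
    params = {"r1": r_best}
    if not umbrella:
        params["w1"] = w_best
    return OptimResult(params=params, value=u_best, n_evals=n_evals)


def _default_interim_starts(
    a1: StageOneParams, umbrella: bool
) -> list:
    if umbrella:
        return [[a1.r1_1], [0.25], [0.75]]
    return [
        [a1.r1_1, a1.w1_1],
        [0.25, 0.25],
        [0.25, 0.75],
        [0.75, 0.25],
        [0.75, 0.75],
    ]


def optimize_interim(
    a1: StageOneParams,
    interim: InterimState,
    prior: PriorSpec,
    cfg: TrialConfig,
    starts: Optional[Iterable[Sequence[float]]] = None,
    extra_starts: Optional[Iterable[Sequence[float]]] = None,
    tol: float = 1e-4,
    step0: float = 0.25,
) -> OptimResult:
    """Bayes-optimal second-stage parameters given the interim state.

    Maximizes W2 over (r1_2, w1_2) in [0,1]^2 (umbrella: r1_2 only) with a
    multi-start Hooke-Jeeves pattern search; the no-adaptation point is
    always a start, so the gain over continuing unchanged is >= 0 up to the
    search tolerance.  If the attained maximum is below 0.01 the surface is
    essentially flat at zero (no realistic rejection chance remains): the
    result is flagged unstable and the no-adaptation parameters returned.
    """
    umbrella = cfg.mode is Mode.UMBRELLA

    def make_a2(x) -> StageTwoParams:
        if umbrella:
            r = min(max(float(x[0]), 0.0), 1.0)
            w = 1.0 if r >= 1 else (0.0 if r <= 0 else 0.5)
            return StageTwoParams(r1_2=r, w1_2=w)
        return coupled_stage_two(float(x[0]), float(x[1]))

    def f(x) -> float:
        return conditional_expected_utility(make_a2(x), a1, interim, prior, cfg)

    no_adapt_x = [a1.r1_1] if umbrella else [a1.r1_1, a1.w1_1]
    w2_no_adapt = f(no_adapt_x)

    start_list = list(starts) if starts is not None else _default_interim_starts(a1, umbrella)
    if extra_starts is not None:
        start_list = list(extra_starts) + start_list

    ndim = 1 if umbrella else 2
    bounds = [(0.0, 1.0)] * ndim
    best_x, best_v, total_evals = None, -np.inf, 1
    for x0 in start_list:
        x, v, ne = pattern_search(f, x0, bounds, step0=step0, tol=tol)
        total_evals += ne
        if v > best_v:
            best_x, best_v = x, v

    if best_v < UNSTABLE_UTILITY_THRESHOLD:
        a2 = make_a2(no_adapt_x)
        params = {"r1_2": a2.r1_2}
        if not umbrella:
            params["w1_2"] = a2.w1_2
        return OptimResult(
            params=params,
            value=w2_no_adapt,
            gain=0.0,
            stable=False,
            n_evals=total_evals,
        )

    a2 = make_a2(best_x)
    params = {"r1_2": a2.r1_2}
    if not umbrella:
        params["w1_2"] = a2.w1_2
    return OptimResult(
        params=params,
        value=best_v,
        gain=best_v - w2_no_adapt,
        stable=True,
        n_evals=total_evals,
    )


def default_stage1_grid(cfg: TrialConfig) -> list:
    """Default candidate grid: s1 in 0.1..0.9, r1 and w1 in 0..1, step 0.1."""
    umbrella = cfg.mode is Mode.UMBRELLA
    cands = []
    for s1 in np.round(np.arange(0.1, 0.95, 0.1), 10):
        for r1 in np.round(np.arange(0.0, 1.05, 0.1), 10):
            if umbrella:
                w = 1.0 if r1 == 1 else (0.0 if r1 == 0 else 0.5)
                cands.append(StageOneParams(s1=float(s1), r1_1=float(r1), w1_1=w))
            elif r1 == 1.0:
                cands.append(StageOneParams(s1=float(s1), r1_1=1.0, w1_1=1.0))
            elif r1 == 0.0:
                cands.append(StageOneParams(s1=float(s1), r1_1=0.0, w1_1=0.0))
            else:
                for w1 in np.round(np.arange(0.0, 1.05, 0.1), 10):
                    cands.append(
                        StageOneParams(s1=float(s1), r1_1=float(r1), w1_1=float(w1))
                    )
    return cands


def optimize_stage1(
    prior: PriorSpec,
    cfg: TrialConfig,
    grid: Optional[Sequence[StageOneParams]] = None,
    n_sims: int = 1000,
    seed: int = 0,
    interim_options: Optional[dict] = None,
) -> OptimResult:
    """Bayes-optimal first-stage parameters by Monte-Carlo backward induction.

    Each candidate a1 is scored by ``expected_utility_two_stage_mc`` with
    common random numbers (the same prior draws and sampling noise for every
    candidate), so that candidate comparisons are not swamped by independent
    MC noise.  Ties (exact value ties) break toward smaller s1, then r1
    closer to the population prevalence.  Returns the argmax with its MC SE
    and the full candidate table in ``params['table']``.
    """
    cands = list(grid) if grid is not None else default_stage1_grid(cfg)
    if not cands:
        raise ValueError("candidate grid is empty")
    rng = np.random.default_rng(seed)
    base = (rng.standard_normal((2, n_sims)), rng.standard_normal((2, n_sims)))

    rows = []
    for a1 in cands:
        est, se = expected_utility_two_stage_mc(
            a1, prior, cfg, interim_options=interim_options, _base=base
        )
        rows.append(
            {"s1": a1.s1, "r1_1": a1.r1_1, "w1_1": a1.w1_1, "value": est, "se": se}
        )
    table = pd.DataFrame(rows)
    order = table.sort_values(
        by=["value", "s1", "r1_1"],
        ascending=[False, True, True],
        key=lambda col: (
            col
            if col.name != "r1_1"
            else (col - cfg.lambda_pop).abs()
        ),
    )
    best = order.iloc[0]
    params = {
        "s1": float(best["s1"]),
        "r1_1": float(best["r1_1"]),
        "w1_1": float(best["w1_1"]),
        "table": table,
    }
    return OptimResult(
        params=params,
        value=float(best["value"]),
        se=float(best["se"]),
        n_evals=len(cands) * n_sims,
    )


def adaptation_rule_map(
    a1: StageOneParams,
    prior: PriorSpec,
    cfg: TrialConfig,
    z_grid: Iterable[Tuple[float, float]],
    tol: float = 1e-4,
    warm_start: bool = True,
) -> pd.DataFrame:
    """Optimal interim decision tabulated over stage-1 Z-value pairs.

    For each (z1, z2) the interim state is reconstructed and the interim
    optimization run; rows hold the optimal a2, the attained W2, the gain
    over no adaptation, and the stability flag.  Consecutive grid points
    warm-start from the previous optimum (the optimal surface is mostly
    smooth), which does not change the estimand — the no-adaptation and
    default starts are always retained.
    """
    umbrella = cfg.mode is Mode.UMBRELLA
    rows = []
    prev = None
    for z1, z2 in z_grid:
        state = interim_state_from_z(z1, z2, a1, prior, cfg)
        extra = [prev] if (warm_start and prev is not None) else None
        res = optimize_interim(
            a1, state, prior, cfg, extra_starts=extra, tol=tol
        )
        row = {
            "z1": z1,
            "z2": z2,
            "r1_2": res.params["r1_2"],
            "value": res.value,
            "gain": res.gain,
            "stable": res.stable,
        }
        if not umbrella:
            row["w1_2"] = res.params["w1_2"]
        rows.append(row)
        if res.stable:
            prev = (
                [res.params["r1_2"]]
                if umbrella
                else [res.params["r1_2"], res.params["w1_2"]]
            )
    return pd.DataFrame(rows)
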