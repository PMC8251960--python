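"""Hypothesis testing: closed test, conditional error rates, adaptive tests.

Enrichment mode uses the closed testing principle with a weighted Bonferroni
test of the intersection H01 ∩ H02: H0j is rejected *globally* iff both its
individual level-alpha test and the intersection test reject.  Umbrella mode
tests each hypothesis at level alpha with no multiplicity adjustment.

For two-stage designs the reference design pools the stage-wise data.  When
the interim analysis changes prevalences or weights, the second-stage tests
are calibrated to the *conditional error rates* of the reference tests given
the stage-1 data — the conditional probabilities, under the null, that the
pooled reference tests would have rejected.  Preserving these rates preserves
the type I error of every test in the closure, for any data-dependent
adaptation rule.

The conditional error rate of the intersection test combines the two
subgroup components as ``1 - (1 - p1)(1 - p2)``: the stage-wise statistics of
the two subgroups are independent because the subgroups are disjoint (no
patient contributes to both), an assumption stated rather than silent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy.stats import norm

from .design import (
    Mode,
    StageOneParams,
    StageSummary,
    StageTwoParams,
    TestResult,
    TrialConfig,
    pooled_z,
    z_statistic,
)

__all__ = [
    "ConditionalErrors",
    "single_stage_test",
    "conditional_error_individual",
    "conditional_error_intersection",
    "conditional_errors",
    "adaptive_final_test",
    "reference_final_test",
    "NO_ADAPTATION_TOL",
]

#: Exact-equality tolerance used to detect "no adaptation was made".
NO_ADAPTATION_TOL = 1e-12


@dataclass(frozen=True)
class ConditionalErrors:
    """Conditional error rates of the reference tests given stage-1 data.

    ``A1``/``A2`` for the individual tests of H01/H02; ``A12`` for the
    weighted Bonferroni intersection test (``None`` in umbrella mode).
    """

    A1: float
    A2: float
    A12: Optional[float] = None

    def __post_init__(self):
        for name in ("A1", "A2", "A12"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _isf(p: float) -> float:
    """Upper-tail standard normal quantile; p = 0 -> +inf, p = 1 -> -inf."""
    if p <= 0.0:
        return math.inf
    if p >= 1.0:
        return -math.inf
    return float(norm.isf(p))


def _effective_weights(w1: float, z1_absent: bool, z2_absent: bool):
    """Force the degenerate-weight convention for unsampled subgroups."""
    if z1_absent and z2_absent:
        raise ValueError("at least one subgroup must be sampled")
    if z1_absent:
        return 0.0, 1.0
    if z2_absent:
        return 1.0, 0.0
    return w1, 1.0 - w1


def single_stage_test(
    z1: Optional[float],
    z2: Optional[float],
    w1: float,
    cfg: TrialConfig,
) -> TestResult:
    """Closed weighted-Bonferroni test of single-stage (or pooled) Z-values.

    ``None`` for a Z-value marks an unsampled subgroup: its hypothesis is
    never rejected and the full intersection weight flows to the other
    subgroup.  Thresholds use '>=' (the single-stage convention).
    """
    alpha = cfg.alpha
    q = _isf(alpha)
    loc1 = z1 is not None and z1 >= q
    loc2 = z2 is not None and z2 >= q

    if cfg.mode is Mode.UMBRELLA:
        return TestResult(loc1, loc2, loc1, loc2, None)

    w1e, w2e = _effective_weights(w1, z1 is None, z2 is None)
    inter = (z1 is not None and z1 >= _isf(w1e * alpha)) or (
        z2 is not None and z2 >= _isf(w2e * alpha)
    )
    return TestResult(loc1 and inter, loc2 and inter, loc1, loc2, inter)


def conditional_error_individual(z_stage1, s1: float, alpha: float):
    """Conditional error rate A_j of the individual reference test.

    Given the stage-1 Z-value, the pooled statistic satisfies
    ``Z_p | Z_1, theta = 0 ~ N(sqrt(s1) Z_1, 1 - s1)``, so

        A_j = 1 - Phi( (Phi^-1(1-alpha) - sqrt(s1) Z_1) / sqrt(1 - s1) ).

    Vectorized over ``z_stage1``.
    """
    if not 0 < s1 < 1:
        raise ValueError(f"s1 must be strictly inside (0, 1), got {s1}")
    q = norm.isf(alpha)
    import numpy as np

    z = np.asarray(z_stage1, dtype=float)
    out = norm.sf((q - math.sqrt(s1) * z) / math.sqrt(1.0 - s1))
    return out if out.ndim else float(out)


def _component_exceedance(z_stage1, s1: float, level) -> float:
    """P(Z_p > Phi^-1(1 - level) | Z_1, theta = 0); level = 0 gives 0."""
    import numpy as np

    lvl = np.asarray(level, dtype=float)
    z = np.asarray(z_stage1, dtype=float)
    q = np.where(lvl > 0, norm.isf(np.clip(lvl, 1e-300, 1.0)), np.inf)
    with np.errstate(invalid="ignore"):
        p = norm.sf((q - math.sqrt(s1) * z) / math.sqrt(1.0 - s1))
    return np.where(lvl > 0, p, 0.0)


def conditional_error_intersection(
    z1, z2, s1: float, w1: float, alpha: float
):
    """Conditional error rate A_12 of the weighted Bonferroni intersection.

    ``A12 = P(Z1_p > Phi^-1(1 - w1 a) or Z2_p > Phi^-1(1 - w2 a) | Z^(1))``
    under the global null, computed as ``1 - (1 - p1)(1 - p2)`` by
    independence of the two subgroups' statistics (disjoint patients).

    ``None`` for a stage-1 Z-value (unsampled subgroup) forces the
    degenerate weights: the whole level flows to the sampled subgroup.
    Vectorized over ``z1``/``z2`` when both are arrays.
    """
    if not 0 < s1 < 1:
        raise ValueError(f"s1 must be strictly inside (0, 1), got {s1}")
    if not 0 <= w1 <= 1:
        raise ValueError(f"w1 must be in [0, 1], got {w1}")
    w1e, w2e = _effective_weights(w1, z1 is None, z2 is None)
    p1 = _component_exceedance(z1, s1, w1e * alpha) if z1 is not None else 0.0
    p2 = _component_exceedance(z2, s1, w2e * alpha) if z2 is not None else 0.0
    out = 1.0 - (1.0 - p1) * (1.0 - p2)
    import numpy as np

    out = np.asarray(out)
    return out if out.ndim else float(out)


def conditional_errors(
    z1: Optional[float],
    z2: Optional[float],
    a1: StageOneParams,
    cfg: TrialConfig,
) -> ConditionalErrors:
    """All conditional error rates at the interim, from stage-1 Z-values."""
    s1, alpha = a1.s1, cfg.alpha
    A1 = conditional_error_individual(z1, s1, alpha) if z1 is not None else 0.0
    A2 = conditional_error_individual(z2, s1, alpha) if z2 is not None else 0.0
    if cfg.mode is Mode.UMBRELLA:
        return ConditionalErrors(A1=A1, A2=A2, A12=None)
    A12 = conditional_error_intersection(z1, z2, s1, a1.w1_1, alpha)
    return ConditionalErrors(A1=A1, A2=A2, A12=A12)


def adaptive_final_test(
    z1_stage2: Optional[float],
    z2_stage2: Optional[float],
    ce: ConditionalErrors,
    a2: StageTwoParams,
    cfg: TrialConfig,
) -> TestResult:
    """Final tests based on stage-2 data alone at the conditional error rates.

    H0j is rejected locally iff ``Zj_2 > Phi^-1(1 - Aj)`` (strict '>', the
    adaptive-test convention); in enrichment mode the intersection is
    rejected iff ``Z1_2 > Phi^-1(1 - w1_2 A12)`` or the analogue for
    subgroup 2.  ``Aj = 0`` gives a +inf threshold (never reject).  A
    subgroup with zero stage-2 prevalence is never rejected and its
    intersection weight is forced to the retained subgroup.
    """
    r1 = a2.r1_2
    if z1_stage2 is None and r1 > 0:
        raise ValueError("subgroup 1 has positive stage-2 prevalence but no Z-value")
    if z2_stage2 is None and r1 < 1:
        raise ValueError("subgroup 2 has positive stage-2 prevalence but no Z-value")

    loc1 = z1_stage2 is not None and z1_stage2 > _isf(ce.A1)
    loc2 = z2_stage2 is not None and z2_stage2 > _isf(ce.A2)

    if cfg.mode is Mode.UMBRELLA:
        return TestResult(loc1, loc2, loc1, loc2, None)

    if ce.A12 is None:
        raise ValueError("enrichment-mode test requires A12")
    w1e, w2e = _effective_weights(
        a2.w1_2, z1_stage2 is None, z2_stage2 is None
    )
    inter = (
        z1_stage2 is not None and z1_stage2 > _isf(w1e * ce.A12)
    ) or (z2_stage2 is not None and z2_stage2 > _isf(w2e * ce.A12))
    return TestResult(loc1 and inter, loc2 and inter, loc1, loc2, inter)


def reference_final_test(
    stage1: StageSummary,
    stage2: StageSummary,
    a1: StageOneParams,
    cfg: TrialConfig,
) -> TestResult:
    """Pooled reference test, applicable only when no adaptation was made.

    Pools each subgroup's stage-wise estimates with weights (s1, 1 - s1) and
    applies the single-stage closed test to the pooled Z-values with the
    stage-1 Bonferroni weight.
    """
    s1 = a1.s1
    zp1 = zp2 = None
    if a1.r1_1 > 0:
        if stage1.theta_hat_1 is None or stage2.theta_hat_1 is None:
            raise ValueError("subgroup 1 sampled but estimate missing")
        z1_1 = z_statistic(stage1.theta_hat_1, a1.r1_1, s1, cfg)
        z1_2 = z_statistic(stage2.theta_hat_1, a1.r1_1, 1.0 - s1, cfg)
        zp1 = pooled_z(z1_1, z1_2, s1)
    if a1.r1_1 < 1:
        if stage1.theta_hat_2 is None or stage2.theta_hat_2 is None:
            raise ValueError("subgroup 2 sampled but estimate missing")
        z2_1 = z_statistic(stage1.theta_hat_2, a1.r2_1, s1, cfg)
        z2_2 = z_statistic(stage2.theta_hat_2, a1.r2_1, 1.0 - s1, cfg)
        zp2 = pooled_z(z2_1, z2_2, s1)
    return single_stage_test(zp1, zp2, a1.w1_1, cfg)


def is_no_adaptation(a1: StageOneParams, a2: StageTwoParams, mode: Mode) -> bool:
    """True iff a2 equals a1's corresponding components to 1e-12."""
    same_r = abs(a2.r1_2 - a1.r1_1) <= NO_ADAPTATION_TOL
    if mode is Mode.UMBRELLA:
        return same_r
    return same_r and abs(a2.w1_2 - a1.w1_1) <= NO_ADAPTATION_TOL
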