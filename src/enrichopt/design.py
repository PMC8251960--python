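"""Domain types and elementary trial statistics.

A trial recruits ``n`` patients from two disjoint biomarker subgroups with a
normally distributed endpoint (SD ``sigma``), randomized 1:1 between treatment
and control within each subgroup and stage.  The treatment effect in subgroup
``j`` is the mean difference ``theta_j``; the one-sided null hypotheses are
``H_0j: theta_j <= 0``.  Two modes are supported:

* ``enrichment`` — familywise error control via closed testing with a
  weighted Bonferroni intersection test;
* ``umbrella`` — per-comparison control only, no intersection test.

Sample sizes are treated as continuous information fractions throughout
(``r * s * n`` need not be an integer); the simulator rounds to whole patients
only when generating patient-level data, an O(1/n) discrepancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

__all__ = [
    "Mode",
    "TrialConfig",
    "PriorSpec",
    "StageOneParams",
    "StageTwoParams",
    "StageSummary",
    "TestResult",
    "ZeroSampleError",
    "z_statistic",
    "pooled_z",
]


class ZeroSampleError(ValueError):
    """Raised when a Z-value is requested for a subgroup that was not sampled."""


class Mode(str, Enum):
    ENRICHMENT = "enrichment"
    UMBRELLA = "umbrella"


def _as_mode(mode) -> Mode:
    if isinstance(mode, Mode):
        return mode
    return Mode(str(mode).lower())


@dataclass(frozen=True)
class TrialConfig:
    """Global constants of a trial.

    Parameters
    ----------
    n : total sample size (patients across both stages and subgroups).
    sigma : outcome standard deviation (common to all patients).
    alpha : one-sided significance level (FWER in enrichment mode,
        per-comparison level in umbrella mode).
    lambda_pop : population prevalence of subgroup 1, in (0, 1).
    mode : "enrichment" or "umbrella".
    """

    n: float
    sigma: float = 1.0
    alpha: float = 0.05
    lambda_pop: float = 0.5
    mode: Mode = Mode.ENRICHMENT

    def __post_init__(self):
        object.__setattr__(self, "mode", _as_mode(self.mode))
        if not self.n > 0:
            raise ValueError(f"n must be > 0, got {self.n}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.lambda_pop < 1:
            raise ValueError(
                f"lambda_pop must be in (0, 1), got {self.lambda_pop}"
            )


@dataclass(frozen=True)
class PriorSpec:
    """Bivariate normal prior on the subgroup treatment effects.

    ``theta ~ N((mu1, mu2), [[psi1^2, rho psi1 psi2], [rho psi1 psi2, psi2^2]])``
    """

    mu1: float
    mu2: float
    psi1: float
    psi2: float
    rho: float = 0.0

    def __post_init__(self):
        if self.psi1 < 0 or self.psi2 < 0:
            raise ValueError("prior SDs must be non-negative")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [-1, 1], got {self.rho}")

    @property
    def mean(self):
        import numpy as np

        return np.array([self.mu1, self.mu2])

    @property
    def cov(self):
        import numpy as np

        c = self.rho * self.psi1 * self.psi2
        return np.array([[self.psi1**2, c], [c, self.psi2**2]])


def _check_weight_coupling(r1: float, w1: float, what: str) -> None:
    if not 0 <= r1 <= 1:
        raise ValueError(f"{what}: prevalence must be in [0, 1], got {r1}")
    if not 0 <= w1 <= 1:
        raise ValueError(f"{what}: weight must be in [0, 1], got {w1}")
    if r1 == 1 and w1 != 1:
        raise ValueError(f"{what}: r1 = 1 requires w1 = 1 (only subgroup 1 tested)")
    if r1 == 0 and w1 != 0:
        raise ValueError(f"{what}: r1 = 0 requires w1 = 0 (subgroup 1 not tested)")


@dataclass(frozen=True)
class StageOneParams:
    """First-stage decision variables: interim timing, prevalence, weight.

    ``s1`` is the fraction of ``n`` recruited before the interim analysis,
    ``r1_1`` the stage-1 trial prevalence of subgroup 1 (``r2 = 1 - r1``),
    ``w1_1`` the stage-1 Bonferroni weight on H01 (ignored in umbrella mode).
    At the prevalence boundaries the weights are forced (r1 = 1 -> w1 = 1,
    r1 = 0 -> w1 = 0): only the sampled subgroup is tested.
    """

    s1: float
    r1_1: float
    w1_1: float = 0.5

    def __post_init__(self):
        if not 0 < self.s1 <= 1:
            raise ValueError(f"s1 must be in (0, 1], got {self.s1}")
        _check_weight_coupling(self.r1_1, self.w1_1, "stage 1")

    @property
    def r2_1(self) -> float:
        return 1.0 - self.r1_1

    @property
    def w2_1(self) -> float:
        return 1.0 - self.w1_1


@dataclass(frozen=True)
class StageTwoParams:
    """Second-stage decision variables: adapted prevalence and weight."""

    r1_2: float
    w1_2: float = 0.5

    def __post_init__(self):
        _check_weight_coupling(self.r1_2, self.w1_2, "stage 2")

    @property
    def r2_2(self) -> float:
        return 1.0 - self.r1_2

    @property
    def w2_2(self) -> float:
        return 1.0 - self.w1_2


def coupled_stage_two(r1_2: float, w1_2: float) -> StageTwoParams:
    """Build StageTwoParams forcing the boundary weight coupling."""
    r1_2 = min(max(r1_2, 0.0), 1.0)
    w1_2 = min(max(w1_2, 0.0), 1.0)
    if r1_2 == 1.0:
        w1_2 = 1.0
    elif r1_2 == 0.0:
        w1_2 = 0.0
    return StageTwoParams(r1_2=r1_2, w1_2=w1_2)


@dataclass(frozen=True)
class StageSummary:
    """Per-subgroup treatment-effect estimates from one stage.

    ``None`` marks a subgroup with zero recruitment in that stage (its
    estimate is undefined).
    """

    theta_hat_1: Optional[float]
    theta_hat_2: Optional[float]
    stage: int = 1

    def __post_init__(self):
        if self.stage not in (1, 2):
            raise ValueError(f"stage must be 1 or 2, got {self.stage}")
        for name in ("theta_hat_1", "theta_hat_2"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"{name} must be finite or None, got {v}")


@dataclass(frozen=True)
class TestResult:
    """Local and global rejection decisions of the closed test.

    In enrichment mode a hypothesis is rejected globally iff its local test
    and the intersection test both reject; in umbrella mode global == local
    and ``reject_intersection`` is ``None``.
    """

    __test__ = False  # not a test case despite the name

    reject_H01_global: bool
    reject_H02_global: bool
    reject_H01_local: bool
    reject_H02_local: bool
    reject_intersection: Optional[bool]

    def __post_init__(self):
        if self.reject_intersection is None:
            ok = (
                self.reject_H01_global == self.reject_H01_local
                and self.reject_H02_global == self.reject_H02_local
            )
        else:
            ok = self.reject_H01_global == (
                self.reject_H01_local and self.reject_intersection
            ) and self.reject_H02_global == (
                self.reject_H02_local and self.reject_intersection
            )
        if not ok:
            raise ValueError("inconsistent closed-test decisions")

    def to_record(self) -> dict:
        return {
            "reject_H01_global": self.reject_H01_global,
            "reject_H02_global": self.reject_H02_global,
            "reject_H01_local": self.reject_H01_local,
            "reject_H02_local": self.reject_H02_local,
            "reject_intersection": self.reject_intersection,
        }


def z_statistic(theta_hat: float, r: float, s: float, cfg: TrialConfig) -> float:
    """Z-value of a per-subgroup effect estimate.

    ``theta_hat`` has sampling law N(theta, 4 sigma^2 / (r s n)) under 1:1
    allocation, so ``Z = theta_hat * sqrt(r s n) / (2 sigma)`` is standard
    normal under ``theta = 0``.  Pass ``s = 1`` for a single-stage trial.
    """
    eff = r * s * cfg.n
    if eff <= 0:
        raise ZeroSampleError(
            f"subgroup not sampled (r={r}, s={s}, n={cfg.n}): Z-value undefined"
        )
    return theta_hat * math.sqrt(eff) / (2.0 * cfg.sigma)


def pooled_z(z_stage1: float, z_stage2: float, s1: float) -> float:
    """Z-value of the stage-pooled estimate under unchanged prevalences.

    ``Z_p = sqrt(s1) Z_1 + sqrt(1 - s1) Z_2`` equals the Z-value of the
    pooled estimate ``s1 theta_hat_1 + (1 - s1) theta_hat_2`` standardized
    by the full-trial variance ``4 sigma^2 / (r n)``.
    """
    if not 0 < s1 < 1:
        raise ValueError(f"s1 must be in (0, 1) for pooling, got {s1}")
    return math.sqrt(s1) * z_stage1 + math.sqrt(1.0 - s1) * z_stage2
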