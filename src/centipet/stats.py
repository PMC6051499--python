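"""Cohort statistics: classification, variability and mean comparisons,
two-tier significance, intra-individual variability, accumulation rate,
effect size, and hypothetical-trial sample size."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, NumericalDomainError, ParameterError
from .thresholds import LongitudinalPair, annualized_rate

__all__ = [
    "ClassificationRule",
    "LongitudinalGroups",
    "ComparisonResult",
    "TrialDesign",
    "classify",
    "longitudinal_groups",
    "group_summary",
    "variance_f_test",
    "paired_t_test",
    "significance_tier",
    "intra_individual_sd",
    "mean_annual_rate",
    "effect_size",
    "trial_sample_size",
    "corrected_alpha",
    "TIER_OVERALL_P",
    "TIER_TENTATIVE_P",
]

#: two-tier significance convention: overall (multiple-comparison safe)
#: and tentative (uncorrected) levels
TIER_OVERALL_P = 0.0005
TIER_TENTATIVE_P = 0.05


@dataclass(frozen=True)
class ClassificationRule:
    """Amyloid positivity rule on the CL scale."""

    threshold_cl: float
    positive_if: str = "greater"  # "greater" | "greater_or_equal"

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold_cl):
            raise ParameterError("threshold_cl must be finite")
        if self.positive_if not in ("greater", "greater_or_equal"):
            raise ParameterError("positive_if must be 'greater' or 'greater_or_equal'")


@dataclass(frozen=True)
class LongitudinalGroups:
    """Partition of longitudinal pairs into stable-negative and accumulator."""

    stable_negative: tuple
    accumulator: tuple


@dataclass(frozen=True)
class ComparisonResult:
    """One hypothesis-test outcome with its significance tier."""

    statistic: float
    p_value: float
    tier: str
    test: str  # "variance_F" | "paired_t"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ParameterError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class TrialDesign:
    """Hypothetical two-arm trial design parameters."""

    reduction: float = 0.5
    power: float = 0.8
    alpha: float = 0.05
    duration: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.reduction <= 1:
            raise ParameterError("reduction must lie in (0, 1]")
        if not 0 < self.power < 1:
            raise ParameterError("power must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must lie in (0, 1)")
        if not self.duration > 0:
            raise ParameterError("duration must be > 0")


def classify(cl: float, rule: ClassificationRule) -> str:
    """Return "positive" or "negative" for a CL value under the rule."""
    if rule.positive_if == "greater":
        pos = cl > rule.threshold_cl
    else:
        pos = cl >= rule.threshold_cl
    return "positive" if pos else "negative"


def longitudinal_groups(
    pairs: Sequence[LongitudinalPair], rule: ClassificationRule
) -> LongitudinalGroups:
    """Split pairs into stable-negatives (negative at both visits) and
    accumulators (positive at either visit); the two groups partition the
    input."""
    stable, accum = [], []
    for p in pairs:
        if (
            classify(p.baseline_cl, rule) == "negative"
            and classify(p.followup_cl, rule) == "negative"
        ):
            stable.append(p)
        else:
            accum.append(p)
    return LongitudinalGroups(stable_negative=tuple(stable), accumulator=tuple(accum))


def group_summary(values) -> tuple:
    """(arithmetic mean, sample SD with n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError(f"group summary needs n >= 2, got {v.size}")
    return float(v.mean()), float(v.std(ddof=1))


def significance_tier(p: float) -> str:
    """Two-tier convention: "overall" if p < 0.0005, "tentative" if
    0.0005 <= p < 0.05, else "ns"."""
    if not 0 <= p <= 1:
        raise ParameterError("p must lie in [0, 1]")
    if p < TIER_OVERALL_P:
        return "overall"
    if p < TIER_TENTATIVE_P:
        return "tentative"
    return "ns"


def variance_f_test(a, b, paired: bool = False) -> ComparisonResult:
    """Two-sided F test of equal variances, F = s_a^2 / s_b^2.

    The two-sided p doubles the smaller tail of F(n_a-1, n_b-1).  When
    ``paired`` is true the Pitman–Morgan correlation-adjusted t statistic
    and p-value are additionally reported in ``extra`` (the plain F remains
    the headline statistic).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("variance F test needs n >= 2 per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0:
        raise NumericalDomainError("denominator sample has zero variance")
    f = va / vb
    dist = sps.f(a.size - 1, b.size - 1)
    p = float(min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f))))
    extra = {}
    if paired:
        if a.size != b.size:
            raise ParameterError("paired comparison requires equal-length samples")
        extra.update(_pitman_morgan(a, b))
    return ComparisonResult(
        statistic=float(f), p_value=p, tier=significance_tier(p), test="variance_F", extra=extra
    )


def _pitman_morgan(a: np.ndarray, b: np.ndarray) -> dict:
    """Pitman–Morgan test of equal variances for paired samples: a t test of
    the correlation between sums and differences, df = n - 2."""
    n = a.size
    if n < 3:
        return {"pitman_morgan_t": float("nan"), "pitman_morgan_p": float("nan")}
    r = np.corrcoef(a + b, a - b)[0, 1]
    if abs(r) >= 1.0:
        return {"pitman_morgan_t": float("inf") * np.sign(r), "pitman_morgan_p": 0.0}
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = float(2 * sps.t.sf(abs(t), n - 2))
    return {"pitman_morgan_t": float(t), "pitman_morgan_p": p}


def paired_t_test(a, b) -> ComparisonResult:
    """Two-sided paired t test on the elementwise differences.

    Zero-variance differences are handled explicitly: all-zero differences
    give t = 0, p = 1; constant nonzero differences give an infinite-t flag
    with p reported as the 0 limit.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ParameterError("paired t test requires equal-length samples")
    if a.size < 2:
        raise InsufficientDataError("paired t test needs n >= 2")
    d = a - b
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return ComparisonResult(0.0, 1.0, "ns", "paired_t")
        return ComparisonResult(
            statistic=float(np.sign(d.mean()) * np.inf),
            p_value=0.0,
            tier="overall",
            test="paired_t",
            extra={"degenerate": "constant nonzero differences"},
        )
    t, p = sps.ttest_rel(a, b)
    p = float(p)
    return ComparisonResult(float(t), p, significance_tier(p), "paired_t")


def intra_individual_sd(stable: Sequence[LongitudinalPair]) -> float:
    """Sample SD of the annualized rate over stable-negative pairs (CL/yr);
    proxies longitudinal measurement noise."""
    if len(stable) < 2:
        raise InsufficientDataError(f"intra-individual SD needs n >= 2, got {len(stable)}")
    rates = np.array([annualized_rate(p) for p in stable])
    return float(rates.std(ddof=1))


def mean_annual_rate(accumulators: Sequence[LongitudinalPair]) -> float:
    """Mean annualized rate over accumulator pairs (CL/yr)."""
    if len(accumulators) < 1:
        raise InsufficientDataError("mean annual rate needs at least one pair")
    return float(np.mean([annualized_rate(p) for p in accumulators]))


def effect_size(rate: float, intra_sd: float) -> float:
    """Annualized rate over intra-individual variability (both CL/yr)."""
    if intra_sd <= 0:
        raise NumericalDomainError(f"intra_sd must be > 0, got {intra_sd}")
    return rate / intra_sd


def trial_sample_size(rate: float, intra_sd: float, design: TrialDesign = TrialDesign()) -> int:
    """Participants per arm to detect a fractional reduction in the
    accumulation rate.

    Normal-approximation two-sample difference-of-means formula:

        n = ceil( 2 * (z_{1-alpha/2} + z_power)^2 * sigma^2 / delta^2 )

    with ``delta = reduction * rate * duration`` and ``sigma = intra_sd *
    duration`` (per-subject change SD over the trial duration, from the
    annualized intra-individual SD).
    """
    if rate <= 0:
        raise ParameterError(f"rate must be > 0, got {rate}")
    if intra_sd <= 0:
        raise ParameterError(f"intra_sd must be > 0, got {intra_sd}")
    z_alpha = sps.norm.ppf(1 - design.alpha / 2)
    z_power = sps.norm.ppf(design.power)
    delta = design.reduction * rate * design.duration
    sigma = intra_sd * design.duration
    n = 2.0 * (z_alpha + z_power) ** 2 * sigma**2 / delta**2
    return int(math.ceil(n))


def corrected_alpha(alpha: float = 0.05, n_comparisons: int = 100) -> float:
    """Bonferroni-corrected family-wise significance level used as the
    overall tier (0.05 / 100 = 0.0005 by default)."""
    if n_comparisons < 1:
        raise ParameterError("n_comparisons must be >= 1")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    return alpha / n_comparisons
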