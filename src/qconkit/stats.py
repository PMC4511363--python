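"""Summary arithmetic for the quantification workflow.

Spike-in calibration linearity, replicate/cohort statistics with
coefficients of variation, enrichment/depletion bookkeeping for the serum
pre-fractionation, method-comparison correlations, and the qPCR
2^ΔCt relative-expression formula.

All statistics are thin, explicit wrappers over scipy/numpy: sample SD uses
the n−1 denominator, quartiles use linear interpolation (type 7),
correlation p-values are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "CalibrationSeries",
    "LinearFit",
    "ReplicateSummary",
    "GroupStats",
    "QPCRRecord",
    "fit_linearity",
    "replicate_summary",
    "sd_percent_of_mean",
    "enrichment_factor",
    "apply_normalization",
    "delta_ct_expression",
    "compare_methods",
    "group_stats",
]


@dataclass(frozen=True)
class CalibrationSeries:
    """A spike-in calibration: heavy standard levels vs measured area ratios.

    ``ratios`` holds one or more measured (spiked heavy ÷ endogenous light)
    area ratios per level, aligned with ``levels``.
    """

    levels: tuple[float, ...]
    ratios: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.ratios):
            raise ValueError("one ratio group per level required")
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("levels must be strictly increasing")
        if any(len(r) == 0 for r in self.ratios):
            raise ValueError("every level needs at least one ratio")

    def points(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to paired (level, ratio) arrays, one point per replicate."""
        xs, ys = [], []
        for level, reps in zip(self.levels, self.ratios):
            for r in reps:
                xs.append(level)
                ys.append(r)
        return np.array(xs), np.array(ys)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r: float

    @property
    def r_rounded(self) -> float:
        """Correlation coefficient at reporting precision (3 decimals)."""
        return round(self.r, 3)


def fit_linearity(series: CalibrationSeries, on_means: bool = False) -> LinearFit:
    """Ordinary least squares of area ratio vs spike level.

    By default every replicate is a point; ``on_means=True`` fits per-level
    means instead.  Requires ≥ 3 distinct levels.
    """
    if len(series.levels) < 3:
        raise ValueError("need at least 3 distinct spike levels")
    if on_means:
        x = np.array(series.levels)
        y = np.array([float(np.mean(r)) for r in series.ratios])
    else:
        x, y = series.points()
    res = _sps.linregress(x, y)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept), r=float(res.rvalue))


@dataclass(frozen=True)
class ReplicateSummary:
    n: int
    mean: float
    sd: float          # sample SD, n−1 denominator; nan when n < 2
    cv_percent: float  # 100 × sd / mean; nan when sd undefined
    sd_defined: bool = True


def replicate_summary(values: Sequence[float]) -> ReplicateSummary:
    """Mean, sample SD (n−1) and CV% of replicate measurements.

    With fewer than two values the SD (and CV) are undefined and flagged.
    """
    arr = np.asarray(values, dtype=float)
    n = len(arr)
    if n == 0:
        raise ValueError("no values")
    mean = float(arr.mean())
    if n < 2:
        return ReplicateSummary(n=n, mean=mean, sd=float("nan"), cv_percent=float("nan"), sd_defined=False)
    sd = float(arr.std(ddof=1))
    cv = 100.0 * sd / mean if mean > 0 else float("nan")
    return ReplicateSummary(n=n, mean=mean, sd=sd, cv_percent=cv)


def sd_percent_of_mean(sd: float, mean: float) -> float:
    """SD expressed as a percentage of the mean (the CV, in percent)."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    return 100.0 * sd / mean


def enrichment_factor(
    depletion_percent: float,
    recovery_percent: float,
    mode: Literal["nominal", "strict"] = "nominal",
) -> float:
    """Overall fold-enrichment from a depletion % and a recovery %.

    ``nominal`` follows the workflow's own bookkeeping convention, equating
    an x% depletion of high-abundance proteins with an x-fold enrichment of
    what remains, scaled by the recovery: fold = depletion × recovery/100
    (e.g. 94.9% depletion recovered at 97.6% → 92.62-fold).  ``strict``
    computes the literal concentration ratio 1/(1 − depletion/100) ×
    recovery/100 instead; at 100% depletion the strict factor is infinite.
    """
    if not 0 <= depletion_percent <= 100 or not 0 <= recovery_percent <= 100:
        raise ValueError("percentages must be within [0, 100]")
    recovery = recovery_percent / 100.0
    if mode == "nominal":
        return depletion_percent * recovery
    if depletion_percent == 100:
        return math.inf
    return recovery / (1.0 - depletion_percent / 100.0)


def apply_normalization(value: float, factor: float) -> float:
    """Scale a detector reading by a normalisation factor (value / factor)."""
    if factor <= 0:
        raise ValueError("normalisation factor must be positive")
    return value / factor


@dataclass(frozen=True)
class QPCRRecord:
    """Paired threshold cycles of a target and a housekeeping gene."""

    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        if self.ct_target <= 0 or self.ct_reference <= 0:
            raise ValueError("Ct values must be positive")


def delta_ct_expression(record: QPCRRecord) -> float:
    """Relative expression 2^(Ct_reference − Ct_target).

    Equal cycles give 1; each cycle the target crosses earlier than the
    housekeeping gene doubles the value.
    """
    return 2.0 ** (record.ct_reference - record.ct_target)


def compare_methods(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["pearson", "spearman"] = "spearman",
) -> tuple[float, float]:
    """Correlation between paired measurements from two methods.

    Returns (coefficient, two-sided p-value).  Spearman is the default for
    method comparison (monotone agreement without assuming linearity).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        res = _sps.pearsonr(x, y)
    elif method == "spearman":
        res = _sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GroupStats:
    """Box-plot summary: quartiles, mean ± SD, SD whiskers."""

    n: int
    median: float
    q1: float
    q3: float
    mean: float
    sd: float
    whisker_low: float
    whisker_high: float
    sd_defined: bool = True


def group_stats(values: Sequence[float]) -> GroupStats:
    """Summary statistics for one cohort group.

    Quartiles use linear interpolation (numpy default, type 7); whiskers are
    mean ± SD, matching box plots whose whiskers show standard deviations.
    A single value yields degenerate statistics with the SD flagged
    undefined.
    """
    arr = np.asarray(values, dtype=float)
    if len(arr) == 0:
        raise ValueError("no values")
    mean = float(arr.mean())
    if len(arr) < 2:
        v = float(arr[0])
        return GroupStats(
            n=1, median=v, q1=v, q3=v, mean=v, sd=float("nan"),
            whisker_low=v, whisker_high=v, sd_defined=False,
        )
    sd = float(arr.std(ddof=1))
    q1, med, q3 = (float(q) for q in np.quantile(arr, [0.25, 0.5, 0.75]))
    return GroupStats(
        n=len(arr), median=med, q1=q1, q3=q3, mean=mean, sd=sd,
        whisker_low=mean - sd, whisker_high=mean + sd,
    )
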