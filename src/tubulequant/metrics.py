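"""Tubule classification, cohort metrics, Z'-factor and t-tests.

A tubule is a skeleton branch whose geodesic length exceeds a minimum
(default 20 px = 2 um at 0.1 um/px, strictly greater). Three metrics
summarise a cohort of images:

* mean number of tubules per image,
* percentage of images with at least one tubule,
* mean length (um) by which the longest tubule per image exceeds the
  threshold — images without a qualifying tubule contribute 0 by
  default, keeping the metric defined for tubule-free cohorts and
  penalising absence (an exclude-empty mode is available).

Assay quality between a positive and negative control is scored by the
Z'-factor; condition comparisons use Student t-tests on per-repeat means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .io_formats import BranchRecord, ImageSummaryRow

__all__ = [
    "ImageResult",
    "CohortSummary",
    "ConditionStats",
    "TTestResult",
    "UndefinedZPrimeError",
    "DegenerateTestError",
    "DEFAULT_MIN_TUBULE_LENGTH_PX",
    "classify_tubules",
    "summarize_cohort",
    "condition_stats",
    "zprime",
    "interpret_zprime",
    "compare_conditions",
]

DEFAULT_MIN_TUBULE_LENGTH_PX = 20.0


class UndefinedZPrimeError(ZeroDivisionError):
    """Z' is undefined when its denominator is zero."""


class DegenerateTestError(ValueError):
    """A t-test cannot be formed (n < 2, or zero-variance paired diffs)."""


@dataclass(frozen=True)
class ImageResult:
    """Qualifying tubules of one image and the per-image metric values."""

    image_id: str
    tubule_lengths_px: tuple[float, ...]
    threshold_px: float

    @property
    def n_tubules(self) -> int:
        return len(self.tubule_lengths_px)

    @property
    def has_tubule(self) -> bool:
        return self.n_tubules >= 1

    @property
    def longest_excess_px(self) -> float:
        if not self.tubule_lengths_px:
            return 0.0
        return max(self.tubule_lengths_px) - self.threshold_px

    def to_summary_row(self) -> ImageSummaryRow:
        return ImageSummaryRow(
            image_id=self.image_id,
            n_tubules=self.n_tubules,
            has_tubule=self.has_tubule,
            longest_excess_px=self.longest_excess_px,
        )


@dataclass(frozen=True)
class CohortSummary:
    """Per-condition aggregate of the three metrics."""

    condition: str
    mean_tubules_per_image: float
    pct_images_with_tubule: float
    mean_longest_excess_um: float
    n_images: int


@dataclass(frozen=True)
class ConditionStats:
    """Mean/sd/n of one metric for one control condition."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    df: float
    paired: bool


def classify_tubules(
    branches: Sequence[BranchRecord] | Sequence[float],
    min_length_px: float = DEFAULT_MIN_TUBULE_LENGTH_PX,
    image_id: str | None = None,
    strict: bool = True,
) -> ImageResult:
    """Filter an image's branch table down to qualifying tubules.

    A branch qualifies when its geodesic length is strictly greater than
    ``min_length_px`` ("over" the threshold); set ``strict=False`` for >=.
    Accepts either BranchRecords (all from one image) or bare lengths.
    """
    if min_length_px <= 0:
        raise ValueError("min_length_px must be > 0")
    lengths: list[float] = []
    ids = set()
    for b in branches:
        if isinstance(b, BranchRecord):
            ids.add(b.image_id)
            lengths.append(b.length_px)
        else:
            lengths.append(float(b))
    if len(ids) > 1:
        raise ValueError(f"branches span multiple images: {sorted(ids)}")
    if image_id is None:
        image_id = next(iter(ids)) if ids else ""
    if strict:
        qualifying = [x for x in lengths if x > min_length_px]
    else:
        qualifying = [x for x in lengths if x >= min_length_px]
    return ImageResult(
        image_id=image_id,
        tubule_lengths_px=tuple(qualifying),
        threshold_px=float(min_length_px),
    )


def summarize_cohort(
    results: Sequence[ImageResult],
    pixel_size_um: float,
    condition: str = "",
    empty_images: Literal["zero", "exclude"] = "zero",
) -> CohortSummary:
    """Aggregate per-image results into the three cohort metrics.

    ``empty_images`` controls the excess-length metric: ``"zero"``
    (default) averages over all images with tubule-free images counted
    as 0; ``"exclude"`` averages over tubule-bearing images only (0 when
    the cohort has none).
    """
    if not results:
        raise ValueError("summarize_cohort requires at least one ImageResult")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    counts = np.array([r.n_tubules for r in results], dtype=float)
    flags = np.array([r.has_tubule for r in results], dtype=float)
    excess_px = np.array([r.longest_excess_px for r in results], dtype=float)
    if empty_images == "exclude":
        with_tubule = flags.astype(bool)
        mean_excess_px = float(excess_px[with_tubule].mean()) if with_tubule.any() else 0.0
    elif empty_images == "zero":
        mean_excess_px = float(excess_px.mean())
    else:
        raise ValueError("empty_images must be 'zero' or 'exclude'")
    return CohortSummary(
        condition=condition,
        mean_tubules_per_image=float(counts.mean()),
        pct_images_with_tubule=float(100.0 * flags.mean()),
        mean_longest_excess_um=mean_excess_px * pixel_size_um,
        n_images=len(results),
    )


def condition_stats(values: Sequence[float]) -> ConditionStats:
    """Mean and sample sd (ddof=1 when n >= 2) of one condition's values."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValueError("need at least one value")
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else 0.0
    return ConditionStats(mean=float(arr.mean()), sd=sd, n=int(arr.size))


def zprime(
    positive: ConditionStats,
    negative: ConditionStats,
    denominator_mode: Literal["difference", "as_printed_sum"] = "difference",
) -> float:
    """Z'-factor between a positive and negative control.

    ``difference`` mode is the standard separation-band definition
    ``1 - 3(sd_p + sd_n)/|mean_p - mean_n|``; ``as_printed_sum`` uses
    ``mean_p + mean_n`` in the denominator instead. The score is
    symmetric in which condition is labelled positive.
    """
    if denominator_mode == "difference":
        denom = abs(positive.mean - negative.mean)
    elif denominator_mode == "as_printed_sum":
        denom = positive.mean + negative.mean
    else:
        raise ValueError("denominator_mode must be 'difference' or 'as_printed_sum'")
    if denom == 0:
        raise UndefinedZPrimeError(
            f"Z' undefined: zero denominator in {denominator_mode!r} mode"
        )
    return 1.0 - 3.0 * (positive.sd + negative.sd) / denom


def interpret_zprime(z: float) -> str:
    """Screening-assay quality rubric.

    > 0.5 -> "robust"; 0 <= z <= 0.5 -> "functional_marginal";
    < 0 -> "unsuitable".
    """
    if not math.isfinite(z):
        raise ValueError("Z' must be finite")
    if z > 0.5:
        return "robust"
    if z >= 0.0:
        return "functional_marginal"
    return "unsuitable"


def compare_conditions(
    a: Sequence[float], b: Sequence[float], paired: bool
) -> TTestResult:
    """Two-sided Student t-test between two conditions' per-repeat values.

    Paired tests use within-repeat differences and require matched
    ordering; a zero-variance set of paired differences (e.g. identical
    inputs) raises :class:`DegenerateTestError`.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DegenerateTestError("each condition needs at least 2 values")
    if paired:
        if x.size != y.size:
            raise DegenerateTestError("paired test requires equal-length, matched values")
        diffs = x - y
        if float(diffs.std(ddof=1)) == 0.0:
            raise DegenerateTestError("paired differences have zero variance")
        res = stats.ttest_rel(x, y)
        df = float(x.size - 1)
    else:
        if float(x.std(ddof=1)) == 0.0 and float(y.std(ddof=1)) == 0.0:
            raise DegenerateTestError("both samples have zero variance")
        res = stats.ttest_ind(x, y, equal_var=True)
        df = float(x.size + y.size - 2)
    return TTestResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue), df=df, paired=paired
    )
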