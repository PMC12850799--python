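"""Sequence-level grading of a stream of per-frame cleanliness ratings.

A video sequence (whole colon or one segment) is summarized by six statistics
of its frame-rating distribution — mean, median, lower/upper quartile, 2nd
and 98th percentile — and each statistic is mapped to the 4-point
Leighton-Rex scale by flooring, then dichotomized (poor = nonacceptable,
fair/good/excellent = acceptable).
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "STATISTICS",
    "LeightonRexGrade",
    "BinaryGrade",
    "CleanlinessSummary",
    "summarize_ratings",
    "rating_to_grade",
    "grade_to_binary",
    "grade_scope",
]

#: The six summary statistics evaluated as grading thresholds, in report order.
STATISTICS = ("mean", "median", "q1", "q3", "p2", "p98")

PercentileMethod = Literal["linear", "nearest"]


class LeightonRexGrade(enum.IntEnum):
    """4-point qualitative bowel-cleansing scale."""

    POOR = 1
    FAIR = 2
    GOOD = 3
    EXCELLENT = 4


class BinaryGrade(enum.IntEnum):
    """2-point acceptability scale; NONACCEPTABLE < ACCEPTABLE."""

    NONACCEPTABLE = 0
    ACCEPTABLE = 1


@dataclasses.dataclass(frozen=True)
class CleanlinessSummary:
    """Six distribution statistics of one rating stream."""

    n_frames: int
    mean: float
    median: float
    q1: float
    q3: float
    p2: float
    p98: float

    def statistic(self, name: str) -> float:
        if name not in STATISTICS:
            raise KeyError(f"unknown statistic {name!r}; expected one of {STATISTICS}")
        return getattr(self, name)


def summarize_ratings(
    ratings: Sequence[float] | np.ndarray,
    percentile_method: PercentileMethod = "linear",
) -> CleanlinessSummary:
    """Compute the six summary statistics of a rating stream.

    ``percentile_method`` selects the quantile convention: "linear"
    interpolates between closest ranks (the usual array-library default);
    "nearest" takes the closest-rank observation. The choice only matters for
    short streams.
    """
    arr = np.asarray(ratings, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty rating stream")
    if percentile_method not in ("linear", "nearest"):
        raise ValueError(f"unknown percentile method {percentile_method!r}")
    q1, med, q3, p2, p98 = np.percentile(
        arr, [25, 50, 75, 2, 98], method=percentile_method
    )
    return CleanlinessSummary(
        n_frames=int(arr.size),
        mean=float(arr.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        p2=float(p2),
        p98=float(p98),
    )


def rating_to_grade(x: float) -> LeightonRexGrade:
    """Map a summary statistic to the Leighton-Rex scale by rounding down.

    Exact integers map to themselves (floor(3.0) = 3 = good). Values at or
    above 5 clamp to excellent; values below 1 clamp to poor with a warning,
    since a degenerate rating stream can sit at the scale floor.
    """
    if x < 1.0:
        warnings.warn(
            f"summary statistic {x} below the rating floor 1; clamping to poor",
            stacklevel=2,
        )
        return LeightonRexGrade.POOR
    return LeightonRexGrade(int(min(np.floor(x), 4)))


def grade_to_binary(g: LeightonRexGrade) -> BinaryGrade:
    """Dichotomize: poor is nonacceptable; fair, good and excellent are acceptable."""
    g = LeightonRexGrade(g)
    return BinaryGrade.NONACCEPTABLE if g == LeightonRexGrade.POOR else BinaryGrade.ACCEPTABLE


def grade_scope(
    ratings: Sequence[float] | np.ndarray,
    statistic: str,
    percentile_method: PercentileMethod = "linear",
) -> tuple[LeightonRexGrade, BinaryGrade]:
    """Grade one scope (segment or whole colon) by a chosen statistic.

    Equivalent to flooring the chosen component of :func:`summarize_ratings`
    and dichotomizing the result.
    """
    summary = summarize_ratings(ratings, percentile_method)
    value = summary.statistic(statistic)
    grade = rating_to_grade(value)
    return grade, grade_to_binary(grade)
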