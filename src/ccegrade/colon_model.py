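"""Colon segmentation and reader-report handling.

The capsule has no localization of its own, so colon segments are cut from
reader-supplied flexure timestamps (expressed as frame indices). Reader
reports carry five per-segment Leighton-Rex grades; for three-segment
comparisons the cecum merges into the right-sided colon and the rectum into
the left-sided colon, each taking the lower of the two grades. Overall
acceptability requires every segment to be acceptable.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Mapping, Sequence

import numpy as np

from .sequence_grading import BinaryGrade, LeightonRexGrade, grade_to_binary

__all__ = [
    "THREE_SEGMENTS",
    "FIVE_SEGMENTS",
    "SegmentBoundaries",
    "ReaderReport",
    "assign_segments",
    "merge_reader_5_to_3",
    "overall_binary",
    "overall_reader_grade",
]

THREE_SEGMENTS = ("right", "transverse", "left")
FIVE_SEGMENTS = ("cecum", "right", "transverse", "left", "rectum")


@dataclasses.dataclass(frozen=True)
class SegmentBoundaries:
    """Frame-index cut points partitioning the colon stream.

    ``three`` mode cuts at (hepatic_flexure, splenic_flexure); ``five`` mode
    additionally cuts at cecum_end and the rectosigmoid junction. Intervals
    are half-open: frame ``i`` belongs to segment ``k`` iff
    ``boundary[k-1] <= i < boundary[k]`` with implicit outer bounds 0 and
    n_frames, so no frame is double-counted.
    """

    mode: Literal["three", "five"]
    boundaries: tuple[int, ...]

    def __post_init__(self) -> None:
        expected = {"three": 2, "five": 4}.get(self.mode)
        if expected is None:
            raise ValueError(f"mode must be 'three' or 'five', got {self.mode!r}")
        b = tuple(int(x) for x in self.boundaries)
        if len(b) != expected:
            raise ValueError(f"{self.mode}-mode needs {expected} boundaries, got {len(b)}")
        if any(x < 0 for x in b) or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(f"boundaries must be nonnegative and strictly increasing: {b}")
        object.__setattr__(self, "boundaries", b)

    @property
    def segment_names(self) -> tuple[str, ...]:
        return THREE_SEGMENTS if self.mode == "three" else FIVE_SEGMENTS


@dataclasses.dataclass(frozen=True)
class ReaderReport:
    """One video's human grading: five segment grades plus boundaries."""

    video_id: str
    grades: tuple[LeightonRexGrade, LeightonRexGrade, LeightonRexGrade,
                  LeightonRexGrade, LeightonRexGrade]
    boundaries: SegmentBoundaries

    def __post_init__(self) -> None:
        if len(self.grades) != 5:
            raise ValueError(f"expected five segment grades, got {len(self.grades)}")
        object.__setattr__(
            self, "grades", tuple(LeightonRexGrade(g) for g in self.grades)
        )

    def grades_by_segment(self) -> dict[str, LeightonRexGrade]:
        return dict(zip(FIVE_SEGMENTS, self.grades))


def assign_segments(
    ratings: Sequence[float] | np.ndarray, b: SegmentBoundaries
) -> dict[str, np.ndarray]:
    """Partition a frame-rating stream into named per-segment streams.

    Raises a ``ValueError`` naming the segment if any interval is empty: an
    unobserved segment cannot be graded and must be excluded upstream.
    """
    arr = np.asarray(ratings, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot segment an empty rating stream")
    n = arr.size
    if b.boundaries[-1] > n:
        raise ValueError(
            f"boundary {b.boundaries[-1]} beyond stream length {n}"
        )
    cuts = (0, *b.boundaries, n)
    out: dict[str, np.ndarray] = {}
    for name, start, stop in zip(b.segment_names, cuts[:-1], cuts[1:]):
        if stop <= start:
            raise ValueError(f"segment {name!r} is empty (frames [{start}, {stop}))")
        out[name] = arr[start:stop]
    return out


def merge_reader_5_to_3(
    grades: Sequence[LeightonRexGrade],
) -> tuple[LeightonRexGrade, LeightonRexGrade, LeightonRexGrade]:
    """Merge the five reader grades to three segments by worst-of-pair.

    Cecum and right-sided colon combine into the right-sided colon at the
    lower of the two grades; likewise left-sided colon and rectum into the
    left-sided colon. The transverse colon passes through.
    """
    g = [LeightonRexGrade(x) for x in grades]
    if len(g) != 5:
        raise ValueError(f"expected five grades (cecum..rectum), got {len(g)}")
    cecum, right, transverse, left, rectum = g
    return (min(cecum, right), transverse, min(left, rectum))


def overall_binary(segment_binaries: Sequence[BinaryGrade]) -> BinaryGrade:
    """Overall acceptability: acceptable iff every segment is acceptable."""
    vals = [BinaryGrade(v) for v in segment_binaries]
    if not vals:
        raise ValueError("overall acceptability needs at least one segment")
    return BinaryGrade(min(vals))


def overall_reader_grade(grades: Sequence[LeightonRexGrade]) -> LeightonRexGrade:
    """Overall 4-point reader grade: the minimum segment grade.

    Consistent with the binary overall rule — dichotomizing the minimum grade
    equals requiring every segment to be acceptable.
    """
    vals = [LeightonRexGrade(g) for g in grades]
    if not vals:
        raise ValueError("overall grade needs at least one segment")
    return min(vals)


def reader_overall_binary(report_grades: Sequence[LeightonRexGrade]) -> BinaryGrade:
    """Convenience: overall acceptability straight from segment grades."""
    return overall_binary([grade_to_binary(g) for g in report_grades])
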