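"""Synthetic study data: frames, rating streams, and reader reports.

No raw capsule videos are publicly deposited, so every pipeline input is
emulated here with seeded randomness and stored ground truth:

* ``generate_frame_image`` paints hard-edged yellow-brown "stool" blobs on a
  pink mucosa background with an exact dirty-pixel count, for image-mode
  tests of the pixel classifier.
* ``generate_rating_stream`` draws per-frame cleanliness ratings around a
  latent per-segment Leighton-Rex grade (truncated normal on [1, 5) centered
  at latent + 0.5, so every summary statistic floors back to the latent grade
  in the noiseless limit).
* ``generate_reader_report`` passes latent grades through a row-stochastic
  confusion matrix to emulate human-reader variability.
* ``generate_cohort`` assembles a whole study cohort; the packaged study-like
  preset reproduces the real cohort's marginal rates (about 26% of videos
  reader-nonacceptable overall, about 6% algorithm-nonacceptable by the mean
  statistic).

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .colon_model import FIVE_SEGMENTS, ReaderReport, SegmentBoundaries
from .frame_scoring import RATING_MAX, PixelMask

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "study_like_config",
    "generate_frame_image",
    "generate_rating_stream",
    "generate_reader_report",
    "generate_cohort",
    "write_cohort",
]

# Flat colour palettes chosen so the default HSV classifier recovers the
# ground-truth mask exactly: dirty shades sit mid-band (hue 34-37 deg, high
# saturation), mucosa shades sit far outside it (hue ~343-347 deg).
_DIRTY_SHADES = np.array([[150, 100, 30], [130, 85, 25], [170, 120, 40]], dtype=np.uint8)
_MUCOSA_SHADES = np.array([[200, 130, 150], [215, 145, 160]], dtype=np.uint8)

IDENTITY_CONFUSION = np.eye(4)
UNIFORM_CONFUSION = np.full((4, 4), 0.25)


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic study cohort.

    latent_grade_distribution
        Probabilities over grades 1..4 for the video-level latent cleanliness.
    segment_correlation
        Probability that a segment inherits the video-level latent draw; with
        the remainder it redraws independently. 1.0 = all five segments share
        one latent grade (whole-colon preparation quality dominates).
    within_segment_noise
        SD of the truncated-normal frame-rating spread around latent + 0.5.
    reader_confusion
        4 x 4 row-stochastic matrix P(reported grade | latent grade).
    """

    n_videos: int = 100
    frames_per_video: tuple[int, int] = (150, 400)
    latent_grade_distribution: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    segment_correlation: float = 1.0
    within_segment_noise: float = 0.4
    reader_confusion: np.ndarray = dataclasses.field(
        default_factory=lambda: IDENTITY_CONFUSION.copy()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_videos < 1:
            raise ValueError("n_videos must be positive")
        lo, hi = self.frames_per_video
        if not (10 <= lo <= hi):
            raise ValueError(f"bad frames_per_video range {self.frames_per_video}")
        p = np.asarray(self.latent_grade_distribution, dtype=float)
        if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("latent_grade_distribution must be 4 probabilities summing to 1")
        if not (0.0 <= self.segment_correlation <= 1.0):
            raise ValueError("segment_correlation must lie in [0, 1]")
        if self.within_segment_noise < 0:
            raise ValueError("within_segment_noise must be nonnegative")
        c = np.asarray(self.reader_confusion, dtype=float)
        if c.shape != (4, 4) or np.any(c < 0) or np.any(np.abs(c.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("reader_confusion must be 4 x 4 row-stochastic")
        object.__setattr__(self, "reader_confusion", c)


def study_like_config(n_videos: int = 842, seed: int = 0) -> CohortConfig:
    """Cohort preset calibrated to the study's marginal rates.

    Video-level latent grades follow (.06, .40, .35, .19) over poor..excellent
    with perfectly correlated segments, and the reader confusion below leaks
    per-segment "poor" reports at rates (.85, .10, .02, .005) by latent grade.
    Analytically this puts the expected reader overall-nonacceptable rate at
    26.2% of videos and the algorithm mean-statistic nonacceptable rate near
    6%, matching the real cohort's 26.37% and 5.94%.
    """
    confusion = np.array(
        [
            [0.850, 0.130, 0.020, 0.000],
            [0.100, 0.650, 0.220, 0.030],
            [0.020, 0.180, 0.600, 0.200],
            [0.005, 0.035, 0.260, 0.700],
        ]
    )
    return CohortConfig(
        n_videos=n_videos,
        frames_per_video=(150, 400),
        latent_grade_distribution=(0.06, 0.40, 0.35, 0.19),
        segment_correlation=1.0,
        within_segment_noise=0.4,
        reader_confusion=confusion,
        seed=seed,
    )


def generate_frame_image(
    dirty_fraction: float, size: int = 256, seed: int = 0
) -> tuple[np.ndarray, PixelMask]:
    """Paint a synthetic capsule frame with an exact dirty-pixel budget.

    The dirty region is the union of hard-edged blobs grown from random seed
    points, trimmed or extended pixel-exactly so that the dirty count equals
    ``round(dirty_fraction * size**2)``. No anti-aliasing: every pixel takes
    a flat palette colour, so the ground-truth mask is recoverable exactly.

    Returns the (size, size, 3) uint8 RGB frame and its ground-truth mask.
    """
    if not (0.0 <= dirty_fraction <= 1.0):
        raise ValueError(f"dirty_fraction out of [0, 1]: {dirty_fraction}")
    if size < 1:
        raise ValueError(f"size must be positive, got {size}")
    rng = np.random.default_rng(seed)
    n_total = size * size
    target = int(round(dirty_fraction * n_total))

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    if target == 0:
        dirty = np.zeros((size, size), dtype=bool)
    elif target == n_total:
        dirty = np.ones((size, size), dtype=bool)
    else:
        # Distance field to random blob centres, normalized per-blob radius;
        # the `target` lowest-scoring pixels become dirty, giving blob-shaped
        # regions with an exact pixel count. A tiny raster-order ramp breaks
        # score ties deterministically.
        n_blobs = max(1, int(round(6 * dirty_fraction)) + rng.integers(1, 4))
        cy = rng.uniform(0, size, n_blobs)
        cx = rng.uniform(0, size, n_blobs)
        radius = rng.uniform(0.2, 1.0, n_blobs) * size * 0.4
        score = np.full((size, size), np.inf)
        for b in range(n_blobs):
            d = np.hypot(yy - cy[b], xx - cx[b]) / radius[b]
            score = np.minimum(score, d)
        score = score.ravel() + np.arange(n_total) * 1e-12
        order = np.argpartition(score, target - 1)[:target]
        dirty = np.zeros(n_total, dtype=bool)
        dirty[order] = True
        dirty = dirty.reshape(size, size)

    frame = np.empty((size, size, 3), dtype=np.uint8)
    mucosa_idx = rng.integers(0, len(_MUCOSA_SHADES), (size, size))
    dirty_idx = rng.integers(0, len(_DIRTY_SHADES), (size, size))
    frame[~dirty] = _MUCOSA_SHADES[mucosa_idx[~dirty]]
    frame[dirty] = _DIRTY_SHADES[dirty_idx[dirty]]
    return frame, PixelMask(dirty=dirty)


def _draw_segment_ratings(
    latent: int, n: int, noise: float, rng: np.random.Generator
) -> np.ndarray:
    center = latent + 0.5
    if noise == 0.0:
        return np.full(n, center)
    a = (1.0 - center) / noise
    b = (RATING_MAX - center) / noise
    return truncnorm.rvs(a, b, loc=center, scale=noise, size=n, random_state=rng)


def generate_rating_stream(
    segment_latents: dict[str, int] | list[int],
    boundaries: SegmentBoundaries,
    n_frames: int,
    noise: float = 0.4,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw one video's frame-rating stream around per-segment latent grades.

    Each segment's frames are i.i.d. truncated-normal on [1, 5) centered at
    its latent grade + 0.5 with SD ``noise``; ``noise = 0`` gives the
    constant latent + 0.5, so every percentile statistic floors back to the
    latent grade (exact parameter recovery).
    """
    if isinstance(segment_latents, dict):
        latents = [segment_latents[name] for name in boundaries.segment_names]
    else:
        latents = list(segment_latents)
    if len(latents) != len(boundaries.segment_names):
        raise ValueError(
            f"{len(latents)} latent grades for {len(boundaries.segment_names)} segments"
        )
    if any(g not in (1, 2, 3, 4) for g in latents):
        raise ValueError(f"latent grades must be in 1..4: {latents}")
    if boundaries.boundaries[-1] >= n_frames:
        raise ValueError("last boundary must leave the final segment non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cuts = (0, *boundaries.boundaries, n_frames)
    parts = [
        _draw_segment_ratings(g, stop - start, noise, rng)
        for g, start, stop in zip(latents, cuts[:-1], cuts[1:])
    ]
    return np.concatenate(parts)


def generate_reader_report(
    video_id: str,
    latent_grades: list[int],
    boundaries: SegmentBoundaries,
    confusion: np.ndarray = IDENTITY_CONFUSION,
    seed: int | np.random.Generator = 0,
) -> ReaderReport:
    """Simulate one human reader report from latent segment grades.

    Each reported grade is drawn from the confusion row of its latent grade;
    an identity matrix reproduces the latents exactly, uniform rows make the
    reports independent of the latents.
    """
    c = np.asarray(confusion, dtype=float)
    if c.shape != (4, 4) or np.any(c < 0) or np.any(np.abs(c.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("confusion must be 4 x 4 row-stochastic")
    if len(latent_grades) != 5:
        raise ValueError("five latent grades required (cecum..rectum)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reported = tuple(
        int(rng.choice(4, p=c[int(g) - 1]) + 1) for g in latent_grades
    )
    return ReaderReport(video_id=video_id, grades=reported, boundaries=boundaries)


@dataclasses.dataclass(frozen=True)
class SyntheticCohort:
    """A generated study cohort with its ground truth."""

    config: CohortConfig
    frame_scores: pd.DataFrame           # video_id, frame_index, rating
    reader_reports: list[ReaderReport]   # three-mode boundaries, as in the study
    ground_truth: dict                   # per-video latent grades and boundaries


def _random_five_boundaries(n_frames: int, rng: np.random.Generator) -> tuple[int, ...]:
    # Four interior cuts with every segment at least ~5% of the stream.
    min_len = max(1, n_frames // 20)
    while True:
        cuts = np.sort(rng.integers(min_len, n_frames - min_len + 1, size=4))
        lengths = np.diff((0, *cuts, n_frames))
        if np.all(lengths >= min_len):
            return tuple(int(c) for c in cuts)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort: frame scores, reader reports, truth.

    Per video: a latent grade is drawn for the whole colon, each of the five
    segments either inherits it (probability ``segment_correlation``) or
    redraws; frame ratings are generated around the segment latents; the
    reader report passes the latents through the confusion matrix and carries
    the flexure boundaries in three-segment mode, as the study's reports did.
    """
    rng = np.random.default_rng(config.seed)
    p = np.asarray(config.latent_grade_distribution, dtype=float)
    frames, reports, truth = [], [], {}
    for v in range(config.n_videos):
        video_id = f"video_{v:04d}"
        n_frames = int(rng.integers(config.frames_per_video[0], config.frames_per_video[1] + 1))
        video_latent = int(rng.choice(4, p=p) + 1)
        latents = [
            video_latent
            if rng.random() < config.segment_correlation
            else int(rng.choice(4, p=p) + 1)
            for _ in range(5)
        ]
        five_cuts = _random_five_boundaries(n_frames, rng)
        five_b = SegmentBoundaries(mode="five", boundaries=five_cuts)
        # Only the flexure timestamps are available in reports.
        three_b = SegmentBoundaries(mode="three", boundaries=five_cuts[1:3])
        ratings = generate_rating_stream(
            latents, five_b, n_frames, config.within_segment_noise, rng
        )
        reports.append(
            generate_reader_report(video_id, latents, three_b, config.reader_confusion, rng)
        )
        frames.append(
            pd.DataFrame(
                {
                    "video_id": video_id,
                    "frame_index": np.arange(n_frames),
                    "rating": ratings,
                }
            )
        )
        truth[video_id] = {
            "video_latent": video_latent,
            "segment_latents": dict(zip(FIVE_SEGMENTS, latents)),
            "five_boundaries": list(five_cuts),
            "n_frames": n_frames,
        }
    return SyntheticCohort(
        config=config,
        frame_scores=pd.concat(frames, ignore_index=True),
        reader_reports=reports,
        ground_truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write a cohort in the CSV/JSON schemas the pipeline reads."""
    from .pipeline_io import write_reader_reports  # local import: avoids a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort.frame_scores.to_csv(
        out_dir / "frame_scores.csv", index=False, float_format="%.6f"
    )
    write_reader_reports(out_dir / "reader_reports.csv", cohort.reader_reports)
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(cohort.ground_truth, fh, indent=1)


def write_frame_png(path: str | Path, frame: np.ndarray) -> None:
    """Write one synthetic frame losslessly (PNG keeps the palette exact)."""
    iio.imwrite(Path(path), frame)
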