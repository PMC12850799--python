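"""Per-frame cleanliness scoring for colon capsule endoscopy video frames.

Each frame is reduced to a clean-pixel fraction by labelling every pixel
"clean" or "dirty", then to a continuous cleanliness rating on [1, 5) whose
floor is a Leighton-Rex grade (1=poor .. 4=excellent).

The pixel labeller here is a configurable HSV-threshold rule: a pixel is
dirty when its hue falls in a yellow/brown band at sufficient saturation and
brightness, which is the colour signature of residual stool against pink
mucosa. It is a deterministic, rule-based classifier, not a trained model.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.color import rgb2hsv

__all__ = [
    "ClassifierConfig",
    "PixelMask",
    "FrameCleanliness",
    "classify_pixels",
    "clean_fraction",
    "clean_to_dirty_ratio",
    "fraction_to_rating",
    "score_frame",
    "score_frame_directory",
    "write_frame_scores",
    "read_frame_scores",
    "RATING_MAX",
]

# Ratings live on [1, 5); the ceiling sits just below 5 so that flooring a
# rating always lands in {1,2,3,4}.
RATING_MAX = np.nextafter(5.0, 1.0)


@dataclasses.dataclass(frozen=True)
class ClassifierConfig:
    """HSV thresholds delimiting "dirty" pixels.

    A pixel is dirty iff hue (degrees) lies in ``hue_band`` AND
    saturation >= ``saturation_min`` AND value >= ``value_min``.
    ``hue_band`` may wrap around 360 (e.g. (350, 20)).
    """

    hue_band: tuple[float, float] = (20.0, 70.0)
    saturation_min: float = 0.35
    value_min: float = 0.15

    def __post_init__(self) -> None:
        lo, hi = self.hue_band
        if not (0.0 <= lo < 360.0 and 0.0 <= hi < 360.0):
            raise ValueError(f"hue_band bounds must lie in [0, 360): {self.hue_band}")
        if not (0.0 <= self.saturation_min <= 1.0):
            raise ValueError(f"saturation_min out of [0, 1]: {self.saturation_min}")
        if not (0.0 <= self.value_min <= 1.0):
            raise ValueError(f"value_min out of [0, 1]: {self.value_min}")


@dataclasses.dataclass(frozen=True)
class PixelMask:
    """Binary clean/dirty labelling of one frame; True marks a dirty pixel."""

    dirty: np.ndarray  # bool array, shape (height, width)

    def __post_init__(self) -> None:
        arr = np.asarray(self.dirty, dtype=bool)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("mask must be a non-empty 2-D boolean array")
        object.__setattr__(self, "dirty", arr)

    @property
    def height(self) -> int:
        return self.dirty.shape[0]

    @property
    def width(self) -> int:
        return self.dirty.shape[1]

    @property
    def n_dirty(self) -> int:
        return int(self.dirty.sum())

    @property
    def n_clean(self) -> int:
        return int(self.dirty.size - self.dirty.sum())


@dataclasses.dataclass(frozen=True)
class FrameCleanliness:
    """One frame's cleanliness: clean-pixel fraction and continuous rating."""

    frame_index: int
    clean_fraction: float
    rating: float
    timestamp_s: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.clean_fraction <= 1.0):
            raise ValueError(f"clean_fraction out of [0, 1]: {self.clean_fraction}")
        if not (1.0 <= self.rating < 5.0):
            raise ValueError(f"rating out of [1, 5): {self.rating}")


def classify_pixels(frame: np.ndarray, config: ClassifierConfig | None = None) -> PixelMask:
    """Label every pixel of an RGB frame clean or dirty.

    Parameters
    ----------
    frame
        ``(H, W, 3)`` RGB raster, uint8 or float in [0, 1].
    config
        HSV thresholds; defaults target yellow/brown stool hues.

    Returns
    -------
    PixelMask with ``dirty[i, j]`` True where the pixel satisfies all three
    thresholds. Deterministic: identical input gives an identical mask.
    """
    config = config or ClassifierConfig()
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3 or frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValueError(f"expected non-empty (H, W, 3) RGB frame, got shape {frame.shape}")
    hsv = rgb2hsv(frame)
    hue_deg = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    val = hsv[..., 2]
    lo, hi = config.hue_band
    if lo <= hi:
        in_band = (hue_deg >= lo) & (hue_deg <= hi)
    else:  # band wraps through 0 degrees
        in_band = (hue_deg >= lo) | (hue_deg <= hi)
    dirty = in_band & (sat >= config.saturation_min) & (val >= config.value_min)
    return PixelMask(dirty=dirty)


def clean_fraction(mask: PixelMask) -> float:
    """Fraction of pixels labelled clean: ``clean / (clean + dirty)``."""
    total = mask.dirty.size
    if total == 0:
        raise ValueError("empty mask has no clean fraction")
    return float(mask.n_clean) / total


def clean_to_dirty_ratio(mask: PixelMask) -> float:
    """Literal quotient clean/dirty; ``inf`` for a fully clean frame."""
    if mask.n_dirty == 0:
        return float("inf")
    return mask.n_clean / mask.n_dirty


def fraction_to_rating(f: float | np.ndarray) -> float | np.ndarray:
    """Affine map of clean fraction to the continuous grade scale [1, 5).

    ``rating = 1 + 4 f``, clamped just below 5 so that flooring always yields
    a Leighton-Rex grade in {1, 2, 3, 4}. Grade bands therefore fall at clean
    fractions <25% (poor), 25-50% (fair), 50-75% (good), >=75% (excellent).
    """
    arr = np.asarray(f, dtype=float)
    if np.any((arr < 0.0) | (arr > 1.0)):
        raise ValueError("clean fraction must lie in [0, 1]")
    rating = np.minimum(1.0 + 4.0 * arr, RATING_MAX)
    return rating if isinstance(f, np.ndarray) else float(rating)


def score_frame(
    frame: np.ndarray,
    config: ClassifierConfig | None = None,
    frame_index: int = 0,
    timestamp_s: float | None = None,
) -> FrameCleanliness:
    """Classify one frame and reduce it to clean fraction + rating."""
    mask = classify_pixels(frame, config)
    f = clean_fraction(mask)
    return FrameCleanliness(
        frame_index=frame_index,
        clean_fraction=f,
        rating=float(fraction_to_rating(f)),
        timestamp_s=timestamp_s,
    )


def score_frame_directory(
    directory: str | Path,
    config: ClassifierConfig | None = None,
    timestamps: Sequence[float] | None = None,
) -> list[FrameCleanliness]:
    """Score every PNG/JPEG frame in a directory.

    Lexicographic file order defines frame order, matching how capsule frame
    dumps are numbered. ``timestamps`` optionally supplies seconds-from-start
    per frame (same order).
    """
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
    )
    if not paths:
        raise ValueError(f"no PNG/JPEG frames found in {directory}")
    if timestamps is not None and len(timestamps) != len(paths):
        raise ValueError(
            f"{len(timestamps)} timestamps for {len(paths)} frames"
        )
    out = []
    for i, p in enumerate(paths):
        frame = iio.imread(p)
        if frame.ndim == 3 and frame.shape[2] == 4:  # tolerate RGBA PNGs
            frame = frame[..., :3]
        ts = None if timestamps is None else float(timestamps[i])
        out.append(score_frame(frame, config, frame_index=i, timestamp_s=ts))
    return out


def frame_scores_to_frame(video_id: str, scores: Iterable[FrameCleanliness]) -> pd.DataFrame:
    rows = [
        {
            "video_id": video_id,
            "frame_index": s.frame_index,
            "timestamp_s": s.timestamp_s,
            "clean_fraction": s.clean_fraction,
            "rating": s.rating,
        }
        for s in scores
    ]
    return pd.DataFrame(rows)


def write_frame_scores(path: str | Path, df: pd.DataFrame) -> None:
    """Write the per-frame score CSV (6 decimal places on real columns)."""
    df.to_csv(path, index=False, float_format="%.6f")


def read_frame_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"video_id", "frame_index", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"frame-score CSV {path} missing columns: {sorted(missing)}")
    return df
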