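"""Study orchestration, file formats, and report rendering.

``run_study`` is the end-to-end driver: given per-frame ratings and reader
reports it grades every video with the algorithm (whole colon pooled, plus
flexure-delimited segments), merges the readers' five segment grades to
three, cross-tabulates algorithm vs reader on the 2-point and 4-point scales
for every summary statistic, and returns a JSON-serializable agreement
report. ``render_report`` turns that report into the study's two table
layouts: a distribution table with "n (percent)" cells and an agreement
table with kappa and its 95% CI.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .agreement import (
    ContingencyTable,
    build_contingency,
    cohen_kappa,
    format_kappa,
    weighted_kappa,
)
from .colon_model import (
    FIVE_SEGMENTS,
    THREE_SEGMENTS,
    ReaderReport,
    SegmentBoundaries,
    assign_segments,
    merge_reader_5_to_3,
    overall_reader_grade,
)
from .sequence_grading import (
    STATISTICS,
    BinaryGrade,
    grade_to_binary,
    rating_to_grade,
    summarize_ratings,
)

logger = logging.getLogger("ccegrade")

__all__ = [
    "StudyConfig",
    "run_study",
    "render_report",
    "read_reader_reports",
    "write_reader_reports",
    "load_study_config",
]

_BOUNDARY_COLS = ("cecum_end", "hepatic_flexure", "splenic_flexure", "rectosigmoid_junction")


@dataclasses.dataclass(frozen=True)
class StudyConfig:
    """Run-level options of an agreement study."""

    statistics: tuple[str, ...] = STATISTICS
    weight_scheme: str = "linear"          # weighted-kappa weights for the 4-point scale
    percentile_method: str = "linear"      # quantile convention for short streams
    segment_mode: str = "three"

    def __post_init__(self) -> None:
        bad = set(self.statistics) - set(STATISTICS)
        if bad:
            raise ValueError(f"unknown statistics {sorted(bad)}; valid: {STATISTICS}")
        if self.weight_scheme not in ("linear", "quadratic"):
            raise ValueError(f"weight_scheme must be linear|quadratic: {self.weight_scheme}")
        if self.percentile_method not in ("linear", "nearest"):
            raise ValueError(f"percentile_method must be linear|nearest: {self.percentile_method}")
        if self.segment_mode not in ("three", "five"):
            raise ValueError(f"segment_mode must be three|five: {self.segment_mode}")
        object.__setattr__(self, "statistics", tuple(self.statistics))

    def digest(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


def load_study_config(path: str | Path) -> StudyConfig:
    """Load run options from a YAML file; missing keys take defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)} in {path}")
    if "statistics" in raw:
        raw["statistics"] = tuple(raw["statistics"])
    return StudyConfig(**raw)


def write_reader_reports(path: str | Path, reports: Sequence[ReaderReport]) -> None:
    rows = []
    for r in reports:
        row: dict = {"video_id": r.video_id}
        for seg, g in r.grades_by_segment().items():
            row[f"grade_{seg}"] = int(g)
        b = dict(zip(_BOUNDARY_COLS[1:3] if r.boundaries.mode == "three" else _BOUNDARY_COLS,
                     r.boundaries.boundaries))
        for col in _BOUNDARY_COLS:
            row[col] = b.get(col, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_reader_reports(path: str | Path) -> list[ReaderReport]:
    """Read the reader-report CSV; boundary mode is inferred per row."""
    df = pd.read_csv(path)
    required = {"video_id"} | {f"grade_{s}" for s in FIVE_SEGMENTS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reader-report CSV {path} missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        grades = tuple(int(row[f"grade_{s}"]) for s in FIVE_SEGMENTS)
        vals = {c: row[c] for c in _BOUNDARY_COLS if c in df.columns and pd.notna(row[c]) and row[c] != ""}
        if len(vals) == 4:
            b = SegmentBoundaries("five", tuple(int(vals[c]) for c in _BOUNDARY_COLS))
        elif set(vals) == {"hepatic_flexure", "splenic_flexure"}:
            b = SegmentBoundaries(
                "three", (int(vals["hepatic_flexure"]), int(vals["splenic_flexure"]))
            )
        else:
            raise ValueError(
                f"video {row['video_id']}: boundary columns {sorted(vals)} match neither mode"
            )
        out.append(ReaderReport(str(row["video_id"]), grades, b))
    return out


def _algorithm_grades(
    ratings: np.ndarray,
    boundaries: SegmentBoundaries,
    config: StudyConfig,
) -> dict[str, dict[str, int]]:
    """Grade the pooled colon and each segment, per summary statistic.

    Returns ``{scope: {statistic: grade}}`` with scope "total" plus the
    segment names. The whole-colon grade pools all frames rather than taking
    a minimum over segments.
    """
    scopes = {"total": ratings}
    scopes.update(assign_segments(ratings, boundaries))
    out: dict[str, dict[str, int]] = {}
    for scope, stream in scopes.items():
        summary = summarize_ratings(stream, config.percentile_method)
        out[scope] = {
            stat: int(rating_to_grade(summary.statistic(stat)))
            for stat in config.statistics
        }
    return out


def _kappa_block(pairs: list[tuple[int, int]], k: int, scheme: str) -> dict:
    t = build_contingency(pairs, k)
    res = cohen_kappa(t) if k == 2 else weighted_kappa(t, scheme)
    return {
        "k": k,
        "n": t.n,
        "counts": t.counts.tolist(),
        "cell_percent": [
            [_pct(c, t.n) for c in row] for row in t.counts.tolist()
        ],
        **res.to_dict(),
    }


def _pct(count: int, n: int) -> float:
    return float(Decimal(repr(100.0 * count / n)).quantize(Decimal("0.01"), ROUND_HALF_UP))


def run_study(
    frame_scores: pd.DataFrame,
    reader_reports: Sequence[ReaderReport],
    config: StudyConfig | None = None,
) -> dict:
    """Run the full agreement study and return the report dict.

    For each statistic the 2-point comparison uses unweighted kappa and the
    4-point comparison weighted kappa; scopes are the whole colon (one pair
    per video) and the pooled three-segment comparison (up to three pairs per
    video, reader grades merged five-to-three). Videos whose frame stream
    cannot be segmented are dropped from segmental comparisons with a logged
    count. Deterministic given its inputs.
    """
    config = config or StudyConfig()
    by_video = {vid: g["rating"].to_numpy() for vid, g in frame_scores.groupby("video_id")}
    report_map = {r.video_id: r for r in reader_reports}
    video_ids = sorted(set(by_video) & set(report_map))
    if not video_ids:
        raise ValueError("no videos common to frame scores and reader reports")

    total_pairs: dict[str, list[tuple[int, int]]] = {s: [] for s in config.statistics}
    seg_pairs: dict[str, list[tuple[int, int]]] = {s: [] for s in config.statistics}
    n_segment_excluded = 0
    for vid in video_ids:
        report = report_map[vid]
        ratings = by_video[vid]
        reader_overall = int(overall_reader_grade(report.grades))
        total_summary = summarize_ratings(ratings, config.percentile_method)
        for stat in config.statistics:
            alg_total = int(rating_to_grade(total_summary.statistic(stat)))
            total_pairs[stat].append((alg_total, reader_overall))
        try:
            alg = _algorithm_grades(ratings, report.boundaries, config)
        except ValueError as err:
            logger.warning("video %s excluded from segmental comparisons: %s", vid, err)
            n_segment_excluded += 1
            continue
        if report.boundaries.mode == "three":
            reader_seg = dict(zip(THREE_SEGMENTS, merge_reader_5_to_3(report.grades)))
        else:
            reader_seg = {s: g for s, g in report.grades_by_segment().items()}
        for seg, reader_grade in reader_seg.items():
            for stat in config.statistics:
                seg_pairs[stat].append((alg[seg][stat], int(reader_grade)))

    def comparisons(pairs_by_stat: dict[str, list[tuple[int, int]]]) -> dict:
        out = {}
        for stat, pairs in pairs_by_stat.items():
            if not pairs:
                raise ValueError(f"empty comparison set for statistic {stat!r}")
            binary = [(1 if grade_to_binary(a) == BinaryGrade.NONACCEPTABLE else 2,
                       1 if grade_to_binary(r) == BinaryGrade.NONACCEPTABLE else 2)
                      for a, r in pairs]
            out[stat] = {
                "binary": _kappa_block(binary, 2, config.weight_scheme),
                "ordinal": _kappa_block(pairs, 4, config.weight_scheme),
            }
        return out

    report = {
        "config": dataclasses.asdict(config) | {"digest": config.digest()},
        "n_videos": len(video_ids),
        "n_excluded": n_segment_excluded,
        "comparisons": {
            "colon_total": comparisons(total_pairs),
            "segmental": comparisons(seg_pairs),
        },
    }
    return report


_BINARY_LABELS = ("Nonacceptable BC", "Acceptable BC")
_ORDINAL_LABELS = ("Poor", "Fair", "Good", "Excellent")


def _distribution_md(block: dict, title: str) -> list[str]:
    labels = _BINARY_LABELS if block["k"] == 2 else _ORDINAL_LABELS
    lines = [f"### {title}", "", "| AIA \\ Readers | " + " | ".join(labels) + " | Total |",
             "|" + "---|" * (block["k"] + 2)]
    counts = np.array(block["counts"])
    n = block["n"]
    for i, lab in enumerate(labels):
        cells = [f"{counts[i, j]} ({block['cell_percent'][i][j]:.2f})" for j in range(block["k"])]
        row_n = int(counts[i].sum())
        lines.append(f"| {lab} | " + " | ".join(cells) + f" | {row_n} ({_pct(row_n, n):.2f}) |")
    col_tot = [f"{int(counts[:, j].sum())} ({_pct(int(counts[:, j].sum()), n):.2f})"
               for j in range(block["k"])]
    lines.append("| Total | " + " | ".join(col_tot) + f" | {n} (100.00) |")
    lines.append("")
    return lines


def render_report(report: dict) -> tuple[str, dict[str, pd.DataFrame]]:
    """Render the agreement report as Markdown plus CSV-ready tables.

    Returns the Markdown text and two DataFrames: ``distribution`` (cell
    counts with percentages) and ``agreement`` (kappa, CI, percent agreement,
    label per scope x statistic x scale).
    """
    md = ["# Bowel-cleansing agreement report", ""]
    dist_rows, agree_rows = [], []
    for scope, stats in report["comparisons"].items():
        md.append(f"## {scope.replace('_', ' ').title()}")
        md.append("")
        for stat, scales in stats.items():
            for scale_name, block in scales.items():
                title = f"{scope} / {stat} / {scale_name} (n={block['n']})"
                md.extend(_distribution_md(block, title))
                ci = block["ci95"]
                md.append(
                    f"kappa {format_kappa(block['kappa'])} "
                    f"({format_kappa(ci[0])}-{format_kappa(ci[1])}), "
                    f"agreement {block['percent_agreement']:.1f}%, "
                    f"interpretation: {block['label']}"
                )
                md.append("")
                counts = np.array(block["counts"])
                for i in range(block["k"]):
                    for j in range(block["k"]):
                        dist_rows.append({
                            "scope": scope, "statistic": stat, "scale": scale_name,
                            "aia_category": i + 1, "reader_category": j + 1,
                            "count": int(counts[i, j]),
                            "percent": block["cell_percent"][i][j],
                        })
                agree_rows.append({
                    "scope": scope, "statistic": stat, "scale": scale_name,
                    "n": block["n"], "kappa": block["kappa"],
                    "kappa_2dp": format_kappa(block["kappa"]),
                    "ci_low": ci[0], "ci_high": ci[1],
                    "percent_agreement": block["percent_agreement"],
                    "scheme": block["scheme"], "label": block["label"],
                })
    tables = {
        "distribution": pd.DataFrame(dist_rows),
        "agreement": pd.DataFrame(agree_rows),
    }
    return "\n".join(md), tables


def write_report(report: dict, out_dir: str | Path) -> None:
    """Write report.json plus rendered Markdown/CSV twins."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    md, tables = render_report(report)
    (out_dir / "report.md").write_text(md)
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
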