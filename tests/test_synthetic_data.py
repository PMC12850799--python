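"""Seeded generators: frames, rating streams, reader reports, cohorts."""

import numpy as np
import pandas as pd
import pytest

from ccegrade.agreement import build_contingency, cohen_kappa, weighted_kappa
from ccegrade.colon_model import SegmentBoundaries
from ccegrade.sequence_grading import grade_scope
from ccegrade.synthetic_data import (
    IDENTITY_CONFUSION,
    CohortConfig,
    generate_cohort,
    generate_frame_image,
    generate_rating_stream,
    generate_reader_report,
    study_like_config,
    write_cohort,
)

FIVE_B = SegmentBoundaries("five", (10, 30, 60, 90))


class TestGenerateFrameImage:
    @pytest.mark.parametrize(
        "fraction,size,expected",
        [(0.0, 64, 0), (1.0, 64, 64 * 64), (0.3, 256, 19661), (0.63, 10, 63)],
    )
    def test_exact_dirty_pixel_budget(self, fraction, size, expected):
        frame, mask = generate_frame_image(fraction, size=size, seed=0)
        assert mask.n_dirty == expected
        assert frame.shape == (size, size, 3) and frame.dtype == np.uint8

    def test_same_seed_is_bit_identical(self):
        f1, m1 = generate_frame_image(0.4, size=64, seed=9)
        f2, m2 = generate_frame_image(0.4, size=64, seed=9)
        assert np.array_equal(f1, f2) and np.array_equal(m1.dirty, m2.dirty)

    def test_different_seeds_move_the_blobs(self):
        _, m1 = generate_frame_image(0.4, size=64, seed=1)
        _, m2 = generate_frame_image(0.4, size=64, seed=2)
        assert not np.array_equal(m1.dirty, m2.dirty)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_fraction_out_of_range(self, bad):
        with pytest.raises(ValueError):
            generate_frame_image(bad, size=32)


class TestGenerateRatingStream:
    def test_noiseless_limit_recovers_latents_exactly(self):
        latents = [3, 1, 4, 2, 3]
        stream = generate_rating_stream(latents, FIVE_B, 100, noise=0.0, seed=0)
        cuts = (0, 10, 30, 60, 90, 100)
        for g, start, stop in zip(latents, cuts[:-1], cuts[1:]):
            seg = stream[start:stop]
            assert np.all(seg == g + 0.5)
            for stat in ("mean", "median", "q1", "q3", "p2", "p98"):
                assert int(grade_scope(seg, stat)[0]) == g

    def test_same_seed_is_bit_identical(self):
        s1 = generate_rating_stream([2] * 5, FIVE_B, 100, noise=0.4, seed=5)
        s2 = generate_rating_stream([2] * 5, FIVE_B, 100, noise=0.4, seed=5)
        assert np.array_equal(s1, s2)

    def test_ratings_stay_on_scale(self):
        stream = generate_rating_stream([1, 1, 4, 4, 2], FIVE_B, 100, noise=1.5, seed=3)
        assert np.all((stream >= 1.0) & (stream < 5.0))

    def test_median_grade_recovery_under_noise(self):
        """Monte Carlo: latent 3 at noise .4 is recovered by the median
        statistic in virtually every replicate."""
        b = SegmentBoundaries("three", (600, 1400))
        hits = 0
        for seed in range(500):
            stream = generate_rating_stream([3, 3, 3], b, 2000, noise=0.4, seed=seed)
            hits += int(grade_scope(stream, "median")[0]) == 3
        assert hits >= 495  # >= 99% of 500 replicates

    def test_invalid_latent_rejected(self):
        with pytest.raises(ValueError):
            generate_rating_stream([0, 2, 3, 4, 2], FIVE_B, 100)


class TestGenerateReaderReport:
    def test_identity_confusion_reproduces_latents(self):
        latents = [4, 2, 1, 3, 2]
        report = generate_reader_report("v0", latents, FIVE_B, IDENTITY_CONFUSION, seed=0)
        assert [int(g) for g in report.grades] == latents

    def test_adjacent_confusion_favors_weighted_kappa(self):
        """With disagreements leaking only to adjacent grades, weighted kappa
        credits the near-misses and exceeds unweighted kappa."""
        confusion = np.array(
            [
                [0.7, 0.3, 0.0, 0.0],
                [0.15, 0.7, 0.15, 0.0],
                [0.0, 0.15, 0.7, 0.15],
                [0.0, 0.0, 0.3, 0.7],
            ]
        )
        rng = np.random.default_rng(11)
        pairs = []
        for i in range(2000):
            latents = list(rng.integers(1, 5, 5))
            report = generate_reader_report(f"v{i}", latents, FIVE_B, confusion, rng)
            pairs.extend(zip(latents, (int(g) for g in report.grades)))
        t = build_contingency(pairs, k=4)
        assert weighted_kappa(t, "linear").kappa > cohen_kappa(t).kappa

    def test_non_stochastic_confusion_rejected(self):
        with pytest.raises(ValueError):
            generate_reader_report("v0", [1, 2, 3, 4, 1], FIVE_B, np.ones((4, 4)))


class TestGenerateCohort:
    def test_single_video_cohort_is_consistent(self):
        cohort = generate_cohort(CohortConfig(n_videos=1, seed=0))
        assert cohort.frame_scores["video_id"].nunique() == 1
        (vid,) = cohort.frame_scores["video_id"].unique()
        assert cohort.reader_reports[0].video_id == vid
        assert vid in cohort.ground_truth
        assert len(cohort.frame_scores) == cohort.ground_truth[vid]["n_frames"]

    def test_fixed_seed_reproduces_written_cohort_byte_for_byte(self, tmp_path):
        config = study_like_config(n_videos=5, seed=3)
        for d in ("a", "b"):
            write_cohort(generate_cohort(config), tmp_path / d)
        for name in ("frame_scores.csv", "reader_reports.csv", "ground_truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_written_cohort_reads_back(self, tmp_path):
        from ccegrade.frame_scoring import read_frame_scores
        from ccegrade.pipeline_io import read_reader_reports

        cohort = generate_cohort(study_like_config(n_videos=4, seed=1))
        write_cohort(cohort, tmp_path)
        df = read_frame_scores(tmp_path / "frame_scores.csv")
        reports = read_reader_reports(tmp_path / "reader_reports.csv")
        assert df["video_id"].nunique() == 4 and len(reports) == 4
        for orig, loaded in zip(cohort.reader_reports, reports):
            assert loaded.video_id == orig.video_id
            assert loaded.grades == orig.grades
            assert loaded.boundaries == orig.boundaries

    def test_study_like_marginals_single_seed(self):
        """One 842-video draw lands near the study's marginal rates."""
        cohort = generate_cohort(study_like_config(n_videos=842, seed=0))
        reader_nonacc = np.mean(
            [min(r.grades) == 1 for r in cohort.reader_reports]
        )
        aia_nonacc = np.mean(
            [
                grade_scope(g["rating"].to_numpy(), "mean")[0] == 1
                for _, g in cohort.frame_scores.groupby("video_id")
            ]
        )
        assert reader_nonacc * 100 == pytest.approx(26.37, abs=5)
        assert aia_nonacc * 100 == pytest.approx(5.94, abs=5)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_videos=0)
        with pytest.raises(ValueError):
            CohortConfig(latent_grade_distribution=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            CohortConfig(within_segment_noise=-0.1)
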