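"""Contingency tables, kappa statistics, and interpretation bands."""

import numpy as np
import pytest

from ccegrade.agreement import (
    ContingencyTable,
    agreement_weights,
    bootstrap_kappa_ci,
    build_contingency,
    cohen_kappa,
    format_kappa,
    interpret_kappa,
    percent_agreement,
    weighted_kappa,
)
from ccegrade.synthetic_data import UNIFORM_CONFUSION, generate_reader_report
from ccegrade.colon_model import SegmentBoundaries

from conftest import TABLE2_MEAN, TABLE2_MEDIAN, kappa_oracle, random_table


class TestBuildContingency:
    def test_diagonal_pairs(self):
        t = build_contingency([(1, 1), (2, 2)], k=2)
        assert t.counts.tolist() == [[1, 0], [0, 1]]
        assert t.n == 2

    def test_reconstructed_published_table(self):
        pairs = (
            [(1, 1)] * 26 + [(1, 2)] * 24 + [(2, 1)] * 196 + [(2, 2)] * 596
        )
        t = build_contingency(pairs, k=2)
        assert t.counts.tolist() == TABLE2_MEAN.tolist()
        assert t.n == 842

    def test_order_invariance(self):
        pairs = [(1, 2), (2, 1), (2, 2), (1, 1), (2, 2)]
        t1 = build_contingency(pairs, k=2)
        t2 = build_contingency(list(reversed(pairs)), k=2)
        assert np.array_equal(t1.counts, t2.counts)

    def test_out_of_range_grade_names_the_record(self):
        with pytest.raises(ValueError, match="record 1"):
            build_contingency([(1, 1), (5, 2)], k=4)


class TestPercentAgreement:
    def test_published_tables(self, table2_mean, table2_median):
        assert round(percent_agreement(table2_mean), 1) == 73.9
        assert round(percent_agreement(table2_median), 1) == 73.8

    def test_diagonal_table_is_full_agreement(self):
        assert percent_agreement(ContingencyTable(np.diag([3, 4, 5, 6]))) == 100.0


class TestCohenKappa:
    def test_published_binary_kappas(self, table2_mean, table2_median):
        r_mean = cohen_kappa(table2_mean)
        r_median = cohen_kappa(table2_median)
        assert round(r_mean.kappa, 2) == 0.10
        assert round(r_median.kappa, 2) == 0.12
        assert tuple(round(x, 2) for x in r_mean.ci95) == (0.05, 0.16)
        assert tuple(round(x, 2) for x in r_median.ci95) == (0.05, 0.18)
        assert r_mean.label == "None" and r_median.label == "None"

    def test_perfect_diagonal(self):
        r = cohen_kappa(ContingencyTable(np.diag([10, 20, 5, 7])))
        assert r.kappa == pytest.approx(1.0)
        assert r.po == pytest.approx(1.0)
        assert r.percent_agreement == 100.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            k = int(rng.integers(2, 5))
            t = random_table(rng, k)
            assert cohen_kappa(ContingencyTable(t)).kappa == pytest.approx(
                kappa_oracle(t), abs=1e-12
            )

    def test_matches_reference_implementations(self, table2_mean):
        """Cross-check kappa and SE against statsmodels and scikit-learn."""
        from sklearn.metrics import cohen_kappa_score
        from statsmodels.stats.inter_rater import cohens_kappa

        rng = np.random.default_rng(3)
        for _ in range(25):
            t = random_table(rng, 4)
            mine = cohen_kappa(ContingencyTable(t))
            ref = cohens_kappa(t, return_results=True)
            assert mine.kappa == pytest.approx(ref.kappa, abs=1e-12)
            assert mine.se == pytest.approx(ref.std_kappa, abs=1e-10)
            labels_a = np.repeat(np.arange(4), t.sum(axis=1))
            labels_b = np.concatenate([np.repeat(np.arange(4), row) for row in t])
            assert mine.kappa == pytest.approx(
                cohen_kappa_score(labels_a, labels_b), abs=1e-12
            )

    def test_degenerate_table_raises(self):
        with pytest.raises(ZeroDivisionError):
            cohen_kappa(ContingencyTable(np.array([[5, 0], [0, 0]])))

    def test_kappa_bounded_by_observed_agreement(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            t = random_table(rng, 3)
            r = cohen_kappa(ContingencyTable(t))
            assert r.kappa <= r.po + 1e-12

    def test_invariant_under_category_relabeling(self):
        rng = np.random.default_rng(12)
        t = random_table(rng, 4)
        perm = rng.permutation(4)
        k0 = cohen_kappa(ContingencyTable(t)).kappa
        k1 = cohen_kappa(ContingencyTable(t[np.ix_(perm, perm)])).kappa
        assert k0 == pytest.approx(k1, abs=1e-12)


class TestWeightedKappa:
    def test_two_by_two_linear_equals_unweighted(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            t = ContingencyTable(random_table(rng, 2))
            assert weighted_kappa(t, "linear").kappa == pytest.approx(
                cohen_kappa(t).kappa, abs=1e-12
            )

    @pytest.mark.parametrize("scheme", ["linear", "quadratic"])
    def test_perfect_diagonal(self, scheme):
        t = ContingencyTable(np.diag([4, 9, 2, 5]))
        assert weighted_kappa(t, scheme).kappa == pytest.approx(1.0)

    @pytest.mark.parametrize("scheme", ["linear", "quadratic"])
    def test_matches_brute_force_double_sum(self, scheme):
        rng = np.random.default_rng(21)
        k = 4
        w = agreement_weights(k, scheme).tolist()
        for _ in range(300):
            t = random_table(rng, k)
            assert weighted_kappa(ContingencyTable(t), scheme).kappa == pytest.approx(
                kappa_oracle(t, w), abs=1e-12
            )

    def test_quadratic_exceeds_linear_on_adjacent_disagreements(self):
        # Disagreements concentrated one category off the diagonal.
        t = ContingencyTable(
            np.array([[20, 10, 0, 0], [8, 25, 12, 0], [0, 9, 30, 11], [0, 0, 7, 18]])
        )
        assert weighted_kappa(t, "quadratic").kappa >= weighted_kappa(t, "linear").kappa

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            weighted_kappa(ContingencyTable(np.eye(3, dtype=int) * 2), "cubic")


class TestIndependenceAndUncertainty:
    def test_independent_raters_give_near_zero_kappa(self):
        """Simulated independent gradings with the published marginals."""
        rng = np.random.default_rng(2024)
        n = 10_000
        alg = rng.choice([1, 2], size=n, p=[0.0594, 0.9406])
        reader = rng.choice([1, 2], size=n, p=[0.2637, 0.7363])
        t = build_contingency(list(zip(alg, reader)), k=2)
        assert abs(cohen_kappa(t).kappa) < 0.05

    def test_uniform_confusion_reader_is_independent_of_latents(self):
        rng = np.random.default_rng(77)
        b = SegmentBoundaries("three", (10, 20))
        pairs = []
        for i in range(2000):
            latents = list(rng.integers(1, 5, 5))
            report = generate_reader_report(f"v{i}", latents, b, UNIFORM_CONFUSION, rng)
            pairs.extend(zip(latents, (int(g) for g in report.grades)))
        t = build_contingency(pairs, k=4)
        assert abs(cohen_kappa(t).kappa) < 0.05

    def test_bootstrap_ci_brackets_published_interval(self, table2_mean):
        lo, hi = bootstrap_kappa_ci(table2_mean, n_boot=2000, seed=1)
        assert lo == pytest.approx(0.05, abs=0.02)
        assert hi == pytest.approx(0.16, abs=0.02)


class TestInterpretation:
    @pytest.mark.parametrize(
        "kappa,label",
        [
            (0.10, "None"),
            (0.12, "None"),
            (0.20, "None"),
            (0.204, "None"),       # rounds half-up to .20
            (0.205, "Minimal"),    # rounds half-up to .21
            (0.21, "Minimal"),
            (0.39, "Minimal"),
            (0.40, "Weak"),
            (0.59, "Weak"),
            (0.69, "Moderate"),
            (0.79, "Moderate"),
            (0.80, "Strong"),
            (0.90, "Strong"),
            (0.91, "Almost perfect"),
            (1.00, "Almost perfect"),
            (-0.20, "None"),
            (-1.0, "None"),
        ],
    )
    def test_ladder(self, kappa, label):
        assert interpret_kappa(kappa) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.5)

    @pytest.mark.parametrize(
        "kappa,text", [(0.104, ".10"), (0.116, ".12"), (-0.2, "-.20"), (1.0, "1.00")]
    )
    def test_printed_style(self, kappa, text):
        assert format_kappa(kappa) == text
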