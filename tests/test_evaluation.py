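"""Sequence aggregation, metrics, LOSO protocol and paired comparison."""

import numpy as np
import pytest
from scipy import stats

from eventfall.core import AnnotatedSequence, ConfigError, TriaxialStream
from eventfall.evaluation import (
    ClassifierSpec,
    SegmenterSpec,
    aggregate_sequence,
    compute_fpr_fnr,
    compute_metrics,
    count_cost,
    loso_evaluate,
    wilcoxon_compare,
)
from eventfall.synth import GeneratorConfig, generate_dataset


def _annotated(category, label="x"):
    stream = TriaxialStream(100.0, np.tile([[0.0, 0.0, 1.0]], (10, 1)))
    return AnnotatedSequence(stream, label, category, "S0")


class TestAggregation:
    @pytest.mark.parametrize(
        "category, labels, expected",
        [
            ("fall", ["nonfall", "fall"], "TP"),
            ("fall", [], "FN"),
            ("fall", ["nonfall", "nonfall"], "FN"),
            ("nonfall", ["fall"], "FP"),
            ("nonfall", [], "TN"),
            ("nonfall", ["nonfall"], "TN"),
        ],
    )
    def test_rules(self, category, labels, expected):
        assert aggregate_sequence(labels, _annotated(category)) == expected


class TestMetrics:
    def test_direct_substitution(self):
        assert compute_metrics(2, 1, 0) == pytest.approx((2 / 3, 1.0, 0.8))

    def test_degenerate_denominators(self):
        precision, recall, fscore = compute_metrics(0, 0, 5)
        assert precision is None
        assert recall == 0.0
        assert fscore == 0.0

    def test_all_undefined_when_no_events(self):
        assert compute_metrics(0, 0, 0) == (None, None, None)

    @pytest.mark.parametrize("tp", [1, 7])
    def test_perfect_classifier(self, tp):
        assert compute_metrics(tp, 0, 0) == (1.0, 1.0, 1.0)

    def test_fscore_is_harmonic_mean(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            tp, fp, fn = (int(v) for v in rng.integers(1, 30, size=3))
            p, r, f = compute_metrics(tp, fp, fn)
            assert f == pytest.approx(2 * p * r / (p + r))

    def test_fpr_fnr_ratios(self):
        fpr, fnr = compute_fpr_fnr(
            {"near_fall": 3, "walking": 10}, {"fall_forward": 0}, {"near_fall": 10, "walking": 10, "fall_forward": 7}
        )
        assert fpr == {"near_fall": 0.3, "walking": 1.0}
        assert fnr == {"fall_forward": 0.0}

    def test_zero_total_omitted_with_warning(self):
        with pytest.warns(UserWarning):
            fpr, _ = compute_fpr_fnr({"ghost": 1}, {}, {"ghost": 0})
        assert fpr == {}


class TestLoso:
    @pytest.fixture(scope="class")
    @staticmethod
    def small_dataset():
        cfg = GeneratorConfig(
            seed=51, n_subjects=4, n_falls_per_subject=3,
            adl_counts={"walking": 1, "near_fall": 1, "standing": 1},
        )
        return generate_dataset(cfg)

    def test_single_subject_rejected(self, small_dataset):
        one = [s for s in small_dataset if s.subject_id == "S0"]
        with pytest.raises(ConfigError):
            loso_evaluate(one, SegmenterSpec(method="event"), ClassifierSpec("logreg"))

    def test_fold_count_equals_subjects(self, small_dataset):
        report = loso_evaluate(small_dataset, SegmenterSpec(method="event"), ClassifierSpec("logreg"))
        assert set(report.per_subject) == {"S0", "S1", "S2", "S3"}

    def test_outcomes_partition_dataset(self, small_dataset):
        for method in ("event", "fnsw"):
            report = loso_evaluate(
                small_dataset, SegmenterSpec(method=method), ClassifierSpec("logreg")
            )
            tp, fp, fn, tn = report.pooled_counts()
            assert tp + fp + fn + tn == len(small_dataset)

    def test_separable_dataset_perfect_with_logreg(self, small_dataset):
        report = loso_evaluate(small_dataset, SegmenterSpec(method="event"), ClassifierSpec("logreg"))
        for metrics in report.per_subject.values():
            assert metrics.metrics()[2] == pytest.approx(1.0)

    def test_deterministic(self, small_dataset):
        spec = SegmenterSpec(method="fosw", overlap_frac=0.5)
        clf = ClassifierSpec("svm", seed=3)
        a = loso_evaluate(small_dataset, spec, clf)
        b = loso_evaluate(small_dataset, spec, clf)
        assert a.pooled_counts() == b.pooled_counts()
        assert a.per_subject == b.per_subject

    def test_all_classifiers_run(self, small_dataset):
        for algorithm in ("cart", "knn", "logreg", "svm"):
            report = loso_evaluate(
                small_dataset, SegmenterSpec(method="event"), ClassifierSpec(algorithm)
            )
            assert report.pooled_counts()[0] > 0  # detects at least one fall


class TestCost:
    def test_fnsw_counts_closed_form(self):
        cfg = GeneratorConfig(seed=52, n_subjects=2, n_falls_per_subject=1, adl_counts={"walking": 2})
        dataset = generate_dataset(cfg)
        cost = count_cost(dataset, SegmenterSpec(method="fnsw", window_s=3.0))
        w = 300
        for sid, entry in cost.items():
            expected = sum(len(s.stream) // w for s in dataset if s.subject_id == sid)
            assert entry["segments"] == expected
            assert entry["feature_invocations"] == expected

    def test_overlap_monotonicity(self):
        cfg = GeneratorConfig(seed=53, n_subjects=2, n_falls_per_subject=1, adl_counts={"walking": 1})
        dataset = generate_dataset(cfg)
        totals = {}
        for overlap in (0.25, 0.9):
            cost = count_cost(dataset, SegmenterSpec(method="fosw", overlap_frac=overlap))
            totals[overlap] = sum(e["segments"] for e in cost.values())
        assert totals[0.9] >= totals[0.25]

    def test_event_zero_on_quiescent_dataset(self):
        cfg = GeneratorConfig(seed=54, n_subjects=2, n_falls_per_subject=0,
                              adl_counts={"standing": 2, "walking": 1})
        dataset = generate_dataset(cfg)
        cost = count_cost(dataset, SegmenterSpec(method="event"))
        assert all(e["feature_invocations"] == 0 for e in cost.values())


class TestWilcoxon:
    def test_identical_vectors(self):
        stat, p, significant = wilcoxon_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (stat, p, significant) == (0.0, 1.0, False)

    def test_five_positive_differences_exact(self):
        stat, p, _ = wilcoxon_compare([1, 2, 3, 4, 5], [0, 1, 2, 3, 4])
        assert p == pytest.approx(2 / 2**5)
        assert stat == pytest.approx(15.0)

    def test_swap_negates_statistic_same_p(self):
        rng = np.random.default_rng(61)
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.3, 1, 8)
        stat_ab, p_ab, _ = wilcoxon_compare(a, b)
        stat_ba, p_ba, _ = wilcoxon_compare(b, a)
        assert stat_ab == pytest.approx(-stat_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(62)
        for n in (4, 6, 9, 12):
            a = rng.normal(0, 1, n)
            b = rng.normal(0.4, 1, n)
            _, p, _ = wilcoxon_compare(a, b)
            expected = stats.wilcoxon(a, b, method="exact").pvalue
            assert p == pytest.approx(expected, rel=1e-12)

    def test_approximation_close_to_scipy_for_large_n(self):
        rng = np.random.default_rng(63)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 30)
        _, p, _ = wilcoxon_compare(a, b)
        expected = stats.wilcoxon(a, b, method="approx", correction=False).pvalue
        assert p == pytest.approx(expected, rel=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([1.0], [1.0, 2.0])
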