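"""Leave-one-subject-out evaluation, metrics and paired comparison.

Classification is binary (every fall type is a fall) and sequence-level: a
sequence counts as a detected fall when at least one of its segments is
classified as a fall. Per-subject true/false positive/negative counts yield

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F-score   = 2 TP / (2 TP + FP + FN)

with zero-denominator cases reported as an explicit ``None`` marker, never a
silent 0. Per-activity false positive / false negative ratios are
``FP_i / p_i`` and ``FN_i / q_i`` over each activity's sequence total.

Segment-level training labels are derived from the sequence annotation: a
segment of a fall sequence is labeled *fall* when its evaluation range (the
impact range for stage segments, the whole window for sliding windows)
overlaps the annotated event region; all segments of non-fall sequences are
non-falls. Classifier internals are delegated to scikit-learn; features are
z-scored with training-fold statistics for knn/logreg/svm, trees see raw
features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.neighbors import KNeighborsClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .baselines import CcaConfig, WindowSegment, cca_segment, fnsw_segment, fosw_segment
from .core import AnnotatedSequence, ConfigError, StageSegment, TriaxialStream
from .event_segmenter import EventSegmenterConfig, segment_stream
from .features import extract_feature_vector, window_features

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# classifier and segmenter specifications


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier algorithm with the evaluation defaults.

    ``cart``: decision tree; ``knn``: k=3 nearest neighbours with Euclidean
    distance and uniform weights; ``logreg``: logistic regression with
    inverse regularization C=1e9; ``svm``: linear-kernel SVC.
    """

    algorithm: str = "logreg"
    k: int = 3
    C: float = 1e9
    kernel: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("cart", "knn", "logreg", "svm"):
            raise ConfigError(f"unknown algorithm {self.algorithm!r}")

    def build(self):
        if self.algorithm == "cart":
            return DecisionTreeClassifier(random_state=self.seed)
        if self.algorithm == "knn":
            clf = KNeighborsClassifier(n_neighbors=self.k, weights="uniform", metric="euclidean")
        elif self.algorithm == "logreg":
            clf = LogisticRegression(C=self.C, max_iter=2000, random_state=self.seed)
        else:
            clf = SVC(kernel=self.kernel, random_state=self.seed)
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass(frozen=True)
class SegmenterSpec:
    """Which segmentation method feeds the classifier, and how.

    ``method`` is one of ``event``, ``fnsw``, ``fosw``, ``cca``. Sliding
    windows default to ``window_s`` = 3 s (the combined stage duration, so
    every method sees equal-duration evidence) and are featurized without
    stage alignment (``feature_split=1`` → 9 features; 3 → 27).
    ``min_overlap_frac`` is the minimum fraction of a segment's evaluation
    range that must overlap the annotated event region for a fall training
    label; 0 means any overlap.
    """

    method: str = "event"
    event_config: EventSegmenterConfig = field(default_factory=EventSegmenterConfig)
    window_s: float = 3.0
    overlap_frac: float = 0.9
    cca_config: CcaConfig = field(default_factory=CcaConfig)
    feature_split: int = 1
    min_overlap_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in ("event", "fnsw", "fosw", "cca"):
            raise ConfigError(f"unknown segmentation method {self.method!r}")

    def segment(self, stream: TriaxialStream) -> list:
        if self.method == "event":
            return segment_stream(stream, self.event_config)
        if self.method == "fnsw":
            return fnsw_segment(stream, self.window_s)
        if self.method == "fosw":
            return fosw_segment(stream, self.window_s, self.overlap_frac)
        return cca_segment(stream, self.cca_config)

    def featurize(self, stream: TriaxialStream, segments: list) -> np.ndarray:
        if not segments:
            return np.empty((0, 27 if self.method in ("event", "cca") else 9 * self.feature_split))
        if self.method in ("event", "cca"):
            return np.vstack([extract_feature_vector(s, stream).values for s in segments])
        return np.vstack(
            [
                window_features(stream.data[s.start : s.end], stream.fs, split=self.feature_split)
                for s in segments
            ]
        )

    @staticmethod
    def eval_range(segment) -> tuple[int, int]:
        if isinstance(segment, StageSegment):
            return segment.impact
        return segment.range

    def training_label(self, segment, sequence: AnnotatedSequence) -> str:
        if sequence.category != "fall":
            return "nonfall"
        region = sequence.event_region or (0, len(sequence.stream))
        lo, hi = self.eval_range(segment)
        overlap = max(0, min(hi, region[1]) - max(lo, region[0]))
        if self.min_overlap_frac > 0:
            return "fall" if overlap >= self.min_overlap_frac * (hi - lo) else "nonfall"
        return "fall" if overlap > 0 else "nonfall"


# ---------------------------------------------------------------------------
# sequence aggregation and metrics


def aggregate_sequence(segment_labels: Sequence[str], annotation: AnnotatedSequence) -> str:
    """Collapse per-segment labels to one sequence outcome (TP/FP/FN/TN)."""
    any_fall = any(lab == "fall" for lab in segment_labels)
    if annotation.category == "fall":
        return "TP" if any_fall else "FN"
    return "FP" if any_fall else "TN"


def compute_metrics(tp: int, fp: int, fn: int) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Precision, recall and F-score; ``None`` marks an undefined ratio."""
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    fscore = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else None
    return precision, recall, fscore


def compute_fpr_fnr(
    fp_counts: dict[str, int],
    fn_counts: dict[str, int],
    totals: dict[str, int],
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-activity false positive / false negative ratios.

    Activities with a zero total are omitted with a warning.
    """
    fpr, fnr = {}, {}
    for name, count in fp_counts.items():
        if totals.get(name, 0) <= 0:
            warnings.warn(f"activity {name!r} has zero total; FPR omitted")
            continue
        fpr[name] = count / totals[name]
    for name, count in fn_counts.items():
        if totals.get(name, 0) <= 0:
            warnings.warn(f"fall type {name!r} has zero total; FNR omitted")
            continue
        fnr[name] = count / totals[name]
    return fpr, fnr


@dataclass
class SubjectMetrics:
    subject_id: str
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def n_sequences(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def metrics(self) -> tuple[Optional[float], Optional[float], Optional[float]]:
        return compute_metrics(self.tp, self.fp, self.fn)


@dataclass
class MetricsReport:
    """Per-subject counts, pooled metrics, per-activity ratios, cost counters."""

    per_subject: dict[str, SubjectMetrics]
    fpr: dict[str, float]
    fnr: dict[str, float]
    segments_per_subject: dict[str, int]
    feature_invocations_per_subject: dict[str, int]

    def pooled_counts(self) -> tuple[int, int, int, int]:
        tp = sum(m.tp for m in self.per_subject.values())
        fp = sum(m.fp for m in self.per_subject.values())
        fn = sum(m.fn for m in self.per_subject.values())
        tn = sum(m.tn for m in self.per_subject.values())
        return tp, fp, fn, tn

    def pooled_metrics(self) -> tuple[Optional[float], Optional[float], Optional[float]]:
        tp, fp, fn, _ = self.pooled_counts()
        return compute_metrics(tp, fp, fn)

    def per_subject_fscores(self) -> list[float]:
        """Per-subject F-scores, skipping subjects where it is undefined."""
        out = []
        for m in self.per_subject.values():
            f = m.metrics()[2]
            if f is not None:
                out.append(f)
        return out

    def total_feature_invocations(self) -> int:
        return sum(self.feature_invocations_per_subject.values())


# ---------------------------------------------------------------------------
# leave-one-subject-out protocol


def _prepare(
    dataset: list[AnnotatedSequence], segmenter: SegmenterSpec
) -> list[tuple[AnnotatedSequence, list, np.ndarray, list[str]]]:
    prepared = []
    for seq in dataset:
        segments = segmenter.segment(seq.stream)
        feats = segmenter.featurize(seq.stream, segments)
        labels = [segmenter.training_label(s, seq) for s in segments]
        prepared.append((seq, segments, feats, labels))
    return prepared


def loso_evaluate(
    dataset: list[AnnotatedSequence],
    segmenter: SegmenterSpec,
    classifier: ClassifierSpec,
) -> MetricsReport:
    """Leave-one-subject-out cross-validation of a segmenter+classifier pair.

    One fold per subject: train on every other subject's segments, classify
    the held-out subject's segments, aggregate to sequence outcomes, and
    accumulate per-subject counts. Deterministic given the classifier seed.

    Raises :class:`~eventfall.core.ConfigError` with fewer than two subjects;
    a fold whose training data holds a single class is skipped with a
    warning.
    """
    subjects = list(dict.fromkeys(seq.subject_id for seq in dataset))
    if len(subjects) < 2:
        raise ConfigError("leave-one-subject-out needs at least two subjects")
    prepared = _prepare(dataset, segmenter)

    per_subject: dict[str, SubjectMetrics] = {}
    fp_counts: dict[str, int] = {}
    fn_counts: dict[str, int] = {}
    totals: dict[str, int] = {}
    seg_counts: dict[str, int] = {s: 0 for s in subjects}
    for seq, segments, _, _ in prepared:
        seg_counts[seq.subject_id] += len(segments)

    for held_out in subjects:
        train = [p for p in prepared if p[0].subject_id != held_out]
        test = [p for p in prepared if p[0].subject_id == held_out]
        x_parts = [feats for _, _, feats, _ in train if len(feats)]
        y_parts = [labels for _, _, _, labels in train if labels]
        if not x_parts:
            warnings.warn(f"fold {held_out}: no training segments; fold skipped")
            continue
        x_train = np.vstack(x_parts)
        y_train = np.array([lab for labels in y_parts for lab in labels])
        if len(set(y_train)) < 2:
            warnings.warn(f"fold {held_out}: single-class training data; fold skipped")
            continue
        clf = classifier.build()
        clf.fit(x_train, y_train)
        counts = SubjectMetrics(held_out)
        for seq, segments, feats, _ in test:
            predicted = list(clf.predict(feats)) if len(feats) else []
            outcome = aggregate_sequence(predicted, seq)
            setattr(counts, outcome.lower(), getattr(counts, outcome.lower()) + 1)
            totals[seq.label] = totals.get(seq.label, 0) + 1
            if outcome == "FP":
                fp_counts[seq.label] = fp_counts.get(seq.label, 0) + 1
            elif outcome == "FN":
                fn_counts[seq.label] = fn_counts.get(seq.label, 0) + 1
        per_subject[held_out] = counts

    fp_full = {lab: fp_counts.get(lab, 0) for lab in totals if any(
        seq.category == "nonfall" and seq.label == lab for seq in dataset)}
    fn_full = {lab: fn_counts.get(lab, 0) for lab in totals if any(
        seq.category == "fall" and seq.label == lab for seq in dataset)}
    fpr, fnr = compute_fpr_fnr(fp_full, fn_full, totals)
    return MetricsReport(
        per_subject=per_subject,
        fpr=fpr,
        fnr=fnr,
        segments_per_subject=seg_counts,
        feature_invocations_per_subject=dict(seg_counts),
    )


def count_cost(dataset: list[AnnotatedSequence], segmenter: SegmenterSpec) -> dict[str, dict[str, int]]:
    """Per-subject segment and feature-extraction invocation counts."""
    out: dict[str, dict[str, int]] = {}
    for seq in dataset:
        n = len(segmenter.segment(seq.stream))
        entry = out.setdefault(seq.subject_id, {"segments": 0, "feature_invocations": 0})
        entry["segments"] += n
        entry["feature_invocations"] += n
    return out


# ---------------------------------------------------------------------------
# paired comparison


def wilcoxon_compare(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Zero differences are dropped. The statistic is the signed-rank sum
    ``W+ - W-`` (negated when the samples are swapped). The null
    distribution is enumerated exactly for n <= 12 remaining pairs and
    normally approximated (tie-corrected) above. Returns
    ``(statistic, p_value, significant)`` with ``significant = p < alpha``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0, False
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    statistic = 2.0 * w_plus - ranks.sum()  # W+ - W-
    if n <= 12:
        # enumerate all 2^n sign assignments of the ranks
        masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        w_all = masks @ ranks
        p_low = np.mean(w_all <= w_plus + 1e-12)
        p_high = np.mean(w_all >= w_plus - 1e-12)
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
        p = min(1.0, p)
    return statistic, float(p), bool(p < alpha)
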