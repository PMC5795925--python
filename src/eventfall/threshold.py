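"""IMPACT+POSTURE threshold classifier and per-fold threshold fitting.

A fall trigger fires when any of four per-sample impact parameters exceeds
its threshold:

* ``SVtot`` — total sum vector, the acceleration vector magnitude (g);
* ``SVD`` — dynamic sum vector, the magnitude of the high-pass-filtered axes
  (first-order filter, 0.25 Hz cutoff), i.e. the gravity-free motion
  component (g);
* ``SVmaxmin`` — max − min of ``SVtot`` over a trailing 0.1 s window (g);
* ``Z2`` — vertical acceleration estimate ``(SVtot² − SVD² − 1)/2`` (g).

After a trigger, a lying posture is confirmed when the mean absolute
acceleration of the nominal vertical axis over a 2-s window starting 2 s
after the trigger is below 0.5 g; only then is the sequence classified as a
fall. The SVD/SVmaxmin/Z2 formulas and the posture timing are
reconstructions of the classical chest/waist threshold detector design; the
trigger thresholds themselves are fitted per training fold by an exhaustive
search over per-parameter decile candidates maximizing training F-score.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .core import AnnotatedSequence, ConfigError, TriaxialStream, seconds_to_samples


class FittingError(ValueError):
    """Threshold fitting needs both categories in the training data."""


@dataclass(frozen=True)
class ParameterSeries:
    """Per-sample impact parameters of one stream."""

    svtot: np.ndarray
    svd: np.ndarray
    svmaxmin: np.ndarray
    z2: np.ndarray

    def stacked(self) -> np.ndarray:
        return np.stack([self.svtot, self.svd, self.svmaxmin, self.z2])


PARAMETER_NAMES: tuple[str, ...] = ("svtot", "svd", "svmaxmin", "z2")


@dataclass(frozen=True)
class ThresholdSet:
    """Trigger thresholds plus the posture check configuration."""

    th_svtot: float
    th_svd: float
    th_svmaxmin: float
    th_z2: float
    posture_limit: float = 0.5
    posture_delay_s: float = 2.0
    posture_window_s: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.posture_limit < 1:
            raise ConfigError("posture_limit must be in (0, 1) g")

    def trigger_values(self) -> np.ndarray:
        return np.array([self.th_svtot, self.th_svd, self.th_svmaxmin, self.th_z2])


def compute_parameters(
    stream: TriaxialStream, fs: float | None = None, hp_cutoff_hz: float = 0.25,
    maxmin_window_s: float = 0.1,
) -> ParameterSeries:
    """Compute the four per-sample impact parameters.

    Raises
    ------
    ValueError
        If the stream is shorter than one max−min window.
    """
    fs = stream.fs if fs is None else fs
    win = max(1, seconds_to_samples(maxmin_window_s, fs))
    if len(stream) < win:
        raise ValueError(f"stream of length {len(stream)} shorter than {win}-sample window")
    svtot = stream.avm()
    b, a = signal.butter(1, hp_cutoff_hz, btype="highpass", fs=fs)
    filtered = signal.lfilter(b, a, stream.data, axis=0)
    svd = np.sqrt(np.einsum("ij,ij->i", filtered, filtered))
    # trailing-window max - min of SVtot (window [i-win+1, i], clipped at 0;
    # 'nearest' padding replicates sample 0, which is inside every clipped
    # window, so the result matches the clipped definition exactly)
    origin = (win - 1) // 2  # shift the filter window so its right edge is at i
    rmax = ndimage.maximum_filter1d(svtot, size=win, mode="nearest", origin=origin)
    rmin = ndimage.minimum_filter1d(svtot, size=win, mode="nearest", origin=origin)
    svmaxmin = rmax - rmin
    z2 = (svtot * svtot - svd * svd - 1.0) / 2.0
    return ParameterSeries(svtot, svd, svmaxmin, z2)


def classify_impact_posture(
    stream: TriaxialStream,
    thresholds: ThresholdSet,
    fs: float | None = None,
    vertical_axis: int = 2,
    parameters: ParameterSeries | None = None,
) -> str:
    """Classify one sequence as ``"fall"`` or ``"nonfall"``.

    The trigger fires at the first sample where any parameter exceeds its
    threshold; a fall is declared iff the posture check (mean |vertical
    acceleration| below ``posture_limit`` over the posture window) passes.
    A posture window extending past stream end is evaluated on the available
    suffix; an empty suffix yields ``"nonfall"``.
    """
    fs = stream.fs if fs is None else fs
    params = parameters if parameters is not None else compute_parameters(stream, fs)
    exceed = (params.stacked() > thresholds.trigger_values()[:, None]).any(axis=0)
    hits = np.nonzero(exceed)[0]
    if len(hits) == 0:
        return "nonfall"
    trigger = int(hits[0])
    return _posture_decision(stream, thresholds, fs, vertical_axis, trigger)


def _posture_decision(
    stream: TriaxialStream, thresholds: ThresholdSet, fs: float, vertical_axis: int, trigger: int
) -> str:
    lo = trigger + seconds_to_samples(thresholds.posture_delay_s, fs)
    hi = lo + seconds_to_samples(thresholds.posture_window_s, fs)
    window = stream.data[lo : min(hi, len(stream)), vertical_axis]
    if window.size == 0:
        return "nonfall"
    return "fall" if float(np.mean(np.abs(window))) < thresholds.posture_limit else "nonfall"


def _decile_candidates(per_sequence_maxima: np.ndarray, grid: int) -> np.ndarray:
    qs = np.linspace(0.0, 1.0, grid, endpoint=False)
    return np.unique(np.quantile(per_sequence_maxima, qs))


def fit_thresholds(
    training: list[AnnotatedSequence],
    fs: float | None = None,
    grid: int = 10,
    vertical_axis: int = 2,
    posture: ThresholdSet | None = None,
) -> ThresholdSet:
    """Fit trigger thresholds on a training split.

    For each parameter independently, candidate thresholds are ``grid``
    quantiles (deciles by default) of that parameter's per-sequence maxima
    over the training set; the joint set maximizing training F-score of
    :func:`classify_impact_posture` is selected by exhaustive search, with
    ties broken toward lower thresholds (favoring recall). Deterministic.

    Raises :class:`FittingError` if the training data holds a single class.
    """
    categories = {seq.category for seq in training}
    if categories != {"fall", "nonfall"}:
        raise FittingError(f"training data must contain both categories, got {categories}")
    base = posture if posture is not None else ThresholdSet(0, 0, 0, 0)
    fs = training[0].stream.fs if fs is None else fs

    series = [compute_parameters(seq.stream, fs) for seq in training]
    maxima = np.array([[s.stacked()[k].max() for s in series] for k in range(4)])
    candidates = [_decile_candidates(maxima[k], grid) for k in range(4)]

    # Precompute, per (sequence, parameter, candidate), the first sample
    # where the parameter crosses the candidate threshold, and the posture
    # decision a trigger at that sample would produce. The joint trigger of a
    # combo is the earliest crossing over the four parameters, so each combo
    # is then scored with a handful of vectorized reductions.
    n_seq = len(training)
    width = max(len(c) for c in candidates)
    fc = np.full((n_seq, 4, width), _NO_CROSS, dtype=np.int64)
    posture_fall = np.zeros((n_seq, 4, width), dtype=bool)
    for s in range(n_seq):
        stacked = series[s].stacked()
        cache: dict[int, bool] = {}
        for k in range(4):
            for ci, cand in enumerate(candidates[k]):
                trig = _first_crossing(stacked[k], float(cand))
                fc[s, k, ci] = trig
                if trig != _NO_CROSS:
                    if trig not in cache:
                        cache[trig] = (
                            _posture_decision(training[s].stream, base, fs, vertical_axis, trig)
                            == "fall"
                        )
                    posture_fall[s, k, ci] = cache[trig]
    is_fall = np.array([seq.category == "fall" for seq in training])
    seq_arange = np.arange(n_seq)
    k_arange = np.arange(4)

    best: tuple[float, tuple[float, float, float, float]] | None = None
    for combo_idx in itertools.product(*[range(len(c)) for c in candidates]):
        ci = np.array(combo_idx)
        crossings = fc[:, k_arange, ci]  # (n_seq, 4)
        first_k = np.argmin(crossings, axis=1)
        trig = crossings[seq_arange, first_k]
        predicted = (trig != _NO_CROSS) & posture_fall[seq_arange, first_k, ci[first_k]]
        tp = int(np.sum(predicted & is_fall))
        fp = int(np.sum(predicted & ~is_fall))
        fn = int(np.sum(~predicted & is_fall))
        denom = 2 * tp + fp + fn
        fscore = (2 * tp / denom) if denom else 0.0
        if best is None or fscore > best[0] + 1e-12:
            combo = tuple(float(candidates[k][combo_idx[k]]) for k in range(4))
            best = (fscore, combo)
    assert best is not None
    return ThresholdSet(
        th_svtot=best[1][0],
        th_svd=best[1][1],
        th_svmaxmin=best[1][2],
        th_z2=best[1][3],
        posture_limit=base.posture_limit,
        posture_delay_s=base.posture_delay_s,
        posture_window_s=base.posture_window_s,
    )


_NO_CROSS = 10**12  # sentinel: larger than any sample index


def _first_crossing(values: np.ndarray, threshold: float) -> int:
    hits = np.nonzero(values > threshold)[0]
    return int(hits[0]) if len(hits) else _NO_CROSS
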