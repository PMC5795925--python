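"""Per-stage feature functions and assembly of the 27-value feature vector.

Nine features are computed from each fall stage (pre-impact, impact,
post-impact) over the stage's acceleration-vector-magnitude (avm) series
``a_i`` with ``n`` samples and sample period ``dt = 1/fs``:

================  ==========================================================
``min_avm``       min of ``a_i`` (g)
``max_avm``       max of ``a_i`` (g)
``mean_avm``      mean of ``a_i`` (g)
``velocity``      gravity-compensated integral ``sum((a_i - 1) * g0 * dt)``
                  (m/s, signed)
``energy``        integrated squared magnitude ``sum(a_i**2 * dt)`` (g²·s)
``variance``      population variance of ``a_i`` (g²)
``rms``           ``sqrt(mean(a_i**2))`` (g)
``ema``           final value of the exponential moving average
                  ``e_0 = a_0``, ``e_i = alpha*a_i + (1-alpha)*e_{i-1}``
                  with ``alpha = 2/(n_ema+1)``, ``n_ema = round(0.5*fs)``
                  (a 0.5 s span) (g)
``sma``           signal magnitude area,
                  ``mean(|ax_i| + |ay_i| + |az_i|)`` (g)
================  ==========================================================

Velocity integrates ``avm - 1 g`` rather than a rotated vertical axis because
device orientation is unknown from a single accelerometer. Variance is the
population variance (stages have fixed length; no n-1 edge case at n = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import G0, StageSegment, TriaxialStream, avm as _avm

STAGE_FEATURE_NAMES: tuple[str, ...] = (
    "min_avm",
    "max_avm",
    "mean_avm",
    "velocity",
    "energy",
    "variance",
    "rms",
    "ema",
    "sma",
)

STAGES: tuple[str, ...] = ("pre", "impact", "post")

#: the 27 feature identifiers, in fixed order: stages outermost.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{stage}.{name}" for stage in STAGES for name in STAGE_FEATURE_NAMES
)


class InvalidSegmentError(ValueError):
    """A stage with no samples cannot be featurized."""


def ema_span_samples(fs: float) -> int:
    """Number of samples in the 0.5 s exponential-moving-average span."""
    return int(round(0.5 * fs))


def stage_features(samples: np.ndarray, fs: float, g0: float = G0) -> np.ndarray:
    """The nine feature values of one stage.

    Parameters
    ----------
    samples : ndarray of shape (n, 3)
        Tri-axial samples of the stage, in g; ``n >= 1``.
    fs : float
        Sampling rate in Hz.
    g0 : float
        Standard gravity in m/s², used by the velocity integral.

    Returns
    -------
    ndarray of shape (9,) ordered as :data:`STAGE_FEATURE_NAMES`.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3 or samples.shape[0] == 0:
        raise InvalidSegmentError(f"stage must have shape (n>=1, 3), got {samples.shape}")
    a = _avm(samples)
    dt = 1.0 / fs
    mean = float(a.mean())
    sq_mean = float(np.mean(a * a))
    velocity = float(np.sum(a - 1.0) * g0 * dt)
    energy = float(np.sum(a * a) * dt)
    variance = sq_mean - mean * mean
    rms = float(np.sqrt(sq_mean))
    n_ema = ema_span_samples(fs)
    alpha = 2.0 / (n_ema + 1)
    ema = float(a[0])
    for value in a[1:]:
        ema = alpha * value + (1.0 - alpha) * ema
    sma = float(np.mean(np.sum(np.abs(samples), axis=1)))
    return np.array(
        [float(a.min()), float(a.max()), mean, velocity, energy, max(variance, 0.0), rms, ema, sma]
    )


@dataclass(frozen=True)
class FeatureVector:
    """The 27 stage-aligned feature values with parallel names."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def extract_feature_vector(
    segment: StageSegment, stream: TriaxialStream, g0: float = G0
) -> FeatureVector:
    """Concatenate the nine features over pre, impact and post stages.

    Raises :class:`InvalidSegmentError` if any stage range is empty or falls
    outside the stream.
    """
    parts = []
    for stage, (lo, hi) in (("pre", segment.pre), ("impact", segment.impact), ("post", segment.post)):
        if not 0 <= lo < hi <= len(stream):
            raise InvalidSegmentError(
                f"{stage} range [{lo}, {hi}) empty or outside stream of length {len(stream)}"
            )
        parts.append(stage_features(stream.data[lo:hi], stream.fs, g0))
    return FeatureVector(np.concatenate(parts))


def window_features(samples: np.ndarray, fs: float, g0: float = G0, split: int = 1) -> np.ndarray:
    """Features of an unaligned sliding window.

    With ``split=1`` (default) the nine feature functions are computed over
    the whole window, yielding a 9-vector — the stage-blind treatment the
    sliding-window baselines are limited to. With ``split=3`` the window is
    cut into thirds and featurized per third for a 27-dimensional variant.
    """
    if split == 1:
        return stage_features(samples, fs, g0)
    if split == 3:
        n = samples.shape[0]
        bounds = [0, n // 3, 2 * n // 3, n]
        return np.concatenate(
            [stage_features(samples[bounds[k] : bounds[k + 1]], fs, g0) for k in range(3)]
        )
    raise ValueError(f"split must be 1 or 3, got {split}")
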