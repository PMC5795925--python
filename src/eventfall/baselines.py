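"""Sliding-window and cascade segmentation baselines.

``fnsw_segment`` and ``fosw_segment`` implement the fixed-size
non-overlapping / overlapping sliding windows that dominate machine-learning
fall detection; they segment blindly, with no alignment to fall stages.
``cca_segment`` implements the cascade approach: a 2-s non-overlapping
trigger window with a 1.6 g threshold anchors a 12-s stage split on the
window's highest peak, but performs no multi-peak re-anchoring — when a later,
higher peak falls outside the trigger window the impact stage is anchored on
the wrong peak, which is precisely the deficiency the event-triggered
segmenter removes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfigError, StageSegment, TriaxialStream, seconds_to_samples


@dataclass(frozen=True)
class WindowSegment:
    """A fixed-size window: a half-open sample range."""

    start: int
    end: int

    @property
    def range(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CcaConfig:
    """Cascade segmenter parameters.

    A 2-s trigger window with a 1.6 g threshold; on trigger, 1 s before the
    window's highest peak is the pre-impact stage and an 11-s tail after it
    holds the impact (first ``impact_s`` seconds) and post-impact stages.
    """

    trigger_window_s: float = 2.0
    tau_cca: float = 1.6
    pre_s: float = 1.0
    tail_s: float = 11.0
    impact_s: float = 1.0

    def __post_init__(self) -> None:
        if min(self.trigger_window_s, self.pre_s, self.tail_s, self.impact_s) <= 0:
            raise ConfigError("all CCA durations must be positive")
        if self.impact_s >= self.tail_s:
            raise ConfigError("impact_s must be smaller than tail_s")


def fnsw_segment(stream: TriaxialStream, window_s: float) -> list[WindowSegment]:
    """Fixed-size non-overlapping windows ``[kW, (k+1)W)``; count floor(L/W)."""
    if window_s <= 0:
        raise ConfigError("window_s must be positive")
    w = seconds_to_samples(window_s, stream.fs)
    n = len(stream) // w
    return [WindowSegment(k * w, (k + 1) * w) for k in range(n)]


def fosw_segment(
    stream: TriaxialStream, window_s: float, overlap_frac: float
) -> list[WindowSegment]:
    """Fixed-size overlapping windows with step ``max(1, round(W*(1-overlap)))``.

    With ``overlap_frac=0`` this reduces exactly to :func:`fnsw_segment`.
    """
    if not 0 <= overlap_frac < 1:
        raise ConfigError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    w = seconds_to_samples(window_s, stream.fs)
    step = max(1, int(round(w * (1.0 - overlap_frac))))
    L = len(stream)
    if L < w:
        return []
    count = (L - w) // step + 1
    return [WindowSegment(k * step, k * step + w) for k in range(count)]


def cca_segment(stream: TriaxialStream, config: CcaConfig | None = None) -> list[StageSegment]:
    """Cascade segmentation with threshold-triggered 12-s stage splits.

    Scans 2-s non-overlapping trigger windows; when a window's maximum avm
    exceeds the 1.6 g threshold, the window's highest sample becomes the
    anchor peak. Scanning resumes at the first trigger window starting after
    the emitted span. Segments whose pre or impact span would leave the
    stream are dropped; the post tail is clipped at stream end (at least one
    sample is required).
    """
    cfg = config if config is not None else CcaConfig()
    a = stream.avm()
    L = len(a)
    w = seconds_to_samples(cfg.trigger_window_s, stream.fs)
    n_pre = seconds_to_samples(cfg.pre_s, stream.fs)
    n_tail = seconds_to_samples(cfg.tail_s, stream.fs)
    n_imp = seconds_to_samples(cfg.impact_s, stream.fs)
    segments: list[StageSegment] = []
    k = 0
    while (k + 1) * w <= L:
        lo, hi = k * w, (k + 1) * w
        window = a[lo:hi]
        if window.max() > cfg.tau_cca:
            peak = lo + int(np.argmax(window))
            span_end = peak + n_tail
            imp_end = peak + n_imp
            post_end = min(span_end, L)
            if peak - n_pre >= 0 and imp_end <= L and post_end > imp_end:
                segments.append(
                    StageSegment(
                        peak_index=peak,
                        pre=(peak - n_pre, peak),
                        impact=(peak, imp_end),
                        post=(imp_end, post_end),
                    )
                )
            # resume at the first trigger window past the emitted 12-s span
            k = max(k + 1, -(-span_end // w))
        else:
            k += 1
    return segments
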