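"""Event-triggered fall-stage segmentation with a streaming finite state machine.

The segmenter consumes one tri-axial sample at a time and emits stage-aligned
segments: a pre-impact window of ``t_pre`` seconds ending at the highest
acceleration peak, an impact window of ``t_mp`` seconds starting at that peak,
and a post-impact window of ``t_sg`` seconds after the impact window.

Four states drive the machine:

``INITIAL_BUFFER``
    Runs once at start-up and collects ``t_pre`` seconds of samples so a full
    pre-impact window always exists when a peak is found.
``PEAK_DETECTION``
    Watches the acceleration vector magnitude (avm) for a *peak*: any sample
    with avm strictly above the threshold ``tau``.
``MULTI_PEAK``
    Resolves multi-peak ambiguity. A countdown of ``t_mp`` seconds runs from
    the recorded peak; any strictly higher sample before it expires becomes
    the new recorded peak and restarts the countdown, so the impact stage is
    always anchored at the highest peak of the burst and spans exactly
    ``t_mp``.
``SAMPLE_GATHERING``
    Collects the ``t_sg``-second post-impact window. Supra-threshold samples
    seen here are remembered as a *temporary peak*; after the segment is
    emitted the machine re-enters ``MULTI_PEAK`` anchored on that peak with
    the countdown reduced by the time already elapsed since it, so closely
    spaced events are not missed.

All durations are quantized as ``round(d * fs)`` samples and every range is
half-open in sample indices. A trailing event whose post window runs past the
end of the stream is dropped, never padded.
"""

from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import (
    ConfigError,
    StageSegment,
    TriaxialSample,
    TriaxialStream,
    compute_avm,
    seconds_to_samples,
)


class StreamError(ValueError):
    """Samples arrived out of order."""


class FsmState(enum.Enum):
    INITIAL_BUFFER = "initial_buffer"
    PEAK_DETECTION = "peak_detection"
    MULTI_PEAK = "multi_peak"
    SAMPLE_GATHERING = "sample_gathering"


@dataclass(frozen=True)
class EventSegmenterConfig:
    """Parameters of the event-triggered segmenter.

    Parameters
    ----------
    tau : float
        Peak threshold in g (default 1.8). Only samples with avm strictly
        above ``tau`` count as peaks; must exceed 1 g so quiet standing never
        triggers.
    t_pre, t_mp, t_sg : float
        Pre-impact, impact and post-impact stage durations in seconds
        (defaults 1, 1, 1).
    fs : float
        Sampling rate in Hz (default 100).
    """

    tau: float = 1.8
    t_pre: float = 1.0
    t_mp: float = 1.0
    t_sg: float = 1.0
    fs: float = 100.0

    def __post_init__(self) -> None:
        if self.tau <= 1.0:
            raise ConfigError(f"tau must exceed 1 g, got {self.tau}")
        if min(self.t_pre, self.t_mp, self.t_sg) <= 0:
            raise ConfigError("stage durations must be positive")
        if self.fs <= 0:
            raise ConfigError("fs must be positive")

    @property
    def n_pre(self) -> int:
        return seconds_to_samples(self.t_pre, self.fs)

    @property
    def n_mp(self) -> int:
        return seconds_to_samples(self.t_mp, self.fs)

    @property
    def n_sg(self) -> int:
        return seconds_to_samples(self.t_sg, self.fs)

    @property
    def buffer_size(self) -> int:
        """Ring-buffer capacity: one full segment, in samples."""
        return self.n_pre + self.n_mp + self.n_sg


@dataclass
class FsmRuntime:
    """Mutable state of the streaming segmenter.

    Memory is bounded: the ring buffer holds at most
    ``config.buffer_size`` samples. ``recorded_peak`` / ``temp_peak`` are
    ``(avm value, sample index)`` pairs; ``temp_peak is None`` plays the role
    of a zero temporary peak.
    """

    config: EventSegmenterConfig
    state: FsmState = FsmState.INITIAL_BUFFER
    buffer: deque = field(default_factory=deque)
    next_index: int = 0
    bft: int = 0
    mpt: int = 0
    sgt: int = 0
    recorded_peak: Optional[tuple[float, int]] = None
    temp_peak: Optional[tuple[float, int]] = None

    def __post_init__(self) -> None:
        self.buffer = deque(self.buffer, maxlen=self.config.buffer_size)
        if self.bft == 0:
            self.bft = self.config.n_pre


def fsm_step(
    runtime: FsmRuntime,
    sample: TriaxialSample,
    config: EventSegmenterConfig | None = None,
) -> tuple[FsmRuntime, Optional[StageSegment]]:
    """Consume one sample; return the updated runtime and any emitted segment.

    The runtime is updated in place (and also returned). Raises
    :class:`StreamError` if ``sample.index`` is not the successor of the last
    consumed index.
    """
    cfg = config if config is not None else runtime.config
    if sample.index != runtime.next_index:
        raise StreamError(
            f"expected sample index {runtime.next_index}, got {sample.index}"
        )
    runtime.next_index += 1
    i = sample.index
    a = compute_avm(sample)
    runtime.buffer.append((sample.ax, sample.ay, sample.az))
    emitted: Optional[StageSegment] = None

    if runtime.state is FsmState.INITIAL_BUFFER:
        runtime.bft -= 1
        if runtime.bft <= 0:
            runtime.state = FsmState.PEAK_DETECTION
        return runtime, None

    if runtime.state is FsmState.PEAK_DETECTION:
        if a > cfg.tau:
            runtime.recorded_peak = (a, i)
            runtime.mpt = cfg.n_mp
            runtime.state = FsmState.MULTI_PEAK
        return runtime, None

    if runtime.state is FsmState.MULTI_PEAK:
        assert runtime.recorded_peak is not None
        if a > runtime.recorded_peak[0]:
            # a strictly higher peak re-anchors the impact stage and restarts
            # the countdown in full (even on the sample where it would expire)
            runtime.recorded_peak = (a, i)
            runtime.mpt = cfg.n_mp
            return runtime, None
        runtime.mpt -= 1
        if runtime.mpt <= 0:
            # impact window complete; this sample opens the gathering window
            runtime.state = FsmState.SAMPLE_GATHERING
            runtime.sgt = cfg.n_sg
            runtime.temp_peak = None
            # fall through to gathering handling below
        else:
            return runtime, None

    if runtime.state is FsmState.SAMPLE_GATHERING:
        if a > cfg.tau and (runtime.temp_peak is None or a > runtime.temp_peak[0]):
            runtime.temp_peak = (a, i)
        runtime.sgt -= 1
        if runtime.sgt <= 0:
            assert runtime.recorded_peak is not None
            p = runtime.recorded_peak[1]
            emitted = StageSegment(
                peak_index=p,
                pre=(p - cfg.n_pre, p),
                impact=(p, p + cfg.n_mp),
                post=(p + cfg.n_mp, p + cfg.n_mp + cfg.n_sg),
            )
            if runtime.temp_peak is None:
                runtime.recorded_peak = None
                runtime.state = FsmState.PEAK_DETECTION
            else:
                q = runtime.temp_peak[1]
                runtime.recorded_peak = runtime.temp_peak
                runtime.temp_peak = None
                # countdown reduced by the time already elapsed since the
                # temporary peak, so its impact window still spans t_mp
                runtime.mpt = cfg.n_mp - (i - q)
                if runtime.mpt > 0:
                    runtime.state = FsmState.MULTI_PEAK
                else:
                    # impact window already elapsed during gathering
                    runtime.state = FsmState.SAMPLE_GATHERING
                    runtime.sgt = runtime.mpt + cfg.n_sg - 1
    return runtime, emitted


def segment_stream(
    stream: TriaxialStream, config: EventSegmenterConfig
) -> list[StageSegment]:
    """Run the state machine over a whole stream and collect emitted segments.

    Equivalent to folding :func:`fsm_step` over the samples in order. Raises
    :class:`~eventfall.core.ConfigError` if the stream's sampling rate does
    not match the configuration.
    """
    if stream.fs != config.fs:
        raise ConfigError(f"stream fs {stream.fs} != config fs {config.fs}")
    runtime = FsmRuntime(config)
    out: list[StageSegment] = []
    for sample in stream.samples():
        _, seg = fsm_step(runtime, sample)
        if seg is not None:
            out.append(seg)
    return out


def oracle_segment_stream(
    stream: TriaxialStream, config: EventSegmenterConfig
) -> list[StageSegment]:
    """Offline (non-streaming) reference segmenter.

    Scans the precomputed avm series left to right: anchor on the first
    supra-``tau`` sample, repeatedly re-anchor on any strictly higher sample
    occurring within ``t_mp`` of the current anchor, fix the peak, consume
    the impact and gathering spans, then continue from any supra-``tau``
    maximum recorded during the gathering span. Produces exactly the output
    of :func:`segment_stream`; exists as an independently-structured
    cross-check.
    """
    if stream.fs != config.fs:
        raise ConfigError(f"stream fs {stream.fs} != config fs {config.fs}")
    a = stream.avm()
    L = len(a)
    n_pre, n_mp, n_sg = config.n_pre, config.n_mp, config.n_sg
    segments: list[StageSegment] = []
    scan = n_pre  # first index evaluated after the initial buffer
    consumed = n_pre  # samples before this index have already been processed
    carried: Optional[int] = None
    while True:
        if carried is not None:
            p = carried
            carried = None
        else:
            above = np.nonzero(a[scan:] > config.tau)[0]
            if len(above) == 0:
                break
            p = scan + int(above[0])
        # re-anchor on the first strictly higher sample within t_mp; the
        # window is inclusive of the countdown-expiry sample itself
        while True:
            window = a[p + 1 : min(p + n_mp + 1, L)]
            higher = np.nonzero(window > a[p])[0]
            if len(higher) == 0:
                break
            p = p + 1 + int(higher[0])
        gather_start = p + n_mp
        gather_end = gather_start + n_sg
        if gather_end > L:
            break  # trailing incomplete event: dropped
        segments.append(
            StageSegment(
                peak_index=p,
                pre=(p - n_pre, p),
                impact=(p, gather_start),
                post=(gather_start, gather_end),
            )
        )
        # the temporary peak is sought only among not-yet-consumed samples of
        # the gathering span (the spans overlap when t_sg far exceeds t_mp)
        temp_lo = max(gather_start, consumed)
        gathered = a[temp_lo:gather_end]
        consumed = gather_end
        if len(gathered) and np.any(gathered > config.tau):
            carried = temp_lo + int(np.argmax(gathered))
        else:
            scan = gather_end
    return segments
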