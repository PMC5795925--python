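"""Streaming FSM segmenter: transition table, hand traces, oracle equivalence."""

import numpy as np
import pytest

from eventfall.core import ConfigError, TriaxialSample, TriaxialStream
from eventfall.event_segmenter import (
    EventSegmenterConfig,
    FsmRuntime,
    FsmState,
    StreamError,
    fsm_step,
    oracle_segment_stream,
    segment_stream,
)
from eventfall.synth import GeneratorConfig, _sequence_rng, generate_adl_sequence, generate_fall_sequence


def _run_to_state(avms, config):
    runtime = FsmRuntime(config)
    emitted = []
    for i, v in enumerate(avms):
        _, seg = fsm_step(runtime, TriaxialSample(i, 0.0, 0.0, v), config)
        if seg is not None:
            emitted.append(seg)
    return runtime, emitted


class TestFsmStep:
    def test_sub_threshold_sample_keeps_peak_detection(self, default_segmenter_config):
        runtime, emitted = _run_to_state([1.0] * 150, default_segmenter_config)
        assert runtime.state is FsmState.PEAK_DETECTION
        assert emitted == []

    def test_higher_peak_resets_multi_peak_countdown(self, default_segmenter_config):
        cfg = default_segmenter_config
        avms = [1.0] * 150 + [2.5] + [1.0] * 30 + [3.0]
        runtime, _ = _run_to_state(avms, cfg)
        assert runtime.state is FsmState.MULTI_PEAK
        assert runtime.recorded_peak == (3.0, len(avms) - 1)
        assert runtime.mpt == cfg.n_mp

    def test_gathering_expiry_without_temp_peak_returns_to_peak_detection(
        self, default_segmenter_config
    ):
        avms = [1.0] * 600
        avms[300] = 2.5
        runtime, emitted = _run_to_state(avms[:500], default_segmenter_config)
        assert len(emitted) == 1
        assert runtime.state is FsmState.PEAK_DETECTION
        assert runtime.temp_peak is None

    def test_out_of_order_sample_rejected(self, default_segmenter_config):
        runtime = FsmRuntime(default_segmenter_config)
        fsm_step(runtime, TriaxialSample(0, 0, 0, 1.0))
        with pytest.raises(StreamError):
            fsm_step(runtime, TriaxialSample(5, 0, 0, 1.0))

    def test_bounded_memory(self, default_segmenter_config, stream_from_avm):
        cfg = default_segmenter_config
        rng = np.random.default_rng(0)
        stream = stream_from_avm(1.0 + rng.uniform(0, 2, size=2000))
        runtime = FsmRuntime(cfg)
        for sample in stream.samples():
            fsm_step(runtime, sample)
            assert len(runtime.buffer) <= cfg.buffer_size


class TestHandTraces:
    """The four worked transcripts of the streaming segmenter."""

    def test_single_peak(self, stream_from_avm, default_segmenter_config):
        a = np.ones(600)
        a[300] = 2.5
        [seg] = segment_stream(stream_from_avm(a), default_segmenter_config)
        assert (seg.peak_index, seg.pre, seg.impact, seg.post) == (
            300, (200, 300), (300, 400), (400, 500))

    def test_two_peak_reanchoring(self, stream_from_avm, default_segmenter_config):
        a = np.ones(600)
        a[300] = 2.5
        a[340] = 3.0
        [seg] = segment_stream(stream_from_avm(a), default_segmenter_config)
        assert (seg.peak_index, seg.pre, seg.impact, seg.post) == (
            340, (240, 340), (340, 440), (440, 540))

    def test_gathering_temp_peak_with_carry_over_timer(
        self, stream_from_avm, default_segmenter_config
    ):
        a = np.ones(700)
        a[300] = 2.0
        a[450] = 2.2
        segs = segment_stream(stream_from_avm(a), default_segmenter_config)
        assert [s.peak_index for s in segs] == [300, 450]
        assert segs[1].impact == (450, 550)
        assert segs[1].post == (550, 650)

    def test_quiescent_stream_emits_nothing(self, stream_from_avm, default_segmenter_config):
        assert segment_stream(stream_from_avm(np.ones(1000)), default_segmenter_config) == []


class TestSegmentStream:
    def test_fs_mismatch_rejected(self, stream_from_avm, default_segmenter_config):
        with pytest.raises(ConfigError):
            segment_stream(stream_from_avm(np.ones(10), fs=50.0), default_segmenter_config)

    def test_trailing_incomplete_event_dropped(self, stream_from_avm, default_segmenter_config):
        a = np.ones(450)
        a[300] = 2.5  # post window [400, 500) extends past the stream end
        assert segment_stream(stream_from_avm(a), default_segmenter_config) == []

    def test_zero_emissions_below_threshold(self, stream_from_avm, default_segmenter_config):
        rng = np.random.default_rng(1)
        a = np.clip(1.0 + rng.normal(0, 0.2, size=3000), 0, 1.8)
        assert segment_stream(stream_from_avm(a), default_segmenter_config) == []

    def test_peak_dominates_impact_range(self, stream_from_avm, default_segmenter_config):
        rng = np.random.default_rng(2)
        a = 1.0 + rng.uniform(0, 2.5, size=4000)
        stream = stream_from_avm(a)
        segs = segment_stream(stream, default_segmenter_config)
        assert segs
        avms = stream.avm()
        for seg in segs:
            assert avms[seg.peak_index] > default_segmenter_config.tau
            assert avms[seg.peak_index] >= avms[slice(*seg.impact)].max()

    def test_impact_ranges_pairwise_disjoint_and_ordered(
        self, stream_from_avm, default_segmenter_config
    ):
        rng = np.random.default_rng(3)
        a = 1.0 + rng.uniform(0, 1.5, size=6000)
        segs = segment_stream(stream_from_avm(a), default_segmenter_config)
        for first, second in zip(segs, segs[1:]):
            assert first.peak_index < second.peak_index
            assert first.impact[1] <= second.impact[0]


class TestOracleEquivalence:
    def test_oracle_matches_hand_traces(self, stream_from_avm, default_segmenter_config):
        for build in (
            lambda: _with_peaks(600, {300: 2.5}),
            lambda: _with_peaks(600, {300: 2.5, 340: 3.0}),
            lambda: _with_peaks(700, {300: 2.0, 450: 2.2}),
            lambda: np.ones(50),
        ):
            stream = stream_from_avm(build())
            assert segment_stream(stream, default_segmenter_config) == oracle_segment_stream(
                stream, default_segmenter_config
            )

    def test_empty_stream(self, stream_from_avm, default_segmenter_config):
        assert oracle_segment_stream(stream_from_avm([]), default_segmenter_config) == []

    def test_equivalence_on_random_noise_streams(self, stream_from_avm):
        cfg = EventSegmenterConfig()
        rng = np.random.default_rng(4)
        for _ in range(50):
            length = int(rng.integers(50, 3000))
            a = 1.0 + rng.uniform(0, 1.8, size=length)
            stream = stream_from_avm(a)
            assert segment_stream(stream, cfg) == oracle_segment_stream(stream, cfg)

    def test_equivalence_with_asymmetric_stage_durations(self, stream_from_avm):
        # exercises the carry-over branch where the impact window of a
        # temporary peak has fully elapsed before re-entry
        cfg = EventSegmenterConfig(t_pre=0.5, t_mp=0.3, t_sg=1.5)
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = 1.0 + rng.uniform(0, 1.5, size=int(rng.integers(100, 2000)))
            stream = stream_from_avm(a)
            assert segment_stream(stream, cfg) == oracle_segment_stream(stream, cfg)


class TestAlignmentRecovery:
    def test_detected_peak_matches_generated_ground_impact(self):
        cfg = GeneratorConfig(seed=99)
        seg_cfg = EventSegmenterConfig()
        for i in range(50):
            rng = _sequence_rng(cfg, 7, i)
            seq, truth = generate_fall_sequence(cfg, "S7", rng)
            peaks = [s.peak_index for s in segment_stream(seq.stream, seg_cfg)]
            assert truth.true_impact_index in peaks


def _with_peaks(length, peaks):
    a = np.ones(length)
    for idx, value in peaks.items():
        a[idx] = value
    return a
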