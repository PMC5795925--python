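"""Seeded generator of annotated tri-axial accelerometer sequences.

Emulates the structure of laboratory fall / activities-of-daily-living (ADL)
recordings from a single body-worn accelerometer sampled at 100 Hz:

* **fall** sequences: quiet standing (avm ≈ 1 g, gravity on the z axis), a
  brief free-fall dip below 1 g, an impact burst of one to four
  supra-threshold half-sine peaks whose unique global maximum is the ground
  impact, then a low-variance lying period during which gravity moves to a
  horizontal axis (so posture checks are exercisable);
* **ADL** sequences: walking/standing/sitting/lying that stay within
  [0.4, 1.7] g, sitting down on the floor, and *near-falls* — an isolated
  supra-1.8 g peak with neither a preceding free-fall dip nor a lying period,
  the principal source of false alarms.

Waveforms are piecewise half-sine/constant envelopes on the gravity axis with
small independent truncated-Gaussian noise on all three axes (clipped at
±3 sd so the generator's amplitude invariants hold deterministically). Gaps
between impact-burst peaks are capped so the whole burst spans less than the
1-s impact window, which makes the highest peak reachable by multi-peak
re-anchoring in every generated fall.

Randomness derives from one root seed; each (subject, sequence) pair gets an
independent counter-derived substream, so generation is reproducible and
order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AnnotatedSequence, ConfigError, TriaxialStream, seconds_to_samples

FALL_LABELS: tuple[str, ...] = ("fall_forward", "fall_backward", "fall_left", "fall_right")
ADL_KINDS: tuple[str, ...] = ("walking", "sitting", "lying", "standing", "near_fall", "sit_floor")


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape parameters of the synthetic dataset.

    Ranges are (low, high) bounds for per-sequence uniform draws. Amplitude
    defaults are the implementer's choices (documented in the methods note);
    the stage structure they realize — sub-1 g dip, supra-threshold burst
    with a unique maximum, quiet lying — is what the event segmenter assumes.
    """

    fs: float = 100.0
    seed: int = 0
    n_subjects: int = 10
    n_falls_per_subject: int = 4
    adl_counts: dict = field(
        default_factory=lambda: {
            "walking": 2,
            "standing": 1,
            "sitting": 1,
            "lying": 1,
            "near_fall": 2,
            "sit_floor": 1,
        }
    )
    # fall shape
    freefall_depth_g: tuple[float, float] = (0.2, 0.7)
    freefall_dur_s: tuple[float, float] = (0.2, 0.5)
    n_impact_peaks: tuple[int, int] = (1, 4)
    peak_height_g: tuple[float, float] = (2.3, 5.5)
    inter_peak_gap_s: tuple[float, float] = (0.05, 0.4)
    burst_span_max_s: float = 0.85
    post_lying_dur_s: float = 3.0
    # adl shape
    walking_amp_g: float = 0.25
    near_fall_peak_g: tuple[float, float] = (2.0, 2.5)
    # noise and inter-subject variation
    noise_sd_g: float = 0.02
    subject_amp_jitter: float = 0.1
    subject_time_jitter: float = 0.1

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if self.n_impact_peaks[0] < 1:
            raise ConfigError("at least one impact peak is required")
        if self.post_lying_dur_s < 2:
            raise ConfigError("post_lying_dur_s must be at least 2 s")
        if self.noise_sd_g < 0:
            raise ConfigError("noise_sd_g must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth for one fall sequence.

    ``true_impact_index`` is the argmax of the generated avm series (the
    ground-impact peak); the other fields record the stage boundaries as
    generated, all half-open sample ranges.
    """

    true_impact_index: int
    freefall: tuple[int, int]
    impact_burst: tuple[int, int]
    lying_start: int


def _sequence_rng(config: GeneratorConfig, subject_idx: int, seq_idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, subject_idx, seq_idx]))


def _subject_factors(config: GeneratorConfig, subject_idx: int) -> tuple[float, float]:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, subject_idx]))
    amp = 1.0 + rng.uniform(-config.subject_amp_jitter, config.subject_amp_jitter)
    tim = 1.0 + rng.uniform(-config.subject_time_jitter, config.subject_time_jitter)
    return amp, tim


def _noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    if sd == 0:
        return np.zeros((n, 3))
    raw = rng.normal(0.0, sd, size=(n, 3))
    return np.clip(raw, -3 * sd, 3 * sd)


def _half_sine(height: float, n: int, baseline: float = 1.0) -> np.ndarray:
    """A pulse of ``n`` samples rising from baseline to ``height`` and back.

    ``n`` is forced odd so the apex lands exactly on the middle sample.
    """
    n = max(3, n | 1)
    phase = np.linspace(0.0, np.pi, n)
    return baseline + (height - baseline) * np.sin(phase)


def generate_fall_sequence(
    config: GeneratorConfig, subject_id: str, rng: np.random.Generator, label: str = "fall_forward"
) -> tuple[AnnotatedSequence, GroundTruth]:
    """One fall: standing → free-fall dip → impact burst → lying.

    The highest burst peak (the last pulse) is the ground impact; earlier
    pulses sit at least 0.3 g below it, so the global maximum is unique even
    after noise.
    """
    fs = config.fs
    subject_idx = _subject_index(subject_id)
    amp_f, time_f = _subject_factors(config, subject_idx)

    stand_n = seconds_to_samples(rng.uniform(2.0, 3.0) * time_f, fs)
    stand_n = max(stand_n, seconds_to_samples(1.5, fs))
    z = [np.full(stand_n, 1.0)]

    ff_dur = rng.uniform(*config.freefall_dur_s) * time_f
    ff_n = max(3, seconds_to_samples(ff_dur, fs))
    depth = rng.uniform(*config.freefall_depth_g)
    dip = 1.0 - (1.0 - depth) * np.sin(np.linspace(0.0, np.pi, ff_n))
    freefall_lo = stand_n
    z.append(dip)

    n_peaks = int(rng.integers(config.n_impact_peaks[0], config.n_impact_peaks[1] + 1))
    main_h = rng.uniform(*config.peak_height_g)
    gap_hi = config.inter_peak_gap_s[1]
    if n_peaks > 1:
        # cap gaps so the first-apex→highest-apex span (gaps plus pulse
        # widths, each ≤ 0.13 s) stays below one impact window
        span_budget = (config.burst_span_max_s - 0.13 * (n_peaks - 1)) / (n_peaks - 1)
        gap_hi = min(gap_hi, max(config.inter_peak_gap_s[0], span_budget))
    burst_lo = freefall_lo + ff_n
    burst = []
    for k in range(n_peaks):
        if k > 0:
            gap_n = seconds_to_samples(rng.uniform(config.inter_peak_gap_s[0], gap_hi), fs)
            burst.append(np.full(max(gap_n, 1), 1.0))
        height = main_h if k == n_peaks - 1 else rng.uniform(1.9, main_h - 0.3)
        pulse_n = seconds_to_samples(rng.uniform(0.06, 0.12), fs)
        burst.append(_half_sine(height, pulse_n))
    burst_arr = np.concatenate(burst)
    z.append(burst_arr)
    burst_hi = burst_lo + len(burst_arr)

    lying_n = seconds_to_samples(config.post_lying_dur_s * time_f, fs)
    lying_n = max(lying_n, seconds_to_samples(2.0, fs))
    lying_start = burst_hi
    z.append(np.zeros(lying_n))  # gravity leaves the vertical axis

    z_axis = np.concatenate(z)
    n = len(z_axis)
    data = np.zeros((n, 3))
    data[:, 2] = z_axis
    data[lying_start:, 0] = 1.0  # lying: gravity on a horizontal axis
    data += _noise(rng, n, config.noise_sd_g * 0.5 if config.noise_sd_g else 0.0)

    stream = TriaxialStream(fs, data)
    a = stream.avm()
    true_impact = int(np.argmax(a))
    truth = GroundTruth(
        true_impact_index=true_impact,
        freefall=(freefall_lo, freefall_lo + ff_n),
        impact_burst=(burst_lo, burst_hi),
        lying_start=lying_start,
    )
    seq = AnnotatedSequence(
        stream, label, "fall", subject_id, event_region=(burst_lo, burst_hi)
    )
    return seq, truth


def generate_adl_sequence(
    kind: str, config: GeneratorConfig, subject_id: str, rng: np.random.Generator
) -> AnnotatedSequence:
    """One non-fall activity bout of the given kind."""
    if kind not in ADL_KINDS:
        raise ConfigError(f"unknown ADL kind {kind!r}; choose from {ADL_KINDS}")
    fs = config.fs
    subject_idx = _subject_index(subject_id)
    amp_f, time_f = _subject_factors(config, subject_idx)
    dur_n = seconds_to_samples(rng.uniform(5.0, 8.0) * time_f, fs)
    t = np.arange(dur_n) / fs
    data = np.zeros((dur_n, 3))

    if kind == "standing":
        data[:, 2] = 1.0
    elif kind == "sitting":
        data[:, 2] = 1.0 + 0.03 * amp_f * np.sin(2 * np.pi * 0.3 * t)
    elif kind == "lying":
        data[:, 0] = 1.0
    elif kind == "walking":
        freq = rng.uniform(1.6, 2.2)
        amp = config.walking_amp_g * amp_f
        data[:, 2] = 1.0 + amp * np.sin(2 * np.pi * freq * t)
        data[:, 0] = (amp / 3.0) * np.sin(2 * np.pi * freq * t + rng.uniform(0, np.pi))
    elif kind == "sit_floor":
        data[:, 2] = 1.0
        bump_n = seconds_to_samples(0.3, fs)
        pos = dur_n // 2
        bump = _half_sine(rng.uniform(1.3, 1.6), bump_n)
        data[pos : pos + len(bump), 2] = bump[: max(0, dur_n - pos)]
    elif kind == "near_fall":
        data[:, 2] = 1.0
        h = rng.uniform(*config.near_fall_peak_g)
        pulse = _half_sine(h, seconds_to_samples(rng.uniform(0.08, 0.14), fs))
        pos = int(rng.integers(seconds_to_samples(2.0, fs), dur_n - len(pulse) - seconds_to_samples(1.0, fs)))
        data[pos : pos + len(pulse), 2] = pulse

    data += _noise(rng, dur_n, config.noise_sd_g)
    stream = TriaxialStream(fs, data)
    return AnnotatedSequence(stream, kind, "nonfall", subject_id)


def _subject_index(subject_id: str) -> int:
    """Stable small integer for a subject id of the form ``S<k>`` (else hash-free fallback)."""
    digits = "".join(ch for ch in subject_id if ch.isdigit())
    if digits:
        return int(digits)
    return sum(ord(c) for c in subject_id) % 10_000


def subject_ids(config: GeneratorConfig) -> list[str]:
    return [f"S{k}" for k in range(config.n_subjects)]


def generate_dataset(
    config: GeneratorConfig, return_truth: bool = False
) -> list[AnnotatedSequence] | tuple[list[AnnotatedSequence], dict[int, GroundTruth]]:
    """Generate the full annotated dataset.

    Sequences are ordered by subject, falls first; each sequence is drawn
    from its own counter-derived substream, so the result is deterministic
    under a fixed seed. With ``return_truth=True`` also returns a mapping
    from sequence position to the fall's :class:`GroundTruth`.
    """
    if config.n_subjects < 1:
        raise ConfigError("need at least one subject")
    total_per_subject = config.n_falls_per_subject + sum(config.adl_counts.values())
    if total_per_subject < 1:
        raise ConfigError("need at least one sequence per subject")
    sequences: list[AnnotatedSequence] = []
    truths: dict[int, GroundTruth] = {}
    for s_idx, sid in enumerate(subject_ids(config)):
        seq_idx = 0
        for f in range(config.n_falls_per_subject):
            rng = _sequence_rng(config, s_idx, seq_idx)
            label = FALL_LABELS[f % len(FALL_LABELS)]
            seq, truth = generate_fall_sequence(config, sid, rng, label=label)
            truths[len(sequences)] = truth
            sequences.append(seq)
            seq_idx += 1
        for kind in ADL_KINDS:
            for _ in range(config.adl_counts.get(kind, 0)):
                rng = _sequence_rng(config, s_idx, seq_idx)
                sequences.append(generate_adl_sequence(kind, config, sid, rng))
                seq_idx += 1
    if return_truth:
        return sequences, truths
    return sequences
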