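"""Core domain types, acceleration-vector-magnitude computation and CSV I/O.

Conventions used throughout the package:

* samples are 0-based and uniformly spaced; the time of sample ``i`` is
  ``i / fs`` seconds;
* every sample range is half-open, ``[start, end)``, in sample indices;
* a duration ``d`` in seconds maps to ``round(d * fs)`` samples;
* accelerations are stored in units of g (1 g = ``g0`` = 9.81 m/s²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: conventional standard gravity used for unit conversion and velocity
#: integration, in m/s².
G0 = 9.81


class FormatError(ValueError):
    """A CSV file does not conform to the expected layout."""


class ConfigError(ValueError):
    """An invalid configuration value."""


class InvalidSampleError(ValueError):
    """A sample with non-finite components."""


@dataclass(frozen=True)
class TriaxialSample:
    """One tri-axial accelerometer reading in g."""

    index: int
    ax: float
    ay: float
    az: float


def compute_avm(sample: TriaxialSample | Sequence[float]) -> float:
    """Acceleration vector magnitude sqrt(ax² + ay² + az²) of one sample, in g.

    Accepts a :class:`TriaxialSample` or any (ax, ay, az) triple.

    Raises
    ------
    InvalidSampleError
        If any component is not a finite real number.
    """
    if isinstance(sample, TriaxialSample):
        ax, ay, az = sample.ax, sample.ay, sample.az
    else:
        ax, ay, az = sample
    if not (math.isfinite(ax) and math.isfinite(ay) and math.isfinite(az)):
        raise InvalidSampleError(f"non-finite acceleration components: ({ax}, {ay}, {az})")
    return math.sqrt(ax * ax + ay * ay + az * az)


@dataclass
class TriaxialStream:
    """A uniformly sampled tri-axial acceleration sequence in g.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz; must be positive.
    data : ndarray of shape (n, 3)
        Per-sample (ax, ay, az) in g. Sample ``i`` occurs at ``i / fs`` s.
    """

    fs: float
    data: np.ndarray

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise ConfigError(f"data must have shape (n, 3), got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise InvalidSampleError("stream contains non-finite samples")

    def __len__(self) -> int:
        return self.data.shape[0]

    def avm(self) -> np.ndarray:
        """Per-sample acceleration vector magnitude, in g."""
        return np.sqrt(np.einsum("ij,ij->i", self.data, self.data))

    def samples(self) -> Iterable[TriaxialSample]:
        """Iterate over :class:`TriaxialSample` views of the stream."""
        for i, (x, y, z) in enumerate(self.data):
            yield TriaxialSample(i, float(x), float(y), float(z))


def avm(stream: TriaxialStream | np.ndarray) -> np.ndarray:
    """Vectorized acceleration vector magnitude of a stream or (n, 3) array."""
    if isinstance(stream, TriaxialStream):
        return stream.avm()
    a = np.asarray(stream, dtype=float)
    return np.sqrt(np.einsum("ij,ij->i", a, a))


@dataclass
class AnnotatedSequence:
    """A stream plus its activity annotation.

    ``category`` is the binary fall / non-fall label used for classifier
    evaluation; ``label`` keeps the free-text activity name (e.g. ``"near
    fall"`` or ``"F13"``). ``event_region`` optionally records the half-open
    sample range of the annotated fall event inside the stream (used to label
    training segments); it is ``None`` for sequences without a localized
    event annotation.
    """

    stream: TriaxialStream
    label: str
    category: str
    subject_id: str
    event_region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.category not in ("fall", "nonfall"):
            raise ConfigError(f"category must be 'fall' or 'nonfall', got {self.category!r}")


@dataclass(frozen=True)
class StageSegment:
    """A detected event with stage-aligned sample ranges.

    ``pre``, ``impact`` and ``post`` are contiguous half-open index ranges
    into the source stream; ``peak_index`` is the recorded (highest) peak and
    always equals ``impact[0]``.
    """

    peak_index: int
    pre: tuple[int, int]
    impact: tuple[int, int]
    post: tuple[int, int]

    @property
    def start(self) -> int:
        return self.pre[0]

    @property
    def end(self) -> int:
        return self.post[1]

    def stage_slices(self) -> dict[str, slice]:
        return {
            "pre": slice(*self.pre),
            "impact": slice(*self.impact),
            "post": slice(*self.post),
        }


def seconds_to_samples(duration_s: float, fs: float) -> int:
    """Map a duration in seconds to a sample count, ``round(d * fs)``."""
    return int(round(duration_s * fs))


# ---------------------------------------------------------------------------
# CSV I/O


@dataclass
class IoConfig:
    """Column map, unit mode and annotation configuration for CSV loading.

    ``unit`` is one of ``"g"`` (stored as-is), ``"m_s2"`` (divided by
    ``g0``) or ``"raw_counts"`` (multiplied by ``scale``). Dataset dialects
    (column names, per-dataset sampling rate, count scale) are configured
    here rather than hard-coded.
    """

    fs: float
    unit: str = "g"
    scale: float = 1.0
    g0: float = G0
    time_col: str = "time"
    axis_cols: tuple[str, str, str] = ("ax", "ay", "az")
    fall_labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.unit not in ("g", "m_s2", "raw_counts"):
            raise ConfigError(f"unknown unit mode {self.unit!r}")
        if self.fs <= 0:
            raise ConfigError("fs must be positive")


def _convert_units(values: np.ndarray, io_config: IoConfig) -> np.ndarray:
    if io_config.unit == "g":
        return values
    if io_config.unit == "m_s2":
        return values / io_config.g0
    return values * io_config.scale  # raw_counts


def read_stream_csv(
    path: str | Path,
    io_config: IoConfig,
    annotations: str | Path | pd.DataFrame | None = None,
    default_subject: str = "S0",
    default_label: str = "unknown",
) -> list[AnnotatedSequence]:
    """Load a stream CSV (``time,ax,ay,az``) into annotated sequences.

    When ``annotations`` is given (CSV or DataFrame with columns
    ``subject,label,category,start_s,end_s``) one sequence is cut per
    annotated activity bout; otherwise the whole file becomes a single
    sequence with the default subject/label and category derived from the
    configured fall-label set.

    Raises
    ------
    FormatError
        On missing columns or non-monotonic / duplicated timestamps.
    """
    df = pd.read_csv(path)
    needed = (io_config.time_col, *io_config.axis_cols)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns {missing} in {path}")
    t = df[io_config.time_col].to_numpy(dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise FormatError(f"non-monotonic or duplicated timestamps in {path}")
    data = _convert_units(df[list(io_config.axis_cols)].to_numpy(dtype=float), io_config)

    def _category(label: str) -> str:
        return "fall" if label in io_config.fall_labels else "nonfall"

    if annotations is None:
        stream = TriaxialStream(io_config.fs, data)
        return [
            AnnotatedSequence(stream, default_label, _category(default_label), default_subject)
        ]

    ann = annotations if isinstance(annotations, pd.DataFrame) else pd.read_csv(annotations)
    needed_ann = ("subject", "label", "category", "start_s", "end_s")
    missing = [c for c in needed_ann if c not in ann.columns]
    if missing:
        raise FormatError(f"missing annotation columns {missing}")
    sequences = []
    for row in ann.itertuples(index=False):
        lo = seconds_to_samples(float(row.start_s), io_config.fs)
        hi = seconds_to_samples(float(row.end_s), io_config.fs)
        if not 0 <= lo < hi <= len(data):
            raise FormatError(f"annotation [{row.start_s}, {row.end_s}] s outside stream")
        stream = TriaxialStream(io_config.fs, data[lo:hi])
        sequences.append(AnnotatedSequence(stream, str(row.label), str(row.category), str(row.subject)))
    return sequences


def write_stream_csv(stream: TriaxialStream, path: str | Path) -> None:
    """Write a stream as ``time,ax,ay,az`` CSV with accelerations in g."""
    t = np.arange(len(stream)) / stream.fs
    df = pd.DataFrame(
        {"time": t, "ax": stream.data[:, 0], "ay": stream.data[:, 1], "az": stream.data[:, 2]}
    )
    df.to_csv(path, index=False, float_format="%.9g")


_SEGMENT_COLUMNS = ("peak", "pre_start", "pre_end", "imp_start", "imp_end", "post_start", "post_end")


def write_segments_csv(segments: Sequence[StageSegment], path: str | Path) -> None:
    """Serialize segments to CSV (one row per segment, header always written)."""
    rows = [
        (s.peak_index, s.pre[0], s.pre[1], s.impact[0], s.impact[1], s.post[0], s.post[1])
        for s in segments
    ]
    pd.DataFrame(rows, columns=_SEGMENT_COLUMNS).to_csv(path, index=False)


def read_segments_csv(path: str | Path) -> list[StageSegment]:
    """Inverse of :func:`write_segments_csv`."""
    df = pd.read_csv(path)
    missing = [c for c in _SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing segment columns {missing} in {path}")
    return [
        StageSegment(
            peak_index=int(r.peak),
            pre=(int(r.pre_start), int(r.pre_end)),
            impact=(int(r.imp_start), int(r.imp_end)),
            post=(int(r.post_start), int(r.post_end)),
        )
        for r in df.itertuples(index=False)
    ]
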