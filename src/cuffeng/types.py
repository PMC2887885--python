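"""Core in-memory containers shared across the pipeline.

A recording is a single-channel voltage trace with stimulus-interval
annotations; a frame set is the result of slicing it into running
observation windows (ROWs) with per-window class labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyFrameError, InvalidConfigError

#: Canonical class identifiers. ``rest`` is the background state; the three
#: stimulus classes correspond to tactile (von Frey filament), proprioceptive
#: (passive toe flexion) and nociceptive (toe pinch) afferent activity.
REST = "rest"
VF = "vf"
PROPRIO = "proprio"
NOCIO = "nocio"
STIMULUS_CLASSES = (VF, PROPRIO, NOCIO)
ALL_CLASSES = (REST,) + STIMULUS_CLASSES


@dataclass(frozen=True)
class StimulusLabel:
    """One stimulus application: a labeled half-open interval [onset, offset)."""

    class_id: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if self.class_id not in STIMULUS_CLASSES:
            raise InvalidConfigError(f"unknown stimulus class {self.class_id!r}")
        if not self.offset_s > self.onset_s:
            raise InvalidConfigError(
                f"label offset ({self.offset_s}) must exceed onset ({self.onset_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class LabeledRecording:
    """Single-channel voltage trace with stimulus annotations.

    Samples are in arbitrary voltage units; intervals not covered by any
    label are the rest state.
    """

    samples: np.ndarray
    sampling_rate: float
    labels: list[StimulusLabel]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise InvalidConfigError("recording must be single-channel (1-D)")
        dur = self.duration_s
        for lab in self.labels:
            if lab.onset_s < 0 or lab.offset_s > dur + 1e-9:
                raise InvalidConfigError(
                    f"label {lab} lies outside the recording [0, {dur:.3f}] s"
                )
        starts = sorted((l.onset_s, l.offset_s) for l in self.labels)
        for (_, prev_off), (nxt_on, _) in zip(starts, starts[1:]):
            if nxt_on < prev_off - 1e-9:
                raise InvalidConfigError("stimulus intervals overlap")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate

    def class_set(self) -> tuple[str, ...]:
        present = {l.class_id for l in self.labels}
        return tuple(c for c in STIMULUS_CLASSES if c in present)


@dataclass(frozen=True)
class WindowConfig:
    """Running-observation-window geometry: length and fractional overlap."""

    row_ms: float = 100.0
    overlap_fraction: float = 0.0

    #: ROW lengths studied for the length sweep, in ms.
    STUDIED_ROWS = (25.0, 50.0, 75.0, 100.0, 125.0, 150.0, 200.0, 300.0)
    #: Overlap fractions studied for the overlap sweep.
    STUDIED_OVERLAPS = (0.0, 0.25, 0.5, 0.75)

    def __post_init__(self) -> None:
        if self.row_ms <= 0:
            raise InvalidConfigError("row_ms must be positive")
        if not 0 <= self.overlap_fraction < 1:
            raise InvalidConfigError("overlap_fraction must lie in [0, 1)")
        if self.step_ms <= 0:
            raise InvalidConfigError("window step must be positive")

    @property
    def step_ms(self) -> float:
        return self.row_ms * (1.0 - self.overlap_fraction)

    def window_samples(self, fs: float) -> int:
        return int(round(self.row_ms * fs / 1000.0))

    def step_samples(self, fs: float) -> int:
        step = int(round(self.step_ms * fs / 1000.0))
        if step < 1:
            raise InvalidConfigError("window step is below one sample")
        return step


@dataclass
class FrameSet:
    """Windowed signal segments with per-window labels and timebase."""

    frames: np.ndarray  # (n_windows, window_samples)
    window_times: np.ndarray  # window-center seconds
    window_labels: np.ndarray  # dtype=object / str, one of ALL_CLASSES
    window_config: WindowConfig
    sampling_rate: float
    duration_s: float  # duration of the source recording

    def __post_init__(self) -> None:
        if self.frames.ndim != 2 or self.frames.shape[0] == 0:
            raise EmptyFrameError("frame set contains no windows")
        if len(self.window_times) != self.n_windows:
            raise InvalidConfigError("window_times length mismatch")
        if len(self.window_labels) != self.n_windows:
            raise InvalidConfigError("window_labels length mismatch")

    @property
    def n_windows(self) -> int:
        return self.frames.shape[0]

    @property
    def window_samples(self) -> int:
        return self.frames.shape[1]

    def subset(self, mask: np.ndarray) -> "FrameSet":
        return FrameSet(
            frames=self.frames[mask],
            window_times=self.window_times[mask],
            window_labels=self.window_labels[mask],
            window_config=self.window_config,
            sampling_rate=self.sampling_rate,
            duration_s=self.duration_s,
        )


@dataclass
class DecisionStream:
    """Per-window class decisions with ground truth, time-ordered."""

    window_times: np.ndarray
    predicted: np.ndarray
    truth: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.window_times) == len(self.predicted) == len(self.truth)):
            raise InvalidConfigError("decision stream arrays must be equal length")
        if len(self.window_times) > 1 and np.any(np.diff(self.window_times) <= 0):
            raise InvalidConfigError("window times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.predicted)
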