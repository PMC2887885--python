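"""Decision smoothing, SNR measurement and performance reporting.

The majority-vote rule replaces each window decision by the modal class of
the 2k+1 decisions centered on it. Because the k future decisions must be
awaited before the smoothed output can be emitted, a real-time delay budget
(175–300 ms is imperceptible to a prosthesis user; 200 ms default) bounds
k: with window step ``ROW·(1 − overlap)`` ms and processing time t_p,

    k = round((delay_budget − t_p) / step),   usable decisions = 2k + 1.

SNR is the decibel ratio of mean window MAV during stimulation to mean
window MAV at rest, measured on the band-pass-filtered signal.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidConfigError, InvalidInputError
from .preprocess import bandpass_filter, frame_windows
from .types import REST, DecisionStream, LabeledRecording, WindowConfig

DEFAULT_DELAY_BUDGET_MS = 200.0


@dataclass(frozen=True)
class MVConfig:
    """Majority-vote neighborhood and the real-time budget that bounds it."""

    k: int = 2
    delay_budget_ms: float = DEFAULT_DELAY_BUDGET_MS
    processing_time_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise InvalidConfigError("k must be >= 0")

    @property
    def points(self) -> int:
        return 2 * self.k + 1


@dataclass
class EvalReport:
    """Accuracy, confusion counts and per-class SNR for one pipeline run."""

    accuracy: float
    confusion: pd.DataFrame  # rows: truth, columns: predicted
    raw_stream: DecisionStream
    voted_stream: DecisionStream
    raw_accuracy: float
    snr_by_class: dict[str, float] = field(default_factory=dict)
    config_provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "raw_accuracy": self.raw_accuracy,
            "confusion": {t: self.confusion.loc[t].to_dict() for t in self.confusion.index},
            "snr_by_class": self.snr_by_class,
            "config_provenance": self.config_provenance,
        }


def majority_vote(stream: DecisionStream, k: int) -> DecisionStream:
    """Smooth a decision stream with the 2k+1-point modal filter.

    At each position the output is the most frequent class among the k
    previous, current and k next decisions; a tie keeps the raw center
    decision; stream edges use the available truncated neighborhood.
    """
    if k < 0:
        raise InvalidConfigError("k must be >= 0")
    pred = stream.predicted
    n = len(pred)
    out = np.empty(n, dtype=object)
    for i in range(n):
        lo, hi = max(0, i - k), min(n, i + k + 1)
        counts = Counter(pred[lo:hi])
        top = max(counts.values())
        winners = [c for c, v in counts.items() if v == top]
        out[i] = winners[0] if len(winners) == 1 else pred[i]
    return DecisionStream(
        window_times=stream.window_times.copy(), predicted=out, truth=stream.truth.copy()
    )


def max_mv_points(
    row_ms: float,
    overlap_fraction: float,
    delay_budget_ms: float = DEFAULT_DELAY_BUDGET_MS,
    processing_time_ms: float = 0.0,
) -> int:
    """Maximum odd decision count 2k+1 allowed by the real-time constraint."""
    step = row_ms * (1.0 - overlap_fraction)
    if step <= 0:
        raise InvalidConfigError("window step must be positive")
    if delay_budget_ms < 0:
        raise InvalidConfigError("delay budget must be non-negative")
    k = int(round(max(delay_budget_ms - processing_time_ms, 0.0) / step))
    return 2 * k + 1


def snr_db(
    rec: LabeledRecording,
    class_id: str,
    row_ms: float = 100.0,
    prefiltered: bool = False,
) -> float:
    """MAV-ratio SNR of one stimulus class, in dB.

    20·log10( mean window MAV over class windows / mean window MAV over rest
    windows ), computed with disjoint windows on the band-passed signal.
    """
    filt = rec if prefiltered else bandpass_filter(rec)
    frames = frame_windows(filt, WindowConfig(row_ms=row_ms, overlap_fraction=0.0))
    stim = frames.window_labels == class_id
    rest = frames.window_labels == REST
    if not stim.any():
        raise InvalidInputError(f"no windows labeled {class_id!r}")
    if not rest.any():
        raise InvalidInputError("no rest windows")
    mavs = np.abs(frames.frames).mean(axis=1)
    return float(20.0 * np.log10(mavs[stim].mean() / mavs[rest].mean()))


def accuracy_report(
    pred: DecisionStream,
    voted: DecisionStream | None = None,
    snr_by_class: dict[str, float] | None = None,
    config_provenance: dict | None = None,
) -> EvalReport:
    """Accuracy and confusion counts for a (possibly smoothed) stream."""
    if len(pred) == 0:
        raise InvalidInputError("empty decision stream")
    voted = voted if voted is not None else pred
    classes = sorted(set(voted.truth) | set(voted.predicted) | set(pred.predicted))
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(voted.truth, voted.predicted):
        conf.loc[t, p] += 1
    acc = float(np.trace(conf.values) / conf.values.sum())
    raw_acc = float(np.mean(pred.predicted == pred.truth))
    return EvalReport(
        accuracy=acc,
        confusion=conf,
        raw_stream=pred,
        voted_stream=voted,
        raw_accuracy=raw_acc,
        snr_by_class=snr_by_class or {},
        config_provenance=config_provenance or {},
    )


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Rank-based H test across ≥2 groups (tie-corrected, χ² p-value).

    The nonparametric extension of the rank-sum test to more than two
    groups, used to compare classifier-configuration performance samples of
    unknown distribution. Identical data in all groups degenerates to
    H = 0, p = 1 with a warning.
    """
    if len(groups) < 2:
        raise InvalidInputError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise InvalidInputError("each group needs at least 2 values")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; Kruskal-Wallis is degenerate")
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)
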