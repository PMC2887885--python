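"""End-to-end experiment driver and parameter sweeps.

One experiment = generate (or load) a labeled recording, band-pass filter,
frame into ROWs, half-split chronologically, extract and normalize
features, train a classifier on the first half, predict on the second,
majority-vote the decision stream, and report accuracy/confusion/SNR.

The sweep helpers vary one configuration axis at a time (ROW length,
overlap + matched MV width, feature set, stimulus-combination ladder),
mirroring how the optimal operating point was identified.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import classify
from .evaluate import EvalReport, accuracy_report, majority_vote, max_mv_points, snr_db
from .features import FeatureSpec, extract_features, normalize_train_test
from .preprocess import bandpass_filter, frame_windows
from .synthetic import GeneratorConfig, generate_recording
from .types import LabeledRecording, WindowConfig


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one pipeline run depends on (all seeds included)."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    features: FeatureSpec = field(default_factory=FeatureSpec)
    classifier: str = "svm"  # "svm" | "ann"
    mv_points: int | None = None  # None -> maximum allowed by the delay budget
    delay_budget_ms: float = 200.0
    processing_time_ms: float = 0.0
    training_seed: int = 0

    def resolved_mv_points(self) -> int:
        if self.mv_points is not None:
            if self.mv_points % 2 != 1 or self.mv_points < 1:
                raise ValueError("mv_points must be a positive odd count")
            return self.mv_points
        return max_mv_points(
            self.window.row_ms,
            self.window.overlap_fraction,
            self.delay_budget_ms,
            self.processing_time_ms,
        )


def run_experiment(
    config: ExperimentConfig, rec: LabeledRecording | None = None
) -> EvalReport:
    """Execute the full pipeline and return its evaluation report.

    ``rec`` may be supplied to reuse an already generated/loaded recording
    (the generator config is then only provenance).
    """
    if rec is None:
        rec = generate_recording(config.generator)
    filt = bandpass_filter(rec)
    frames = frame_windows(filt, config.window)
    train_frames, test_frames = classify.split_half(frames)
    train_f = extract_features(train_frames, config.features)
    test_f = extract_features(test_frames, config.features)
    train_n, test_n = normalize_train_test(train_f, test_f)
    model = classify.train(train_n, kind=config.classifier, seed=config.training_seed)
    raw = classify.predict(model, test_n)
    k = (config.resolved_mv_points() - 1) // 2
    voted = majority_vote(raw, k)

    snrs = {}
    for c in rec.class_set():
        try:
            snrs[c] = snr_db(filt, c, row_ms=config.window.row_ms, prefiltered=True)
        except Exception:
            pass
    provenance = {
        "generator_seed": config.generator.seed,
        "generator_hash": config.generator.config_hash(),
        "training_seed": config.training_seed,
        "classifier": config.classifier,
        "row_ms": config.window.row_ms,
        "overlap_fraction": config.window.overlap_fraction,
        "mv_points": 2 * k + 1,
        "feature_names": list(config.features.column_names()),
        "model_parameters": {
            kk: vv for kk, vv in model.parameters.items() if np.isscalar(vv)
        },
    }
    return accuracy_report(raw, voted, snr_by_class=snrs, config_provenance=provenance)


def sweep_row(
    config: ExperimentConfig, row_lengths_ms: tuple[float, ...] = WindowConfig.STUDIED_ROWS
) -> dict[float, EvalReport]:
    """Vary the ROW length, everything else fixed (MV bound re-resolved)."""
    out = {}
    rec = generate_recording(config.generator)
    for row in row_lengths_ms:
        cfg = replace(config, window=replace(config.window, row_ms=row), mv_points=None)
        out[row] = run_experiment(cfg, rec=rec)
    return out


def sweep_overlap(
    config: ExperimentConfig,
    overlaps: tuple[float, ...] = WindowConfig.STUDIED_OVERLAPS,
) -> dict[float, EvalReport]:
    """Vary the overlap fraction with the matched maximal MV width."""
    out = {}
    rec = generate_recording(config.generator)
    for olap in overlaps:
        cfg = replace(
            config, window=replace(config.window, overlap_fraction=olap), mv_points=None
        )
        out[olap] = run_experiment(cfg, rec=rec)
    return out


def sweep_features(
    config: ExperimentConfig, feature_sets: tuple[str, ...]
) -> dict[str, EvalReport]:
    """Vary the feature set, everything else fixed."""
    out = {}
    rec = generate_recording(config.generator)
    for name in feature_sets:
        cfg = replace(config, features=replace(config.features, names=(name,)))
        out[name] = run_experiment(cfg, rec=rec)
    return out


def sweep_stimuli(
    config: ExperimentConfig,
    ladder: tuple[tuple[str, ...], ...] = (
        ("proprio",),
        ("vf", "proprio"),
        ("vf", "proprio", "nocio"),
    ),
) -> dict[tuple[str, ...], EvalReport]:
    """Discrimination ladder: one stimulus vs rest, then two, then three."""
    out = {}
    for classes in ladder:
        gen = replace(config.generator, classes=tuple(classes))
        out[tuple(classes)] = run_experiment(replace(config, generator=gen))
    return out
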