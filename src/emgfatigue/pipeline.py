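"""End-to-end orchestration: training, streaming test runs and summaries.

Glues the stages together under a single serializable run configuration,
emits the LED-style status stream (GREEN / ORANGE / RED) and produces the
per-subject accuracy and prediction summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from . import features as ft
from .errors import ConfigError
from .fuzzy import (
    FATIGUE,
    NON_FATIGUE,
    TRANSITION,
    LabelSeries,
    MembershipConfig,
    label_trial,
)
from .lda import LDAModel, accuracy_over_time, classify_series, fit_lda
from .predictor import (
    OnsetEvent,
    PredictionRecord,
    SubjectTransitionProfile,
    detect_ttf_onset,
    measure_transition_duration,
    prediction_error,
    predict_fatigue_time,
)
from .preprocessing import WindowSpec, zero_phase_bandpass
from .synthetic import TrialBundle

__all__ = [
    "RunConfig",
    "StatusEvent",
    "TestRunResult",
    "PredictionSummary",
    "trial_features",
    "trial_labels",
    "run_training",
    "run_test_stream",
    "summarize_accuracy",
    "summarize_predictions",
    "run_manifest",
]

GREEN, ORANGE, RED = "GREEN", "ORANGE", "RED"
_STATUS_FOR_LABEL = {NON_FATIGUE: GREEN, TRANSITION: ORANGE, FATIGUE: RED}
_SEVERITY = {GREEN: 0, ORANGE: 1, RED: 2}


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs, serializable to YAML with stable key order."""

    window_len: float = 1.0
    hop: float = 1.0
    filter_low: float = 1.0
    filter_high: float = 499.0
    filter_order: int = 5
    welch_segment_len: int = ft.DEFAULT_SEGMENT_LEN
    welch_overlap: float = ft.DEFAULT_OVERLAP
    band_low: float = ft.DEFAULT_BAND[0]
    band_high: float = ft.DEFAULT_BAND[1]
    normalization: str = "causal_zscore"
    baseline_windows: int = 10
    membership: MembershipConfig = field(default_factory=MembershipConfig)
    persistence: int = 3
    red_trigger: str = "labeller"  # or "predicted" (classifier-only mode)
    seed: int = 0

    def __post_init__(self):
        if self.red_trigger not in ("labeller", "predicted"):
            raise ConfigError("red_trigger must be 'labeller' or 'predicted'")
        if self.normalization not in ft.NORMALIZATION_MODES:
            raise ConfigError(f"unknown normalization mode: {self.normalization!r}")
        if self.persistence < 1:
            raise ConfigError("persistence must be >= 1")

    @property
    def window_spec(self) -> WindowSpec:
        return WindowSpec(self.window_len, self.hop)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("membership"), dict):
            d["membership"] = MembershipConfig(**d["membership"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class StatusEvent:
    """One LED-style status sample."""

    time: float
    status: str
    source: str  # "classifier" or "labeller"

    def __post_init__(self):
        if self.status not in (GREEN, ORANGE, RED):
            raise ConfigError("status must be GREEN, ORANGE or RED")


def trial_features(trial: TrialBundle, cfg: RunConfig) -> ft.FeatureSeries:
    """Filter the sEMG and extract the per-window composite feature."""
    filtered = zero_phase_bandpass(
        trial.emg, cfg.filter_low, cfg.filter_high, cfg.filter_order,
        clamp_high=True,
    )
    return ft.extract_features(
        filtered,
        cfg.window_spec,
        segment_len=cfg.welch_segment_len,
        overlap_fraction=cfg.welch_overlap,
        band=(cfg.band_low, cfg.band_high),
        normalization=cfg.normalization,
        baseline_windows=cfg.baseline_windows,
    )


def trial_labels(trial: TrialBundle, cfg: RunConfig) -> LabelSeries:
    """Fuzzy ground-truth labels for a trial (angle is used unfiltered)."""
    return label_trial(trial.angle, cfg.window_spec, cfg.membership)


def run_training(training_trials, cfg: RunConfig):
    """Fit the discriminant and the transition-duration profile.

    Features and fuzzy labels are computed per trial (normalization stays
    within-trial) and pooled for the two-class fit; the transition duration
    is measured on each trial's fuzzy labels and averaged.

    Returns ``(model, profile)``.
    """
    if not training_trials:
        raise ValueError("need at least one training trial")
    X_parts, y_parts, durations = [], [], []
    for trial in training_trials:
        feats = trial_features(trial, cfg)
        labels = trial_labels(trial, cfg)
        present = set(labels.labels.tolist())
        missing = [lab for lab in (NON_FATIGUE, TRANSITION, FATIGUE)
                   if lab not in present]
        if missing:
            raise ValueError(
                f"training trial {trial.subject_id!r} lacks label class(es): "
                f"{', '.join(missing)}"
            )
        X_parts.append(feats.values)
        y_parts.append(labels.labels)
        durations.append(measure_transition_duration(labels))
    model = fit_lda(np.vstack(X_parts), np.concatenate(y_parts))
    profile = SubjectTransitionProfile(
        training_trials[0].subject_id, tuple(durations)
    )
    return model, profile


@dataclass(frozen=True)
class TestRunResult:
    """Everything produced by one streaming test run."""

    status_events: tuple
    predicted_labels: LabelSeries
    truth_labels: LabelSeries
    scores: np.ndarray
    onset: Optional[OnsetEvent]
    predicted_fatigue_time: Optional[float]
    actual_fatigue_time: Optional[float]
    accuracy_times: np.ndarray
    accuracy_curve: np.ndarray
    prediction: Optional[PredictionRecord]

    @property
    def final_accuracy(self) -> float:
        return float(self.accuracy_curve[-1])


def run_test_stream(
    model: LDAModel,
    profile: SubjectTransitionProfile,
    trial: TrialBundle,
    cfg: RunConfig,
) -> TestRunResult:
    """Process a test trial in window order using only past samples.

    The feature normalization modes used here are causal, so the
    vectorized pass below equals true window-by-window streaming. Status
    starts GREEN, latches ORANGE when the classifier confirms a persistent
    transition run, and latches RED either at the fuzzy labeller's first
    Fatigue window (default) or at the predicted fatigue time
    (classifier-only deployment). The fuzzy labels also score the
    cumulative accuracy curve.
    """
    feats = trial_features(trial, cfg)
    truth = trial_labels(trial, cfg)
    predicted, scores = classify_series(model, feats.values, feats.times)

    onset = detect_ttf_onset(predicted, cfg.persistence)
    predicted_fatigue = (
        predict_fatigue_time(onset, profile) if onset is not None else None
    )

    fat_idx = np.flatnonzero(truth.labels == FATIGUE)
    actual_fatigue = float(truth.times[fat_idx[0]]) if fat_idx.size else None

    # Streaming status reconstruction with severity latching.
    events = []
    severity = 0
    run = 0
    for k, t in enumerate(predicted.times):
        run = run + 1 if predicted.labels[k] == TRANSITION else 0
        source = "classifier"
        level = 1 if run >= cfg.persistence else 0
        if cfg.red_trigger == "labeller":
            if actual_fatigue is not None and t >= actual_fatigue:
                level, source = 2, "labeller"
        else:
            if predicted_fatigue is not None and t >= predicted_fatigue:
                level = 2
        severity = max(severity, level)
        events.append(StatusEvent(float(t), [GREEN, ORANGE, RED][severity], source))

    acc_times, acc_curve = accuracy_over_time(predicted, truth)
    prediction = None
    if predicted_fatigue is not None and actual_fatigue is not None:
        prediction = prediction_error(actual_fatigue, predicted_fatigue)
    return TestRunResult(
        status_events=tuple(events),
        predicted_labels=predicted,
        truth_labels=truth,
        scores=scores,
        onset=onset,
        predicted_fatigue_time=predicted_fatigue,
        actual_fatigue_time=actual_fatigue,
        accuracy_times=acc_times,
        accuracy_curve=acc_curve,
        prediction=prediction,
    )


def summarize_accuracy(accuracies) -> tuple:
    """Arithmetic mean and sample (n-1) standard deviation, in percent."""
    vals = np.asarray(list(accuracies), dtype=float)
    if vals.size == 0:
        raise ValueError("no accuracies to summarize")
    if vals.size < 2:
        raise ValueError("sample standard deviation undefined for n < 2")
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


@dataclass(frozen=True)
class PredictionSummary:
    """Column means and sample sds of a set of prediction records.

    sd fields are ``None`` when only one record is available (the sample
    convention leaves them undefined); the means stay reportable.
    """

    n: int
    mean_actual_s: float
    mean_predicted_s: float
    mean_error_s: float
    mean_error_pct: float
    sd_actual_s: Optional[float]
    sd_predicted_s: Optional[float]
    sd_error_s: Optional[float]
    sd_error_pct: Optional[float]


def summarize_predictions(records) -> PredictionSummary:
    """Table-style summary of prediction records (means + sample sds)."""
    records = list(records)
    if not records:
        raise ValueError("no prediction records to summarize")
    cols = {
        "actual_s": np.array([r.actual_s for r in records]),
        "predicted_s": np.array([r.predicted_s for r in records]),
        "error_s": np.array([r.error_s for r in records]),
        "error_pct": np.array([r.error_pct for r in records]),
    }
    n = len(records)
    sds = {
        k: (float(np.std(v, ddof=1)) if n >= 2 else None) for k, v in cols.items()
    }
    return PredictionSummary(
        n=n,
        mean_actual_s=float(np.mean(cols["actual_s"])),
        mean_predicted_s=float(np.mean(cols["predicted_s"])),
        mean_error_s=float(np.mean(cols["error_s"])),
        mean_error_pct=float(np.mean(cols["error_pct"])),
        sd_actual_s=sds["actual_s"],
        sd_predicted_s=sds["predicted_s"],
        sd_error_s=sds["error_s"],
        sd_error_pct=sds["error_pct"],
    )


def run_manifest(cfg: RunConfig, extra: Optional[dict] = None) -> dict:
    """Reproducibility manifest: config hash, seed and package version."""
    from . import __version__

    text = cfg.to_yaml()
    manifest = {
        "config_sha256": hashlib.sha256(text.encode()).hexdigest(),
        "seed": cfg.seed,
        "package_version": __version__,
    }
    if extra:
        manifest.update(extra)
    return manifest


def write_manifest(cfg: RunConfig, path, extra: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        json.dump(run_manifest(cfg, extra), fh, indent=2, sort_keys=True)
        fh.write("\n")
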