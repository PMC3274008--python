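"""Transition-onset detection and time-to-fatigue prediction.

Once the classifier stream shows a persistent run of Transition-to-Fatigue
windows a timer starts; the fatigue time is predicted as that onset plus
the subject's mean training-trial transition duration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fuzzy import FATIGUE, TRANSITION, LabelSeries

__all__ = [
    "OnsetEvent",
    "SubjectTransitionProfile",
    "PredictionRecord",
    "detect_ttf_onset",
    "measure_transition_duration",
    "predict_fatigue_time",
    "prediction_error",
    "save_profile",
    "load_profile",
]

DEFAULT_PERSISTENCE = 3


@dataclass(frozen=True)
class OnsetEvent:
    """Detected transition onset; the fatigue onset is evaluation-only."""

    t_ttf_onset: float
    t_fatigue_onset: Optional[float] = None

    def __post_init__(self):
        if self.t_fatigue_onset is not None and not (
            self.t_fatigue_onset > self.t_ttf_onset
        ):
            raise ValueError("t_fatigue_onset must exceed t_ttf_onset")


@dataclass(frozen=True)
class SubjectTransitionProfile:
    """Per-subject transition durations measured on the training trials."""

    subject_id: str
    training_durations: tuple

    def __post_init__(self):
        durations = tuple(float(d) for d in self.training_durations)
        if any(d <= 0 for d in durations):
            raise ValueError("training durations must be > 0")
        object.__setattr__(self, "training_durations", durations)

    @property
    def mean_duration(self) -> float:
        if not self.training_durations:
            raise ValueError("profile has no training durations")
        return float(np.mean(self.training_durations))


@dataclass(frozen=True)
class PredictionRecord:
    """One subject's actual vs predicted seconds to fatigue."""

    actual_s: float
    predicted_s: float
    error_s: float = field(init=False)
    error_pct: float = field(init=False)

    def __post_init__(self):
        if not self.actual_s > 0:
            raise ValueError("actual_s must be > 0")
        object.__setattr__(self, "error_s", abs(self.actual_s - self.predicted_s))
        object.__setattr__(self, "error_pct", 100.0 * self.error_s / self.actual_s)


def detect_ttf_onset(predicted: LabelSeries,
                     persistence: int = DEFAULT_PERSISTENCE):
    """First window starting a run of >= ``persistence`` consecutive
    Transition-to-Fatigue predictions; ``None`` if no such run exists."""
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    if len(predicted) == 0:
        raise ValueError("empty label series")
    is_ttf = predicted.labels == TRANSITION
    run = 0
    for k, flag in enumerate(is_ttf):
        run = run + 1 if flag else 0
        if run >= persistence:
            return OnsetEvent(float(predicted.times[k - persistence + 1]))
    return None


def measure_transition_duration(labels: LabelSeries) -> float:
    """Seconds between the first Transition label and the first Fatigue
    label that follows it (typically on a fuzzy-labelled training trial)."""
    ttf_idx = np.flatnonzero(labels.labels == TRANSITION)
    fat_idx = np.flatnonzero(labels.labels == FATIGUE)
    if ttf_idx.size == 0:
        raise ValueError("series contains no TransitionToFatigue onset")
    if fat_idx.size == 0:
        raise ValueError("series contains no Fatigue onset")
    if fat_idx[0] < ttf_idx[0]:
        raise ValueError("Fatigue appears before any TransitionToFatigue")
    return float(labels.times[fat_idx[0]] - labels.times[ttf_idx[0]])


def predict_fatigue_time(onset: OnsetEvent,
                         profile: SubjectTransitionProfile) -> float:
    """Predicted absolute fatigue time: onset + mean training duration."""
    if not profile.training_durations:
        raise ValueError("profile has no training durations")
    return onset.t_ttf_onset + profile.mean_duration


def prediction_error(actual_s: float, predicted_s: float) -> PredictionRecord:
    """Absolute and percentage error of one fatigue-time prediction."""
    return PredictionRecord(float(actual_s), float(predicted_s))


def save_profile(profile: SubjectTransitionProfile, path) -> None:
    payload = {
        "subject_id": profile.subject_id,
        "training_durations": list(profile.training_durations),
        "mean_duration": profile.mean_duration,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_profile(path) -> SubjectTransitionProfile:
    with open(path) as fh:
        payload = json.load(fh)
    return SubjectTransitionProfile(
        payload["subject_id"], tuple(payload["training_durations"])
    )
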