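"""Fuzzy kinematic labeller.

Maps per-window elbow angle and angular oscillation (rolling std of the
angle) onto the three fatigue stages through a six-rule Mamdani-style rule
base with min-conjunction, max-aggregation and crisp argmax defuzzification.
Ties resolve toward the more fatigued class (safety-first for a warning
device).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigError, CoverageError
from .preprocessing import AngleSignal, WindowSpec, segment_windows

__all__ = [
    "NON_FATIGUE",
    "TRANSITION",
    "FATIGUE",
    "LABELS",
    "SEVERITY",
    "MembershipConfig",
    "LabelSeries",
    "angle_memberships",
    "oscillation_memberships",
    "fuzzy_label",
    "label_trial",
    "transition_deviation_threshold",
    "fatigue_deviation_threshold",
    "write_labels_csv",
]

NON_FATIGUE = "NonFatigue"
TRANSITION = "TransitionToFatigue"
FATIGUE = "Fatigue"
LABELS = (NON_FATIGUE, TRANSITION, FATIGUE)
SEVERITY = {NON_FATIGUE: 0, TRANSITION: 1, FATIGUE: 2}

_LOW = "Low"
_HIGH = "High"


@dataclass(frozen=True)
class MembershipConfig:
    """Piecewise-linear membership breakpoints.

    Angle sets act on the absolute deviation from ``baseline_angle``:
    NonFatigue is 1 up to ``d1`` and falls to 0 at ``d2``; Transition rises
    from ``d1`` to a peak at ``d2`` and falls to 0 at ``d3``; Fatigue rises
    from ``d2`` and saturates at ``d3``. Oscillation sets act on the rolling
    angle std: Low is 1 below ``s1``, High is 1 above ``s2``, with a linear
    crossover between. The breakpoints are not dictated by physiology here;
    they are exposed so deployments can calibrate them.
    """

    d1: float = 5.0
    d2: float = 10.0
    d3: float = 20.0
    s1: float = 1.0
    s2: float = 3.0
    baseline_angle: float = 90.0

    def __post_init__(self):
        if not 0 < self.d1 < self.d2 < self.d3:
            raise ConfigError("require 0 < d1 < d2 < d3")
        if not 0 < self.s1 < self.s2:
            raise ConfigError("require 0 < s1 < s2")
        if not 0 <= self.baseline_angle <= 180:
            raise ConfigError("baseline_angle must be within [0, 180]")


DEFAULT_MEMBERSHIP = MembershipConfig()


def transition_deviation_threshold(cfg: MembershipConfig = DEFAULT_MEMBERSHIP) -> float:
    """Smallest angle deviation labelled Transition under Low oscillation."""
    return 0.5 * (cfg.d1 + cfg.d2)


def fatigue_deviation_threshold(cfg: MembershipConfig = DEFAULT_MEMBERSHIP) -> float:
    """Smallest angle deviation labelled Fatigue (any oscillation)."""
    return 0.5 * (cfg.d2 + cfg.d3)


def _ramp_down(x, a, b):
    # 1 below a, 0 above b, linear between
    if x <= a:
        return 1.0
    if x >= b:
        return 0.0
    return (b - x) / (b - a)


def angle_memberships(angle_deg: float, cfg: MembershipConfig = DEFAULT_MEMBERSHIP):
    """Memberships of the three angle sets at one elbow angle (degrees)."""
    if not 0 <= angle_deg <= 180:
        raise ValueError(f"angle {angle_deg} outside [0, 180] degrees")
    x = abs(angle_deg - cfg.baseline_angle)
    mu_nf = _ramp_down(x, cfg.d1, cfg.d2)
    mu_f = 1.0 - _ramp_down(x, cfg.d2, cfg.d3)
    if x <= cfg.d1 or x >= cfg.d3:
        mu_ttf = 0.0
    elif x <= cfg.d2:
        mu_ttf = (x - cfg.d1) / (cfg.d2 - cfg.d1)
    else:
        mu_ttf = (cfg.d3 - x) / (cfg.d3 - cfg.d2)
    return {NON_FATIGUE: mu_nf, TRANSITION: mu_ttf, FATIGUE: mu_f}


def oscillation_memberships(std_deg: float, cfg: MembershipConfig = DEFAULT_MEMBERSHIP):
    """Memberships of the Low/High oscillation sets at one rolling std."""
    if std_deg < 0:
        raise ValueError("oscillation std must be >= 0")
    low = _ramp_down(std_deg, cfg.s1, cfg.s2)
    return {_LOW: low, _HIGH: 1.0 - low}


# (angle set, oscillation set) -> output class; six rules
_RULES = (
    (NON_FATIGUE, _LOW, NON_FATIGUE),
    (NON_FATIGUE, _HIGH, TRANSITION),
    (TRANSITION, _LOW, TRANSITION),
    (TRANSITION, _HIGH, TRANSITION),
    (FATIGUE, _LOW, FATIGUE),
    (FATIGUE, _HIGH, FATIGUE),
)


def fuzzy_label(angle_mu, osc_mu):
    """Evaluate the rule base and defuzzify to a crisp class.

    Returns ``(label, activations)`` where ``activations`` maps each output
    class to its max-aggregated rule strength.
    """
    act = {lab: 0.0 for lab in LABELS}
    for angle_set, osc_set, out in _RULES:
        act[out] = max(act[out], min(angle_mu[angle_set], osc_mu[osc_set]))
    best = max(act.values())
    if best <= 0:
        raise CoverageError("all rule activations are zero")
    label = max(LABELS, key=lambda lab: (act[lab], SEVERITY[lab]))
    return label, act


@dataclass(frozen=True)
class LabelSeries:
    """Per-window fatigue stage with provenance.

    ``source`` records whether the labels came from the fuzzy labeller
    ("fuzzy") or the trained classifier ("classifier").
    """

    times: np.ndarray
    labels: np.ndarray
    source: str = "fuzzy"
    memberships: Optional[dict] = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        labels = np.asarray(self.labels, dtype=object)
        if times.shape != labels.shape:
            raise ConfigError("times and labels must align")
        unknown = set(labels.tolist()) - set(LABELS)
        if unknown:
            raise ConfigError(f"unknown labels: {sorted(unknown)}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.times.shape[0]


def label_trial(
    angle: AngleSignal,
    spec: WindowSpec = WindowSpec(),
    cfg: MembershipConfig = DEFAULT_MEMBERSHIP,
) -> LabelSeries:
    """Label every window of a trial from its angle trace.

    Each window is summarized by its mean angle and sample std, which feed
    the rule base; window times match the feature extractor's for the same
    :class:`WindowSpec`.
    """
    centers, windows = segment_windows(angle, spec)
    means = windows.mean(axis=1)
    stds = np.std(windows, axis=1, ddof=1)
    labels = []
    acts = {lab: np.empty(len(centers)) for lab in LABELS}
    for k in range(len(centers)):
        lab, act = fuzzy_label(
            angle_memberships(float(means[k]), cfg),
            oscillation_memberships(float(stds[k]), cfg),
        )
        labels.append(lab)
        for name in LABELS:
            acts[name][k] = act[name]
    return LabelSeries(centers, np.array(labels, dtype=object),
                       source="fuzzy", memberships=acts)


def write_labels_csv(series: LabelSeries, path,
                     include_activations: bool = True) -> None:
    """Write a label series as CSV: time_s, label[, per-class activations]."""
    import pandas as pd

    data = {"time_s": series.times, "label": series.labels}
    if include_activations and series.memberships:
        for name in LABELS:
            data[f"activation_{name}"] = series.memberships[name]
    pd.DataFrame(data).to_csv(path, index=False)
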