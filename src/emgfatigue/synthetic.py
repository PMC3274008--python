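"""Seeded synthetic fatiguing-trial generator.

Produces sEMG whose per-window median frequency follows a programmed
trajectory (flat, then a linear decline between transition and fatigue
onset) with stagewise RMS scaling, plus a goniometer trace that drifts away
from the 90 degree target with growing oscillation after transition onset.
Every draw derives from the master seed, so bundles are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ConfigError
from .fuzzy import DEFAULT_MEMBERSHIP, fatigue_deviation_threshold
from .preprocessing import AngleSignal, MultiChannelSignal

__all__ = [
    "StageTimeline",
    "RMSProfile",
    "TimelineJitter",
    "SyntheticTrialConfig",
    "TrialBundle",
    "generate_semg",
    "generate_goniometer",
    "generate_trial",
    "generate_subject",
]


@dataclass(frozen=True)
class StageTimeline:
    """Programmed stage boundaries of one trial, in seconds."""

    t_transition_onset: float = 55.0
    t_fatigue_onset: float = 150.0
    t_end: float = 180.0

    def __post_init__(self):
        if not 0 < self.t_transition_onset < self.t_fatigue_onset < self.t_end:
            raise ConfigError(
                "timeline must satisfy 0 < t_transition_onset < "
                "t_fatigue_onset < t_end"
            )


@dataclass(frozen=True)
class RMSProfile:
    """Stagewise amplitude multipliers applied to the unit-RMS carrier."""

    non_fatigue: float = 1.0
    transition: float = 1.5
    fatigue: float = 2.0

    def __post_init__(self):
        for name in ("non_fatigue", "transition", "fatigue"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"rms_profile.{name} must be > 0")


@dataclass(frozen=True)
class TimelineJitter:
    """Uniform +/- perturbation (seconds) of per-trial stage boundaries."""

    transition_s: float = 0.0
    fatigue_s: float = 0.0

    def __post_init__(self):
        if self.transition_s < 0 or self.fatigue_s < 0:
            raise ConfigError("jitter magnitudes must be >= 0")


@dataclass(frozen=True)
class SyntheticTrialConfig:
    duration: float = 180.0
    sampling_rate: float = 1000.0
    n_emg_channels: int = 2
    timeline: StageTimeline = field(default_factory=StageTimeline)
    mf_start: float = 100.0
    mf_end: float = 60.0
    spectral_width_hz: float = 60.0
    rms_profile: RMSProfile = field(default_factory=RMSProfile)
    angle_baseline: float = 90.0
    # None -> calibrated so the deviation reaches the default labeller's
    # Fatigue decision boundary exactly at t_fatigue_onset.
    angle_drift_rate: Optional[float] = None
    osc_std_low: float = 0.3
    osc_std_high: float = 5.0
    osc_ramp_s: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not self.duration > 0:
            raise ConfigError("duration must be > 0")
        if not self.sampling_rate > 0:
            raise ConfigError("sampling_rate must be > 0")
        if self.n_emg_channels < 1:
            raise ConfigError("n_emg_channels must be >= 1")
        if not 0 < self.mf_end <= self.mf_start:
            raise ConfigError("require 0 < mf_end <= mf_start")
        if not self.spectral_width_hz > 0:
            raise ConfigError("spectral_width_hz must be > 0")
        half = self.spectral_width_hz / 2.0
        if self.mf_end - half <= 0:
            raise ConfigError("mf_end too low for spectral_width_hz")
        if self.mf_start + half >= self.sampling_rate / 2:
            raise ConfigError(
                "mf_start too high: band-limited synthesis needs "
                "mf_start + spectral_width_hz/2 < Nyquist"
            )
        if self.timeline.t_end > self.duration + 1e-9:
            raise ConfigError("timeline.t_end must not exceed duration")
        if not 0 <= self.osc_std_low <= self.osc_std_high:
            raise ConfigError("require 0 <= osc_std_low <= osc_std_high")
        if self.osc_ramp_s < 0:
            raise ConfigError("osc_ramp_s must be >= 0")
        if self.angle_drift_rate is not None and self.angle_drift_rate < 0:
            raise ConfigError("angle_drift_rate must be >= 0")
        if not 0 <= self.angle_baseline <= 180:
            raise ConfigError("angle_baseline must be within [0, 180]")


@dataclass(frozen=True)
class TrialBundle:
    """One contraction trial: signals, ground truth and role."""

    emg: MultiChannelSignal
    angle: AngleSignal
    timeline: Optional[StageTimeline]
    subject_id: str = "synthetic"
    trial_role: str = "testing"

    def __post_init__(self):
        if self.trial_role not in ("training", "testing"):
            raise ConfigError("trial_role must be 'training' or 'testing'")
        if abs(self.emg.sampling_rate - self.angle.sampling_rate) > 1e-9:
            raise ConfigError("emg and angle must share a sampling rate")
        if abs(self.emg.n_samples - self.angle.n_samples) > 1:
            raise ConfigError("emg and angle must share a duration")


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic sub-stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _median_freq_at(t: float, cfg: SyntheticTrialConfig) -> float:
    tl = cfg.timeline
    if t <= tl.t_transition_onset:
        return cfg.mf_start
    if t >= tl.t_fatigue_onset:
        return cfg.mf_end
    frac = (t - tl.t_transition_onset) / (tl.t_fatigue_onset - tl.t_transition_onset)
    return cfg.mf_start + frac * (cfg.mf_end - cfg.mf_start)


def _rms_envelope(t: np.ndarray, cfg: SyntheticTrialConfig) -> np.ndarray:
    tl, rp = cfg.timeline, cfg.rms_profile
    out = np.full(t.shape, rp.non_fatigue)
    out[t >= tl.t_transition_onset] = rp.transition
    out[t >= tl.t_fatigue_onset] = rp.fatigue
    return out


def resolved_drift_rate(cfg: SyntheticTrialConfig) -> float:
    """Drift rate in degrees/s, auto-calibrated when not set explicitly."""
    if cfg.angle_drift_rate is not None:
        return cfg.angle_drift_rate
    tl = cfg.timeline
    span = tl.t_fatigue_onset - tl.t_transition_onset
    return fatigue_deviation_threshold(DEFAULT_MEMBERSHIP) / span


def generate_semg(config: SyntheticTrialConfig) -> MultiChannelSignal:
    """Synthesize the multichannel sEMG carrier.

    Mechanism: overlap-add of half-overlapping sqrt-Hann-windowed blocks of
    band-limited Gaussian noise. Each block's spectrum is flat over
    ``[m - W/2, m + W/2]`` where ``m`` is the programmed median at the block
    center and ``W`` the spectral width, so the spectral median tracks the
    trajectory exactly; the unit-RMS result is then scaled by the stagewise
    RMS envelope. Channels use independent deterministic sub-streams of the
    master seed.
    """
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    block = max(int(round(0.5 * fs)) // 2 * 2, 16)  # even, ~0.5 s
    hop = block // 2
    win = np.sqrt(np.hanning(block + 1)[:block])  # periodic sqrt-Hann, OLA power 1
    freqs = np.fft.rfftfreq(block, 1.0 / fs)
    pad = block
    starts = range(-hop, n, hop)

    out = np.zeros((n, config.n_emg_channels))
    for ch in range(config.n_emg_channels):
        rng = _rng(config.seed, 0, ch)
        acc = np.zeros(n + 2 * pad)
        for s in starts:
            t_center = (s + block / 2.0) / fs
            m = _median_freq_at(t_center, config)
            z = rng.standard_normal(block)
            spec = np.fft.rfft(z)
            half = config.spectral_width_hz / 2.0
            spec[(freqs < m - half) | (freqs > m + half)] = 0.0
            b = np.fft.irfft(spec, block)
            rms = np.sqrt(np.mean(b**2))
            if rms > 0:
                b /= rms
            acc[s + pad : s + pad + block] += b * win
        out[:, ch] = acc[pad : pad + n]

    t = np.arange(n) / fs
    out *= _rms_envelope(t, config)[:, None]
    labels = tuple(f"emg_ch{i + 1}" for i in range(config.n_emg_channels))
    return MultiChannelSignal(fs, out, labels)


def generate_goniometer(config: SyntheticTrialConfig) -> AngleSignal:
    """Synthesize the elbow-angle trace.

    Flat at the baseline with oscillation std ``osc_std_low`` during
    NonFatigue; from transition onset the oscillation std ramps to
    ``osc_std_high`` over ``osc_ramp_s`` seconds and the angle drifts away
    from the baseline at the (possibly auto-calibrated) drift rate, crossing
    the default labeller's Fatigue boundary at the programmed fatigue onset.
    """
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs
    tl = config.timeline

    rate = resolved_drift_rate(config)
    dev = rate * np.clip(t - tl.t_transition_onset, 0.0, None)

    if config.osc_ramp_s > 0:
        frac = np.clip((t - tl.t_transition_onset) / config.osc_ramp_s, 0.0, 1.0)
    else:
        frac = (t >= tl.t_transition_onset).astype(float)
    std_env = config.osc_std_low + frac * (config.osc_std_high - config.osc_std_low)

    rng = _rng(config.seed, 1)
    noise = rng.standard_normal(n) * std_env
    angle = np.clip(config.angle_baseline - dev + noise, 0.0, 180.0)
    return AngleSignal(fs, angle)


def generate_trial(
    config: SyntheticTrialConfig,
    subject_id: str = "synthetic",
    trial_role: str = "testing",
) -> TrialBundle:
    """Generate one complete trial bundle from a config."""
    return TrialBundle(
        emg=generate_semg(config),
        angle=generate_goniometer(config),
        timeline=config.timeline,
        subject_id=subject_id,
        trial_role=trial_role,
    )


def generate_subject(
    config: SyntheticTrialConfig,
    n_trials: int = 3,
    jitter: Optional[TimelineJitter] = None,
    subject_id: str = "synthetic",
) -> list:
    """Generate a subject's trials: the last is the testing trial.

    Each trial perturbs the stage boundaries by an independent uniform draw
    within the jitter bounds and uses a deterministically derived sub-seed,
    so trials differ in noise but the whole subject reproduces from the
    master seed.
    """
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    jitter = jitter or TimelineJitter()
    trials = []
    for i in range(n_trials):
        jrng = _rng(config.seed, 2, i)
        dt = jrng.uniform(-jitter.transition_s, jitter.transition_s) if jitter.transition_s else 0.0
        df = jrng.uniform(-jitter.fatigue_s, jitter.fatigue_s) if jitter.fatigue_s else 0.0
        try:
            tl = StageTimeline(
                config.timeline.t_transition_onset + dt,
                config.timeline.t_fatigue_onset + df,
                config.timeline.t_end,
            )
        except ConfigError as exc:
            raise ConfigError(f"jitter produced an invalid timeline: {exc}") from exc
        sub_seed = int(np.random.SeedSequence([config.seed, 3, i]).generate_state(1)[0])
        cfg_i = replace(config, timeline=tl, seed=sub_seed)
        role = "training" if i < n_trials - 1 else "testing"
        trials.append(generate_trial(cfg_i, subject_id=subject_id, trial_role=role))
    return trials
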