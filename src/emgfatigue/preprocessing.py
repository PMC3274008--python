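"""Signal containers, zero-phase filtering and windowing.

Holds the two raw-signal types (multichannel sEMG and single-channel elbow
angle), the software band-pass applied to the sEMG before feature
extraction, and the hop-based windowing shared by every downstream stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigError

__all__ = [
    "MultiChannelSignal",
    "AngleSignal",
    "WindowSpec",
    "zero_phase_bandpass",
    "segment_windows",
    "rolling_angle_std",
]


@dataclass(frozen=True)
class MultiChannelSignal:
    """Uniformly sampled multichannel signal.

    Parameters
    ----------
    sampling_rate : float
        Samples per second, > 0.
    samples : ndarray, shape (n_samples, n_channels)
        Amplitudes in arbitrary units; a 1-D array is promoted to a single
        channel.
    channel_labels : tuple of str
        One label per channel.
    t0 : float
        Time of the first sample in seconds.
    """

    sampling_rate: float
    samples: np.ndarray
    channel_labels: tuple = ()
    t0: float = 0.0

    def __post_init__(self):
        if not self.sampling_rate > 0:
            raise ConfigError("sampling_rate must be > 0")
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim == 1:
            samples = samples[:, None]
        if samples.ndim != 2:
            raise ConfigError("samples must be 1-D or 2-D")
        labels = tuple(self.channel_labels)
        if not labels:
            labels = tuple(f"ch{i + 1}" for i in range(samples.shape[1]))
        if len(labels) != samples.shape[1]:
            raise ConfigError("channel_labels length must equal channel count")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "channel_labels", labels)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class AngleSignal:
    """Goniometer elbow-angle trace in degrees, sharing the sEMG clock."""

    sampling_rate: float
    angle: np.ndarray
    t0: float = 0.0

    def __post_init__(self):
        if not self.sampling_rate > 0:
            raise ConfigError("sampling_rate must be > 0")
        angle = np.asarray(self.angle, dtype=float).ravel()
        if not np.all(np.isfinite(angle)):
            raise ConfigError("angle contains non-finite values")
        object.__setattr__(self, "angle", angle)

    @property
    def n_samples(self) -> int:
        return self.angle.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class WindowSpec:
    """Analysis-window geometry: window length and hop, both in seconds."""

    window_len: float = 1.0
    hop: float = 1.0

    def __post_init__(self):
        if not self.hop > 0:
            raise ConfigError("hop must be > 0")
        if self.hop > self.window_len:
            raise ConfigError("hop must be <= window_len")


def zero_phase_bandpass(
    signal: MultiChannelSignal,
    low: float,
    high: float,
    order: int = 5,
    clamp_high: bool = False,
) -> MultiChannelSignal:
    """Forward-backward Butterworth band-pass, per channel.

    The dual pass cancels phase and squares the single-pass magnitude
    response. ``high`` at or above Nyquist is not realizable digitally;
    pass ``clamp_high=True`` to clamp it to 0.99 x Nyquist instead of
    raising.
    """
    fs = signal.sampling_rate
    nyq = fs / 2.0
    if order < 1:
        raise ConfigError("order must be >= 1")
    if not 0 <= low < high:
        raise ConfigError("require 0 <= low < high")
    if high >= nyq:
        if not clamp_high:
            raise ConfigError(
                f"high={high} Hz is at or above Nyquist ({nyq} Hz); "
                "pass clamp_high=True to clamp to 0.99 x Nyquist"
            )
        high = 0.99 * nyq
        warnings.warn(f"band upper edge clamped to {high} Hz", stacklevel=2)
    if low == 0:
        sos = sps.butter(order, high, btype="lowpass", fs=fs, output="sos")
    else:
        sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if signal.n_samples <= max(padlen, 3 * order):
        raise ValueError(
            f"signal too short for zero-phase filtering: need > {padlen} samples"
        )
    filtered = sps.sosfiltfilt(sos, signal.samples, axis=0)
    return MultiChannelSignal(fs, filtered, signal.channel_labels, signal.t0)


def _signal_parts(signal):
    if isinstance(signal, MultiChannelSignal):
        return signal.samples, signal.sampling_rate, signal.t0
    if isinstance(signal, AngleSignal):
        return signal.angle, signal.sampling_rate, signal.t0
    raise TypeError("expected MultiChannelSignal or AngleSignal")


def segment_windows(signal, spec: WindowSpec):
    """Cut a signal into hop-spaced windows.

    Windows cover ``[k*hop, k*hop + window_len)`` in continuous time; a
    trailing partial window is dropped. Returns ``(centers, windows)`` where
    ``centers[k] = t0 + k*hop + window_len/2`` and ``windows`` has shape
    ``(n_windows, win_samples)`` for 1-D input or
    ``(n_windows, win_samples, n_channels)`` for multichannel input.
    """
    x, fs, t0 = _signal_parts(signal)
    wlen = int(round(spec.window_len * fs))
    hop = int(round(spec.hop * fs))
    if wlen < 1 or hop < 1:
        raise ConfigError("window_len and hop must span at least one sample")
    n = x.shape[0]
    if n < wlen:
        raise ValueError(
            f"signal ({n} samples) shorter than one window ({wlen} samples)"
        )
    views = np.lib.stride_tricks.sliding_window_view(x, wlen, axis=0)[::hop]
    if x.ndim == 2:
        views = np.moveaxis(views, -1, 1)  # (n_win, wlen, n_ch)
    starts = np.arange(views.shape[0]) * hop
    centers = t0 + starts / fs + spec.window_len / 2.0
    return centers, np.ascontiguousarray(views)


def rolling_angle_std(angle: AngleSignal, spec: WindowSpec):
    """Per-window sample (n-1) standard deviation of the elbow angle.

    Returns ``(centers, std_deg)``.
    """
    centers, windows = segment_windows(angle, spec)
    if windows.shape[1] < 2:
        raise ValueError("windows must contain >= 2 samples for a sample std")
    return centers, np.std(windows, axis=1, ddof=1)
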