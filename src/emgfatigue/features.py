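"""Composite spectral fatigue feature.

Per analysis window the feature is (normalized) total band power minus
(normalized) instantaneous median frequency. At the transition to fatigue
the band power rises while the median frequency falls, so the difference
increases; normalization makes the two commensurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from .errors import ConfigError

__all__ = [
    "PSDEstimate",
    "FeatureSeries",
    "welch_psd",
    "total_band_power",
    "instantaneous_median_frequency",
    "compute_1d_spectro",
    "extract_features",
    "write_feature_csv",
]

DEFAULT_SEGMENT_LEN = 256
DEFAULT_OVERLAP = 0.5
DEFAULT_BAND = (10.0, 499.0)

NORMALIZATION_MODES = ("raw", "zscore", "baseline", "causal_zscore")


@dataclass(frozen=True)
class PSDEstimate:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    resolution: float

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        if freqs.ndim != 1 or freqs.shape != power.shape:
            raise ConfigError("freqs and power must be 1-D and equal length")
        if np.any(np.diff(freqs) <= 0):
            raise ConfigError("freqs must be strictly increasing")
        if np.any(power < 0):
            raise ConfigError("power must be non-negative")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)


@dataclass(frozen=True)
class FeatureSeries:
    """Per-window feature vectors with their raw components.

    ``values`` has shape (n_windows, n_channels); degenerate (zero-power)
    windows carry NaN. ``band_power`` and ``imf`` keep the unnormalized
    components for inspection.
    """

    times: np.ndarray
    values: np.ndarray
    band_power: Optional[np.ndarray] = None
    imf: Optional[np.ndarray] = None
    normalization: str = "raw"

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ConfigError("times must be strictly increasing")
        if values.shape[0] != times.shape[0]:
            raise ConfigError("values and times must align")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    @property
    def n_windows(self) -> int:
        return self.times.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def welch_psd(
    x,
    sampling_rate: float,
    segment_len: int = DEFAULT_SEGMENT_LEN,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> PSDEstimate:
    """Welch PSD of one window: averaged Hann-tapered periodograms.

    Density scaling, so the trapezoidal integral over frequency
    approximates the signal variance (power for zero-mean signals).
    """
    x = np.asarray(x, dtype=float).ravel()
    if segment_len < 8:
        raise ConfigError("segment_len must be >= 8")
    if not 0 <= overlap_fraction < 1:
        raise ConfigError("overlap_fraction must be in [0, 1)")
    if x.size < segment_len:
        raise ValueError(
            f"window ({x.size} samples) shorter than segment_len ({segment_len})"
        )
    freqs, power = sps.welch(
        x,
        fs=sampling_rate,
        window="hann",
        nperseg=segment_len,
        noverlap=int(segment_len * overlap_fraction),
        detrend=False,
        scaling="density",
    )
    return PSDEstimate(freqs, power, float(freqs[1] - freqs[0]))


def total_band_power(psd: PSDEstimate, band) -> float:
    """Trapezoidal integral of the PSD over ``band = (low, high)`` Hz."""
    low, high = float(band[0]), float(band[1])
    if not low < high:
        raise ConfigError("band must satisfy low < high")
    if low < psd.freqs[0] or high > psd.freqs[-1]:
        raise ConfigError(
            f"band [{low}, {high}] outside PSD range "
            f"[{psd.freqs[0]}, {psd.freqs[-1]}]"
        )
    inside = (psd.freqs > low) & (psd.freqs < high)
    fgrid = np.concatenate(([low], psd.freqs[inside], [high]))
    pgrid = np.concatenate(
        (
            [np.interp(low, psd.freqs, psd.power)],
            psd.power[inside],
            [np.interp(high, psd.freqs, psd.power)],
        )
    )
    return float(np.trapezoid(pgrid, fgrid))


def instantaneous_median_frequency(psd: PSDEstimate) -> float:
    """Frequency splitting the spectral power into equal halves.

    Computed from the trapezoid-rule cumulative power with linear
    interpolation inside the crossing segment; a plateau exactly at the
    half-power level resolves to its midpoint.
    """
    f = psd.freqs
    p = psd.power
    areas = 0.5 * (p[1:] + p[:-1]) * np.diff(f)
    cum = np.concatenate(([0.0], np.cumsum(areas)))
    total = cum[-1]
    if not total > 0:
        raise ValueError("zero total power: median frequency undefined")
    half = total / 2.0

    def _cross(side):
        j = int(np.searchsorted(cum, half, side=side))
        j = min(max(j, 1), len(cum) - 1)
        dc = cum[j] - cum[j - 1]
        if dc <= 0:
            return f[j - 1]
        return f[j - 1] + (half - cum[j - 1]) / dc * (f[j] - f[j - 1])

    return 0.5 * (_cross("left") + _cross("right"))


def _normalize(x: np.ndarray, mode: str, baseline_windows: int) -> np.ndarray:
    """Normalize one component series (1-D, may contain NaN)."""
    if mode == "raw":
        return x.copy()
    if mode == "zscore":
        mu = np.nanmean(x)
        sd = np.nanstd(x, ddof=1) if np.sum(np.isfinite(x)) > 1 else 0.0
        return (x - mu) / sd if sd > 0 else np.where(np.isfinite(x), 0.0, np.nan)
    if mode in ("baseline", "causal_zscore"):
        out = np.full_like(x, np.nan)
        run_vals = []
        frozen = None  # (mu, sd) once the baseline is locked
        for k, v in enumerate(x):
            if mode == "baseline" and frozen is None and k >= baseline_windows:
                mu = float(np.mean(run_vals)) if run_vals else 0.0
                sd = float(np.std(run_vals, ddof=1)) if len(run_vals) > 1 else 0.0
                frozen = (mu, sd)
            if not np.isfinite(v):
                continue
            if frozen is not None:
                mu, sd = frozen
            else:
                run_vals.append(v)
                mu = float(np.mean(run_vals))
                sd = float(np.std(run_vals, ddof=1)) if len(run_vals) > 1 else 0.0
            out[k] = (v - mu) / sd if sd > 0 else 0.0
        return out
    raise ConfigError(f"unknown normalization mode: {mode!r}")


def compute_1d_spectro(
    emg_windows,
    sampling_rate: float,
    segment_len: int = DEFAULT_SEGMENT_LEN,
    overlap_fraction: float = DEFAULT_OVERLAP,
    band=DEFAULT_BAND,
    normalization: str = "causal_zscore",
    baseline_windows: int = 10,
    times=None,
) -> FeatureSeries:
    """Per-window, per-channel composite feature.

    value = normalize(band power) - normalize(median frequency), under the
    selected mode:

    - ``raw``: plain subtraction, no scaling.
    - ``zscore``: z-score each component over all windows (batch only).
    - ``baseline``: z-score against the first ``baseline_windows`` windows
      (causal after the baseline is locked; expanding stats before).
    - ``causal_zscore``: z-score against the expanding history of windows
      seen so far (streaming-safe everywhere).

    Windows with zero total power yield NaN for that window/channel.
    """
    windows = np.asarray(emg_windows, dtype=float)
    if windows.ndim == 2:
        windows = windows[:, :, None]
    if windows.ndim != 3:
        raise ConfigError("emg_windows must have shape (n_win, wlen[, n_ch])")
    n_win, _, n_ch = windows.shape
    if normalization not in NORMALIZATION_MODES:
        raise ConfigError(f"unknown normalization mode: {normalization!r}")
    if normalization != "raw" and n_win < 2:
        raise ValueError("need >= 2 windows for statistics-based normalization")

    if times is None:
        times = np.arange(n_win, dtype=float)
    times = np.asarray(times, dtype=float)

    bp = np.full((n_win, n_ch), np.nan)
    imf = np.full((n_win, n_ch), np.nan)
    for c in range(n_ch):
        for k in range(n_win):
            psd = welch_psd(windows[k, :, c], sampling_rate, segment_len,
                            overlap_fraction)
            try:
                imf[k, c] = instantaneous_median_frequency(psd)
            except ValueError:
                continue  # degenerate window, stays NaN
            bp[k, c] = total_band_power(psd, band)

    values = np.full((n_win, n_ch), np.nan)
    for c in range(n_ch):
        values[:, c] = _normalize(bp[:, c], normalization, baseline_windows) - \
            _normalize(imf[:, c], normalization, baseline_windows)
    return FeatureSeries(times, values, band_power=bp, imf=imf,
                         normalization=normalization)


def extract_features(emg, spec, **kwargs) -> FeatureSeries:
    """Window a :class:`MultiChannelSignal` and run :func:`compute_1d_spectro`."""
    from .preprocessing import segment_windows

    centers, windows = segment_windows(emg, spec)
    return compute_1d_spectro(windows, emg.sampling_rate, times=centers, **kwargs)


def write_feature_csv(series: FeatureSeries, path, channel_labels=None) -> None:
    """Write a feature series as CSV: time_s, ch*_feature[, ch*_bandpower,
    ch*_imf]."""
    import pandas as pd

    labels = channel_labels or [f"ch{i + 1}" for i in range(series.n_channels)]
    if len(labels) != series.n_channels:
        raise ConfigError("channel_labels length must equal channel count")
    data = {"time_s": series.times}
    for i, lab in enumerate(labels):
        data[f"{lab}_feature"] = series.values[:, i]
    for name, comp in (("bandpower", series.band_power), ("imf", series.imf)):
        if comp is not None:
            for i, lab in enumerate(labels):
                data[f"{lab}_{name}"] = comp[:, i]
    pd.DataFrame(data).to_csv(path, index=False)
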