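import numpy as np
import pytest
from scipy import stats

from emgfatigue.errors import ConfigError
from emgfatigue.features import (
    PSDEstimate,
    compute_1d_spectro,
    extract_features,
    instantaneous_median_frequency,
    total_band_power,
    welch_psd,
)
from emgfatigue.synthetic import generate_semg

FS = 1000.0


def _brute_force_imf(psd):
    """Independent oracle: grid search for the frequency that best splits
    the trapezoid-rule cumulative power into halves."""
    areas = 0.5 * (psd.power[1:] + psd.power[:-1]) * np.diff(psd.freqs)
    cum = np.concatenate(([0.0], np.cumsum(areas)))
    total = cum[-1]
    k = np.argmin(np.abs(cum - (total - cum)))
    return psd.freqs[k]


class TestWelchPSD:
    def test_zero_window_zero_power(self):
        psd = welch_psd(np.zeros(1000), FS)
        np.testing.assert_allclose(psd.power, 0.0)

    def test_white_noise_integral_matches_variance(self):
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(4000)
            x = (x - x.mean()) / x.std()
            psd = welch_psd(x, FS)
            integral = np.trapezoid(psd.power, psd.freqs)
            assert integral == pytest.approx(1.0, rel=0.15)

    def test_sine_at_bin_center_power(self):
        a = 3.0
        t = np.arange(4000) / FS
        x = a * np.sin(2 * np.pi * 125.0 * t)  # bin center for nperseg=256
        psd = welch_psd(x, FS, segment_len=256)
        integral = np.trapezoid(psd.power, psd.freqs)
        assert integral == pytest.approx(a**2 / 2, rel=0.10)

    def test_short_window_errors(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), FS, segment_len=256)

    def test_bad_segment_len_errors(self):
        with pytest.raises(ConfigError):
            welch_psd(np.zeros(100), FS, segment_len=4)


class TestTotalBandPower:
    def test_full_band_white_noise(self):
        x = np.random.default_rng(0).standard_normal(8000)
        x = (x - x.mean()) / x.std()
        psd = welch_psd(x, FS)
        assert total_band_power(psd, (0.0, FS / 2)) == pytest.approx(1.0, rel=0.15)

    def test_zero_width_band_errors(self):
        psd = welch_psd(np.random.default_rng(0).standard_normal(1000), FS)
        with pytest.raises(ConfigError):
            total_band_power(psd, (100.0, 100.0))

    def test_band_outside_range_errors(self):
        psd = welch_psd(np.random.default_rng(0).standard_normal(1000), FS)
        with pytest.raises(ConfigError):
            total_band_power(psd, (100.0, 600.0))

    def test_band_excluding_sine_sees_little_leakage(self):
        t = np.arange(4000) / FS
        x = np.sin(2 * np.pi * 100.0 * t)
        psd = welch_psd(x, FS, segment_len=256)
        inside = total_band_power(psd, (0.0, FS / 2))
        outside = total_band_power(psd, (150.0, 300.0))
        assert outside < 0.05 * inside


class TestInstantaneousMedianFrequency:
    def test_pure_sine(self):
        t = np.arange(4000) / FS
        psd = welch_psd(np.sin(2 * np.pi * 100.0 * t), FS, segment_len=256)
        assert abs(instantaneous_median_frequency(psd) - 100.0) <= psd.resolution

    def test_band_limited_white_noise(self):
        rng = np.random.default_rng(5)
        spec = rng.standard_normal(4001) + 1j * rng.standard_normal(4001)
        freqs = np.fft.rfftfreq(8000, 1 / FS)
        spec[freqs > 250.0] = 0.0
        x = np.fft.irfft(spec, 8000)
        psd = welch_psd(x, FS, segment_len=512)
        assert instantaneous_median_frequency(psd) == pytest.approx(125.0, abs=10.0)

    def test_two_equal_sines_symmetric_median(self):
        # idealized two-line spectrum on a 5 Hz grid: the cumulative power
        # plateaus exactly at one half between the lines, so the median must
        # resolve to the plateau midpoint by symmetry
        freqs = np.arange(0.0, 500.0 + 5.0, 5.0)
        power = np.zeros_like(freqs)
        power[freqs == 50.0] = 1.0
        power[freqs == 150.0] = 1.0
        psd = PSDEstimate(freqs, power, 5.0)
        assert instantaneous_median_frequency(psd) == pytest.approx(
            100.0, abs=psd.resolution
        )

    def test_zero_power_errors(self):
        psd = welch_psd(np.zeros(1000), FS)
        with pytest.raises(ValueError, match="zero total power"):
            instantaneous_median_frequency(psd)

    def test_agrees_with_brute_force_oracle(self):
        for seed in range(10):
            x = np.random.default_rng(seed).standard_normal(2000)
            psd = welch_psd(x, FS, segment_len=256)
            fast = instantaneous_median_frequency(psd)
            assert abs(fast - _brute_force_imf(psd)) <= psd.resolution

    def test_amplitude_invariance(self):
        x = np.random.default_rng(8).standard_normal(2000)
        p1 = welch_psd(x, FS)
        p2 = welch_psd(5.0 * x, FS)
        imf1 = instantaneous_median_frequency(p1)
        imf2 = instantaneous_median_frequency(p2)
        assert imf1 == pytest.approx(imf2, rel=1e-9)
        bp1 = total_band_power(p1, (10.0, 499.0))
        bp2 = total_band_power(p2, (10.0, 499.0))
        assert bp2 == pytest.approx(25.0 * bp1, rel=1e-9)


class TestCompute1DSpectro:
    def test_stationary_signal_has_no_trend(self, flat_cfg, one_second_windows):
        emg = generate_semg(flat_cfg)
        feats = extract_features(emg, one_second_windows,
                                 normalization="causal_zscore")
        vals = feats.values[5:, 0]  # skip the expanding-stats burn-in
        res = stats.linregress(feats.times[5:], vals)
        assert abs(res.slope) < 2.6 * res.stderr  # 99% CI covers zero

    def test_fatigue_trial_trend_positive_after_transition(
        self, short_cfg, one_second_windows
    ):
        emg = generate_semg(short_cfg)
        # baseline mode keeps the scale fixed after the burn-in, so the
        # programmed power rise / median-frequency fall shows as a trend
        feats = extract_features(emg, one_second_windows,
                                 normalization="baseline")
        tl = short_cfg.timeline
        mask = feats.times >= tl.t_transition_onset
        res = stats.linregress(feats.times[mask], feats.values[mask, 0])
        assert res.slope > 0
        assert res.slope > 2.6 * res.stderr

    def test_transition_mean_exceeds_nonfatigue_mean(
        self, short_cfg, one_second_windows
    ):
        emg = generate_semg(short_cfg)
        feats = extract_features(emg, one_second_windows)
        tl = short_cfg.timeline
        nf = feats.values[feats.times < tl.t_transition_onset, :]
        ttf = feats.values[
            (feats.times >= tl.t_transition_onset)
            & (feats.times < tl.t_fatigue_onset), :
        ]
        assert np.nanmean(ttf) > np.nanmean(nf)

    def test_global_zscore_mode_has_zero_mean(self, flat_cfg, one_second_windows):
        emg = generate_semg(flat_cfg)
        feats = extract_features(emg, one_second_windows, normalization="zscore")
        # difference of two zero-mean z-scored components
        assert np.nanmean(feats.values) == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_window_flagged_not_crashed(self):
        wins = np.random.default_rng(0).standard_normal((5, 1000))
        wins[2] = 0.0
        series = compute_1d_spectro(wins, FS, normalization="raw")
        assert np.isnan(series.values[2, 0])
        assert np.isfinite(series.values[[0, 1, 3, 4], 0]).all()

    def test_unknown_mode_errors(self):
        wins = np.zeros((3, 1000))
        with pytest.raises(ConfigError, match="normalization"):
            compute_1d_spectro(wins, FS, normalization="nope")

    def test_components_retained(self, flat_cfg, one_second_windows):
        emg = generate_semg(flat_cfg)
        feats = extract_features(emg, one_second_windows)
        assert feats.band_power.shape == feats.values.shape
        assert feats.imf.shape == feats.values.shape
        assert np.nanmean(np.abs(feats.imf - 100.0)) < 5.0

    def test_csv_export(self, tmp_path, flat_cfg, one_second_windows):
        import pandas as pd

        from emgfatigue.features import write_feature_csv

        emg = generate_semg(flat_cfg)
        feats = extract_features(emg, one_second_windows)
        path = tmp_path / "features.csv"
        write_feature_csv(feats, path, channel_labels=["a", "b"])
        frame = pd.read_csv(path)
        assert list(frame.columns) == [
            "time_s", "a_feature", "b_feature",
            "a_bandpower", "b_bandpower", "a_imf", "b_imf",
        ]
        np.testing.assert_allclose(frame["a_imf"], feats.imf[:, 0])
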