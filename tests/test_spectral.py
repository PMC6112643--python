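import numpy as np
import pytest
from scipy.signal.windows import hann

from ehgkit import spectral
from ehgkit.filterbank import B0, B1, B2, B3, Band
from ehgkit.spectral import PowerSpectrum


def _random_spectrum(seed, M=1800, fs=20.0, smoothed=True, normalized=False):
    rng = np.random.default_rng(seed)
    v = rng.uniform(0, 1, M // 2 + 1)
    if normalized:
        v = v / v.max()
    return PowerSpectrum(v, M, fs, smoothed=smoothed, normalized=normalized)


class TestPowerSpectrum:
    def test_sinusoid_peak_location(self):
        t = np.arange(1800) / 20.0
        ps = spectral.power_spectrum(np.sin(2 * np.pi * 1.6 * t), 20.0)
        peak_hz = np.argmax(ps.values) * ps.df
        assert abs(peak_hz - 1.6) <= ps.df

    def test_windowed_parseval(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(1234)
        ps = spectral.power_spectrum(x, 20.0)
        energy = np.sum((x * hann(1234, sym=True)) ** 2)
        assert abs(ps.values.sum() - energy) / energy < 1e-6

    def test_zero_signal_gives_zero_spectrum(self):
        ps = spectral.power_spectrum(np.zeros(64), 20.0)
        assert np.all(ps.values == 0)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            spectral.power_spectrum(np.ones(8), 20.0)


class TestSmoothing:
    def test_constant_spectrum_unchanged(self):
        ps = PowerSpectrum(np.full(901, 3.3), 1800, 20.0)
        out = spectral.smooth_spectrum(ps)
        np.testing.assert_allclose(out.values, 3.3)
        assert out.smoothed

    def test_unit_spike_spreads_over_nine_bins(self):
        # df = 20/1800 = 0.0111 Hz -> w = round(0.1/0.0111) = 9 bins
        v = np.zeros(901)
        v[450] = 1.0
        out = spectral.smooth_spectrum(PowerSpectrum(v, 1800, 20.0))
        nz = np.flatnonzero(out.values)
        assert len(nz) == 9
        assert np.allclose(out.values[nz], 1 / 9)
        assert out.values[450] == pytest.approx(1 / 9)

    def test_width_below_bin_width_is_identity(self):
        ps = _random_spectrum(0, M=64, smoothed=False)
        out = spectral.smooth_spectrum(ps, width=0.1)   # df = 0.3125 > width
        np.testing.assert_array_equal(out.values, ps.values)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            spectral.smooth_spectrum(_random_spectrum(0), width=0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_smoothing_never_increases_maximum(self, seed):
        ps = _random_spectrum(seed, smoothed=False)
        out = spectral.smooth_spectrum(ps)
        assert out.values.max() <= ps.values.max() + 1e-15

    def test_mass_approximately_preserved(self):
        ps = _random_spectrum(1, smoothed=False)
        out = spectral.smooth_spectrum(ps)
        assert abs(out.values.sum() - ps.values.sum()) / ps.values.sum() < 0.01


class TestNormalization:
    def test_max_is_one(self):
        out = spectral.normalize_spectrum(_random_spectrum(2))
        assert out.values.max() == 1.0
        assert out.normalized and out.p_max > 0

    def test_scale_invariance(self):
        ps = _random_spectrum(3)
        a = spectral.normalize_spectrum(ps)
        b = spectral.normalize_spectrum(
            PowerSpectrum(ps.values * 17.0, ps.M, ps.fs, smoothed=True))
        np.testing.assert_allclose(a.values, b.values)

    def test_zero_spectrum_rejected(self):
        ps = PowerSpectrum(np.zeros(33), 64, 20.0, smoothed=True)
        with pytest.raises(ValueError, match="all-zero"):
            spectral.normalize_spectrum(ps)

    def test_requires_smoothed_input(self):
        ps = _random_spectrum(4, smoothed=False)
        with pytest.raises(ValueError, match="smoothed"):
            spectral.normalize_spectrum(ps)

    def test_pipeline_invariant_to_signal_rescaling(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(800)
        norm = lambda sig: spectral.normalize_spectrum(
            spectral.smooth_spectrum(spectral.power_spectrum(sig, 20.0)))
        np.testing.assert_allclose(norm(x).values, norm(5.5 * x).values,
                                   atol=1e-12)


def _mf_oracle(ps, band):
    """Independent prefix-sum scan over the band's bins."""
    k_lo, k_hi = band.bin_range(ps.M, ps.fs)
    total = ps.values[k_lo:k_hi + 1].sum()
    acc = 0.0
    for k in range(k_lo, k_hi + 1):
        acc += ps.values[k]
        if acc >= total / 2.0:
            return k * ps.fs / ps.M
    raise AssertionError("unreachable")


class TestMedianFrequency:
    def test_point_mass(self):
        v = np.zeros(901)
        v[200] = 2.0                       # 200 * 20/1800 = 2.222 Hz, in B2
        ps = PowerSpectrum(v, 1800, 20.0, smoothed=True)
        assert spectral.median_frequency(ps, B2) == pytest.approx(
            200 * 20.0 / 1800)

    def test_symmetric_spectrum_centers(self):
        v = np.zeros(901)
        k_lo, k_hi = B1.bin_range(1800, 20.0)
        v[k_lo:k_hi + 1] = 1.0
        ps = PowerSpectrum(v, 1800, 20.0, smoothed=True)
        mf = spectral.median_frequency(ps, B1)
        center = (k_lo + k_hi) / 2 * 20.0 / 1800
        assert abs(mf - center) <= 20.0 / 1800

    @pytest.mark.parametrize("seed", range(20))
    @pytest.mark.parametrize("band", [B0, B1, B2, B3], ids=lambda b: b.name)
    def test_matches_prefix_sum_oracle_exactly(self, seed, band):
        ps = _random_spectrum(seed)
        assert spectral.median_frequency(ps, band) == _mf_oracle(ps, band)

    def test_mf_stays_inside_band(self):
        for seed in range(10):
            ps = _random_spectrum(100 + seed)
            for band in (B0, B1, B2, B3):
                mf = spectral.median_frequency(ps, band)
                assert band.f_low - ps.df <= mf <= band.f_high + ps.df

    def test_zero_in_band_power_rejected(self):
        v = np.zeros(901)
        v[10] = 1.0                        # only B0 has power
        ps = PowerSpectrum(v, 1800, 20.0, smoothed=True)
        with pytest.raises(ValueError, match="in-band"):
            spectral.median_frequency(ps, B3)

    def test_band_outside_spectrum_rejected(self):
        ps = _random_spectrum(0)
        with pytest.raises(ValueError):
            spectral.median_frequency(ps, Band("x", 9.0, 12.0))


class TestPeakAmplitude:
    def test_band_with_global_peak_reads_one(self):
        ps = _random_spectrum(5, normalized=True)
        k_star = int(np.argmax(ps.values))
        band = next(b for b in (B0, B1, B2, B3)
                    if b.bin_range(ps.M, ps.fs)[0] <= k_star
                    <= b.bin_range(ps.M, ps.fs)[1])
        assert spectral.peak_amplitude(ps, band) == 1.0

    def test_uniform_fraction_band(self):
        v = np.zeros(901)
        v[20] = 1.0                        # global peak in B0
        k_lo, k_hi = B2.bin_range(1800, 20.0)
        v[k_lo:k_hi + 1] = 0.3
        ps = PowerSpectrum(v, 1800, 20.0, smoothed=True, normalized=True,
                           p_max=1.0)
        assert spectral.peak_amplitude(ps, B2) == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_max_scan(self, seed):
        ps = _random_spectrum(seed, normalized=True)
        for band in (B1, B2, B3):
            k_lo, k_hi = band.bin_range(ps.M, ps.fs)
            brute = max(ps.values[k] for k in range(k_lo, k_hi + 1))
            pa = spectral.peak_amplitude(ps, band)
            assert pa == brute and 0 < pa <= 1.0

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            spectral.peak_amplitude(_random_spectrum(0), B1)


class TestSpectrogram:
    def test_stationary_tone_has_constant_ridge(self):
        t = np.arange(4000) / 20.0
        sg = spectral.spectrogram(np.sin(2 * np.pi * 1.3 * t), 20.0)
        ridge = sg.freqs[np.argmax(sg.power, axis=0)]
        assert np.all(np.abs(ridge - 1.3) <= 20.0 / 256)

    def test_chirp_ridge_non_decreasing(self):
        from scipy.signal import chirp
        t = np.arange(12000) / 20.0
        x = chirp(t, f0=0.5, f1=3.0, t1=t[-1], method="linear")
        sg = spectral.spectrogram(x, 20.0)
        ridge = np.argmax(sg.power, axis=0)
        assert np.all(np.diff(ridge) >= -1)    # one-bin jitter allowed

    def test_frequency_resolution(self):
        sg = spectral.spectrogram(np.random.default_rng(0).normal(size=600),
                                  20.0)
        assert sg.freqs[1] - sg.freqs[0] == pytest.approx(20.0 / 256)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="window"):
            spectral.spectrogram(np.ones(100), 20.0)
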