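"""Power spectra, spectral smoothing/normalization, MF/PA read-out, STFT.

The spectral pipeline mirrors the feature-extraction flow: a Hanning window
is applied to the (wide-band filtered) segment, the one-sided power spectrum
is computed by FFT, smoothed with a centered moving average spanning 0.1 Hz,
and normalized by its global maximum P_max.  Two band-limited statistics are
then read off:

* ``MF`` — the median frequency: the bin at which the cumulative in-band
  power first reaches half of the total in-band power.
* ``PA`` — the peak amplitude of the normalized spectrum: the in-band
  maximum, which equals 1 exactly when the global spectral peak lies in the
  band.

No zero-padding is applied (M equals the segment length), so the moving
average span in bins tracks the segment's actual frequency resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .filterbank import Band

__all__ = [
    "PowerSpectrum", "Spectrogram", "power_spectrum", "smooth_spectrum",
    "normalize_spectrum", "median_frequency", "peak_amplitude", "spectrogram",
]


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided discrete power spectrum with processing-state flags."""

    values: np.ndarray             # P(k), k = 0..M//2, all >= 0
    M: int                         # transform length (= segment length)
    fs: float
    smoothed: bool = False
    normalized: bool = False
    p_max: float | None = None     # recorded when normalized

    @property
    def df(self) -> float:
        """Bin width fs / M in Hz."""
        return self.fs / self.M

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.values.size) * self.df


@dataclass(frozen=True)
class Spectrogram:
    """Time-frequency power matrix from a sliding Hanning-window STFT."""

    power: np.ndarray              # (n_freqs, n_windows)
    freqs: np.ndarray
    times: np.ndarray
    fs: float
    window_samples: int
    hop: int


def power_spectrum(x: np.ndarray, fs: float) -> PowerSpectrum:
    """Hanning-windowed one-sided power spectrum of ``x``.

    The spectrum is scaled so that the sum of the one-sided components
    equals the windowed time-domain energy.  The mean is not removed: the
    wide-band filter upstream already rejects DC.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 16:
        raise ValueError(f"need a 1-D signal of >= 16 samples, got {x.shape}")
    M = x.size
    xw = x * sps.windows.hann(M, sym=True)
    X = np.fft.rfft(xw)
    p = np.abs(X) ** 2 / M
    p[1:] *= 2.0
    if M % 2 == 0:
        p[-1] /= 2.0                      # Nyquist bin is not duplicated
    return PowerSpectrum(p, M, float(fs))


def smooth_spectrum(ps: PowerSpectrum, width: float = 0.1) -> PowerSpectrum:
    """Centered moving average over a ``width``-Hz span (default 0.1 Hz).

    The window is ``w = round(width / df)`` bins, forced odd; edge bins
    average over the bins actually available (shrinking window).  A width
    below one bin leaves the spectrum unchanged apart from the state flag.
    """
    if width <= 0:
        raise ValueError(f"smoothing width must be positive, got {width}")
    w = max(1, int(round(width / ps.df)))
    if w % 2 == 0:
        w += 1
    if w == 1:
        return replace(ps, smoothed=True)
    kernel = np.ones(w)
    num = np.convolve(ps.values, kernel, mode="same")
    den = np.convolve(np.ones_like(ps.values), kernel, mode="same")
    return replace(ps, values=num / den, smoothed=True)


def normalize_spectrum(ps: PowerSpectrum) -> PowerSpectrum:
    """Divide by the global maximum P_max over [0, fs/2]; records P_max."""
    if not ps.smoothed:
        raise ValueError("normalize_spectrum expects a smoothed spectrum")
    p_max = float(ps.values.max())
    if p_max <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return replace(ps, values=ps.values / p_max, normalized=True, p_max=p_max)


def median_frequency(ps: PowerSpectrum, band: Band) -> float:
    """Median frequency of ``ps`` within ``band`` (Hz).

    Returns ``k_j * fs / M`` where ``k_j`` is the smallest in-band bin at
    which the cumulative power reaches half the total in-band power.
    """
    if band.f_high > ps.fs / 2 + 1e-12:
        raise ValueError(f"band {band.name} exceeds the spectrum range")
    k_lo, k_hi = band.bin_range(ps.M, ps.fs)
    seg = ps.values[k_lo:k_hi + 1]
    total = seg.sum()
    if total <= 0:
        raise ValueError(f"zero in-band power in {band.name}")
    k_j = k_lo + int(np.searchsorted(np.cumsum(seg), total / 2.0))
    return k_j * ps.fs / ps.M


def peak_amplitude(ps: PowerSpectrum, band: Band) -> float:
    """In-band maximum of the normalized spectrum; 1 iff the global peak
    lies inside ``band``."""
    if not ps.normalized:
        raise ValueError("peak_amplitude expects a normalized spectrum")
    k_lo, k_hi = band.bin_range(ps.M, ps.fs)
    return float(ps.values[k_lo:k_hi + 1].max())


def spectrogram(x: np.ndarray, fs: float, window_samples: int = 256,
                hop: int = 64) -> Spectrogram:
    """Sliding Hanning-window STFT power spectrogram.

    At fs = 20 Hz the default 256-sample window spans 12.8 s with a
    frequency resolution of fs/256 ≈ 0.078 Hz; the 64-sample hop gives
    75% overlap.  The input is expected to be wide-band filtered
    (0.08-5.0 Hz) upstream.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < window_samples:
        raise ValueError(
            f"signal of {x.size} samples shorter than one "
            f"{window_samples}-sample window")
    freqs, times, sxx = sps.spectrogram(
        x, fs=fs, window=sps.windows.hann(window_samples, sym=True),
        nperseg=window_samples, noverlap=window_samples - hop,
        detrend=False, scaling="spectrum", mode="psd")
    return Spectrogram(sxx, freqs, times, float(fs), window_samples, hop)
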