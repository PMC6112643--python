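"""Zero-phase Butterworth filter bank over the uterine analysis bands.

The decomposition uses four strictly separated bands plus one wide band:

====  ===========  ==========================================
band  range (Hz)   physiological content
====  ===========  ==========================================
B0    0.08 - 1.0   uterine contractions, maternal respiration
B1    1.0 - 2.2    maternal heart rate (72-90 bpm fundamental)
B2    2.2 - 3.5    2nd cardiac harmonic
B3    3.5 - 5.0    3rd cardiac harmonic
WIDE  0.08 - 5.0   baseline-wander / high-frequency rejection
====  ===========  ==========================================

Each band is realized as a fourth-order band-pass Butterworth filter applied
bidirectionally (forward and reverse), which doubles the stop-band
attenuation and yields an exactly zero phase response.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .records_io import UterineRecord

__all__ = [
    "Band", "FilterSpec", "B0", "B1", "B2", "B3", "WIDE",
    "SUBBANDS", "ALL_BANDS", "design_bandpass", "zero_phase_filter",
    "decompose_record", "bidirectional_gain",
]


@dataclass(frozen=True)
class Band:
    """A frequency band ``(f_low, f_high]`` or ``[f_low, f_high]`` in Hz.

    ``owns_low_edge`` controls spectral read-out only: when two analysis
    bands share an edge frequency, the edge bin belongs to the lower band,
    keeping band features disjoint.
    """

    name: str
    f_low: float
    f_high: float
    owns_low_edge: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError(
                f"band {self.name}: need 0 < f_low < f_high, "
                f"got [{self.f_low}, {self.f_high}]")

    def bin_range(self, M: int, fs: float) -> tuple[int, int]:
        """Inclusive one-sided spectrum bin range ``(k_start, k_stop)``."""
        k_low = int(round(self.f_low * M / fs))
        k_high = int(round(self.f_high * M / fs))
        if not self.owns_low_edge:
            k_low += 1
        k_high = min(k_high, M // 2)
        if k_low > k_high:
            raise ValueError(
                f"band {self.name} resolves to an empty bin range for M={M}")
        return k_low, k_high


B0 = Band("B0", 0.08, 1.0)
B1 = Band("B1", 1.0, 2.2, owns_low_edge=False)
B2 = Band("B2", 2.2, 3.5, owns_low_edge=False)
B3 = Band("B3", 3.5, 5.0, owns_low_edge=False)
WIDE = Band("WIDE", 0.08, 5.0)

SUBBANDS = (B0, B1, B2, B3)
ALL_BANDS = SUBBANDS + (WIDE,)


@dataclass(frozen=True)
class FilterSpec:
    """A realized Butterworth band-pass design for one (band, fs) pair."""

    band: Band
    fs: float
    order: int
    sos: np.ndarray                # second-order sections

    @property
    def min_input_length(self) -> int:
        # odd-reflection pad of 3x the transfer-function length on each side
        return 3 * (2 * self.order + 1) + 1

    @property
    def pad_target(self) -> int:
        """Preferred reflection-pad length: ~3 ring times of the filter.

        The transient of a narrow band-pass rings for roughly
        ``order / min(bandwidth, f_low)`` seconds; padding shorter than that
        leaks direction-dependent edge transients into the output.  The pad
        is capped at the signal length - 1 at call time.
        """
        tau = min(self.band.f_high - self.band.f_low, self.band.f_low)
        return max(self.min_input_length - 1,
                   int(np.ceil(6 * self.order * self.fs / tau)))


@lru_cache(maxsize=64)
def _design(name: str, f_low: float, f_high: float, owns_low: bool,
            fs: float, order: int) -> FilterSpec:
    band = Band(name, f_low, f_high, owns_low)
    nyq = fs / 2.0
    if band.f_high >= nyq:
        raise ValueError(
            f"band {band.name} upper edge {band.f_high} Hz needs headroom "
            f"below Nyquist ({nyq} Hz)")
    sos = sps.butter(order, [band.f_low, band.f_high], btype="bandpass",
                     fs=fs, output="sos")
    spec = FilterSpec(band, fs, order, sos)
    # stability: all section poles inside the unit circle
    for sec in sos:
        poles = np.roots(sec[3:])
        if np.any(np.abs(poles) >= 1.0):
            raise ValueError(f"unstable design for band {band.name} at fs={fs}")
    return spec


def design_bandpass(band: Band, fs: float, order: int = 4) -> FilterSpec:
    """Design (and cache) a fourth-order band-pass Butterworth filter."""
    return _design(band.name, band.f_low, band.f_high, band.owns_low_edge,
                   float(fs), int(order))


def bidirectional_gain(spec: FilterSpec, freqs: np.ndarray | float) -> np.ndarray:
    """Squared magnitude response = gain of the forward+backward pass."""
    w, h = sps.sosfreqz(spec.sos, worN=2 * np.pi * np.atleast_1d(freqs) / spec.fs)
    return np.abs(h) ** 2


def zero_phase_filter(x: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Apply ``spec`` forward and backward (zero net phase shift)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < spec.min_input_length:
        raise ValueError(
            f"input of length {x.shape[-1]} too short for band "
            f"{spec.band.name}: need more than {spec.min_input_length - 1} "
            f"samples")
    padlen = min(x.shape[-1] - 1, spec.pad_target)
    return sps.sosfiltfilt(spec.sos, x, padtype="odd", padlen=padlen)


def decompose_record(record: UterineRecord, order: int = 4,
                     bands: tuple[Band, ...] = ALL_BANDS
                     ) -> dict[str, UterineRecord]:
    """Filter every channel of ``record`` into each analysis band.

    Returns ``{"WIDE": R0-3, "B0": R0, ..., "B3": R3}``; the tocogram is
    processed identically to the EHG channels.
    """
    out: dict[str, UterineRecord] = {}
    for band in bands:
        spec = design_bandpass(band, record.fs, order)
        out[band.name] = record.with_signals(
            zero_phase_filter(record.signals, spec))
    return out
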