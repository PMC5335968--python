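"""Band-pass filtering, periodogram spectra and peak utilities.

The spectral conventions used throughout: an N-point zero-padded DFT of an
M-sample window, amplitude ``|X_j|`` stored one-sided (bins 1..N//2+1,
1-based), with bin b mapping to frequency ``(b-1)/N*fs`` Hz. Peaks are strict
local maxima; "dominant"/"significant" peaks are those exceeding a stated
fraction of the maximum amplitude over the searched range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt


@dataclass
class Spectrum:
    amp: np.ndarray   # one-sided amplitude, bins 1..len(amp) (1-based)
    fs: float
    n_fft: int        # DFT length N used for the bin->Hz mapping

    def __post_init__(self) -> None:
        self.amp = np.asarray(self.amp, dtype=float)
        if self.amp.ndim != 1 or self.amp.size == 0:
            raise ValueError("amp must be a non-empty 1-d array")
        if not np.all(np.isfinite(self.amp)) or np.any(self.amp < 0):
            raise ValueError("amplitudes must be finite and non-negative")

    @property
    def n_bins(self) -> int:
        return self.amp.size

    def bin_to_hz(self, b) -> float:
        return (np.asarray(b) - 1) / self.n_fft * self.fs

    def hz_to_bin(self, hz: float) -> int:
        """Nearest 1-based bin for a frequency in Hz."""
        b = int(round(hz * self.n_fft / self.fs)) + 1
        return min(max(b, 1), self.n_bins)

    def band_bins(self, lo_hz: float, hi_hz: float) -> tuple[int, int]:
        """Inclusive 1-based bin interval covering [lo_hz, hi_hz]."""
        lo = int(np.ceil(lo_hz * self.n_fft / self.fs)) + 1
        hi = int(np.floor(hi_hz * self.n_fft / self.fs)) + 1
        return max(lo, 1), min(hi, self.n_bins)


@dataclass
class PeakSet:
    locations: list      # 1-based bin indices, amplitude-descending
    amplitudes: list
    threshold_frac: float

    def __len__(self) -> int:
        return len(self.locations)


def bandpass(x, fs: float, lo: float = 0.4, hi: float = 5.0, order: int = 4):
    """Zero-phase Butterworth band-pass (applied forward-backward)."""
    x = np.asarray(x, dtype=float)
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    if hi >= fs / 2:
        raise ValueError("upper edge must be below the Nyquist frequency")
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def periodogram_spectrum(x, fs: float, n_fft: int) -> Spectrum:
    """One-sided amplitude spectrum of a zero-padded rectangular periodogram.

    Parseval holds as ``sum(|X_j|^2)/N == sum(x^2)`` over the full (two-sided)
    DFT; the one-sided storage keeps only bins up to Nyquist.
    """
    x = np.asarray(x, dtype=float)
    if n_fft < x.size:
        raise ValueError(f"n_fft ({n_fft}) must be >= signal length ({x.size})")
    amp = np.abs(np.fft.rfft(x, n=n_fft))
    return Spectrum(amp, fs, n_fft)


def local_maxima(amp: np.ndarray) -> np.ndarray:
    """0-based indices of strict local maxima: amp[i-1] < amp[i] >= amp[i+1].

    Array endpoints are never maxima; on a flat plateau only the first
    sample qualifies, so ties break toward the lower bin.
    """
    amp = np.asarray(amp, dtype=float)
    if amp.size < 3:
        return np.array([], dtype=int)
    inner = (amp[:-2] < amp[1:-1]) & (amp[1:-1] >= amp[2:])
    return np.flatnonzero(inner) + 1


def find_peaks_above(
    spec: Spectrum, frac: float, bin_range: tuple[int, int] | None = None
) -> PeakSet:
    """Local maxima within ``bin_range`` reaching ``frac`` of the range max.

    Maxima are judged against the full spectrum (an in-range bin whose larger
    neighbour lies just outside the range is not a peak); the threshold is
    relative to the maximum amplitude over the searched range. Results are
    sorted by amplitude descending, ties toward the lower bin.
    """
    if not (0 < frac <= 1):
        raise ValueError("frac must lie in (0, 1]")
    lo, hi = (1, spec.n_bins) if bin_range is None else bin_range
    lo, hi = max(int(lo), 1), min(int(hi), spec.n_bins)
    if lo > hi:
        raise ValueError(f"empty bin range [{lo}, {hi}]")
    peaks0 = local_maxima(spec.amp)
    in_range = peaks0[(peaks0 >= lo - 1) & (peaks0 <= hi - 1)]
    range_max = spec.amp[lo - 1 : hi].max()
    if range_max <= 0:
        return PeakSet([], [], frac)
    keep = in_range[spec.amp[in_range] >= frac * range_max]
    order = sorted(range(keep.size), key=lambda j: (-spec.amp[keep[j]], keep[j]))
    locs = [int(keep[j]) + 1 for j in order]
    amps = [float(spec.amp[keep[j]]) for j in order]
    return PeakSet(locs, amps, frac)


def band_argmax(spec: Spectrum, lo_hz: float, hi_hz: float) -> int:
    """1-based bin of the maximum amplitude within a frequency band."""
    lo, hi = spec.band_bins(lo_hz, hi_hz)
    if lo > hi:
        raise ValueError("empty frequency band")
    return lo + int(np.argmax(spec.amp[lo - 1 : hi]))
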