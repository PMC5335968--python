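"""Singular spectrum analysis and acceleration-guided artifact removal.

SSA embeds an M-sample series into an L x K trajectory (Hankel) matrix
(K = M - L + 1), takes its SVD, and turns each rank-1 term back into an
additive sub-series by diagonal (anti-diagonal) averaging. Sub-series whose
dominant spectral bin coincides with a dominant acceleration frequency are
attributed to motion and dropped; the remainder is summed back into the
cleaned window. The residual beyond the examined leading components is kept
as one lump that is never dropped, so the decomposition always sums exactly
to its input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh, hankel

from .preprocess import Spectrum, find_peaks_above, periodogram_spectrum


@dataclass
class SSADecomposition:
    components: list          # n_elementary series + one residual (each M,)
    eigenvalues: np.ndarray   # leading singular values, non-increasing
    L: int                    # embedding length
    n_elementary: int

    @property
    def residual(self) -> np.ndarray:
        return self.components[-1]


def ssa_decompose(s, L: int, k: int) -> SSADecomposition:
    """Leading k elementary SSA components of a series, plus the residual.

    Requires 1 < L < M and 1 <= k <= L. The sum of all returned components
    (including the residual) reproduces the input exactly by construction.
    """
    s = np.asarray(s, dtype=float)
    m = s.size
    if not (1 < L < m):
        raise ValueError(f"embedding length must satisfy 1 < L < {m}, got {L}")
    if not (1 <= k <= L):
        raise ValueError(f"component count must satisfy 1 <= k <= {L}")
    K = m - L + 1
    X = hankel(s[:L], s[L - 1 :])            # L x K
    k = min(k, min(L, K))
    # top-k singular triplets from the symmetric eigenproblem of X X^T;
    # much cheaper than a full SVD for k << L.
    C = X @ X.T
    w, U = eigh(C, subset_by_index=[L - k, L - 1])
    sv = np.sqrt(np.maximum(w[::-1], 0.0))
    U = U[:, ::-1]
    # anti-diagonal sums of the rank-1 outer product u v^T are the full
    # convolution u * v; dividing by the anti-diagonal lengths averages them.
    counts = np.convolve(np.ones(L), np.ones(K))
    tiny = max(sv[0], 1.0) * 1e-14
    comps = []
    total = np.zeros(m)
    for j in range(k):
        if sv[j] > tiny:
            v = (X.T @ U[:, j]) / sv[j]
            c = sv[j] * np.convolve(U[:, j], v) / counts
        else:
            c = np.zeros(m)
        comps.append(c)
        total += c
    comps.append(s - total)
    return SSADecomposition(comps, sv.copy(), L, k)


def accel_dominant_bins(a_spec: Spectrum, frac: float = 0.5) -> set[int]:
    """Bin indices of dominant acceleration peaks (>= frac of the max)."""
    return set(find_peaks_above(a_spec, frac).locations)


def dominant_bin(x, fs: float, n_fft: int) -> int:
    """1-based bin of the largest one-sided periodogram amplitude."""
    spec = periodogram_spectrum(np.asarray(x, dtype=float), fs, n_fft)
    return 1 + int(np.argmax(spec.amp))


def ssa_remove_ma(
    s_hat,
    a_spec: Spectrum,
    L: int = 500,
    k: int = 20,
    frac: float = 0.5,
    match_tol: int = 2,
) -> np.ndarray:
    """Drop SSA components whose dominant frequency matches the acceleration.

    A component is attributed to motion when its dominant spectral bin lies
    within ``match_tol`` bins of any dominant acceleration bin. If every
    elementary component would be dropped the window is returned unchanged
    with a warning (the signal would vanish).
    """
    s_hat = np.asarray(s_hat, dtype=float)
    L = min(L, s_hat.size // 2)
    lacc = accel_dominant_bins(a_spec, frac)
    if not lacc:
        return s_hat.copy()
    dec = ssa_decompose(s_hat, L, k)
    total_energy = float(np.sum(s_hat**2))
    kept, dropped, significant = [], 0, 0
    for c in dec.components[: dec.n_elementary]:
        if np.sum(c**2) <= 1e-10 * total_energy:
            kept.append(c)       # numerically negligible; harmless to keep
            continue
        significant += 1
        b = dominant_bin(c, a_spec.fs, a_spec.n_fft)
        if any(abs(b - lb) <= match_tol for lb in lacc):
            dropped += 1
        else:
            kept.append(c)
    if significant > 0 and dropped == significant:
        warnings.warn(
            "all SSA components matched acceleration frequencies; "
            "returning the window unchanged"
        )
        return s_hat.copy()
    return np.sum(kept, axis=0) + dec.residual if kept else dec.residual.copy()
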