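"""Spectral peak tracking as 3-class classification.

Given the previous heart-rate bin Lprev, the tracker searches a fundamental
range LRange1 = [Lprev - Ds, Lprev + Ds] and its first-harmonic image
LRange2 = [h(Lprev - Ds), h(Lprev + Ds)] with h(b) = 2(b-1)+1, collects up to
two dominant peaks in each, and builds three candidate bins:

* candidate 1 — the fundamental of a harmonic peak-pair if one exists, else
  Lprev stepped by sigma1 toward the strongest in-range peak;
* candidate 2 — the fundamental-range peak (or inverse-harmonic-mapped
  LRange2 peak) closest to Lprev, capped at a sigma2 step;
* candidate 3 — Lprev itself.

A random forest classifies the spectrum state into Class 1/2/3 and the
corresponding candidate becomes the new location Loc, converted to
HR = (Loc-1)/N*fs*60 BPM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import kurtosis, skew
from sklearn.ensemble import RandomForestClassifier

from .preprocess import Spectrum, band_argmax, find_peaks_above

STAGE2_FEATURE_NAMES = [
    "n_peaks_r1", "n_peaks_r2", "accel_energy", "cc_time", "cc_spec",
    "mean", "skewness", "kurtosis", "pair_flag",
]


@dataclass
class TrackerState:
    lprev: int
    delta_s: int = 2
    sigma1: int = 2
    sigma2: int = 2

    def __post_init__(self) -> None:
        if self.lprev < 1:
            raise ValueError("lprev must be >= 1")


@dataclass
class SearchRanges:
    r1: tuple[int, int]   # fundamental range, inclusive 1-based bins
    r2: tuple[int, int]   # first-harmonic range


@dataclass
class CandidateSet:
    l1: int
    l2: int
    l3: int
    harmonic_pair: tuple[int, int] | None = None
    class_label: int | None = None

    def get(self, label: int) -> int:
        return {1: self.l1, 2: self.l2, 3: self.l3}[label]


def harmonic_map(b: int) -> int:
    """Bin of the first harmonic of bin b: 2(b-1)+1."""
    return 2 * (b - 1) + 1


def inverse_harmonic(b: int) -> int:
    """Fundamental bin whose harmonic image is nearest to bin b."""
    return int(round((b - 1) / 2)) + 1


def loc_to_bpm(loc: int, fs: float, n_fft: int) -> float:
    """HR = (Loc - 1) / N * fs * 60."""
    if not (1 <= loc <= n_fft):
        raise ValueError(f"bin {loc} outside [1, {n_fft}]")
    return (loc - 1) / n_fft * fs * 60.0


def bpm_to_loc(bpm: float, fs: float, n_fft: int) -> int:
    """Nearest integer bin for a BPM value (inverse of loc_to_bpm)."""
    if bpm < 0:
        raise ValueError("bpm must be >= 0")
    loc = int(round(bpm / 60.0 * n_fft / fs)) + 1
    if loc > n_fft:
        raise ValueError(f"bpm {bpm} maps beyond bin {n_fft}")
    return loc


def compute_ranges(state: TrackerState, n_bins: int) -> SearchRanges:
    """Fundamental and harmonic search ranges, clipped to [1, n_bins]."""
    if not (1 <= state.lprev <= n_bins):
        raise ValueError(f"lprev {state.lprev} outside spectrum [1, {n_bins}]")
    lo1 = max(state.lprev - state.delta_s, 1)
    hi1 = min(state.lprev + state.delta_s, n_bins)
    lo2 = max(harmonic_map(state.lprev - state.delta_s), 1)
    hi2 = min(harmonic_map(state.lprev + state.delta_s), n_bins)
    return SearchRanges((lo1, hi1), (lo2, hi2))


def range_peaks(
    spec: Spectrum, ranges: SearchRanges, frac: float = 0.5
) -> tuple[list[int], list[int]]:
    """Up to two dominant peak bins in each range, amplitude-descending."""
    p1 = find_peaks_above(spec, frac, ranges.r1).locations[:2]
    p2 = find_peaks_above(spec, frac, ranges.r2).locations[:2]
    return p1, p2


def detect_harmonic_pair(
    li0s: list[int], li1s: list[int], tol: int = 1
) -> tuple[int, int] | None:
    """Best (fundamental, harmonic) pair within tol bins of h(b)=2(b-1)+1."""
    best, best_d = None, None
    for b0 in li0s:
        for b1 in li1s:
            d = abs(b1 - harmonic_map(b0))
            if best_d is None or d < best_d:
                best, best_d = (b0, b1), d
    if best is not None and best_d <= tol:
        return best
    return None


def _step_toward(lprev: int, target: int, step: int, n_bins: int) -> int:
    out = lprev + step * int(np.sign(target - lprev))
    return min(max(out, 1), n_bins)


def build_candidates(
    state: TrackerState,
    spec: Spectrum,
    li0s: list[int],
    li1s: list[int],
    pair: tuple[int, int] | None,
) -> CandidateSet:
    nb = spec.n_bins
    # candidate 1: harmonic-pair fundamental, else step toward the strongest
    # fundamental-range peak (peaks arrive amplitude-descending).
    if pair is not None:
        l1 = pair[0]
    elif li0s:
        l1 = _step_toward(state.lprev, li0s[0], state.sigma1, nb)
    else:
        l1 = state.lprev
    # candidate 2: peak (or inverse-mapped harmonic peak) closest to lprev,
    # capped at a sigma2 step; no peaks at all -> lprev.
    cands = list(li0s) + [inverse_harmonic(b) for b in li1s]
    if cands:
        closest = min(cands, key=lambda b: (abs(b - state.lprev), b))
        if abs(closest - state.lprev) <= state.sigma2:
            l2 = closest
        else:
            l2 = _step_toward(state.lprev, closest, state.sigma2, nb)
    else:
        l2 = state.lprev
    return CandidateSet(l1=min(max(l1, 1), nb), l2=l2, l3=state.lprev,
                        harmonic_pair=pair)


def extract_stage2_features(
    s_recon,
    accel_norm,
    spec: Spectrum,
    accel_spec: Spectrum,
    ranges: SearchRanges,
    frac: float = 0.5,
    pair: tuple[int, int] | None = None,
    band: tuple[float, float] = (0.4, 5.0),
) -> np.ndarray:
    """9 tracking features for one window (see STAGE2_FEATURE_NAMES)."""
    s_recon = np.asarray(s_recon, dtype=float)
    accel_norm = np.asarray(accel_norm, dtype=float)
    n1 = len(find_peaks_above(spec, frac, ranges.r1))
    n2 = len(find_peaks_above(spec, frac, ranges.r2))
    lo, hi = spec.band_bins(*band)
    amp = spec.amp[lo - 1 : hi]
    acc_amp = accel_spec.amp[lo - 1 : hi]

    def corr(u, v):
        if np.std(u) == 0 or np.std(v) == 0:
            return 0.0
        return float(np.corrcoef(u, v)[0, 1])

    degenerate = np.std(s_recon) == 0
    return np.asarray([
        float(n1),
        float(n2),
        float(np.sum(accel_norm**2)),
        corr(s_recon, accel_norm),
        corr(amp, acc_amp),
        float(np.mean(s_recon)),
        0.0 if degenerate else float(skew(s_recon)),
        0.0 if degenerate else float(kurtosis(s_recon, fisher=False)),
        1.0 if pair is not None else 0.0,
    ])


def label_stage2(candidates: CandidateSet, lreal: int) -> int:
    """Class of the candidate nearest Lreal; ties go to the lower class."""
    d = [abs(candidates.l1 - lreal), abs(candidates.l2 - lreal),
         abs(candidates.l3 - lreal)]
    return 1 + int(np.argmin(d))


def train_stage2(
    X, y, seed: int = 0, n_trees: int = 100, n_folds: int = 10
) -> tuple[RandomForestClassifier, dict]:
    """Fit the 3-class tracking forest and report stratified CV."""
    from .ma_decision import _cv_report  # shared report helper

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    report = _cv_report(
        model, X, y, seed, n_folds,
        {"recall_class1": 1, "recall_class2": 2, "recall_class3": 3},
    )
    model.fit(X, y)
    return model, report


def select_loc(
    model: RandomForestClassifier, features, candidates: CandidateSet
) -> tuple[int, int]:
    """Predict the spectrum class and return (Loc, class)."""
    if not hasattr(model, "estimators_"):
        raise RuntimeError("stage-2 model has not been fitted")
    cls = int(model.predict(np.asarray(features, dtype=float).reshape(1, -1))[0])
    return candidates.get(cls), cls


def initialize_tracker(
    spec: Spectrum,
    hr_band_bpm: tuple[float, float] = (50.0, 180.0),
    initial_bpm: float | None = None,
    delta_s: int = 2,
    sigma1: int = 2,
    sigma2: int = 2,
    avoid_bins: set[int] | frozenset[int] = frozenset(),
    avoid_tol: int = 4,
) -> TrackerState:
    """Seed Lprev from a user-supplied BPM or the first window's spectrum.

    Without a user-supplied BPM the initial bin is the significant HR-band
    peak with the strongest fundamental-plus-first-harmonic support (the
    pulse carries harmonics; artifact residues usually do not), falling back
    to the plain band argmax when no significant peak exists. Peaks within
    ``avoid_tol`` bins of any member of ``avoid_bins`` — typically the
    dominant accelerometer frequencies, whose cancellation residues can
    outweigh the pulse in the first window — are skipped unless every peak
    would be skipped.
    """
    lo_bpm, hi_bpm = hr_band_bpm
    if lo_bpm >= hi_bpm:
        raise ValueError("empty HR band")
    if initial_bpm is not None:
        lprev = bpm_to_loc(initial_bpm, spec.fs, spec.n_fft)
        return TrackerState(lprev, delta_s, sigma1, sigma2)
    lo, hi = spec.band_bins(lo_bpm / 60.0, hi_bpm / 60.0)
    if lo > hi:
        raise ValueError("HR band contains no spectral bins")
    if spec.amp[lo - 1 : hi].max() <= 0:
        warnings.warn("flat first-window spectrum; starting at the band edge")
        return TrackerState(lo, delta_s, sigma1, sigma2)
    peaks = find_peaks_above(spec, 0.3, (lo, hi))
    cands = list(zip(peaks.locations, peaks.amplitudes))
    if avoid_bins:
        kept = [
            (b, a) for b, a in cands
            if all(abs(b - ab) > avoid_tol for ab in avoid_bins)
        ]
        if kept:
            cands = kept
    best, best_score = None, -1.0
    for b, a in cands:
        hb = harmonic_map(b)
        h_lo = max(hb - delta_s, 1)
        h_hi = min(hb + delta_s, spec.n_bins)
        h_amp = float(spec.amp[h_lo - 1 : h_hi].max()) if h_lo <= h_hi else 0.0
        # cap harmonic support at the fundamental's own amplitude: a real
        # pulse harmonic is weaker than its fundamental, and an uncapped
        # score lets a spurious half-frequency peak claim the true
        # fundamental as its "harmonic" (octave error).
        score = a + min(h_amp, a)
        if score > best_score:
            best, best_score = b, score
    lprev = best if best is not None else band_argmax(
        spec, lo_bpm / 60.0, hi_bpm / 60.0
    )
    return TrackerState(lprev, delta_s, sigma1, sigma2)


def robust_initialize(
    specs: list[Spectrum],
    avoid_sets: list[set[int]],
    hr_band_bpm: tuple[float, float] = (50.0, 180.0),
    delta_s: int = 2,
    sigma1: int = 2,
    sigma2: int = 2,
    downweight: float = 0.25,
    avoid_tol: int = 4,
    frac: float = 0.3,
    smear: int = 2,
) -> TrackerState:
    """Seed Lprev from accumulated peak evidence over several early windows.

    Every window votes for its significant HR-band peaks with a
    capped-harmonic score (normalised so each window votes equally); votes
    within ``avoid_tol`` bins of that window's dominant accelerometer
    frequencies are down-weighted, since cancellation residues cluster
    there. The pulse persists at a consistent bin across windows while
    artifact residues wander, so the accumulated vote concentrates on the
    pulse even when single windows are dominated by residue peaks.
    """
    if not specs or len(specs) != len(avoid_sets):
        raise ValueError("need matching spectra and avoid-bin sets")
    ref = specs[0]
    lo_bpm, hi_bpm = hr_band_bpm
    lo, hi = ref.band_bins(lo_bpm / 60.0, hi_bpm / 60.0)
    if lo > hi:
        raise ValueError("HR band contains no spectral bins")
    votes = np.zeros(ref.n_bins)
    for spec, avoid in zip(specs, avoid_sets):
        if spec.amp[lo - 1 : hi].max() <= 0:
            continue
        peaks = find_peaks_above(spec, frac, (lo, hi))
        scored = []
        for b, a in zip(peaks.locations, peaks.amplitudes):
            hb = harmonic_map(b)
            h_lo, h_hi = max(hb - delta_s, 1), min(hb + delta_s, spec.n_bins)
            h_amp = float(spec.amp[h_lo - 1 : h_hi].max()) if h_lo <= h_hi else 0.0
            s = a + min(h_amp, a)
            if any(abs(b - ab) <= avoid_tol for ab in avoid):
                s *= downweight
            scored.append((b, s))
        if not scored:
            continue
        m = max(s for _, s in scored)
        if m <= 0:
            continue
        for b, s in scored:
            votes[max(b - 1 - smear, 0) : b + smear] += s / m
    if votes[lo - 1 : hi].max() <= 0:
        return initialize_tracker(ref, hr_band_bpm, None, delta_s, sigma1, sigma2)
    lprev = lo + int(np.argmax(votes[lo - 1 : hi]))
    return TrackerState(lprev, delta_s, sigma1, sigma2)
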