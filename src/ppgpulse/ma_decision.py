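"""Stage-1 gate: is the residual motion artifact Strong or NotStrong?

After the adaptive canceller, a random forest decides whether the window
still carries strong artifacts and hence whether SSA should run. Training
labels come from ground truth: a window is NotStrong when the heart rate
implied by the largest spectral peak of the denoised window falls within
``tol_bpm`` of the ECG-derived truth, Strong otherwise.

The 24 features per window: time-domain energy; the number of significant
spectral peaks (>= delta1 of the max); mean and kurtosis of the spectrum;
correlations of the denoised spectrum with the raw-PPG and acceleration
spectra; and energy/mean/std of the six db4 wavelet sub-bands (five detail
levels plus the final approximation).
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.stats import kurtosis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .preprocess import band_argmax, find_peaks_above, periodogram_spectrum
from .peak_tracking import loc_to_bpm

NOT_STRONG, STRONG = 0, 1

_WAVELET_BANDS = ["cA5", "cD5", "cD4", "cD3", "cD2", "cD1"]
STAGE1_FEATURE_NAMES = (
    ["energy_time", "n_sig_peaks", "spec_mean", "spec_kurtosis",
     "cc_spec_raw", "cc_spec_accel"]
    + [f"wav_energy_{b}" for b in _WAVELET_BANDS]
    + [f"wav_mean_{b}" for b in _WAVELET_BANDS]
    + [f"wav_std_{b}" for b in _WAVELET_BANDS]
)


def _safe_corr(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation; 0 when either input has zero variance."""
    if np.std(u) == 0 or np.std(v) == 0:
        return 0.0
    return float(np.corrcoef(u, v)[0, 1])


def extract_stage1_features(
    s_hat,
    raw_ppg,
    accel_norm,
    fs: float,
    n_fft: int,
    delta1: float = 0.30,
    band: tuple[float, float] = (0.4, 5.0),
) -> np.ndarray:
    """Deterministic 24-element feature vector for one denoised window."""
    s_hat = np.asarray(s_hat, dtype=float)
    raw_ppg = np.asarray(raw_ppg, dtype=float)
    accel_norm = np.asarray(accel_norm, dtype=float)
    if not (s_hat.shape == raw_ppg.shape == accel_norm.shape):
        raise ValueError("window lengths differ")

    spec = periodogram_spectrum(s_hat, fs, n_fft)
    lo, hi = spec.band_bins(*band)
    amp = spec.amp[lo - 1 : hi]
    raw_amp = periodogram_spectrum(raw_ppg, fs, n_fft).amp[lo - 1 : hi]
    acc_amp = periodogram_spectrum(accel_norm, fs, n_fft).amp[lo - 1 : hi]

    feats = [
        float(np.sum(s_hat**2)),
        float(len(find_peaks_above(spec, delta1, (lo, hi)))) if amp.max() > 0 else 0.0,
        float(np.mean(amp)),
        float(kurtosis(amp, fisher=False)) if np.std(amp) > 0 else 0.0,
        _safe_corr(amp, raw_amp),
        _safe_corr(amp, acc_amp),
    ]
    coeffs = pywt.wavedec(s_hat, "db4", level=5, mode="symmetric")
    feats += [float(np.sum(c**2)) for c in coeffs]
    feats += [float(np.mean(c)) for c in coeffs]
    feats += [float(np.std(c)) for c in coeffs]
    return np.asarray(feats)


def label_stage1(
    s_hat,
    truth_bpm: float,
    fs: float,
    n_fft: int,
    tol_bpm: float = 3.0,
    band: tuple[float, float] = (0.4, 5.0),
) -> int:
    """NotStrong iff the max-amplitude peak maps within tol_bpm of truth."""
    spec = periodogram_spectrum(np.asarray(s_hat, dtype=float), fs, n_fft)
    loc = band_argmax(spec, *band)
    est = loc_to_bpm(loc, fs, n_fft)
    return NOT_STRONG if abs(est - truth_bpm) <= tol_bpm else STRONG


def _cv_report(model, X, y, seed: int, n_folds: int, labels) -> dict:
    y = np.asarray(y)
    counts = {int(c): int(n) for c, n in zip(*np.unique(y, return_counts=True))}
    folds = min(n_folds, min(counts.values()))
    if folds < 2:
        raise ValueError("need at least 2 examples of every class for CV")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(model, X, y, cv=cv)
    report = {
        "n_folds": folds,
        "n_samples": int(y.size),
        "class_counts": counts,
        "accuracy": float(np.mean(pred == y)),
    }
    for name, c in labels.items():
        mask = y == c
        if mask.any():
            report[name] = float(np.mean(pred[mask] == c))
    return report


def train_stage1(
    X, y, seed: int = 0, n_trees: int = 100, n_folds: int = 10
) -> tuple[RandomForestClassifier, dict]:
    """Fit the Strong/NotStrong random forest and report stratified CV.

    Sensitivity is the recall of Strong, specificity the recall of NotStrong.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    report = _cv_report(
        model, X, y, seed, n_folds,
        {"sensitivity": STRONG, "specificity": NOT_STRONG},
    )
    model.fit(X, y)
    return model, report


def decide(model: RandomForestClassifier, features) -> int:
    """Classify one window; STRONG means SSA should run."""
    if not hasattr(model, "estimators_"):
        raise RuntimeError("stage-1 model has not been fitted")
    return int(model.predict(np.asarray(features, dtype=float).reshape(1, -1))[0])
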