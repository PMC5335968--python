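"""End-to-end two-stage heart-rate estimator.

`HeartRateEstimator` is a scikit-learn-style estimator. ``fit`` consumes
truth-labelled recordings: every window is passed through the Volterra-RLS
canceller, stage-1 Strong/NotStrong labels are derived from ground truth
(teacher-forced gate for SSA), the tracker's previous-location state is
teacher-forced from the previous window's true bin, and two random forests
are trained. ``predict`` runs the full closed loop on an unlabelled
recording: cancel, gate, (optionally) SSA-clean, track, and convert the
selected bin to BPM.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import PipelineConfig
from .ma_decision import (
    STRONG,
    decide,
    extract_stage1_features,
    label_stage1,
    train_stage1,
)
from .peak_tracking import (
    bpm_to_loc,
    build_candidates,
    compute_ranges,
    detect_harmonic_pair,
    extract_stage2_features,
    initialize_tracker,
    label_stage2,
    robust_initialize,
    loc_to_bpm,
    range_peaks,
    select_loc,
    train_stage2,
    TrackerState,
)
from .preprocess import band_argmax, bandpass, periodogram_spectrum
from .signal_io import Recording, combine_ppg, consolidate_accel, slide_windows
from .ssa import ssa_remove_ma
from .volterra_anc import VolterraConfig, rls_denoise


class HeartRateEstimator(BaseEstimator):
    """Two-stage heart-rate estimator for motion-corrupted wrist PPG.

    Parameters
    ----------
    config : PipelineConfig, optional
        All pipeline constants; defaults to :class:`PipelineConfig`.
    random_state : int, optional
        Overrides ``config.seed`` for classifier training.

    Attributes (after ``fit``)
    --------------------------
    stage1_model_, stage2_model_ : fitted random forests.
    stage1_report_, stage2_report_ : stratified-CV summaries.
    """

    def __init__(self, config: PipelineConfig | None = None,
                 random_state: int | None = None):
        self.config = config
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _cfg(self) -> PipelineConfig:
        return self.config if self.config is not None else PipelineConfig()

    def _seed(self) -> int:
        return self.random_state if self.random_state is not None else self._cfg().seed

    def _volterra_cfg(self) -> VolterraConfig:
        cfg = self._cfg()
        return VolterraConfig(
            memory=cfg.volterra_memory,
            lam=cfg.forgetting,
            delay_s=cfg.delay_s,
            init_diag=cfg.init_diag,
            order=cfg.volterra_order,
        )

    def _windows(self, rec: Recording):
        """Band-pass, consolidate and window one recording."""
        cfg = self._cfg()
        if abs(rec.fs - cfg.fs) > 1e-9:
            raise ValueError(
                f"recording fs={rec.fs} differs from configured fs={cfg.fs}"
            )
        lo, hi = cfg.band
        ppg = bandpass(combine_ppg(rec.ppg, cfg.ppg_combine), rec.fs, lo, hi)
        acc = bandpass(consolidate_accel(rec.accel), rec.fs, lo, hi)
        return slide_windows(rec, cfg.window_s, cfg.step_s, ppg=ppg, accel_norm=acc)

    def _stage1(self, win):
        """Run the canceller and extract gate features for one window."""
        cfg = self._cfg()
        s_hat, _ = rls_denoise(
            win.ppg, win.accel_norm, self._volterra_cfg(), fs=cfg.fs,
            burn_in=cfg.anc_burn_in,
        )
        feats = extract_stage1_features(
            s_hat, win.ppg, win.accel_norm, cfg.fs, cfg.n_fft, cfg.delta1, cfg.band
        )
        return s_hat, feats

    def _filter_harmonic_peaks(self, p2, a_spec):
        """Drop harmonic-range peaks sitting on accelerometer frequencies.

        A peak in the first-harmonic search range that coincides with a
        dominant accelerometer bin is almost always the cadence line or its
        cancellation residue, not the pulse harmonic; treating it as pair
        evidence locks the tracker onto half the cadence frequency.
        """
        from .ssa import accel_dominant_bins

        cfg = self._cfg()
        acc = accel_dominant_bins(a_spec, cfg.delta2)
        return [b for b in p2
                if all(abs(b - ab) > cfg.init_avoid_tol for ab in acc)]

    def _clean(self, s_hat, win):
        """Apply SSA guided by the window's acceleration spectrum."""
        cfg = self._cfg()
        a_spec = periodogram_spectrum(win.accel_norm, cfg.fs, cfg.n_fft)
        s_recon = ssa_remove_ma(
            s_hat, a_spec,
            L=cfg.ssa_embed, k=cfg.ssa_components,
            frac=cfg.delta2, match_tol=cfg.ssa_match_tol,
        )
        return s_recon, a_spec

    # ------------------------------------------------------------------
    def fit(self, recordings, y=None):
        """Train both classifiers on truth-labelled recordings."""
        cfg = self._cfg()
        if isinstance(recordings, Recording):
            recordings = [recordings]
        X1, y1, X2, y2 = [], [], [], []
        for rec in recordings:
            if rec.truth_bpm is None:
                raise ValueError(f"recording {rec.id!r} has no ground truth")
            wins = self._windows(rec)
            for i, win in enumerate(wins):
                s_hat, feats1 = self._stage1(win)
                lab1 = label_stage1(
                    s_hat, rec.truth_bpm[i], cfg.fs, cfg.n_fft, cfg.tol_bpm, cfg.band
                )
                X1.append(feats1)
                y1.append(lab1)
                if lab1 == STRONG:
                    s_recon, a_spec = self._clean(s_hat, win)
                else:
                    s_recon = s_hat
                    a_spec = periodogram_spectrum(win.accel_norm, cfg.fs, cfg.n_fft)
                if i == 0:
                    continue
                state = TrackerState(
                    bpm_to_loc(rec.truth_bpm[i - 1], cfg.fs, cfg.n_fft),
                    cfg.delta_s, cfg.sigma1, cfg.sigma2,
                )
                spec = periodogram_spectrum(s_recon, cfg.fs, cfg.n_fft)
                ranges = compute_ranges(state, spec.n_bins)
                p1, p2 = range_peaks(spec, ranges, cfg.delta2)
                p2 = self._filter_harmonic_peaks(p2, a_spec)
                pair = detect_harmonic_pair(p1, p2, cfg.harmonic_tol)
                cands = build_candidates(state, spec, p1, p2, pair)
                feats2 = extract_stage2_features(
                    s_recon, win.accel_norm, spec, a_spec, ranges,
                    cfg.delta2, pair, cfg.band,
                )
                X2.append(feats2)
                y2.append(label_stage2(cands, bpm_to_loc(rec.truth_bpm[i], cfg.fs, cfg.n_fft)))
        seed = self._seed()
        self.stage1_training_ = (np.asarray(X1), np.asarray(y1))
        self.stage2_training_ = (np.asarray(X2), np.asarray(y2))
        self.stage1_model_, self.stage1_report_ = train_stage1(
            *self.stage1_training_, seed=seed, n_trees=cfg.n_trees
        )
        self.stage2_model_, self.stage2_report_ = train_stage2(
            *self.stage2_training_, seed=seed, n_trees=cfg.n_trees
        )
        self.n_training_windows_ = (len(y1), len(y2))
        return self

    def export_training(self, stage1_path=None, stage2_path=None) -> None:
        """Write the per-window training tables (features + label) as CSV."""
        self._check_fitted()
        from .ma_decision import STAGE1_FEATURE_NAMES
        from .peak_tracking import STAGE2_FEATURE_NAMES

        for path, (X, y), names in (
            (stage1_path, self.stage1_training_, STAGE1_FEATURE_NAMES),
            (stage2_path, self.stage2_training_, STAGE2_FEATURE_NAMES),
        ):
            if path is None:
                continue
            df = pd.DataFrame(X, columns=names)
            df["label"] = y
            df.to_csv(path, index=False)

    # ------------------------------------------------------------------
    def estimate(self, rec: Recording, initial_bpm: float | None = None) -> pd.DataFrame:
        """Per-window trace: gate decision, candidates, class, Loc and BPM.

        Stage 1 (cancellation + gate + optional SSA) runs window-by-window
        first; the tracker is then seeded from the pooled evidence of the
        first few cleaned windows and run across the whole trace.
        """
        self._check_fitted()
        cfg = self._cfg()
        from .ssa import accel_dominant_bins

        cleaned = []   # (window, gate, ssa_invoked, s_recon, spec, a_spec)
        for win in self._windows(rec):
            s_hat, feats1 = self._stage1(win)
            gate = decide(self.stage1_model_, feats1)
            if gate == STRONG:
                s_recon, a_spec = self._clean(s_hat, win)
                ssa_invoked = True
            else:
                s_recon = s_hat
                a_spec = periodogram_spectrum(win.accel_norm, cfg.fs, cfg.n_fft)
                ssa_invoked = False
            spec = periodogram_spectrum(s_recon, cfg.fs, cfg.n_fft)
            cleaned.append((win, gate, ssa_invoked, s_recon, spec, a_spec))

        if initial_bpm is not None:
            state = initialize_tracker(
                cleaned[0][4], cfg.hr_band_bpm, initial_bpm,
                cfg.delta_s, cfg.sigma1, cfg.sigma2,
            )
        else:
            head = cleaned[: max(cfg.init_windows, 1)]
            state = robust_initialize(
                [c[4] for c in head],
                [accel_dominant_bins(c[5], cfg.delta2) for c in head],
                cfg.hr_band_bpm, cfg.delta_s, cfg.sigma1, cfg.sigma2,
                downweight=cfg.init_accel_downweight,
                avoid_tol=cfg.init_avoid_tol,
            )

        rows = []
        recent_argmax: list[int] = []   # trusted argmax bins disagreeing with
                                        # the tracker, for track-loss recovery
        b_lo, b_hi = cleaned[0][4].band_bins(
            cfg.hr_band_bpm[0] / 60.0, cfg.hr_band_bpm[1] / 60.0
        )
        for i, (win, gate, ssa_invoked, s_recon, spec, a_spec) in enumerate(cleaned):
            if i == 0:
                rows.append({
                    "window": win.index, "gate": gate, "ssa_invoked": ssa_invoked,
                    "lprev": state.lprev, "class": 0,
                    "l1": state.lprev, "l2": state.lprev, "l3": state.lprev,
                    "loc": state.lprev,
                    "bpm": loc_to_bpm(state.lprev, cfg.fs, cfg.n_fft),
                })
                continue
            ranges = compute_ranges(state, spec.n_bins)
            p1, p2 = range_peaks(spec, ranges, cfg.delta2)
            p2 = self._filter_harmonic_peaks(p2, a_spec)
            pair = detect_harmonic_pair(p1, p2, cfg.harmonic_tol)
            cands = build_candidates(state, spec, p1, p2, pair)
            feats2 = extract_stage2_features(
                s_recon, win.accel_norm, spec, a_spec, ranges,
                cfg.delta2, pair, cfg.band,
            )
            loc, cls = select_loc(self.stage2_model_, feats2, cands)
            rows.append({
                "window": win.index, "gate": gate, "ssa_invoked": ssa_invoked,
                "lprev": state.lprev, "class": cls,
                "l1": cands.l1, "l2": cands.l2, "l3": cands.l3,
                "loc": loc, "bpm": loc_to_bpm(loc, cfg.fs, cfg.n_fft),
            })
            state.lprev = loc

            # track-loss recovery: a NotStrong gate asserts the spectrum's
            # argmax is trustworthy; if a stable trusted argmax (away from
            # the accelerometer frequencies) disagrees with the tracker for
            # several consecutive windows, the tracker is lost - re-anchor.
            if cfg.reacquire_windows > 0:
                b = b_lo + int(np.argmax(spec.amp[b_lo - 1 : b_hi]))
                from .ssa import accel_dominant_bins as _adb

                near_accel = any(
                    abs(b - ab) <= cfg.init_avoid_tol
                    for ab in _adb(a_spec, cfg.delta2)
                )
                if (gate != STRONG and not near_accel
                        and abs(b - state.lprev) > 2 * cfg.delta_s):
                    recent_argmax.append(b)
                else:
                    recent_argmax.clear()
                if (len(recent_argmax) >= cfg.reacquire_windows
                        and max(recent_argmax[-cfg.reacquire_windows:])
                        - min(recent_argmax[-cfg.reacquire_windows:]) <= 2):
                    state.lprev = int(np.median(
                        recent_argmax[-cfg.reacquire_windows:]
                    ))
                    recent_argmax.clear()
        return pd.DataFrame(rows)

    def predict(self, rec: Recording, initial_bpm: float | None = None) -> np.ndarray:
        """Per-window BPM estimates for one recording."""
        return self.estimate(rec, initial_bpm)["bpm"].to_numpy()

    def _check_fitted(self) -> None:
        if not hasattr(self, "stage1_model_"):
            raise RuntimeError("estimator has not been fitted")


def argmax_baseline(rec: Recording, config: PipelineConfig | None = None) -> np.ndarray:
    """No-tracking baseline: per-window band-limited spectral argmax in BPM.

    Works on the band-passed consolidated PPG without artifact removal; the
    reference the tracking pipeline must beat under strong motion.
    """
    cfg = config or PipelineConfig()
    lo, hi = cfg.band
    ppg = bandpass(combine_ppg(rec.ppg, cfg.ppg_combine), rec.fs, lo, hi)
    acc = bandpass(consolidate_accel(rec.accel), rec.fs, lo, hi)
    out = []
    for win in slide_windows(rec, cfg.window_s, cfg.step_s, ppg=ppg, accel_norm=acc):
        spec = periodogram_spectrum(win.ppg, cfg.fs, cfg.n_fft)
        b0, b1 = cfg.hr_band_bpm
        loc = band_argmax(spec, b0 / 60.0, b1 / 60.0)
        out.append(loc_to_bpm(loc, cfg.fs, cfg.n_fft))
    return np.asarray(out)


def train_models(recordings, config: PipelineConfig | None = None,
                 random_state: int | None = None) -> HeartRateEstimator:
    """Thin functional wrapper: fit a HeartRateEstimator on recordings."""
    return HeartRateEstimator(config, random_state).fit(recordings)
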