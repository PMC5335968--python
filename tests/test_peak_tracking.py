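import numpy as np
import pytest

from ppgpulse.preprocess import Spectrum
from ppgpulse.peak_tracking import (
    CandidateSet,
    SearchRanges,
    TrackerState,
    bpm_to_loc,
    build_candidates,
    compute_ranges,
    detect_harmonic_pair,
    extract_stage2_features,
    harmonic_map,
    initialize_tracker,
    inverse_harmonic,
    label_stage2,
    loc_to_bpm,
    range_peaks,
    select_loc,
    train_stage2,
)

FS, NFFT = 125.0, 4096


def _spectrum(amps_at, n=300):
    amp = np.zeros(n)
    for b, a in amps_at.items():
        amp[b - 1] = a
    return Spectrum(amp, FS, NFFT)


class TestRanges:
    def test_fundamental_and_harmonic_ranges(self):
        r = compute_ranges(TrackerState(60, delta_s=2), 2049)
        assert r.r1 == (58, 62)
        assert r.r2 == (115, 123)

    def test_degenerate_width(self):
        r = compute_ranges(TrackerState(60, delta_s=0), 2049)
        assert r.r1 == (60, 60)
        assert r.r2 == (119, 119)

    def test_harmonic_range_clipped_at_spectrum_end(self):
        r = compute_ranges(TrackerState(1024, delta_s=2), 2049)
        assert r.r2[1] == 2049

    def test_out_of_spectrum_lprev_rejected(self):
        with pytest.raises(ValueError):
            compute_ranges(TrackerState(3000), 2049)


class TestRangePeaks:
    def test_single_tone_in_fundamental_range(self):
        spec = _spectrum({60: 1.0})
        p1, p2 = range_peaks(spec, SearchRanges((58, 62), (115, 123)))
        assert p1 == [60] and p2 == []

    def test_flat_range_has_no_peaks(self):
        spec = _spectrum({200: 1.0})
        p1, p2 = range_peaks(spec, SearchRanges((58, 62), (115, 123)))
        assert p1 == [] and p2 == []

    def test_two_dominant_peaks_ordered_by_amplitude(self):
        spec = _spectrum({58: 0.8, 61: 1.0})
        p1, _ = range_peaks(spec, SearchRanges((56, 63), (115, 123)), frac=0.5)
        assert p1 == [61, 58]


class TestHarmonicPair:
    def test_exact_harmonic_distance_zero(self):
        assert detect_harmonic_pair([60], [119], tol=1) == (60, 119)

    def test_distance_beyond_tolerance_rejected(self):
        assert detect_harmonic_pair([60], [123], tol=1) is None

    def test_no_harmonic_peaks_gives_none(self):
        assert detect_harmonic_pair([60], [], tol=1) is None

    def test_inverse_harmonic_inverts_map(self):
        for b in (40, 60, 75):
            assert inverse_harmonic(harmonic_map(b)) == b


class TestCandidates:
    def test_pair_fundamental_becomes_candidate_one(self):
        spec = _spectrum({60: 1.0, 119: 0.6})
        state = TrackerState(58)
        c = build_candidates(state, spec, [60], [119], (60, 119))
        assert c.l1 == 60

    def test_no_pair_steps_toward_strongest_peak(self):
        spec = _spectrum({65: 1.0})
        state = TrackerState(60, sigma1=2)
        c = build_candidates(state, spec, [65], [], None)
        assert c.l1 == 62

    def test_candidate_three_is_always_lprev(self):
        spec = _spectrum({65: 1.0})
        for lprev in (55, 60, 70):
            c = build_candidates(TrackerState(lprev), spec, [65], [], None)
            assert c.l3 == lprev

    def test_close_peak_becomes_candidate_two(self):
        spec = _spectrum({61: 1.0})
        c = build_candidates(TrackerState(60, sigma2=2), spec, [61], [], None)
        assert c.l2 == 61

    def test_far_peak_capped_at_sigma2_step(self):
        spec = _spectrum({70: 1.0})
        c = build_candidates(TrackerState(60, sigma2=2), spec, [70], [], None)
        assert c.l2 == 62

    def test_harmonic_peak_mapped_back_for_candidate_two(self):
        spec = _spectrum({119: 1.0})
        c = build_candidates(TrackerState(60, sigma2=2), spec, [], [119], None)
        assert c.l2 == 60  # inverse harmonic of 119


class TestLabelAndSelect:
    def test_label_is_argmin_distance(self):
        c = CandidateSet(l1=60, l2=59, l3=58)
        assert label_stage2(c, 61) == 1
        assert label_stage2(c, 57) == 3

    def test_ties_break_toward_lower_class(self):
        c = CandidateSet(l1=60, l2=60, l3=60)
        assert label_stage2(c, 70) == 1

    def test_select_loc_uses_predicted_class(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(i * 10, 1, size=(60, 9)) for i in range(3)])
        y = np.repeat([1, 2, 3], 60)
        model, report = train_stage2(X, y, seed=0)
        assert report["accuracy"] >= 0.9
        c = CandidateSet(l1=60, l2=62, l3=58)
        loc, cls = select_loc(model, np.full(9, 20.0), c)
        assert cls == 3 and loc == 58  # class 3 always returns Lprev

    def test_unfitted_model_raises(self):
        from sklearn.ensemble import RandomForestClassifier

        with pytest.raises(RuntimeError):
            select_loc(RandomForestClassifier(), np.zeros(9), CandidateSet(1, 1, 1))


class TestStage2Features:
    def test_pair_flag_reflects_pair_presence(self):
        spec = _spectrum({60: 1.0})
        acc = _spectrum({80: 1.0})
        r = SearchRanges((58, 62), (115, 123))
        s = np.sin(np.arange(1000) * 0.1)
        a = np.cos(np.arange(1000) * 0.2)
        with_pair = extract_stage2_features(s, a, spec, acc, r, pair=(60, 119))
        without = extract_stage2_features(s, a, spec, acc, r, pair=None)
        assert with_pair[-1] == 1.0 and without[-1] == 0.0

    def test_constant_window_degenerate_moments_are_zero(self):
        spec = _spectrum({60: 1.0})
        acc = _spectrum({80: 1.0})
        r = SearchRanges((58, 62), (115, 123))
        f = extract_stage2_features(np.ones(1000), np.zeros(1000), spec, acc, r)
        # accel energy, time correlation, skewness, kurtosis all degenerate
        assert f[2] == 0.0 and f[3] == 0.0 and f[6] == 0.0 and f[7] == 0.0


class TestBpmConversion:
    def test_dc_bin_is_zero_bpm(self):
        assert loc_to_bpm(1, FS, NFFT) == 0.0

    def test_bin_56_reference_value(self):
        assert loc_to_bpm(56, FS, NFFT) == pytest.approx(55 * 7500 / 4096)

    def test_round_trip_identity_on_all_bins(self):
        for loc in range(1, NFFT + 1):
            assert bpm_to_loc(loc_to_bpm(loc, FS, NFFT), FS, NFFT) == loc

    def test_monotone_in_bin(self):
        bpm = [loc_to_bpm(b, FS, NFFT) for b in range(1, 200)]
        assert np.all(np.diff(bpm) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            loc_to_bpm(0, FS, NFFT)
        with pytest.raises(ValueError):
            bpm_to_loc(-1.0, FS, NFFT)


class TestInitialization:
    def test_user_supplied_bpm_wins(self):
        spec = _spectrum({60: 1.0})
        st = initialize_tracker(spec, (50, 180), initial_bpm=75.0)
        assert st.lprev == bpm_to_loc(75.0, FS, NFFT)

    def test_flat_spectrum_warns_and_starts_at_band_edge(self):
        spec = Spectrum(np.zeros(300), FS, NFFT)
        with pytest.warns(UserWarning):
            st = initialize_tracker(spec, (50, 180))
        assert st.lprev == spec.band_bins(50 / 60, 180 / 60)[0]

    def test_clean_tone_initialises_at_its_bin(self):
        b = bpm_to_loc(90.0, FS, NFFT)
        spec = _spectrum({b: 1.0, harmonic_map(b): 0.5})
        st = initialize_tracker(spec, (50, 180))
        assert abs(st.lprev - b) <= 1

    def test_accel_matched_peak_avoided(self):
        b_true = bpm_to_loc(90.0, FS, NFFT)
        b_cad = bpm_to_loc(120.0, FS, NFFT)
        spec = _spectrum({b_cad: 2.0, b_true: 1.0, harmonic_map(b_true): 0.5})
        st = initialize_tracker(spec, (50, 180), avoid_bins={b_cad})
        assert st.lprev == b_true
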