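import numpy as np
import pytest

from ppgpulse.signal_io import (
    CSV_COLUMNS,
    IntegrityError,
    Recording,
    SchemaError,
    consolidate_accel,
    count_windows,
    read_recording,
    slide_windows,
    write_recording,
)


def _make_recording(n=7500, fs=125.0, truth=None, seed=0):
    rng = np.random.default_rng(seed)
    return Recording(rng.normal(size=(2, n)), rng.normal(size=(3, n)), fs,
                     truth_bpm=truth, id="fixture")


class TestConsolidateAccel:
    @pytest.mark.parametrize(
        "triplet, expected",
        [((3.0, 4.0, 0.0), 5.0), ((0.0, 0.0, 0.0), 0.0), ((1.0, 1.0, 1.0), np.sqrt(3))],
    )
    def test_pointwise_euclidean_norm(self, triplet, expected):
        accel = np.array(triplet).reshape(3, 1)
        assert consolidate_accel(accel)[0] == pytest.approx(expected, abs=1e-12)

    def test_rejects_wrong_channel_count(self):
        with pytest.raises(IntegrityError):
            consolidate_accel(np.zeros((2, 10)))


class TestSlideWindows:
    def test_window_count_matches_formula(self):
        rec = _make_recording(n=7500)  # 60 s at 125 Hz
        wins = slide_windows(rec, 8.0, 2.0)
        assert len(wins) == 27  # floor((7500-1000)/250)+1

    def test_window_length_is_t_times_fs(self):
        rec = _make_recording()
        wins = slide_windows(rec, 8.0, 2.0)
        assert all(w.ppg.size == 1000 for w in wins)

    def test_exactly_one_window_when_recording_equals_t(self):
        rec = _make_recording(n=1000)
        assert len(slide_windows(rec, 8.0, 2.0)) == 1

    def test_start_offsets_are_arithmetic(self):
        rec = _make_recording()
        starts = [w.start_sample for w in slide_windows(rec, 8.0, 2.0)]
        assert np.all(np.diff(starts) == 250)

    def test_too_short_recording_raises(self):
        rec = _make_recording(n=500)
        with pytest.raises(ValueError, match="shorter"):
            slide_windows(rec, 8.0, 2.0)

    def test_truth_length_mismatch_raises(self):
        rec = _make_recording(n=7500, truth=np.full(5, 80.0))
        with pytest.raises(IntegrityError):
            slide_windows(rec, 8.0, 2.0)

    def test_count_windows_helper_agrees(self):
        rec = _make_recording(n=7500)
        assert count_windows(7500, 125.0, 8.0, 2.0) == len(slide_windows(rec, 8.0, 2.0))


class TestRecordingInvariants:
    def test_unequal_channel_lengths_rejected(self):
        with pytest.raises(IntegrityError):
            Recording(np.zeros((2, 10)), np.zeros((3, 9)), 125.0)

    def test_nonpositive_fs_rejected(self):
        with pytest.raises(IntegrityError):
            Recording(np.zeros((2, 10)), np.zeros((3, 10)), 0.0)


class TestRoundTrips:
    @pytest.mark.parametrize("dialect,tol", [("csv", 0.0), ("mat", 1e-12)])
    def test_write_read_round_trip(self, tmp_path, dialect, tol):
        rec = _make_recording(n=2000, truth=None)
        rec.truth_bpm = np.array([80.0, 82.5, 85.0, 81.0, 79.0])
        path = tmp_path / f"rec.{dialect}"
        write_recording(rec, path, dialect)
        back = read_recording(path, dialect)
        assert back.fs == rec.fs
        if tol == 0:
            assert np.array_equal(back.ppg, rec.ppg)
            assert np.array_equal(back.accel, rec.accel)
        else:
            np.testing.assert_allclose(back.ppg, rec.ppg, atol=tol)
            np.testing.assert_allclose(back.accel, rec.accel, atol=tol)
        np.testing.assert_allclose(back.truth_bpm, rec.truth_bpm, atol=tol)

    def test_csv_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        with open(path, "w") as fh:
            fh.write("# fs=125\n")
            fh.write(",".join(CSV_COLUMNS[:-1]) + "\n")
            fh.write(",".join(["0"] * 4) + "\n")
        with pytest.raises(SchemaError):
            read_recording(path)

    def test_csv_without_fs_header_needs_override(self, tmp_path):
        rec = _make_recording(n=1000)
        path = tmp_path / "rec.csv"
        write_recording(rec, path, "csv")
        # strip the fs comment line
        lines = path.read_text().splitlines()[1:]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(SchemaError):
            read_recording(path)
        assert read_recording(path, fs=125.0).fs == 125.0

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_recording(tmp_path / "nope.csv")
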