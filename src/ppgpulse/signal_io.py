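"""Recording containers and I/O.

A :class:`Recording` bundles the synchronized raw channels of one wrist
session: two PPG channels, tri-axial acceleration, the sampling rate, and
(for training/evaluation) per-window ground-truth heart rate. Recordings can
be read from and written to a MAT layout (channel-per-row ``sig`` matrix, as
distributed with the 2015 SP-Cup-style datasets) or a plain CSV dialect with
one column per channel and the sampling rate in a ``# fs=`` comment line.
Ground truth travels in a ``bpm0`` MAT variable or a ``*_bpm.csv`` sidecar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import loadmat, savemat

CSV_COLUMNS = ["ppg1", "ppg2", "ax", "ay", "az"]


class SchemaError(ValueError):
    """A file does not match the expected channel layout."""


class IntegrityError(ValueError):
    """Channel data violate a container invariant (e.g. unequal lengths)."""


@dataclass
class Recording:
    ppg: np.ndarray          # shape (2, n)
    accel: np.ndarray        # shape (3, n)
    fs: float
    truth_bpm: np.ndarray | None = None   # per-window ground truth (BPM)
    id: str = "recording"

    def __post_init__(self) -> None:
        self.ppg = np.atleast_2d(np.asarray(self.ppg, dtype=float))
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        if self.ppg.shape[0] != 2:
            raise IntegrityError(f"expected 2 PPG channels, got {self.ppg.shape[0]}")
        if self.accel.shape[0] != 3:
            raise IntegrityError(f"expected 3 accel channels, got {self.accel.shape[0]}")
        if self.ppg.shape[1] != self.accel.shape[1]:
            raise IntegrityError("PPG and acceleration channel lengths differ")
        if self.fs <= 0:
            raise IntegrityError("sampling rate must be positive")
        if self.truth_bpm is not None:
            self.truth_bpm = np.asarray(self.truth_bpm, dtype=float).ravel()

    @property
    def n_samples(self) -> int:
        return self.ppg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class WindowView:
    """One T-second analysis frame of consolidated signals."""

    index: int
    ppg: np.ndarray          # M samples, consolidated PPG
    accel_norm: np.ndarray   # M samples
    start_sample: int


def consolidate_accel(accel: np.ndarray) -> np.ndarray:
    """Euclidean norm of the tri-axial vector at every sampling point."""
    accel = np.atleast_2d(np.asarray(accel, dtype=float))
    if accel.shape[0] != 3:
        raise IntegrityError("consolidate_accel expects 3 channels")
    return np.linalg.norm(accel, axis=0)


def combine_ppg(ppg: np.ndarray, mode: str = "mean") -> np.ndarray:
    ppg = np.atleast_2d(np.asarray(ppg, dtype=float))
    if mode == "mean":
        return ppg.mean(axis=0)
    if mode == "channel1":
        return ppg[0]
    if mode == "channel2":
        return ppg[1]
    raise ValueError(f"unknown PPG combination mode {mode!r}")


def count_windows(n_samples: int, fs: float, window_s: float, step_s: float) -> int:
    m = int(round(window_s * fs))
    m0 = int(round(step_s * fs))
    if n_samples < m:
        return 0
    return (n_samples - m) // m0 + 1


def slide_windows(
    rec: Recording,
    window_s: float,
    step_s: float,
    *,
    ppg: np.ndarray | None = None,
    accel_norm: np.ndarray | None = None,
    combine: str = "mean",
) -> list[WindowView]:
    """Cut the recording into overlapping analysis windows.

    ``ppg`` / ``accel_norm`` allow passing pre-filtered consolidated signals;
    otherwise the raw channels are consolidated unfiltered.
    """
    m = window_s * rec.fs
    m0 = step_s * rec.fs
    if abs(m - round(m)) > 1e-9 or abs(m0 - round(m0)) > 1e-9:
        raise ValueError("window_s*fs and step_s*fs must be integral")
    m, m0 = int(round(m)), int(round(m0))
    if step_s > window_s / 2:
        warnings.warn("step exceeds half the window length; windows barely overlap")
    if rec.n_samples < m:
        raise ValueError(
            f"recording {rec.id!r} ({rec.n_samples} samples) shorter than one "
            f"window ({m} samples)"
        )
    if ppg is None:
        ppg = combine_ppg(rec.ppg, combine)
    if accel_norm is None:
        accel_norm = consolidate_accel(rec.accel)
    n_win = (rec.n_samples - m) // m0 + 1
    if rec.truth_bpm is not None and len(rec.truth_bpm) != n_win:
        raise IntegrityError(
            f"truth_bpm has {len(rec.truth_bpm)} entries but windowing "
            f"produces {n_win} windows"
        )
    out = []
    for i in range(n_win):
        s = i * m0
        out.append(WindowView(i, ppg[s : s + m], accel_norm[s : s + m], s))
    return out


# ---------------------------------------------------------------------------
# file I/O


def _sidecar(path: Path) -> Path:
    return path.with_name(path.stem + "_bpm.csv")


def write_recording(rec: Recording, path, dialect: str | None = None) -> None:
    path = Path(path)
    dialect = dialect or ("mat" if path.suffix.lower() == ".mat" else "csv")
    if dialect == "mat":
        data = {"sig": np.vstack([rec.ppg, rec.accel]), "fs": float(rec.fs)}
        if rec.truth_bpm is not None:
            data["bpm0"] = rec.truth_bpm.reshape(-1, 1)
        savemat(path, data)
    elif dialect == "csv":
        df = pd.DataFrame(
            np.vstack([rec.ppg, rec.accel]).T, columns=CSV_COLUMNS
        )
        with open(path, "w") as fh:
            fh.write(f"# fs={rec.fs!r}\n")
            df.to_csv(fh, index=False, float_format="%.17g")
        if rec.truth_bpm is not None:
            pd.DataFrame({"truth_bpm": rec.truth_bpm}).to_csv(
                _sidecar(path), index=False, float_format="%.17g"
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_recording(path, dialect: str | None = None, fs: float | None = None) -> Recording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or ("mat" if path.suffix.lower() == ".mat" else "csv")
    if dialect == "mat":
        return _read_mat(path, fs)
    if dialect == "csv":
        return _read_csv(path, fs)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_mat(path: Path, fs: float | None) -> Recording:
    data = loadmat(path)
    if "sig" not in data:
        raise SchemaError(f"{path}: missing 'sig' matrix")
    sig = np.atleast_2d(data["sig"]).astype(float)
    if sig.shape[0] == 6:
        # SP-Cup layout carries a leading ECG row; drop it.
        sig = sig[1:]
    if sig.shape[0] != 5:
        raise SchemaError(
            f"{path}: 'sig' must have 5 rows (ppg1,ppg2,ax,ay,az) or 6 "
            f"with a leading ECG row; got {sig.shape[0]}"
        )
    if fs is None:
        if "fs" not in data:
            raise SchemaError(f"{path}: missing 'fs' and no override given")
        fs = float(np.asarray(data["fs"]).ravel()[0])
    truth = None
    if "bpm0" in data:
        truth = np.asarray(data["bpm0"], dtype=float).ravel()
    return Recording(sig[:2], sig[2:], fs, truth, id=path.stem)


def _read_csv(path: Path, fs: float | None) -> Recording:
    header_fs = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "fs=" in first:
        header_fs = float(first.split("fs=")[1].strip())
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing or len(df.columns) != len(CSV_COLUMNS):
        raise SchemaError(
            f"{path}: expected columns {CSV_COLUMNS}, got {list(df.columns)}"
            + (f" (missing {missing})" if missing else "")
        )
    if fs is None:
        fs = header_fs
    if fs is None:
        raise SchemaError(f"{path}: no '# fs=' header and no override given")
    arr = df[CSV_COLUMNS].to_numpy(dtype=float).T
    truth = None
    side = _sidecar(path)
    if side.exists():
        tdf = pd.read_csv(side, float_precision="round_trip")
        if "truth_bpm" not in tdf.columns:
            raise SchemaError(f"{side}: missing 'truth_bpm' column")
        truth = tdf["truth_bpm"].to_numpy(dtype=float)
    return Recording(arr[:2], arr[2:], fs, truth, id=path.stem)
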