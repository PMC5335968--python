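"""Pipeline configuration.

All tunable constants of the two-stage estimator live here: windowing,
spectral resolution, peak thresholds, the Volterra/RLS canceller, SSA, the
gate tolerance and classifier settings. Defaults follow the standard
operating point for 125 Hz wrist PPG (8 s windows sliding by 2 s, 4096-point
spectra, 0.4-5 Hz analysis band).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import yaml


@dataclass
class PipelineConfig:
    # sampling / windowing
    fs: float = 125.0            # Hz
    window_s: float = 8.0        # analysis window T (s)
    step_s: float = 2.0          # window increment M0 (s)
    n_fft: int = 4096            # DFT length N (zero-padded periodogram)

    # spectral analysis
    band: tuple = (0.4, 5.0)     # analysis band (Hz)
    delta1: float = 0.30         # significant-peak fraction (stage-1 feature)
    delta2: float = 0.50         # dominant-peak fraction (SSA / tracking)

    # tracking geometry (bins)
    delta_s: int = 2             # half-width of the fundamental search range
    sigma1: int = 2              # fallback step for candidate 1
    sigma2: int = 2              # fallback step for candidate 2
    harmonic_tol: int = 1        # max bin distance for a harmonic pair

    # Volterra adaptive noise canceller
    delay_s: float = 0.08        # accel-to-artifact lag (s)
    volterra_memory: int = 10    # reference history length (samples)
    volterra_order: int = 2      # 1 = linear-only ablation, 2 = full
    forgetting: float = 0.999    # RLS forgetting factor lambda
    init_diag: float = 100.0     # RLS inverse-correlation init scale
    anc_burn_in: bool = True     # converge coefficients before denoising

    # singular spectrum analysis
    ssa_embed: int = 500         # embedding length L (capped at M // 2)
    ssa_components: int = 20     # elementary components examined
    ssa_match_tol: int = 2       # bin tolerance for accel-frequency match

    # gate / labels
    tol_bpm: float = 3.0         # "very close" threshold for Strong/NotStrong
    hr_band_bpm: tuple = (50.0, 180.0)

    # tracker initialisation
    init_windows: int = 5        # early windows pooled for the initial bin
    init_accel_downweight: float = 0.25  # vote weight near accel frequencies
    init_avoid_tol: int = 4      # bin radius of the down-weighted zone

    # track-loss recovery: re-anchor Lprev when this many consecutive
    # NotStrong windows show a stable in-band argmax far from the tracker
    # (0 disables)
    reacquire_windows: int = 5

    # misc
    ppg_combine: str = "mean"    # {mean, channel1, channel2}
    n_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        lo, hi = self.band
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError("band must satisfy 0 < lo < hi < fs/2")
        if self.window_s <= 0 or self.step_s <= 0:
            raise ValueError("window_s and step_s must be positive")
        for name in ("window_s", "step_s"):
            v = getattr(self, name) * self.fs
            if abs(v - round(v)) > 1e-9:
                raise ValueError(f"{name}*fs must be an integral sample count")
        if self.n_fft < self.window_samples:
            raise ValueError("n_fft must be >= window length in samples")
        if not (0 < self.forgetting <= 1):
            raise ValueError("forgetting factor must lie in (0, 1]")
        if self.volterra_memory < 0:
            raise ValueError("volterra_memory must be >= 0")
        if self.volterra_order not in (1, 2):
            raise ValueError("volterra_order must be 1 or 2")
        if self.delay_s < 0:
            raise ValueError("delay_s must be >= 0")
        if not (0 < self.delta1 <= 1 and 0 < self.delta2 <= 1):
            raise ValueError("delta1/delta2 must lie in (0, 1]")
        if self.ppg_combine not in ("mean", "channel1", "channel2"):
            raise ValueError("ppg_combine must be mean|channel1|channel2")
        b0, b1 = self.hr_band_bpm
        if not (0 <= b0 < b1):
            raise ValueError("hr_band_bpm must be an increasing interval")

    # -- derived quantities ----------------------------------------------
    @property
    def window_samples(self) -> int:
        """M = T * fs."""
        return int(round(self.window_s * self.fs))

    @property
    def step_samples(self) -> int:
        return int(round(self.step_s * self.fs))

    @property
    def bin_resolution_bpm(self) -> float:
        """BPM width of one frequency bin: fs * 60 / N."""
        return self.fs * 60.0 / self.n_fft

    # -- (de)serialisation -----------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band)
        d["hr_band_bpm"] = list(self.hr_band_bpm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "band" in d:
            d["band"] = tuple(d["band"])
        if "hr_band_bpm" in d:
            d["hr_band_bpm"] = tuple(d["hr_band_bpm"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Short stable hash, used to tie serialized models to a config."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
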