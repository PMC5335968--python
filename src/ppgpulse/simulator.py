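"""Synthetic wrist recordings with known heart rate.

The generator emulates the structure of treadmill wrist data: a
quasi-periodic pulse whose fundamental follows a slowly drifting BPM
trajectory (decaying harmonics, phase-continuous), tri-axial acceleration
dominated by a cadence-locked oscillation riding on a gravity offset, and
motion artifacts injected into the PPG channels as a delayed linear +
quadratic transform of the cadence signal — the same functional family the
Volterra canceller models, so artifact cancellation is well-posed by
construction. Ground-truth BPM is the per-window mean of the instantaneous
heart rate, matching the per-window ECG-derived truth convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .signal_io import Recording, count_windows
from .volterra_anc import shift_reference


@dataclass
class SimConfig:
    duration_s: float = 180.0
    fs: float = 125.0
    window_s: float = 8.0        # windowing used for the truth trace
    step_s: float = 2.0
    hr_start_bpm: float = 80.0
    hr_drift_bpm: float = 1.0    # random-walk step per window step (BPM)
    hr_band_bpm: tuple = (60.0, 170.0)
    n_harmonics: int = 3
    harmonic_decay: float = 0.5  # amplitude ratio between successive harmonics
    pulse_amp: float = 1.0
    cadence_hz: float = 2.0      # step frequency of the simulated motion
    accel_osc_amp: float = 1.0   # scale of the cadence oscillation on the axes
    cadence_harmonic: float = 0.2  # relative amplitude of the 2x-cadence line
    cadence_freq_jitter: float = 0.01  # rel. SD of step-timing variability
    cadence_jitter_corr_s: float = 4.0
    ma_gain_linear: float = 0.0
    ma_gain_quadratic: float = 0.0
    ma_gain_jitter: float = 0.5  # rel. SD of the slow optical-coupling drift
    jitter_corr_s: float = 2.0   # correlation time of that drift (s)
    ma_gain_independent: float = 0.0  # RMS of accel-independent artifact
    ma_burst_mean_s: float = 20.0  # mean on/off episode length; 0 = continuous
    delay_s: float = 0.08        # accel leads the artifact by this lag
    noise_sd: float = 0.05       # white noise on each PPG channel
    accel_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.hr_band_bpm
        if not (0 < lo < hi < self.fs * 30):
            raise ValueError("hr_band_bpm must lie inside (0, fs*30)")
        if min(self.ma_gain_linear, self.ma_gain_quadratic, self.noise_sd,
               self.accel_noise_sd, self.pulse_amp) < 0:
            raise ValueError("gains and noise levels must be >= 0")


def _reflect(v: float, lo: float, hi: float) -> float:
    # reflect a random-walk value back into [lo, hi]
    span = hi - lo
    v = (v - lo) % (2 * span)
    return lo + (v if v <= span else 2 * span - v)


def simulate_hr_trace(cfg: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-window ground-truth BPM: a reflected random walk inside hr_band."""
    _, truth = _hr_trajectory(cfg, rng or np.random.default_rng(cfg.seed))
    return truth


def _hr_trajectory(cfg: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """(per-sample instantaneous BPM, per-window mean BPM)."""
    n = int(round(cfg.duration_s * cfg.fs))
    m0 = int(round(cfg.step_s * cfg.fs))
    lo, hi = cfg.hr_band_bpm
    n_ctrl = n // m0 + 2
    ctrl = np.empty(n_ctrl)
    ctrl[0] = _reflect(cfg.hr_start_bpm, lo, hi)
    for j in range(1, n_ctrl):
        ctrl[j] = _reflect(ctrl[j - 1] + rng.normal(0, cfg.hr_drift_bpm), lo, hi)
    inst = np.interp(np.arange(n), np.arange(n_ctrl) * m0, ctrl)
    n_win = count_windows(n, cfg.fs, cfg.window_s, cfg.step_s)
    m = int(round(cfg.window_s * cfg.fs))
    truth = np.array([inst[i * m0 : i * m0 + m].mean() for i in range(n_win)])
    return inst, truth


def simulate_recording(cfg: SimConfig, rec_id: str | None = None) -> Recording:
    """One synthetic recording with per-window ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    inst, truth = _hr_trajectory(cfg, rng)

    # phase-continuous pulse with decaying harmonics
    phase = 2 * np.pi * np.cumsum(inst / 60.0) / cfg.fs
    pulse = np.zeros(n)
    for h in range(1, cfg.n_harmonics + 1):
        pulse += cfg.pulse_amp * cfg.harmonic_decay ** (h - 1) * np.sin(h * phase)

    # cadence-locked oscillation shared by the accelerometer and the
    # artifact. Step timing carries natural variability (an AR(1) drift of
    # the instantaneous step frequency): the artifact stays perfectly
    # coherent with the accelerometer (same source), but an independent
    # pulse at a nearby frequency decorrelates from the reference over the
    # window instead of being cancelled with it.
    ph0, ph1 = rng.uniform(0, 2 * np.pi, size=2)
    if cfg.cadence_freq_jitter > 0:
        rho = np.exp(-1.0 / (cfg.cadence_jitter_corr_s * cfg.fs))
        eps = rng.normal(0, cfg.cadence_freq_jitter * np.sqrt(1 - rho**2), size=n)
        drift = np.empty(n)
        drift[0] = rng.normal(0, cfg.cadence_freq_jitter)
        for i in range(1, n):
            drift[i] = rho * drift[i - 1] + eps[i]
        inst_cad = cfg.cadence_hz * (1.0 + drift)
    else:
        inst_cad = np.full(n, cfg.cadence_hz)
    cad_phase = 2 * np.pi * np.cumsum(inst_cad) / cfg.fs
    cad = np.sin(cad_phase + ph0)
    cad = cad + cfg.cadence_harmonic * np.sin(2 * cad_phase + ph1)

    # gravity offset keeps the triaxial norm linear in the oscillation
    gravity = np.array([0.0, 0.0, 1.0])
    proj = cfg.accel_osc_amp * np.array([0.15, 0.15, 0.4])
    accel = (
        gravity[:, None]
        + proj[:, None] * cad[None, :]
        + rng.normal(0, cfg.accel_noise_sd, size=(3, n))
    )

    # artifact: delayed linear + quadratic transform of the cadence signal,
    # scaled by a slowly drifting optical-coupling gain. The drift emulates
    # varying sensor contact pressure: it modulates how strongly motion leaks
    # into the PPG but leaves the accelerometer unchanged, which is what
    # defeats a within-window canceller on real data.
    cad_d = shift_reference(cad, int(round(cfg.delay_s * cfg.fs)))
    artifact = cfg.ma_gain_linear * cad_d + cfg.ma_gain_quadratic * cad_d**2
    if cfg.ma_gain_jitter > 0:
        rho = np.exp(-1.0 / (cfg.jitter_corr_s * cfg.fs))
        eps = rng.normal(0, cfg.ma_gain_jitter * np.sqrt(1 - rho**2), size=n)
        ou = np.empty(n)
        ou[0] = rng.normal(0, cfg.ma_gain_jitter)
        for i in range(1, n):
            ou[i] = rho * ou[i - 1] + eps[i]
        artifact = artifact * np.exp(ou - cfg.ma_gain_jitter**2 / 2)

    # accel-independent artifact: band-limited motion of the sensor against
    # the skin (contact-pressure transients, episodic arm movements) that has
    # no accelerometer signature, hence survives reference-based
    # cancellation. Episodes arrive as an on/off telegraph process with
    # exponentially distributed durations, emulating intermittent movements.
    if cfg.ma_gain_independent > 0:
        from .preprocess import bandpass

        raw = rng.normal(0, 1, size=n)
        ind = bandpass(raw, cfg.fs, 0.5, 3.5)
        ind *= cfg.ma_gain_independent / max(np.std(ind), 1e-12)
        if cfg.ma_burst_mean_s > 0:
            env = np.zeros(n)
            pos, on = 0, rng.random() < 0.5
            while pos < n:
                dur = int(round(rng.exponential(cfg.ma_burst_mean_s) * cfg.fs))
                dur = max(dur, 1)
                if on:
                    env[pos : pos + dur] = 1.0
                pos += dur
                on = not on
            # half-second cosine ramps avoid step discontinuities
            ramp = max(int(0.5 * cfg.fs), 1)
            kern = 0.5 - 0.5 * np.cos(np.linspace(0, 2 * np.pi, 2 * ramp + 1))
            env = np.convolve(env, kern / kern.sum(), mode="same")
            ind = ind * env
        artifact = artifact + ind

    ppg = np.vstack([
        pulse + artifact + rng.normal(0, cfg.noise_sd, size=n),
        0.95 * pulse + 1.05 * artifact + rng.normal(0, cfg.noise_sd, size=n),
    ])
    return Recording(ppg, accel, cfg.fs, truth,
                     id=rec_id or f"sim-{cfg.seed}")


# per-condition overrides: clean = near rest (little wrist motion at all),
# moderate = walking with episodic arm movements, strong = running with
# episodic arm movements.
GAIN_LEVELS = {
    "clean": dict(ma_gain_linear=0.0, ma_gain_quadratic=0.0,
                  ma_gain_independent=0.0, accel_osc_amp=0.0),
    "moderate": dict(ma_gain_linear=1.0, ma_gain_quadratic=0.5,
                     ma_gain_independent=5.0),
    "strong": dict(ma_gain_linear=4.0, ma_gain_quadratic=2.0,
                   ma_gain_independent=5.0),
}


def simulate_dataset(
    base_cfg: SimConfig,
    n_per_level: int = 2,
    seed: int = 0,
    levels: dict[str, dict] | None = None,
) -> list[Recording]:
    """Factorial grid over motion-artifact conditions, seeded per cell."""
    levels = levels or GAIN_LEVELS
    rng = np.random.default_rng(seed)
    out = []
    for name, overrides in levels.items():
        for j in range(n_per_level):
            child = int(rng.integers(0, 2**31 - 1))
            cfg = replace(
                base_cfg,
                hr_start_bpm=float(rng.uniform(*base_cfg.hr_band_bpm)),
                seed=child,
            )
            cfg = replace(cfg, **overrides)
            out.append(simulate_recording(cfg, rec_id=f"sim-{name}-{j}"))
    return out


# training conditions: the three gain levels plus the canonical challenge
# case of running with the heart rate close to the step cadence, where the
# canceller inevitably damages the pulse and holding the previous location
# is the right tracking behaviour.
TRAINING_LEVELS = {
    **GAIN_LEVELS,
    "overlap": dict(ma_gain_linear=4.0, ma_gain_quadratic=2.0,
                    ma_gain_independent=5.0, hr_start_bpm=118.0),
}


def make_training_grid(
    duration_s: float = 180.0, n_per_level: int = 3, seed: int = 42,
    base_cfg: SimConfig | None = None,
) -> list[Recording]:
    """The canonical labelled training dataset for both classifiers."""
    base = base_cfg or SimConfig(duration_s=duration_s, seed=seed)
    return simulate_dataset(base, n_per_level=n_per_level, seed=seed,
                            levels=TRAINING_LEVELS)
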