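"""Agreement metrics between estimated and ground-truth heart-rate traces.

Average absolute error (AAE), Bland-Altman limits of agreement
(mu -+ 1.96 sigma of the per-window differences, sample SD), Pearson
correlation, and per-recording report tables. An ordinary-least-squares fit
of estimate on truth (slope/intercept/R^2) is reported for scatter plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class HRTrace:
    est_bpm: np.ndarray
    true_bpm: np.ndarray
    id: str = "trace"

    def __post_init__(self) -> None:
        self.est_bpm = np.asarray(self.est_bpm, dtype=float).ravel()
        self.true_bpm = np.asarray(self.true_bpm, dtype=float).ravel()
        if self.est_bpm.size != self.true_bpm.size:
            raise ValueError("estimate and truth lengths differ")
        if self.est_bpm.size < 1:
            raise ValueError("empty trace")
        if np.any(self.est_bpm < 0) or np.any(self.true_bpm < 0):
            raise ValueError("BPM values must be non-negative")

    @property
    def n_windows(self) -> int:
        return self.est_bpm.size


def aae(trace: HRTrace) -> float:
    """Average absolute error (BPM): mean |est - true| over windows."""
    return float(np.mean(np.abs(trace.est_bpm - trace.true_bpm)))


def bland_altman(trace: HRTrace) -> tuple[float, float, float, float]:
    """(mu, sigma, loa_low, loa_high) of the est-true differences.

    sigma is the sample standard deviation (denominator W-1); the limits of
    agreement are mu -+ 1.96 sigma.
    """
    if trace.n_windows < 2:
        raise ValueError("Bland-Altman requires at least 2 windows")
    diff = trace.est_bpm - trace.true_bpm
    mu = float(np.mean(diff))
    sigma = float(np.std(diff, ddof=1))
    return mu, sigma, mu - 1.96 * sigma, mu + 1.96 * sigma


def pearson(trace: HRTrace) -> float:
    """Pearson correlation between truth and estimates; NaN if constant."""
    if np.std(trace.est_bpm) == 0 or np.std(trace.true_bpm) == 0:
        return float("nan")
    return float(stats.pearsonr(trace.true_bpm, trace.est_bpm)[0])


def ols_fit(trace: HRTrace) -> dict:
    """OLS of estimate on truth: slope, intercept, r2."""
    res = stats.linregress(trace.true_bpm, trace.est_bpm)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
    }


def report(traces: list[HRTrace]) -> pd.DataFrame:
    """Per-recording AAE table plus a pooled mean +- sample-SD row."""
    if not traces:
        raise ValueError("need at least one trace")
    rows = [
        {"id": tr.id, "n_windows": tr.n_windows, "aae_bpm": aae(tr)}
        for tr in traces
    ]
    vals = np.array([r["aae_bpm"] for r in rows])
    rows.append({
        "id": "pooled",
        "n_windows": int(sum(r["n_windows"] for r in rows)),
        "aae_bpm": float(vals.mean()),
        "aae_sd_bpm": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
    })
    return pd.DataFrame(rows)


def bland_altman_plot(trace: HRTrace, path) -> None:
    """Optional Bland-Altman figure (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mu, sigma, lo, hi = bland_altman(trace)
    mean_pair = (trace.est_bpm + trace.true_bpm) / 2
    fig, ax = plt.subplots()
    ax.scatter(mean_pair, trace.est_bpm - trace.true_bpm, s=8, alpha=0.6)
    for y, style in ((mu, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, linestyle=style, color="k")
    ax.set_xlabel("mean of estimate and truth (BPM)")
    ax.set_ylabel("estimate - truth (BPM)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
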