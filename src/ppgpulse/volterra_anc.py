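"""Second-order Volterra adaptive noise cancellation with RLS adaptation.

The measured PPG window x(k) is modelled as pulse + motion artifact, where
the artifact is a (possibly nonlinear) function of wrist acceleration. The
canceller builds a second-order Volterra expansion of the consolidated
acceleration reference — the lagged linear terms a(i-p), p=0..memory, followed
by all distinct pairwise products a(i-p)*a(i-q), p <= q — and adapts a
coefficient vector w by exponentially-weighted recursive least squares with
forgetting factor lambda. The denoised sample is

    s_hat(k) = x(k) - w(k)^T a_hat(k),

with w(k) the coefficient vector after processing sample k (i.e. the
a-posteriori residual), matching the closed-form exponentially weighted
least-squares solution over samples 0..k up to the P(0) = init_diag*I
regularisation.

The motion-to-artifact lag is handled by delaying the acceleration reference
by ``delay_s`` before expansion, so that the artifact-causing acceleration
appears at lag 0 of the expansion (acceleration leads the artifact).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class VolterraConfig:
    memory: int = 10          # reference history length (samples)
    lam: float = 0.999        # RLS forgetting factor
    delay_s: float = 0.08     # reference lag (s); applied by the caller or
                              # via fs in rls_denoise
    init_diag: float = 100.0  # P(0) scale
    order: int = 2            # 1 = linear-only, 2 = full second order

    def __post_init__(self) -> None:
        if not (0 < self.lam <= 1):
            raise ValueError("forgetting factor must lie in (0, 1]")
        if self.memory < 0:
            raise ValueError("memory must be >= 0")
        if self.delay_s < 0:
            raise ValueError("delay_s must be >= 0")
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")


@dataclass
class RLSState:
    w: np.ndarray   # coefficient vector, length D
    P: np.ndarray   # D x D inverse correlation matrix

    @property
    def dim(self) -> int:
        return self.w.size


def expansion_dim(memory: int, order: int = 2) -> int:
    """D = (memory+1) linear terms [+ (memory+1)(memory+2)/2 products]."""
    n = memory + 1
    return n if order == 1 else n + n * (n + 1) // 2


def _quad_index_pairs(memory: int) -> tuple[np.ndarray, np.ndarray]:
    # lag pairs (p, q) with p <= q, row-major in p: (0,0),(0,1),..,(m,m)
    p, q = np.triu_indices(memory + 1)
    return p, q


def volterra_expand(a, i: int, memory: int, order: int = 2) -> np.ndarray:
    """Expansion vector a_hat(i); history before the signal start is zero."""
    a = np.asarray(a, dtype=float)
    lags = np.array(
        [a[i - p] if 0 <= i - p < a.size else 0.0 for p in range(memory + 1)]
    )
    if order == 1:
        return lags
    p, q = _quad_index_pairs(memory)
    return np.concatenate([lags, lags[p] * lags[q]])


def build_design(a, memory: int, order: int = 2) -> np.ndarray:
    """All expansion vectors of a reference series, stacked as rows (M x D)."""
    a = np.asarray(a, dtype=float)
    m = a.size
    padded = np.concatenate([np.zeros(memory), a])
    # lag matrix: column p holds a(i - p)
    lagmat = np.stack(
        [padded[memory - p : memory - p + m] for p in range(memory + 1)], axis=1
    )
    if order == 1:
        return lagmat
    p, q = _quad_index_pairs(memory)
    return np.concatenate([lagmat, lagmat[:, p] * lagmat[:, q]], axis=1)


def shift_reference(a, delay_samples: int) -> np.ndarray:
    """Delay the acceleration by ``delay_samples`` (zero-padded at the start).

    The artifact at sample k is driven by acceleration at k - delay, so the
    delayed reference aligns the driving acceleration with lag 0.
    """
    a = np.asarray(a, dtype=float)
    if delay_samples == 0:
        return a.copy()
    if delay_samples < 0:
        out = np.concatenate([a[-delay_samples:], np.zeros(-delay_samples)])
        return out
    return np.concatenate([np.zeros(delay_samples), a[:-delay_samples]])


def _rls_pass(x, phi_all, w, P, lam):
    m = x.size
    s_hat = np.empty(m)
    for k in range(m):
        phi = phi_all[k]
        Pphi = P @ phi
        g = Pphi / (lam + phi @ Pphi)
        w = w + g * (x[k] - w @ phi)
        P = (P - np.outer(g, Pphi)) / lam
        s_hat[k] = x[k] - w @ phi
        if k % 128 == 127:   # keep P symmetric against roundoff drift
            P = 0.5 * (P + P.T)
    return s_hat, w, P


def rls_denoise(
    x,
    a,
    cfg: VolterraConfig | None = None,
    fs: float | None = None,
    burn_in: bool = False,
) -> tuple[np.ndarray, RLSState]:
    """Cancel the motion artifact in one window.

    Parameters
    ----------
    x : measured PPG window (M samples).
    a : consolidated acceleration reference, same length. If ``fs`` is given
        the reference is delayed by round(cfg.delay_s * fs) samples first;
        otherwise it is taken as already aligned.
    burn_in : when True, the adaptation is run over the window once to
        converge the coefficients and then re-run from that state to produce
        the output, removing the convergence transient from the first
        seconds of every window while keeping windows independent.

    Returns the denoised window and the final RLS state. Coefficients start
    at zero each call (windows are processed independently), so a zero
    reference leaves the window untouched.
    """
    cfg = cfg or VolterraConfig()
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    if x.shape != a.shape or x.ndim != 1:
        raise ValueError("x and a must be 1-d arrays of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(a))):
        raise ValueError("non-finite input")
    if fs is not None:
        a = shift_reference(a, int(round(cfg.delay_s * fs)))
    phi_all = build_design(a, cfg.memory, cfg.order)
    d = phi_all.shape[1]
    w = np.zeros(d)
    P = cfg.init_diag * np.eye(d)
    if burn_in:
        _, w, P = _rls_pass(x, phi_all, w, P, cfg.lam)
    s_hat, w, P = _rls_pass(x, phi_all, w, P, cfg.lam)
    return s_hat, RLSState(w, P)
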