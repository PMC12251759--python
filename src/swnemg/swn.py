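"""Sliding-window z-score normalization (SWN).

At every discrete time ``t`` the trailing window of ``L_norm`` samples is
z-scored with its own mean ``m_t`` and population standard deviation ``s_t``:

    y[t] = (x[t] - m_t) / max(s_t, eps),   window = x[t-L_norm+1 .. t]

Because a z-score is invariant to any per-channel affine map ``x -> g*x + b``
with ``g > 0``, SWN cancels the static amplitude rescaling that an electrode
shift induces -- which is precisely why it confers shift robustness to a
classifier trained at a single electrode position, with no extra data.

Two forms are provided:

* :func:`normalize_stream` -- vectorized batch form emitting, per time step,
  the normalized value of the newest sample (one output per input sample once
  the window is full); this is the real-time filter the pipeline uses.
* :class:`SwnState` -- a true sample-by-sample streaming state (ring buffer +
  running sums) whose outputs match the batch form exactly.

:func:`normalize_window` exposes the full re-normalized window at one ``t``
for exactness tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["SwnConfig", "SwnState", "normalize_window", "normalize_stream"]


@dataclass(frozen=True)
class SwnConfig:
    """Normalization window length and numerics.

    ``window_ms`` is the sliding-window length L_norm in milliseconds
    (200-1000 ms in the standard sweep, any positive length allowed);
    ``eps`` is the variance floor below which the window is treated as
    constant and the output zeroed; ``warmup_policy`` governs the first
    ``L_norm - 1`` samples: ``"skip"`` drops them (the window statistic is
    only defined for a full window), ``"grow"`` uses the partial window
    (minimum two samples).
    """

    window_ms: float = 600.0
    fs: float = 500.0
    eps: float = 1e-8
    warmup_policy: str = "skip"

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.warmup_policy not in ("skip", "grow"):
            raise ValueError("warmup_policy must be 'skip' or 'grow'")
        l_norm = self.window_ms * self.fs / 1000.0
        if abs(l_norm - round(l_norm)) > 1e-9 or round(l_norm) < 2:
            raise ValueError("window_ms * fs / 1000 must be an integer >= 2")

    @property
    def l_norm(self) -> int:
        return int(round(self.window_ms * self.fs / 1000.0))


def normalize_window(x: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """z-score one full window with population (divide-by-N) SD.

    Returns all zeros when the window SD is at or below ``eps``.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("non-finite input")
    m = x.mean()
    s = x.std()  # population SD
    if s <= eps:
        return np.zeros_like(x)
    return (x - m) / s


class SwnState:
    """Streaming SWN state for one multi-channel signal.

    Keeps a ring buffer of the last ``L_norm`` samples per channel plus
    running sum and sum-of-squares.  To keep the running statistics equal to
    direct recomputation despite floating-point cancellation, the sums are
    refreshed from the ring buffer once per ``L_norm`` pushes and whenever the
    computed variance turns negative.
    """

    def __init__(self, n_channels: int, config: SwnConfig):
        self.config = config
        self.n_channels = n_channels
        self.l_norm = config.l_norm
        self.buffer = np.zeros((n_channels, self.l_norm))
        self.sum = np.zeros(n_channels)
        self.sumsq = np.zeros(n_channels)
        self.samples_seen = 0
        # per-channel reference subtracted from every stored sample: the
        # z-score is offset invariant, and centering near the signal level
        # prevents catastrophic cancellation in sumsq/n - mean**2 when the
        # signal rides on a large DC offset
        self.ref = np.zeros(n_channels)

    def _refresh(self, n: int) -> None:
        buf = self.buffer[:, :n] if n < self.l_norm else self.buffer
        self.sum = buf.sum(axis=1)
        self.sumsq = (buf**2).sum(axis=1)

    def push(self, sample: np.ndarray) -> np.ndarray | None:
        """Feed one sample per channel; return the normalized newest sample,
        or None while the warm-up policy withholds output."""
        sample = np.asarray(sample, dtype=np.float64)
        if sample.shape != (self.n_channels,):
            raise ValueError("sample must have shape (n_channels,)")
        if not np.isfinite(sample).all():
            bad = int(np.flatnonzero(~np.isfinite(sample))[0])
            raise ValueError(
                f"non-finite sample at channel {bad}, index {self.samples_seen}"
            )
        if self.samples_seen == 0:
            self.ref = sample.copy()
        sample = sample - self.ref
        idx = self.samples_seen % self.l_norm
        old = self.buffer[:, idx].copy()
        full = self.samples_seen >= self.l_norm
        self.buffer[:, idx] = sample
        if full:
            self.sum += sample - old
            self.sumsq += sample**2 - old**2
        else:
            self.sum += sample
            self.sumsq += sample**2
        self.samples_seen += 1
        n = min(self.samples_seen, self.l_norm)
        if idx == self.l_norm - 1:
            self._refresh(n)  # periodic exact refresh

        policy = self.config.warmup_policy
        if self.samples_seen < self.l_norm:
            if policy == "skip" or self.samples_seen < 2:
                return None
        m = self.sum / n
        var = self.sumsq / n - m**2
        if (var < 0).any():
            self._refresh(n)
            m = self.sum / n
            var = np.maximum(self.sumsq / n - m**2, 0.0)
        s = np.sqrt(np.maximum(var, 0.0))
        eps = self.config.eps
        out = np.where(s <= eps, 0.0, (sample - m) / np.where(s <= eps, 1.0, s))
        return out


def normalize_stream(
    signal: np.ndarray, config: SwnConfig
) -> tuple[np.ndarray, SwnState, int]:
    """Causally normalize a (channels x samples) signal.

    Per channel and per time ``t`` with a full trailing window, the newest
    sample is emitted as ``(x_t - m_t) / max(s_t, eps)`` (zero when
    ``s_t <= eps``).  Returns ``(normalized, state, offset)`` where ``offset``
    is the index of the first input sample that produced an output
    (``L_norm - 1`` under the ``skip`` policy, 1 under ``grow``), and
    ``state`` can continue the stream sample-by-sample.

    The computation is vectorized with cumulative sums; a final-pass guard
    clamps negative variances from cancellation to zero (flat windows are
    emitted as zeros via the eps floor).
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
        squeeze = True
    else:
        squeeze = False
    if x.ndim != 2:
        raise ValueError("signal must be (channels, samples)")
    if x.shape[1] < 1:
        raise ValueError("need at least one sample")
    if not np.isfinite(x).all():
        ch, ix = np.argwhere(~np.isfinite(x))[0]
        raise ValueError(f"non-finite sample at channel {ch}, index {ix}")

    l_norm = config.l_norm
    n = x.shape[1]
    # center each channel on its first sample: a z-score is offset invariant,
    # and working near zero keeps the cumulative sum of squares well
    # conditioned even when the signal rides on a large DC offset
    ref = x[:, :1].copy()
    x = x - ref
    cs = np.cumsum(x, axis=1)
    cs2 = np.cumsum(x * x, axis=1)

    def window_stats(t_idx: np.ndarray, length: np.ndarray):
        """Mean/SD of windows ending at t_idx (inclusive) of given lengths."""
        hi_s = cs[:, t_idx]
        hi_q = cs2[:, t_idx]
        lo = t_idx - length
        lo_s = np.where(lo >= 0, cs[:, np.maximum(lo, 0)], 0.0)
        lo_q = np.where(lo >= 0, cs2[:, np.maximum(lo, 0)], 0.0)
        m = (hi_s - lo_s) / length
        var = np.maximum((hi_q - lo_q) / length - m**2, 0.0)
        return m, np.sqrt(var)

    if config.warmup_policy == "skip":
        if n < l_norm:
            warnings.warn("signal shorter than the normalization window; empty output")
            out = np.zeros((x.shape[0], 0))
            offset = l_norm - 1
        else:
            t = np.arange(l_norm - 1, n)
            m, s = window_stats(t, np.full(t.size, l_norm))
            out = _emit(x[:, t], m, s, config.eps)
            offset = l_norm - 1
    else:  # grow
        if n < 2:
            warnings.warn("need at least two samples under the grow policy")
            out = np.zeros((x.shape[0], 0))
            offset = 1
        else:
            t = np.arange(1, n)
            length = np.minimum(t + 1, l_norm)
            m, s = window_stats(t, length)
            out = _emit(x[:, t], m, s, config.eps)
            offset = 1

    # rebuild the streaming state by replaying the tail into the ring buffer
    # (at most L_norm pushes, preserving the alignment a full replay would have)
    state = SwnState(x.shape[0], config)
    state.ref = ref[:, 0].copy()  # x is already centered on this reference
    tail = x[:, -min(n, l_norm):]
    state.samples_seen = n - tail.shape[1]
    for k in range(tail.shape[1]):
        state.buffer[:, state.samples_seen % l_norm] = tail[:, k]
        state.samples_seen += 1
    state._refresh(min(n, l_norm))
    return (out[0] if squeeze else out), state, offset


def _emit(newest: np.ndarray, m: np.ndarray, s: np.ndarray, eps: float) -> np.ndarray:
    return np.where(s <= eps, 0.0, (newest - m) / np.where(s <= eps, 1.0, s))
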