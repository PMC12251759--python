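"""Finite-difference gradient checking utilities (float64 only)."""

import numpy as np


def fd_gradient(loss_fn, x, eps=1e-6, idx=None):
    """Central finite-difference gradient of ``loss_fn`` at ``x``.

    ``idx``: optional iterable of flat indices to probe (all by default).
    Returns an array shaped like ``x`` with unprobed entries NaN.
    """
    x = np.asarray(x, dtype=np.float64)
    g = np.full(x.shape, np.nan)
    flat_x = x.reshape(-1)
    flat_g = g.reshape(-1)
    indices = range(flat_x.size) if idx is None else idx
    for i in indices:
        old = flat_x[i]
        flat_x[i] = old + eps
        lp = loss_fn(x)
        flat_x[i] = old - eps
        lm = loss_fn(x)
        flat_x[i] = old
        flat_g[i] = (lp - lm) / (2 * eps)
    return g


def assert_grad_close(analytic, numeric, rtol=1e-5, atol=1e-7):
    """Compare where the numeric gradient was probed (non-NaN)."""
    mask = ~np.isnan(numeric)
    a = np.asarray(analytic)[mask]
    n = numeric[mask]
    err = np.abs(a - n)
    tol = atol + rtol * np.abs(n)
    worst = (err - tol).max(initial=-np.inf)
    assert (err <= tol).all(), f"gradient mismatch, worst excess {worst:g}"


def probe_indices(size, n, seed=0):
    """Up to ``n`` deterministic flat indices into an array of ``size``."""
    if size <= n:
        return range(size)
    return np.random.default_rng(seed).choice(size, size=n, replace=False)
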