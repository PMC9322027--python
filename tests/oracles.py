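"""Independent brute-force integrators used as oracles in tests.

These deliberately avoid the package's eigendecomposition solver: classic
fixed-step fourth-order Runge-Kutta on dc/dt = M c, vectorized over a batch
of networks.
"""

from __future__ import annotations

import numpy as np


def rk4_batch(
    ms: np.ndarray, c0s: np.ndarray, sample_times: np.ndarray, dt: float = 1e-3
) -> np.ndarray:
    """Integrate a batch of linear systems; sample at multiples of dt.

    ms: (B, n, n) generators; c0s: (B, n) initial fractions;
    sample_times: 1-D, each (approximately) a multiple of dt.
    Returns (B, T, n).
    """
    sample_steps = np.rint(np.asarray(sample_times) / dt).astype(int)
    assert np.allclose(sample_steps * dt, sample_times, atol=dt * 1e-6)
    n_steps = int(sample_steps.max())
    want = {s: i for i, s in enumerate(sample_steps)}
    c = np.array(c0s, dtype=float)
    out = np.empty((c.shape[0], len(sample_times), c.shape[1]))
    if 0 in want:
        out[:, want[0], :] = c
    mm = np.asarray(ms)

    def f(x):
        return np.einsum("bij,bj->bi", mm, x)

    for step in range(1, n_steps + 1):
        k1 = f(c)
        k2 = f(c + 0.5 * dt * k1)
        k3 = f(c + 0.5 * dt * k2)
        k4 = f(c + dt * k3)
        c = c + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if step in want:
            out[:, want[step], :] = c
    return out


def rk4_single(
    m: np.ndarray, c0: np.ndarray, sample_times: np.ndarray, dt: float = 1e-3
) -> np.ndarray:
    return rk4_batch(m[None], np.asarray(c0, dtype=float)[None], sample_times, dt)[0]
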