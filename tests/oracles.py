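"""Independent reference implementations used only by the tests.

Everything here is deliberately written from first principles (direct
formulas, plain loops) and kept separate from the package code paths
it is used to check.
"""

from __future__ import annotations

import numpy as np


def kernel_direct(delta: float, tau: float, fs: float, duration: float) -> np.ndarray:
    """Gamma-like kernel sampled by direct evaluation, normalized by a
    long-horizon numeric sum (no closed forms)."""
    t = np.arange(int(round(duration * fs)) + 1) / fs
    s = np.maximum(t - delta, 0.0)
    h = s**2 * np.exp(-s / tau)
    th = np.arange(int(round((delta + 80 * tau) * fs)) + 1) / fs
    sh = np.maximum(th - delta, 0.0)
    total = float(np.sum(sh**2 * np.exp(-sh / tau))) / fs
    return h / total


def convolve_direct(kernel: np.ndarray, u: np.ndarray, fs: float) -> np.ndarray:
    """Brute-force discrete convolution of a sampled kernel (1/s units)
    with an input train; output truncated to the input length."""
    full = np.convolve(kernel / fs, u)
    return full[: len(u)]


def riccati_textbook(F, H, Qn, R, iters=200_000, tol=1e-14):
    """Predicted-covariance Riccati recursion, plain matrix formulas."""
    F = np.asarray(F, dtype=float)
    H = np.asarray(H, dtype=float).reshape(1, -1)
    P = np.eye(F.shape[0])
    for _ in range(iters):
        S = H @ P @ H.T + R
        P_new = F @ P @ F.T - F @ P @ H.T @ np.linalg.inv(S) @ H @ P @ F.T + Qn
        if np.max(np.abs(P_new - P)) < tol:
            P = P_new
            break
        P = P_new
    K = (P @ H.T @ np.linalg.inv(H @ P @ H.T + R)).reshape(-1)
    return P, K


def kalman_textbook(F, Gu, H, Du, Qn, R, y, u, P0):
    """Time-varying predict/update Kalman loop from the standard
    equations; returns (posterior states, innovations, outputs)."""
    F = np.asarray(F, dtype=float)
    Gu = np.asarray(Gu, dtype=float).reshape(-1)
    Hr = np.asarray(H, dtype=float).reshape(1, -1)
    n = len(y)
    dim = F.shape[0]
    x = np.zeros(dim)
    P = np.asarray(P0, dtype=float).copy()
    states = np.empty((n, dim))
    innov = np.empty(n)
    out = np.empty(n)
    for k in range(n):
        S = (Hr @ P @ Hr.T)[0, 0] + R
        K = (P @ Hr.T / S).reshape(-1)
        e = y[k] - (Hr @ x)[0] - Du * u[k]
        x = x + K * e
        P = P - np.outer(K, Hr @ P)
        states[k] = x
        innov[k] = e
        out[k] = (Hr @ x)[0] + Du * u[k]
        x = F @ x + Gu * u[k]
        P = F @ P @ F.T + Qn
    return states, innov, out


def ema_direct(x: np.ndarray, alpha: float) -> np.ndarray:
    """Causal exponential moving average by explicit recursion."""
    out = np.empty_like(np.asarray(x, dtype=float))
    out[0] = x[0]
    for k in range(1, len(x)):
        out[k] = alpha * x[k] + (1 - alpha) * out[k - 1]
    return out


def sine_probe_gain(filter_fn, freq: float, fs: float, n_cycles: int = 30):
    """Empirical steady-state amplitude gain of a causal filter at one
    frequency, by fitting a quadrature pair to the final cycles."""
    n = int(np.ceil(n_cycles * fs / freq))
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * freq * t)
    y = np.asarray(filter_fn(x))
    tail = slice(n // 2, n)
    design = np.column_stack([
        np.sin(2 * np.pi * freq * t[tail]),
        np.cos(2 * np.pi * freq * t[tail]),
    ])
    coef, *_ = np.linalg.lstsq(design, y[tail], rcond=None)
    return float(np.hypot(*coef))
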