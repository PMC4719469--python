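"""Causal filters for single-channel fNIRS series.

Four filters share one calling convention (raw series in, denoised
series out):

* the *nominal* Kalman filter — the state noise ``w`` enters at the
  stimulus input of the hemodynamic model (a zero-mean perception
  bias, ``b = w``);
* the *augmented* Kalman filter — the bias is a random walk
  (``b(k+1) = b(k) + w(k)``, the discrete form of ``db/dt = w``) and is
  estimated as an extra state, so it need not average to zero;
* the MACD filter (difference of two causal exponential moving
  averages), which needs no stimulus information;
* a Butterworth IIR bandpass (0.02–0.1 Hz by default).

Only the ratio Q/R of state-to-measurement noise variance is
identified by the steady-state gain, so R is fixed at 1 and Q carries
the ratio.  The gain is the fixed point of the discrete Riccati
recursion, making the Kalman filters time-invariant (they admit Bode
diagrams and run in O(1) memory per sample — usable in real time).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal as sps

from .hrf import StateSpaceModel

__all__ = [
    "KalmanSpec",
    "FilteredSignal",
    "MACDParams",
    "IIRParams",
    "build_kalman",
    "run_kalman",
    "macd_filter",
    "iir_bandpass",
    "frequency_response",
]

Structure = Literal["nominal", "augmented"]

#: iteration cap / tolerance for the Riccati fixed point
_RICCATI_TOL = 1e-12
_RICCATI_MAXITER = 1_000_000


@dataclass(frozen=True)
class KalmanSpec:
    """A fully solved steady-state Kalman filter.

    ``F, Gu, H, Du`` are the (possibly bias-augmented) dynamics;
    ``gain`` is the steady-state predicted-state gain K and
    ``covariance`` the prior error covariance P⁻ solving the Riccati
    fixed point.  ``posterior_covariance`` is (I − KH) P⁻.
    """

    model: StateSpaceModel
    structure: Structure
    qr_ratio: float
    Q: float
    R: float
    F: np.ndarray
    Gu: np.ndarray
    H: np.ndarray
    Du: float
    noise_input: np.ndarray
    gain: np.ndarray
    covariance: np.ndarray
    iterations: int

    @property
    def state_dim(self) -> int:
        return self.F.shape[0]

    @property
    def posterior_covariance(self) -> np.ndarray:
        KH = np.outer(self.gain, self.H)
        return (np.eye(self.state_dim) - KH) @ self.covariance


@dataclass(frozen=True)
class FilteredSignal:
    """Kalman filter output trajectories (all causal, input-length)."""

    denoised: np.ndarray
    state_trajectory: np.ndarray
    innovations: np.ndarray
    bias_estimate: np.ndarray | None = None


def riccati_fixed_point(
    F: np.ndarray,
    H: np.ndarray,
    Qn: np.ndarray,
    R: float,
    tol: float = _RICCATI_TOL,
    maxiter: int = _RICCATI_MAXITER,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterate P <- F (P - K H P) F' + Qn to convergence.

    Returns (P_prior, K, iterations).  Raises if the recursion does
    not settle within ``maxiter`` iterations.
    """
    n = F.shape[0]
    P = Qn + np.eye(n)
    for it in range(1, maxiter + 1):
        S = float(H @ P @ H) + R
        K = (P @ H) / S
        P_next = F @ (P - np.outer(K, H @ P)) @ F.T + Qn
        P_next = 0.5 * (P_next + P_next.T)
        if np.max(np.abs(P_next - P)) < tol * (1.0 + np.max(np.abs(P_next))):
            S = float(H @ P_next @ H) + R
            return P_next, (P_next @ H) / S, it
        P = P_next
    raise RuntimeError("Riccati iteration did not converge")


def build_kalman(
    model: StateSpaceModel,
    structure: Structure,
    qr_ratio: float,
) -> KalmanSpec:
    """Design a steady-state Kalman filter on the hemodynamic model.

    Nominal:   x(k+1) = A x(k) + B (u(k) + w(k)),     y = C x + D u + v
    Augmented: x(k+1) = A x(k) + B (u(k) + b(k)),     y = C x + D u + v
               b(k+1) = b(k) + w(k)

    with Var[w] = Q = qr_ratio, Var[v] = R = 1 (only the ratio matters
    for the gain).
    """
    if not qr_ratio > 0:
        raise ValueError(f"qr_ratio must be positive, got {qr_ratio}")
    if structure not in ("nominal", "augmented"):
        raise ValueError(f"unknown Kalman structure {structure!r}")
    Q, R = float(qr_ratio), 1.0
    A = model.A
    B = model.B.reshape(-1)
    C = model.C.reshape(-1)
    n = A.shape[0]
    if structure == "nominal":
        F = A.copy()
        Gu = B.copy()
        H = C.copy()
        noise_input = B.copy()
    else:
        F = np.zeros((n + 1, n + 1))
        F[:n, :n] = A
        F[:n, n] = B
        F[n, n] = 1.0
        Gu = np.concatenate([B, [0.0]])
        H = np.concatenate([C, [model.D]])
        noise_input = np.zeros(n + 1)
        noise_input[n] = 1.0
    Qn = Q * np.outer(noise_input, noise_input)
    try:
        P, K, it = riccati_fixed_point(F, H, Qn, R)
    except RuntimeError as exc:
        raise RuntimeError(
            f"Riccati iteration failed for structure={structure!r}, "
            f"qr_ratio={qr_ratio:g}"
        ) from exc
    return KalmanSpec(
        model=model, structure=structure, qr_ratio=qr_ratio, Q=Q, R=R,
        F=F, Gu=Gu, H=H, Du=model.D, noise_input=noise_input,
        gain=K, covariance=P, iterations=it,
    )


def run_kalman(
    spec: KalmanSpec,
    signal: np.ndarray,
    stimulus: np.ndarray,
) -> FilteredSignal:
    """Filter a raw series (or a (n, channels) matrix) causally.

    ``stimulus`` must already be shifted by the model's
    ``delay_samples`` (see :func:`kalnirs.hrf.shift_stimulus`); the
    steady-state gain is channel-independent, so a matrix of channels
    sharing one stimulus train is filtered in a single pass.
    """
    y = np.asarray(signal, dtype=float)
    u = np.asarray(stimulus, dtype=float)
    if u.ndim != 1 or y.shape[0] != u.shape[0]:
        raise ValueError(
            f"signal (len {y.shape[0]}) and stimulus (len {u.shape[0]}) "
            "must have the same length"
        )
    one_d = y.ndim == 1
    Y = y[:, None] if one_d else y
    n, m = Y.shape
    dim = spec.state_dim
    F, Gu, H, Du, K = spec.F, spec.Gu, spec.H, spec.Du, spec.gain

    x_prior = np.zeros((dim, m))
    states = np.empty((n, dim, m))
    denoised = np.empty((n, m))
    innov = np.empty((n, m))
    for k in range(n):
        y_pred = H @ x_prior + Du * u[k]
        e = Y[k] - y_pred
        x_post = x_prior + np.outer(K, e)
        states[k] = x_post
        denoised[k] = H @ x_post + Du * u[k]
        innov[k] = e
        x_prior = F @ x_post + Gu[:, None] * u[k]

    bias = states[:, -1, :] if spec.structure == "augmented" else None
    if one_d:
        denoised, innov, states = denoised[:, 0], innov[:, 0], states[:, :, 0]
        bias = None if bias is None else bias[:, 0]
    return FilteredSignal(
        denoised=denoised, state_trajectory=states,
        innovations=innov, bias_estimate=bias,
    )


def implied_input_bias(spec: KalmanSpec, filtered: FilteredSignal) -> float:
    """Time-averaged estimate of the stimulus-perception bias.

    For the augmented structure this is the mean of the estimated bias
    state over the final half of the record.  The nominal structure
    carries no bias state; its per-sample minimum-variance estimate of
    w(k) given the next innovation, E[w|e] = Q (C B) e / (H P H' + R),
    is averaged instead — the zero-mean prior shrinks it, which is
    precisely why a sustained bias defeats the nominal filter.
    """
    n = len(filtered.innovations)
    tail = slice(n // 2, n)
    if spec.structure == "augmented":
        assert filtered.bias_estimate is not None
        return float(np.mean(filtered.bias_estimate[tail]))
    S = float(spec.H @ spec.covariance @ spec.H) + spec.R
    cb = float(spec.H @ spec.model.B.reshape(-1))
    w_hat = spec.Q * cb / S * filtered.innovations
    return float(np.mean(w_hat[tail]))


@dataclass(frozen=True)
class MACDParams:
    """Moving-average convergence/divergence filter settings."""

    short_span: float = 4.0   # seconds
    long_span: float = 40.0   # seconds
    fs: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.short_span < self.long_span:
            raise ValueError(
                f"need 0 < short_span < long_span, got "
                f"{self.short_span}, {self.long_span}"
            )

    def alphas(self) -> tuple[float, float]:
        a_s = 2.0 / (self.short_span * self.fs + 1.0)
        a_l = 2.0 / (self.long_span * self.fs + 1.0)
        return a_s, a_l


def _ema(x: np.ndarray, alpha: float) -> np.ndarray:
    # causal EMA seeded at the first sample so a constant maps to itself
    b, a = [alpha], [1.0, alpha - 1.0]
    zi = np.atleast_1d(sps.lfilter_zi(b, a))
    if x.ndim == 1:
        out, _ = sps.lfilter(b, a, x, zi=zi * x[0])
        return out
    out, _ = sps.lfilter(b, a, x, axis=0, zi=zi[:, None] * x[0][None, :])
    return out


def macd_filter(
    signal: np.ndarray,
    short_span: float = 4.0,
    long_span: float = 40.0,
    fs: float = 2.0,
) -> np.ndarray:
    """Short-EMA minus long-EMA, both causal; spans in seconds."""
    p = MACDParams(short_span, long_span, fs)
    x = np.asarray(signal, dtype=float)
    a_s, a_l = p.alphas()
    return _ema(x, a_s) - _ema(x, a_l)


@dataclass(frozen=True)
class IIRParams:
    """Butterworth bandpass settings (band edges in Hz)."""

    low: float = 0.02
    high: float = 0.1
    fs: float = 2.0
    order: int = 3
    zero_phase: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high < self.fs / 2:
            raise ValueError(
                f"band edges must satisfy 0 < low < high < fs/2, got "
                f"low={self.low}, high={self.high}, fs={self.fs}"
            )

    def sos(self) -> np.ndarray:
        return sps.butter(
            self.order, [self.low, self.high], btype="bandpass",
            fs=self.fs, output="sos",
        )


def iir_bandpass(
    signal: np.ndarray,
    low: float = 0.02,
    high: float = 0.1,
    fs: float = 2.0,
    order: int = 3,
    zero_phase: bool = False,
) -> np.ndarray:
    """Butterworth bandpass; causal by default, zero-phase on request."""
    p = IIRParams(low, high, fs, order, zero_phase)
    x = np.asarray(signal, dtype=float)
    sos = p.sos()
    if zero_phase:
        return sps.sosfiltfilt(sos, x, axis=0)
    return sps.sosfilt(sos, x, axis=0)


def _kalman_measurement_ss(spec: KalmanSpec):
    """LTI map from measurement y to denoised output (stimulus = 0)."""
    K, H, F = spec.gain, spec.H, spec.F
    IKH = np.eye(spec.state_dim) - np.outer(K, H)
    Ac = F @ IKH
    Bc = F @ K
    Cc = H @ IKH
    Dc = float(H @ K)
    return Ac, Bc, Cc, Dc


def frequency_response(
    filt: KalmanSpec | MACDParams | IIRParams,
    freqs: np.ndarray,
    fs: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude (dB) and phase (degrees) at the given frequencies (Hz).

    For a Kalman filter this is the transfer from the measurement to
    the denoised output at the steady-state gain (stimulus held at 0);
    for MACD and IIR it is the ordinary filter transfer function.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if fs is None:
        fs = filt.fs if not isinstance(filt, KalmanSpec) else filt.model.fs
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise ValueError("frequencies must lie strictly inside (0, fs/2)")
    z = np.exp(2j * np.pi * freqs / fs)
    if isinstance(filt, KalmanSpec):
        Ac, Bc, Cc, Dc = _kalman_measurement_ss(filt)
        resp = np.array([
            Cc @ np.linalg.solve(zi * np.eye(Ac.shape[0]) - Ac, Bc) + Dc
            for zi in z
        ])
    elif isinstance(filt, MACDParams):
        a_s, a_l = filt.alphas()
        ema = lambda a: a * z / (z - (1.0 - a))  # noqa: E731
        resp = ema(a_s) - ema(a_l)
    elif isinstance(filt, IIRParams):
        _, resp = sps.sosfreqz(filt.sos(), worN=freqs, fs=fs)
        if filt.zero_phase:
            resp = np.abs(resp) ** 2
    else:
        raise TypeError(f"unsupported filter object {type(filt).__name__}")
    with np.errstate(divide="ignore"):
        mag_db = 20.0 * np.log10(np.abs(resp))
    phase_deg = np.degrees(np.angle(resp))
    return mag_db, phase_deg
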