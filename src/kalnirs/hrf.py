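"""Hemodynamic response model and its discrete state-space realization.

The canonical impulse response used throughout the package is the
third-order gamma-like kernel

    h(t) = C * (t - delta)^2 * exp(-(t - delta) / tau)   for t >= delta,
    h(t) = 0                                             otherwise,

i.e. a triple real pole at -1/tau preceded by a pure transport delay
``delta``.  Its peak sits at t = delta + 2*tau (about 5 s for the
typical delta = 2 s, tau = 1.5 s), matching the time-to-peak reported
for prefrontal HbO2 responses.  The gain ``C`` is fixed by a unit-DC
convention: the kernel samples at the recording rate sum to ``fs``, so
that discrete convolution with a sustained unit stimulus settles at 1.
This makes response amplitudes directly comparable across (delta, tau)
and across sampling rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "HRFParameters",
    "StateSpaceModel",
    "hrf_kernel",
    "discretize_hrf",
    "convolve_stimulus",
    "shift_stimulus",
]


@dataclass(frozen=True)
class HRFParameters:
    """Continuous-time response parameters.

    Parameters
    ----------
    delta : float
        Pure onset delay between stimulation and the start of the
        hemodynamic rise, in seconds.  Must be >= 0.
    tau : float
        Time constant shaping the time-to-peak (peak at delta + 2*tau),
        in seconds.  Must be > 0.
    fs : float
        Sampling frequency of the recording, in Hz.  Must be > 0.
    """

    delta: float = 2.0
    tau: float = 1.5
    fs: float = 2.0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")

    @property
    def delay_samples(self) -> int:
        """Pure delay rounded to whole samples (non-negative)."""
        return int(round(self.delta * self.fs))

    @property
    def peak_time(self) -> float:
        """Analytic time of the kernel maximum, delta + 2*tau (s)."""
        return self.delta + 2.0 * self.tau


def _discrete_kernel_sum(params: HRFParameters) -> tuple[float, float, int]:
    """Closed-form infinite sum of the raw kernel over the sample grid.

    Returns (S, u0, k0) where S = sum_{k >= k0} (t_k-delta)^2
    exp(-(t_k-delta)/tau) over the grid t_k = k/fs, k0 is the first
    sample index with t_k >= delta and u0 = t_{k0} - delta.
    """
    T = 1.0 / params.fs
    k0 = int(np.ceil(params.delta * params.fs - 1e-12))
    u0 = k0 * T - params.delta
    a = np.exp(-T / params.tau)
    s0 = 1.0 / (1.0 - a)
    s1 = a / (1.0 - a) ** 2
    s2 = a * (1.0 + a) / (1.0 - a) ** 3
    S = np.exp(-u0 / params.tau) * (u0 * u0 * s0 + 2.0 * u0 * T * s1 + T * T * s2)
    return float(S), float(u0), k0


def hrf_kernel(params: HRFParameters, duration: float) -> np.ndarray:
    """Sample the hemodynamic impulse-response kernel.

    Parameters
    ----------
    params : HRFParameters
    duration : float
        Length of the returned kernel, in seconds.  Must be at least
        ``delta + 10*tau`` so that >= 99.9% of the kernel mass is
        contained.

    Returns
    -------
    ndarray
        ``h(t_k)`` for ``t_k = k / fs`` up to ``duration``, in 1/s
        units, normalized so that ``sum(h) / fs == 1`` over the full
        (infinite) grid.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    min_dur = params.delta + 10.0 * params.tau
    if duration < min_dur:
        raise ValueError(
            f"duration {duration} s truncates the kernel; need >= "
            f"delta + 10*tau = {min_dur} s to capture the peak and tail"
        )
    n = int(round(duration * params.fs)) + 1
    t = np.arange(n) / params.fs
    s = np.clip(t - params.delta, 0.0, None)
    raw = s * s * np.exp(-s / params.tau)
    S, _, _ = _discrete_kernel_sum(params)
    return raw * (params.fs / S)


@dataclass(frozen=True)
class StateSpaceModel:
    """Discrete LTI realization of the HRF at the recording rate.

    The pure delay is kept outside the dynamics: the 3-state core
    (A, B, C, D) realizes the delay-free kernel exactly on the sample
    grid, and ``delay_samples`` records the input lag applied to the
    (known) stimulus before it enters the core.  ``num``/``den`` hold
    the equivalent transfer-function coefficients for fast filtering.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: float
    num: np.ndarray
    den: np.ndarray
    delay_samples: int
    fs: float
    params: HRFParameters = field(repr=False)

    @property
    def state_dim(self) -> int:
        return self.A.shape[0]

    def impulse_response(self, n: int) -> np.ndarray:
        """First ``n`` samples of the full (delay included) response."""
        imp = np.zeros(n)
        if self.delay_samples < n:
            imp[self.delay_samples] = 1.0
        return sps.lfilter(self.num, self.den, imp)

    def dc_gain(self) -> float:
        return float(np.sum(self.num) / np.sum(self.den))


def discretize_hrf(params: HRFParameters) -> StateSpaceModel:
    """Build the exact 3-state discrete realization of the kernel.

    The delay-free core's impulse response reproduces
    ``hrf_kernel(params, ...) / fs`` sample-for-sample (the 1/fs makes
    discrete convolution approximate continuous convolution), which in
    turn gives the core unit DC gain.  A sub-sample residual of the
    pure delay (when ``delta*fs`` is not an integer) is folded into the
    core analytically rather than rounded away.
    """
    T = 1.0 / params.fs
    tau = params.tau
    ds = params.delay_samples
    # residual offset between the rounded delay and the true delay
    o = ds * T - params.delta
    a = np.exp(-T / tau)
    S, _, _ = _discrete_kernel_sum(params)

    # Desired core impulse response, for k >= 0 with k*T + o >= 0:
    #   d[k] = (1/S) * (k*T + o)^2 * exp(-(k*T + o)/tau)
    #        = c * (T^2 k^2 + 2 T o k + o^2) * a^k,   c = exp(-o/tau)/S
    # z-transforms: {a^k} -> z/(z-a), {k a^k} -> a z/(z-a)^2,
    # {k^2 a^k} -> a z (z+a)/(z-a)^3, all over den = (z-a)^3.
    c = np.exp(-o / tau) / S
    den = np.polynomial.polynomial.polyfromroots([a, a, a])[::-1]  # (z-a)^3
    num_k2 = a * np.array([0.0, 1.0, a, 0.0])            # a z (z+a)
    num_k1 = a * np.polymul([1.0, -a], [1.0, 0.0])       # a z (z-a)
    num_k1 = np.concatenate([[0.0], num_k1])
    num_k0 = np.polymul(np.polymul([1.0, -a], [1.0, -a]), [1.0, 0.0])  # z(z-a)^2
    num = c * (T * T * num_k2 + 2.0 * T * o * num_k1 + (o * o) * num_k0)
    if o < 0:
        # sample k=0 falls before the kernel onset: zero it out by
        # removing the constant feedthrough it would contribute
        num = num - (c * o * o) * den
    # enforce exact unit DC gain against closed-form-sum roundoff
    num = num * (np.sum(den) / np.sum(num))

    import warnings

    with warnings.catch_warnings():
        # integer delays give a strictly proper tf (leading num coeff 0)
        warnings.simplefilter("ignore", sps.BadCoefficients)
        A, B, C, D = sps.tf2ss(num, den)
    eig = np.abs(np.linalg.eigvals(A))
    if np.any(eig >= 1.0):
        raise ValueError(f"unstable realization (|eig| up to {eig.max()})")
    return StateSpaceModel(
        A=A, B=B, C=C, D=float(np.atleast_2d(D)[0, 0]),
        num=num, den=den, delay_samples=ds, fs=params.fs, params=params,
    )


def shift_stimulus(stimulus: np.ndarray, delay_samples: int) -> np.ndarray:
    """Delay a stimulus train by a whole number of samples (causal)."""
    stimulus = np.asarray(stimulus, dtype=float)
    if delay_samples == 0:
        return stimulus.copy()
    out = np.zeros_like(stimulus)
    out[delay_samples:] = stimulus[:-delay_samples]
    return out


def convolve_stimulus(model: StateSpaceModel, stimulus: np.ndarray) -> np.ndarray:
    """Noise-free model response to a sampled stimulus train.

    Applies the pure delay then the 3-state core; output has the same
    length as the input and is causal and linear.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    if stimulus.ndim != 1 or stimulus.size == 0:
        raise ValueError("stimulus must be a non-empty 1-D sequence")
    u = shift_stimulus(stimulus, model.delay_samples)
    return sps.lfilter(model.num, model.den, u)
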