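"""Convenience glue: apply a named filter to a whole recording."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .filters import build_kalman, iir_bandpass, macd_filter, run_kalman
from .hrf import HRFParameters, discretize_hrf, shift_stimulus
from .io import Recording
from .simulate import stimulus_train

__all__ = ["FILTER_KINDS", "filter_recording"]

FILTER_KINDS = ("kalman_nominal", "kalman_augmented", "macd", "iir", "none")


def filter_recording(
    recording: Recording,
    events: pd.DataFrame | None,
    kind: str,
    qr_ratio: float = 0.5,
    macd_short_s: float = 4.0,
    macd_long_s: float = 40.0,
    iir_low_hz: float = 0.02,
    iir_high_hz: float = 0.1,
    iir_order: int = 3,
    iir_zero_phase: bool = False,
    hrf: HRFParameters | None = None,
    chromophores: tuple[str, ...] = ("HbO2", "HHb"),
    stimulus_encoding: str = "boxcar",
) -> Recording:
    """Denoise every channel of the given chromophores with one filter.

    Kalman kinds require the events table (the stimulus train is built
    from it and delay-shifted); MACD and IIR ignore it.
    """
    if kind == "none":
        return recording
    if kind not in FILTER_KINDS:
        raise ValueError(f"unknown filter kind {kind!r}; choose from {FILTER_KINDS}")
    out = recording
    if kind.startswith("kalman"):
        if events is None:
            raise ValueError("Kalman filtering requires an events table")
        if hrf is None:
            hrf = HRFParameters(fs=recording.fs)
        model = discretize_hrf(hrf)
        spec = build_kalman(model, kind.removeprefix("kalman_"), qr_ratio)
        u = shift_stimulus(
            stimulus_train(events, recording.n_samples, recording.fs,
                           encoding=stimulus_encoding),
            model.delay_samples,
        )
        for which in chromophores:
            mat = out.chromophore(which)
            sign = 1.0
            if which == "HHb":
                # the model kernel is positive-going; HHb deflects the
                # other way, so filter the sign-flipped series
                sign = -1.0
            res = run_kalman(spec, sign * mat, u)
            out = out.with_channels(sign * res.denoised, which)
        return out
    for which in chromophores:
        mat = out.chromophore(which)
        if kind == "macd":
            den = macd_filter(mat, macd_short_s, macd_long_s, recording.fs)
        else:
            den = iir_bandpass(
                mat, iir_low_hz, iir_high_hz, recording.fs,
                iir_order, iir_zero_phase,
            )
        out = out.with_channels(np.asarray(den), which)
    return out
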