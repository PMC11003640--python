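"""Denoising and baseline-wander removal.

Two operators run before fiducial detection:

* cascaded median filters (200 ms then 600 ms) estimate the baseline
  wander, which is subtracted — this keeps the waveform itself
  un-differentiated so QRS widths can still be measured afterwards;
* an adaptive line enhancer (LMS filter predicting the signal from a
  delayed copy of itself) cancels narrowband interference such as 50/60
  Hz powerline pickup while leaving the broadband ECG in the error
  signal, which is the output.

The 5-point derivative used inside the Pan-Tompkins detector also lives
here; it doubles as a crude high-pass (it annihilates constants, hence
slow drift) and recovers slope on ramps.

The LMS update defaults to a power-normalized form
``w <- w + mu * e(n) * u(n) / (order * mean(x^2))``: dividing the step
by the average reference power makes the whole preprocessing chain
exactly equivariant to amplitude scaling (time-based features
downstream must not depend on signal gain) and makes one step size work
across signal powers.  The textbook un-normalized update is available
with ``normalized_lms=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .errors import LengthError, NumericError, ParameterError

__all__ = ["FilterParams", "five_point_derivative", "remove_baseline", "lms_denoise", "preprocess_signal"]


@dataclass(frozen=True)
class FilterParams:
    """Tunable preprocessing constants.

    ``lms_delay`` defaults to fs/10 samples (set at call time when None):
    long enough to decorrelate the broadband ECG between primary and
    reference, short enough that periodic interference stays coherent.
    """

    deriv_gain: float = 1.0
    lms_order: int = 16
    lms_step: float = 0.01
    lms_delay: int | None = None
    baseline_med1_ms: float = 200.0
    baseline_med2_ms: float = 800.0
    normalized_lms: bool = True

    def __post_init__(self) -> None:
        if self.lms_step <= 0:
            raise ParameterError("lms_step must be > 0")
        if self.baseline_med1_ms <= 0 or self.baseline_med2_ms <= 0:
            raise ParameterError("median windows must be positive")
        if self.baseline_med2_ms <= self.baseline_med1_ms:
            raise ParameterError("baseline_med2_ms must exceed baseline_med1_ms")
        if self.lms_order < 1:
            raise ParameterError("lms_order must be >= 1")


def five_point_derivative(x: np.ndarray, fs: float | None = None) -> np.ndarray:
    """Five-point derivative, y(n) = (1/8)(-x[n-2] - 2x[n-1] + 2x[n+1] + x[n+2]).

    Output has the input's length; the two edge samples at each end are
    zero-padded.  Annihilates constants and maps a unit-slope ramp to 1
    on interior samples.  ``fs`` is accepted for interface symmetry; the
    kernel is expressed per sample.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise LengthError(f"need at least 5 samples, got {x.size}")
    y = np.zeros_like(x)
    y[2:-2] = (-x[:-4] - 2 * x[1:-3] + 2 * x[3:-1] + x[4:]) / 8.0
    return y


def _odd_window(ms: float, fs: float) -> int:
    w = int(round(ms / 1000.0 * fs))
    return max(w + (w % 2 == 0), 3)


def remove_baseline(
    x: np.ndarray, fs: float, params: FilterParams | None = None
) -> np.ndarray:
    """Subtract the cascaded-median-filter baseline estimate.

    The baseline is ``median(median(x, w1), w2)`` with w1/w2 from
    ``params``; median widths must be shorter than the signal.  Reflect
    padding at the edges.  The defaults (200/800 ms) kill the QRS in the
    first stage and the P/T footprint in the second: the second window
    must exceed roughly twice the beat's active span, or the T wave
    bleeds into the baseline estimate.
    """
    params = params or FilterParams()
    x = np.asarray(x, dtype=float)
    w1 = _odd_window(params.baseline_med1_ms, fs)
    w2 = _odd_window(params.baseline_med2_ms, fs)
    if max(w1, w2) >= x.size:
        raise ParameterError(
            f"median window ({max(w1, w2)} samples) must be shorter than the signal ({x.size})"
        )
    baseline = median_filter(x, size=w1, mode="reflect")
    baseline = median_filter(baseline, size=w2, mode="reflect")
    return x - baseline


def lms_denoise(
    x: np.ndarray, fs: float, params: FilterParams | None = None
) -> np.ndarray:
    """Adaptive line enhancer: cancel periodic interference, keep the ECG.

    The primary input is ``x``; the reference is ``x`` delayed by
    ``lms_delay`` samples.  An ``lms_order``-tap filter predicts the
    delay-coherent (periodic) part; the returned error signal is the
    input minus that prediction.  With ``mu = 0`` (or zero taps and no
    adaptation) the output equals the input.

    Raises :class:`NumericError` if the output norm exceeds 1e3 x the
    input norm (divergence; lower ``lms_step``).
    """
    params = params or FilterParams()
    x = np.asarray(x, dtype=float)
    order = params.lms_order
    if order >= x.size:
        raise ParameterError(f"lms_order {order} must be < signal length {x.size}")
    delay = params.lms_delay if params.lms_delay is not None else max(int(round(fs / 10)), 1)
    mu = params.lms_step
    out = _ale(x, order, delay, mu, params.normalized_lms)
    norm_in = float(np.linalg.norm(x))
    norm_out = float(np.linalg.norm(out))
    if norm_in > 0 and (not np.isfinite(norm_out) or norm_out > 1e3 * norm_in):
        raise NumericError(
            "LMS filter diverged (output norm > 1e3 x input norm); use a smaller lms_step"
        )
    return out


def _ale_py(x, order, delay, mu, normalized):
    n = x.size
    w = np.zeros(order)
    e = x.copy()
    if normalized:
        # normalize the step by the average reference power (not the
        # instantaneous window norm, which explodes when a large sample
        # follows a quiet stretch); keeps the update scale-equivariant
        power = 0.0
        for i in range(n):
            power += x[i] * x[i]
        power /= n
        denom = order * power + 1e-12
    else:
        denom = 1.0
    step = mu / denom
    for i in range(delay + order - 1, n):
        u = x[i - delay - order + 1 : i - delay + 1][::-1]
        yhat = 0.0
        for k in range(order):
            yhat += w[k] * u[k]
        err = x[i] - yhat
        e[i] = err
        for k in range(order):
            w[k] = w[k] + step * err * u[k]
    return e


try:  # pragma: no cover - thin wrapper, exercised via lms_denoise
    from numba import njit

    _ale = njit(cache=True)(_ale_py)
except Exception:  # numba optional; pure-python fallback
    _ale = _ale_py


def preprocess_signal(
    x: np.ndarray, fs: float, params: FilterParams | None = None
) -> np.ndarray:
    """Full chain: baseline removal then adaptive denoising.

    Equal to composing :func:`remove_baseline` and :func:`lms_denoise`
    (no hidden state); length and sampling rate are preserved.
    """
    params = params or FilterParams()
    return lms_denoise(remove_baseline(x, fs, params), fs, params)
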