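"""R-peak detection (Pan-Tompkins) and QRS boundary/RR measurement.

The detector follows the canonical Pan-Tompkins pipeline: band-pass
(5-15 Hz) -> 5-point derivative -> pointwise squaring -> moving-window
integration (150 ms) -> adaptive dual thresholds with a 200 ms
refractory period, T-wave rejection by slope comparison inside a 360 ms
window, and a search-back pass at 1.66x the running RR estimate when a
beat appears to be missed.  Every accepted detection is finally
relocated to the local maximum of ``|x|`` within +/-75 ms, so the
returned indices sit on the R wave of the *input* signal regardless of
filter group delay (the band-pass is applied zero-phase anyway) or lead
polarity.

QRS boundaries use an energy envelope (short moving-window integral of
the squared signal): the onset is the last sample before the peak, and
the offset the first sample after it, where the envelope drops below
10 % of the beat's envelope maximum; the searches are bounded at 100 ms
before and 160 ms after the peak, which also keeps P and T waves out of
the measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import DetectionError, ParameterError
from .preprocess import five_point_derivative

__all__ = [
    "PtParams",
    "FiducialSet",
    "pan_tompkins_rpeaks",
    "qrs_boundaries",
    "rr_intervals",
    "detect_fiducials",
]


@dataclass(frozen=True)
class PtParams:
    """Detector constants (canonical Pan-Tompkins values)."""

    bp_low_hz: float = 5.0
    bp_high_hz: float = 15.0
    mwi_ms: float = 150.0
    refractory_ms: float = 200.0
    twave_window_ms: float = 360.0
    searchback_factor: float = 1.66
    update_fast: float = 0.125  # weight of the new peak in threshold updates
    update_slow: float = 0.875
    relocate_ms: float = 75.0
    boundary_mwi_ms: float = 40.0
    boundary_frac: float = 0.10
    onset_search_ms: float = 100.0
    offset_search_ms: float = 160.0

    def validate(self, fs: float) -> None:
        if not 0 < self.bp_low_hz < self.bp_high_hz < fs / 2:
            raise ParameterError(
                f"need 0 < bp_low < bp_high < fs/2; got ({self.bp_low_hz}, {self.bp_high_hz}) at fs={fs}"
            )
        if self.mwi_ms <= 0:
            raise ParameterError("mwi_ms must be positive")


@dataclass
class FiducialSet:
    """Aligned fiducials for one lead: R peaks and QRS boundaries."""

    r_peaks: np.ndarray  # sample indices, strictly increasing
    qrs_onsets: np.ndarray
    qrs_offsets: np.ndarray
    fs: float
    edge_flags: np.ndarray | None = None  # True where a boundary was clamped

    def __post_init__(self) -> None:
        self.r_peaks = np.asarray(self.r_peaks, dtype=int)
        self.qrs_onsets = np.asarray(self.qrs_onsets, dtype=int)
        self.qrs_offsets = np.asarray(self.qrs_offsets, dtype=int)
        if np.any(np.diff(self.r_peaks) <= 0):
            raise ParameterError("r_peaks must be strictly increasing")

    @property
    def qrs_durations_ms(self) -> np.ndarray:
        """Per-beat QRS duration in milliseconds."""
        return (self.qrs_offsets - self.qrs_onsets) / self.fs * 1000.0

    @property
    def rr_s(self) -> np.ndarray:
        """RR intervals in seconds (length = n_peaks - 1)."""
        return rr_intervals(self.r_peaks, self.fs)


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    b, a = butter(2, [lo, hi], btype="bandpass", fs=fs)
    return filtfilt(b, a, x)


def _mwi(x: np.ndarray, width: int) -> np.ndarray:
    width = max(width, 1)
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def pan_tompkins_rpeaks(
    x: np.ndarray, fs: float, params: PtParams | None = None
) -> np.ndarray:
    """Detect R-peak sample indices in a (preprocessed) single-lead signal.

    Requires at least 2 s of signal.  Raises :class:`DetectionError` on a
    flat (zero-variance) signal or when no peak survives thresholding.
    """
    params = params or PtParams()
    params.validate(fs)
    x = np.asarray(x, dtype=float)
    if x.size / fs < 2.0:
        raise ParameterError("need at least 2 s of signal")
    if np.ptp(x) == 0:
        raise DetectionError("no peaks found: flat signal")

    bp = _bandpass(x, fs, params.bp_low_hz, params.bp_high_hz)
    der = five_point_derivative(bp, fs)
    sq = der**2
    mwi = _mwi(sq, int(round(params.mwi_ms / 1000 * fs)))

    refractory = int(round(params.refractory_ms / 1000 * fs))
    # candidate peaks: local maxima of the integrated energy
    from scipy.signal import find_peaks

    cand, _ = find_peaks(mwi, distance=max(refractory, 1))
    if cand.size == 0:
        raise DetectionError("no peaks found")

    # threshold state, initialized from the first two seconds
    head = mwi[: int(2 * fs)]
    spki = 0.25 * float(np.max(head))
    npki = 0.5 * float(np.mean(head))
    f, s = params.update_fast, params.update_slow

    accepted: list[int] = []
    slopes: list[float] = []
    rr_buf: list[float] = []
    twin = params.twave_window_ms / 1000 * fs

    def local_slope(i: int) -> float:
        lo = max(i - int(0.075 * fs), 0)
        hi = min(i + int(0.075 * fs) + 1, der.size)
        return float(np.max(np.abs(der[lo:hi])))

    def rr_mean() -> float:
        return float(np.mean(rr_buf[-8:])) if rr_buf else 0.0

    def accept(i: int, peak_val: float, searchback: bool) -> None:
        nonlocal spki
        if accepted:
            rr_buf.append(i - accepted[-1])
        accepted.append(i)
        slopes.append(local_slope(i))
        w = 0.25 if searchback else f
        spki = w * peak_val + (1 - w) * spki

    for i in cand:
        thr = npki + 0.25 * (spki - npki)
        pv = float(mwi[i])
        if accepted and i - accepted[-1] < refractory:
            continue
        if pv > thr:
            # T-wave test: close to the previous beat and much shallower slope
            if accepted and (i - accepted[-1]) < twin and local_slope(i) < 0.5 * slopes[-1]:
                npki = f * pv + s * npki
                continue
            # search-back first if a long gap preceded this strong peak
            if accepted and rr_buf and (i - accepted[-1]) > params.searchback_factor * rr_mean():
                gap = cand[(cand > accepted[-1] + refractory) & (cand < i - refractory)]
                if gap.size:
                    j = gap[np.argmax(mwi[gap])]
                    if mwi[j] > 0.5 * thr:
                        accept(int(j), float(mwi[j]), searchback=True)
            accept(int(i), pv, searchback=False)
        else:
            npki = f * pv + s * npki
            # search-back: has too long an interval elapsed?
            if accepted and rr_buf and (i - accepted[-1]) > params.searchback_factor * rr_mean():
                gap = cand[(cand > accepted[-1] + refractory) & (cand <= i)]
                if gap.size:
                    j = gap[np.argmax(mwi[gap])]
                    if mwi[j] > 0.5 * thr and j - accepted[-1] >= refractory:
                        accept(int(j), float(mwi[j]), searchback=True)

    if not accepted:
        raise DetectionError("no peaks found")

    # relocate each detection to the local extremum of |x|
    rad = int(round(params.relocate_ms / 1000 * fs))
    relocated = []
    for i in sorted(accepted):
        lo, hi = max(i - rad, 0), min(i + rad + 1, x.size)
        relocated.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    peaks = np.unique(np.asarray(relocated, dtype=int))
    # enforce the refractory on the relocated indices (keep the larger peak)
    keep: list[int] = []
    for p in peaks:
        if keep and p - keep[-1] < refractory:
            if abs(x[p]) > abs(x[keep[-1]]):
                keep[-1] = int(p)
        else:
            keep.append(int(p))
    return np.asarray(keep, dtype=int)


def qrs_boundaries(
    x: np.ndarray,
    fs: float,
    r_peaks: np.ndarray,
    params: PtParams | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Locate QRS onset/offset around each R peak.

    Returns ``(onsets, offsets, edge_flags)``.  The envelope is a short
    (40 ms) moving-window integral of ``x**2``; onset/offset are the 10 %
    crossings of the per-beat envelope maximum, searched at most 100 ms
    before and 160 ms after the peak.  Peaks too close to the record edge
    get boundaries clamped to the edge and flagged.
    """
    params = params or PtParams()
    x = np.asarray(x, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=int)
    env = _mwi(x**2, int(round(params.boundary_mwi_ms / 1000 * fs)))
    pre = int(round(params.onset_search_ms / 1000 * fs))
    post = int(round(params.offset_search_ms / 1000 * fs))
    onsets = np.empty(r_peaks.size, dtype=int)
    offsets = np.empty(r_peaks.size, dtype=int)
    flags = np.zeros(r_peaks.size, dtype=bool)
    for b, p in enumerate(r_peaks):
        lo, hi = p - pre, p + post
        if lo < 0 or hi >= x.size:
            flags[b] = True
            lo, hi = max(lo, 0), min(hi, x.size - 1)
        seg = env[lo : hi + 1]
        thr = params.boundary_frac * float(np.max(seg))
        # onset: last sample before the peak below threshold
        before = env[lo : p + 1]
        under = np.nonzero(before < thr)[0]
        onsets[b] = lo + (under[-1] if under.size else 0)
        # offset: first sample after the peak below threshold
        after = env[p : hi + 1]
        under = np.nonzero(after < thr)[0]
        offsets[b] = p + (under[0] if under.size else hi - p)
    return onsets, offsets, flags


def rr_intervals(r_peaks: np.ndarray, fs: float) -> np.ndarray:
    """RR intervals in seconds; empty for fewer than two peaks."""
    r_peaks = np.asarray(r_peaks)
    if r_peaks.size < 2:
        return np.empty(0, dtype=float)
    return np.diff(r_peaks) / fs


def detect_fiducials(
    x: np.ndarray, fs: float, params: PtParams | None = None
) -> FiducialSet:
    """Convenience: R peaks plus QRS boundaries as one :class:`FiducialSet`."""
    peaks = pan_tompkins_rpeaks(x, fs, params)
    onsets, offsets, flags = qrs_boundaries(x, fs, peaks, params)
    return FiducialSet(
        r_peaks=peaks, qrs_onsets=onsets, qrs_offsets=offsets, fs=fs, edge_flags=flags
    )
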