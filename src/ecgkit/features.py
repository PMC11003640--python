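"""Sliding-window RR/QRS feature extraction and labeling.

Two dynamic features drive every classifier in this package: the RR
interval (seconds) and the QRS duration (milliseconds).  They are
aggregated two ways, matching how each arrhythmia manifests:

* **PVC / PAC** — a sliding window of 5 consecutive R peaks, advancing
  one beat at a time; the window features are the *longest* RR interval
  and the *widest* QRS inside the window (a premature beat leaves a
  pause and, for PVC, a wide QRS somewhere in the window).
* **AF** — the record is tiled into non-overlapping 10-second segments;
  the segment features are the *mean* RR and *mean* QRS duration (AF
  shows up as a shifted, dispersed mean RR).

Window labels use the any-ectopic rule (a window containing at least one
annotated 'V' — or 'A' for the PAC task — is positive); 10-s segments
take the rhythm label covering the majority of the segment.

``sliding_window_max_sum`` is the incremental fixed-window maximum-sum
scan underlying the "long" aggregation, exposed as a utility in exactly
its textbook form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import LabelingError, ParameterError
from .fiducials import FiducialSet, PtParams, detect_fiducials
from .preprocess import FilterParams, preprocess_signal
from .record_io import AnnotationTrack, EcgRecord, FeatureTable

__all__ = [
    "BeatWindow",
    "sliding_window_max_sum",
    "beat_windows",
    "pvc_pac_features",
    "af_features",
    "af_segments",
    "label_window",
    "label_segment",
    "build_feature_table",
]

log = logging.getLogger(__name__)

TASK_POSITIVE = {"PVC": "V", "PAC": "A", "AF": "AFIB"}
AF_SEGMENT_S = 10.0


@dataclass
class BeatWindow:
    """A run of ``k`` consecutive R peaks with its member measurements."""

    window_id: int
    r_peaks: np.ndarray  # k sample indices
    rr_s: np.ndarray  # k-1 intervals, seconds
    qrs_ms: np.ndarray  # k durations, milliseconds
    start_beat: int  # index of the first peak in the record's peak list

    def __post_init__(self) -> None:
        if len(self.r_peaks) < 2:
            raise ParameterError("a beat window needs at least 2 peaks")


def sliding_window_max_sum(a, k: int) -> float:
    """Maximum sum over all contiguous windows of length ``k``.

    Incremental scan: the first window sum is updated by subtracting the
    element that leaves and adding the one that enters.  Equals the
    brute-force maximum over all ``len(a) - k + 1`` window sums.
    """
    a = list(a)
    n = len(a)
    if not 1 <= k <= n:
        raise ParameterError(f"window size k={k} must satisfy 1 <= k <= len(a)={n}")
    window_sum = sum(a[:k])
    max_sum = window_sum
    for i in range(n - k):
        window_sum = window_sum - a[i] + a[i + k]
        max_sum = max(max_sum, window_sum)
    return max_sum


def beat_windows(fids: FiducialSet, k: int = 5, stride: int = 1) -> list[BeatWindow]:
    """Slide a ``k``-peak window over the fiducials.

    Returns ``floor((n_peaks - k)/stride) + 1`` windows; an empty list
    (with a warning log) when fewer than ``k`` peaks exist.
    """
    if k < 2:
        raise ParameterError("window size k must be >= 2")
    if stride < 1:
        raise ParameterError("stride must be >= 1")
    n = len(fids.r_peaks)
    if n < k:
        log.warning("only %d peaks for window size %d; no windows", n, k)
        return []
    rr = fids.rr_s
    qrs = fids.qrs_durations_ms
    out = []
    for wid, start in enumerate(range(0, n - k + 1, stride)):
        out.append(
            BeatWindow(
                window_id=wid,
                r_peaks=fids.r_peaks[start : start + k],
                rr_s=rr[start : start + k - 1],
                qrs_ms=qrs[start : start + k],
                start_beat=start,
            )
        )
    return out


def pvc_pac_features(w: BeatWindow) -> tuple[float, float]:
    """(longest RR in s, widest QRS in ms) for one window."""
    return float(np.max(w.rr_s)), float(np.max(w.qrs_ms))


def af_segments(fids: FiducialSet, duration_s: float, segment_s: float = AF_SEGMENT_S):
    """Non-overlapping segment boundaries ``(start_s, end_s)`` tiling the record."""
    n_seg = int(duration_s // segment_s)
    return [(i * segment_s, (i + 1) * segment_s) for i in range(n_seg)]


def af_features(
    fids: FiducialSet, segment: tuple[float, float]
) -> tuple[float, float] | None:
    """(mean RR in s, mean QRS in ms) over beats inside ``segment``.

    Beats belong to the segment when their R peak lies in
    ``[start, end)``; the RR interval assigned to a beat is the one it
    opens.  Returns None (with a warning) when the segment holds fewer
    than 2 peaks.
    """
    start, end = segment
    t = fids.r_peaks / fids.fs
    inside = np.nonzero((t >= start) & (t < end))[0]
    if inside.size < 2:
        log.warning("segment (%.1f, %.1f) has %d peaks; skipped", start, end, inside.size)
        return None
    rr = fids.rr_s
    rr_idx = inside[inside < rr.size]
    qrs = fids.qrs_durations_ms[inside]
    if rr_idx.size == 0:
        log.warning("segment (%.1f, %.1f) has no complete RR interval; skipped", start, end)
        return None
    return float(np.mean(rr[rr_idx])), float(np.mean(qrs))


def label_window(ann: AnnotationTrack, w: BeatWindow, task: str) -> str:
    """Any-ectopic rule: the task's symbol if any annotated beat in the
    window span carries it, else 'N'."""
    if task not in ("PVC", "PAC"):
        raise ParameterError(f"window labeling applies to PVC/PAC, got {task!r}")
    if not ann.beats:
        raise LabelingError("no beat annotations cover the record")
    positive = TASK_POSITIVE[task]
    lo, hi = int(w.r_peaks[0]), int(w.r_peaks[-1])
    for s, sym in ann.beats:
        if lo <= s <= hi and sym == positive:
            return positive
    return "N"


def label_segment(
    ann: AnnotationTrack, segment: tuple[float, float], fs: float
) -> str:
    """Majority rhythm label ('AFIB' or 'N') over a 10-s segment."""
    start, end = segment
    if not ann.rhythms:
        return "N"
    # rhythm intervals as (onset_s, label), each holding to the next onset
    onsets = [(s / fs, lab) for s, lab in ann.rhythms]
    afib = 0.0
    for (t0, lab), t1 in zip(onsets, [t for t, _ in onsets[1:]] + [float("inf")]):
        a, b = max(t0, start), min(t1, end)
        if b > a and lab == "AFIB":
            afib += b - a
    return "AFIB" if afib > (end - start) / 2 else "N"


def build_feature_table(
    record: EcgRecord,
    ann: AnnotationTrack,
    task: str,
    lead: str | None = None,
    k: int = 5,
    stride: int = 1,
    filter_params: FilterParams | None = None,
    pt_params: PtParams | None = None,
) -> dict[str, FeatureTable]:
    """Run the full chain preprocess -> fiducials -> features -> labels.

    Returns one :class:`FeatureTable` per lead (or only ``lead`` when
    given).  Deterministic for fixed inputs.
    """
    if task not in TASK_POSITIVE:
        raise ParameterError(f"task must be one of {sorted(TASK_POSITIVE)}, got {task!r}")
    leads = [lead] if lead is not None else list(record.lead_names)
    tables: dict[str, FeatureTable] = {}
    for name in leads:
        x = preprocess_signal(record.lead(name), record.fs, filter_params)
        fids = detect_fiducials(x, record.fs, pt_params)
        rows = []
        if task in ("PVC", "PAC"):
            for w in beat_windows(fids, k=k, stride=stride):
                rr_f, qrs_f = pvc_pac_features(w)
                rows.append(
                    (record.record_id, name, w.window_id, rr_f, qrs_f, label_window(ann, w, task))
                )
        else:
            for wid, seg in enumerate(af_segments(fids, record.duration_s)):
                feats = af_features(fids, seg)
                if feats is None:
                    continue
                rows.append(
                    (record.record_id, name, wid, feats[0], feats[1], label_segment(ann, seg, record.fs))
                )
        df = pd.DataFrame(
            rows,
            columns=["record_id", "lead", "window_id", "rr_feature", "qrs_feature", "label"],
        )
        tables[name] = FeatureTable(df=df, task=task)
    return tables
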