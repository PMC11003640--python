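"""Synthetic two-lead ECG with planted ground truth.

The generator exists so every downstream stage (preprocessing, fiducial
detection, feature extraction, classification) can be exercised against a
known answer without any database download.  It emulates what the
detection method actually consumes — fiducial geometry, not clinical
realism:

* beat morphology is a sum of Gaussian deflections (P, Q, R, S, T);
* normal sinus RR intervals are ``mean_rr_s`` plus Gaussian jitter,
  truncated to the physiologic 0.6-1.2 s band;
* a premature beat (PAC 'A' or PVC 'V') shortens its preceding RR by
  25-40 %; a PVC is followed by a compensatory pause (x1.25-1.4) and has
  a wide QRS with no P wave; a PAC keeps a narrow QRS and is followed by
  a smaller non-compensatory pause (x1.05-1.2, sinus-node reset);
* inside an atrial-fibrillation episode RR is i.i.d. uniform on
  [0.35, 1.1] s and beats lose their P wave — AF is modeled purely as RR
  irregularity plus absent atrial activity;
* both leads share the beat train; lead 2 is the lead-1 morphology
  scaled by 0.7 with independent noise; baseline wander (slow sinusoid),
  powerline interference and white noise are added per lead.

A single ``numpy`` Generator keyed by ``seed`` drives every draw, in a
fixed documented order (per beat: sinus RR, beat-type uniform, ectopic
shortening, post-ectopic pause; then per lead: baseline phase; then
noise arrays), so identical configs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .record_io import AnnotationTrack, EcgRecord

__all__ = ["SynthConfig", "GroundTruth", "BeatTemplate", "make_beat_template", "synthesize"]

#: QRS width multiplier for ventricular ectopic beats (>= the 1.5x
#: "wide QRS" convention with margin).
V_WIDTH_FACTOR = 5.0 / 3.0

# Gaussian deflection geometry, relative to the R peak.  Times in
# seconds except the QRS terms, which scale with the requested width w
# (seconds).  Amplitudes in mV before final normalization.
_P_CENTER, _P_AMP, _P_SIGMA = -0.17, 0.12, 0.02
_T_CENTER, _T_AMP, _T_SIGMA = 0.26, 0.22, 0.028
_Q_AMP, _S_AMP = -0.15, -0.20
_QS_OFFSET = 0.35  # Q/S centers at -/+ w * _QS_OFFSET
_R_SIGMA_FRAC = 1 / 4.0  # sigma_R = w * frac; calibrated so the 10 %
_QS_SIGMA_FRAC = 1 / 9.0  # energy-envelope width of the beat ~= w


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults are the package's study conditions."""

    fs: float = 360.0
    duration_s: float = 60.0
    mean_rr_s: float = 0.8
    rr_jitter_s: float = 0.02
    qrs_width_ms: float = 90.0
    pvc_rate: float = 0.0
    pac_rate: float = 0.0
    af_episodes: tuple[tuple[float, float], ...] = ()
    baseline_amp_mv: float = 0.0
    baseline_freq_hz: float = 0.3
    noise_sd_mv: float = 0.0
    powerline_amp_mv: float = 0.0
    powerline_freq_hz: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 100:
            raise ParameterError(f"fs must be >= 100 Hz, got {self.fs}")
        if not 0 <= self.pvc_rate + self.pac_rate <= 1:
            raise ParameterError("pvc_rate + pac_rate must lie in [0, 1]")
        eps = sorted(self.af_episodes)
        for (a, b) in eps:
            if not (0 <= a < b <= self.duration_s):
                raise ParameterError(f"AF episode ({a}, {b}) outside [0, {self.duration_s}]")
        for (_, b), (a2, _) in zip(eps, eps[1:]):
            if a2 < b:
                raise ParameterError("AF episodes must not overlap")
        object.__setattr__(self, "af_episodes", tuple(eps))


@dataclass
class GroundTruth:
    """Planted truth: beat positions/types/widths and rhythm intervals."""

    beat_samples: np.ndarray  # int, strictly increasing
    beat_types: list[str]  # 'N' | 'A' | 'V'
    true_qrs_width_ms: np.ndarray  # per beat
    rhythms: list[tuple[float, float, str]] = field(default_factory=list)  # (start_s, end_s, label)

    def __post_init__(self) -> None:
        n = len(self.beat_samples)
        if not (n == len(self.beat_types) == len(self.true_qrs_width_ms)):
            raise ParameterError("ground-truth arrays must have aligned lengths")


@dataclass
class BeatTemplate:
    """One beat's waveform; ``samples[r_index]`` is the R peak (1 mV)."""

    samples: np.ndarray
    r_index: int
    fs: float


def _gauss(t: np.ndarray, center: float, amp: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _template(kind: str, fs: float, qrs_width_ms: float, with_p: bool) -> BeatTemplate:
    w = qrs_width_ms / 1000.0
    span_l, span_r = -0.30, 0.50
    n_l = int(round(-span_l * fs))
    n_r = int(round(span_r * fs))
    t = np.arange(-n_l, n_r + 1) / fs
    y = _gauss(t, 0.0, 1.0, w * _R_SIGMA_FRAC)
    y += _gauss(t, -w * _QS_OFFSET, _Q_AMP, w * _QS_SIGMA_FRAC)
    s_amp = _S_AMP * (2.0 if kind == "V" else 1.0)
    y += _gauss(t, w * _QS_OFFSET, s_amp, w * _QS_SIGMA_FRAC)
    y += _gauss(t, _T_CENTER, _T_AMP, _T_SIGMA)
    if with_p:
        y += _gauss(t, _P_CENTER, _P_AMP, _P_SIGMA)
    y /= y[n_l]  # R sample exactly 1 mV
    return BeatTemplate(samples=y, r_index=n_l, fs=fs)


def make_beat_template(
    kind: str, fs: float, qrs_width_ms: float | None = None
) -> BeatTemplate:
    """Build a single-beat waveform of the given kind.

    ``kind`` is 'N' (sinus), 'A' (atrial premature: sinus-like
    morphology) or 'V' (ventricular premature: no P wave, wide QRS,
    deep S).  Default QRS width is 90 ms for N/A and 150 ms for V.
    Width must lie in [40, 200] ms.
    """
    if kind not in ("N", "A", "V"):
        raise ParameterError(f"beat kind must be one of N, A, V; got {kind!r}")
    if qrs_width_ms is None:
        qrs_width_ms = 90.0 * V_WIDTH_FACTOR if kind == "V" else 90.0
    if not 40.0 <= qrs_width_ms <= 200.0:
        raise ParameterError(f"qrs_width_ms must be in [40, 200], got {qrs_width_ms}")
    return _template(kind, fs, qrs_width_ms, with_p=kind != "V")


def _in_episode(t: float, episodes) -> bool:
    return any(a <= t < b for a, b in episodes)


def synthesize(config: SynthConfig) -> tuple[EcgRecord, AnnotationTrack, GroundTruth]:
    """Generate a two-lead record with annotations and planted truth.

    Returns ``(record, annotations, truth)``.  The annotation track
    mirrors the ground truth exactly ('N'/'A'/'V' beats, 'AFIB'/'N'
    rhythm onsets), which stands in for a database's expert labels.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration_s * fs))

    # --- beat train -------------------------------------------------------
    # The interval t -> t+rr belongs to the beat at t; a premature next
    # beat shortens it, an ectopic beat at t lengthens it (pause).
    times: list[float] = [0.5]
    types: list[str] = ["N"]
    guard = config.duration_s - 0.55
    t = 0.5
    while True:
        if _in_episode(t, config.af_episodes):
            rr = rng.uniform(0.35, 1.1)
            nxt = "N"
        else:
            rr = float(
                np.clip(
                    config.mean_rr_s + config.rr_jitter_s * rng.standard_normal(),
                    0.6,
                    1.2,
                )
            )
            u = rng.random()
            if u < config.pvc_rate:
                nxt = "V"
            elif u < config.pvc_rate + config.pac_rate:
                nxt = "A"
            else:
                nxt = "N"
            if nxt != "N":
                rr *= 1.0 - rng.uniform(0.25, 0.40)
            if types[-1] == "V":
                rr = min(rr * rng.uniform(1.25, 1.40), 1.3)
            elif types[-1] == "A":
                rr = min(rr * rng.uniform(1.05, 1.20), 1.3)
        t_next = t + rr
        if t_next >= guard:
            break
        if _in_episode(t_next, config.af_episodes):
            nxt = "N"
        times.append(t_next)
        types.append(nxt)
        t = t_next

    beat_samples = np.round(np.asarray(times) * fs).astype(int)
    widths = np.array(
        [config.qrs_width_ms * (V_WIDTH_FACTOR if bt == "V" else 1.0) for bt in types]
    )

    # --- waveform ---------------------------------------------------------
    clean = np.zeros(n)
    tmpl_cache: dict[tuple[str, float, bool], BeatTemplate] = {}
    for samp, bt, w, tt in zip(beat_samples, types, widths, times):
        with_p = bt != "V" and not _in_episode(tt, config.af_episodes)
        key = (bt, w, with_p)
        if key not in tmpl_cache:
            tmpl_cache[key] = _template(bt, fs, w, with_p)
        tp = tmpl_cache[key]
        lo = samp - tp.r_index
        hi = lo + len(tp.samples)
        a, b = max(lo, 0), min(hi, n)
        clean[a:b] += tp.samples[a - lo : b - lo]

    tgrid = np.arange(n) / fs
    signals = np.empty((2, n))
    for lead, scale in enumerate((1.0, 0.7)):
        phase = rng.uniform(0, 2 * np.pi)
        y = scale * clean
        if config.baseline_amp_mv:
            y = y + config.baseline_amp_mv * np.sin(
                2 * np.pi * config.baseline_freq_hz * tgrid + phase
            )
        if config.powerline_amp_mv:
            y = y + config.powerline_amp_mv * np.sin(
                2 * np.pi * config.powerline_freq_hz * tgrid + phase
            )
        signals[lead] = y
    if config.noise_sd_mv:
        signals += rng.normal(0.0, config.noise_sd_mv, size=signals.shape)

    record = EcgRecord(
        signals=signals,
        fs=fs,
        lead_names=["MLII", "V1"],
        record_id=f"synth{config.seed}",
    )

    # --- annotations & truth ---------------------------------------------
    rhythm_events: list[tuple[int, str]] = []
    intervals: list[tuple[float, float, str]] = []
    cursor = 0.0
    for a, b in config.af_episodes:
        if a > cursor:
            intervals.append((cursor, a, "N"))
        intervals.append((a, b, "AFIB"))
        cursor = b
    if cursor < config.duration_s:
        intervals.append((cursor, config.duration_s, "N"))
    for start, _, lab in intervals:
        rhythm_events.append((int(round(start * fs)), lab))

    ann = AnnotationTrack(
        beats=[(int(s), bt) for s, bt in zip(beat_samples, types)],
        rhythms=rhythm_events,
    )
    truth = GroundTruth(
        beat_samples=beat_samples,
        beat_types=list(types),
        true_qrs_width_ms=widths,
        rhythms=intervals,
    )
    return record, ann, truth
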