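"""Reading and writing ECG records, annotations, and feature tables.

Records use the WFDB conventions of the MIT-BIH databases: a plain-text
header (``<record>.hea``) describing one or more signal files, and binary
signal files in format 16 (little-endian 16-bit two's complement,
sample-interleaved).  Only format 16 is supported by the built-in reader;
it is the format MITDB/AFDB ship in after conversion and the one this
package writes.  Amplitudes are converted to millivolts on read using the
per-signal ADC gain, so every downstream stage works in mV.

Annotations for fixtures use a small JSON dialect::

    {"beats": [[sample, "N"], ...], "rhythms": [[onset_sample, "N"], ...]}

Beat symbols follow the MIT-BIH alphabet ('N' normal, 'A' atrial
premature, 'V' ventricular premature); rhythm labels are 'N' / 'AFIB'.
Binary ``.atr`` annotation files are not parsed here — convert them with
the optional real-data script (requires the ``wfdb`` package).

Sample indices are 0-based everywhere.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, LeadLookupError, ParameterError

__all__ = [
    "EcgRecord",
    "AnnotationTrack",
    "FeatureTable",
    "read_record",
    "write_record",
    "read_annotations",
    "write_annotations",
    "read_feature_table",
    "write_feature_table",
]

BEAT_ALPHABET = frozenset("NAVFLRJSEjnaQ?/fx|")  # MIT-BIH beat symbols we accept
FEATURE_COLUMNS = ["record_id", "lead", "window_id", "rr_feature", "qrs_feature", "label"]


@dataclass
class EcgRecord:
    """A multi-lead sampled ECG signal in millivolts.

    Parameters
    ----------
    signals : ndarray, shape (n_leads, n_samples)
        Per-lead amplitude samples in mV.
    fs : float
        Sampling frequency in Hz, strictly positive.
    lead_names : list of str
        Ordered lead labels, e.g. ``["MLII", "V1"]``.
    record_id : str
        Identifier used in feature tables and file names.
    """

    signals: np.ndarray
    fs: float
    lead_names: list[str]
    record_id: str = "record"

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if self.signals.shape[0] != len(self.lead_names):
            raise ParameterError(
                f"{self.signals.shape[0]} signal rows but {len(self.lead_names)} lead names"
            )
        if len(self.lead_names) < 1:
            raise ParameterError("a record needs at least one lead")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return the signal of one lead by name."""
        try:
            return self.signals[self.lead_names.index(name)]
        except ValueError:
            raise LeadLookupError(
                f"lead {name!r} not in record; available leads: {self.lead_names}"
            ) from None


@dataclass
class AnnotationTrack:
    """Beat and rhythm annotations for one record.

    ``beats`` is a list of ``(sample_index, symbol)`` with strictly
    increasing sample indices; ``rhythms`` is a list of
    ``(onset_sample, label)`` with non-decreasing onsets, each entry
    holding until the next onset.
    """

    beats: list[tuple[int, str]] = field(default_factory=list)
    rhythms: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        samples = [s for s, _ in self.beats]
        if any(b >= a for a, b in zip(samples[1:], samples)):
            raise FormatError("beat sample indices must be strictly increasing")
        if any(s < 0 for s in samples):
            raise FormatError("beat sample indices must be >= 0")
        onsets = [s for s, _ in self.rhythms]
        if any(b > a for a, b in zip(onsets[1:], onsets)):
            raise FormatError("rhythm onsets must be non-decreasing")
        for _, sym in self.beats:
            if len(sym) != 1 or sym not in BEAT_ALPHABET:
                raise FormatError(f"unknown beat symbol {sym!r}")

    def rhythm_at(self, sample: int) -> str:
        """Rhythm label in force at ``sample`` ('N' if none declared yet)."""
        label = "N"
        for onset, lab in self.rhythms:
            if onset <= sample:
                label = lab
            else:
                break
        return label


@dataclass
class FeatureTable:
    """Labeled (RR, QRS) feature rows for one detection task.

    ``df`` has columns record_id, lead, window_id, rr_feature (seconds),
    qrs_feature (milliseconds), label; ``task`` is one of
    ``{"AF", "PVC", "PAC"}``.
    """

    df: pd.DataFrame
    task: str

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"feature table missing columns {missing}")
        self.df = self.df[FEATURE_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def X(self) -> np.ndarray:
        """Feature matrix (n_rows, 2): rr_feature, qrs_feature."""
        return self.df[["rr_feature", "qrs_feature"]].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Label vector (n_rows,) of strings."""
        return self.df["label"].to_numpy(dtype=object)


# ---------------------------------------------------------------------------
# WFDB header + format-16 signals
# ---------------------------------------------------------------------------

_GAIN_RE = re.compile(r"^([-+0-9.eE]+)(?:\(([-+0-9]+)\))?(?:/(\S+))?$")


def _parse_gain(token: str) -> tuple[float, int]:
    """Parse a WFDB gain token like ``200``, ``200/mV`` or ``200(0)/mV``."""
    m = _GAIN_RE.match(token)
    if m is None:
        raise FormatError(f"cannot parse gain token {token!r}")
    gain = float(m.group(1))
    baseline = int(m.group(2)) if m.group(2) is not None else 0
    if gain == 0:
        gain = 200.0  # WFDB convention: 0 means the default gain
    return gain, baseline


def read_record(path: str | Path, leads: Sequence[str] | None = None) -> EcgRecord:
    """Read a WFDB header/signal pair into an :class:`EcgRecord` in mV.

    ``path`` may point at the ``.hea`` file or at the record stem.  Only
    format-16 signal files are supported.  ``leads`` selects and orders a
    subset of leads; unknown names raise :class:`LeadLookupError` naming
    the available leads.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"no header file {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"malformed header line {lines[0]!r}")
    record_id = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0])
    n_samples = int(head[3])
    if len(lines) < 1 + n_sig:
        raise FormatError(f"header declares {n_sig} signals but lists {len(lines) - 1}")

    sig_files: list[str] = []
    gains: list[float] = []
    baselines: list[int] = []
    names: list[str] = []
    for i, ln in enumerate(lines[1 : 1 + n_sig]):
        tok = ln.split()
        if len(tok) < 3:
            raise FormatError(f"malformed signal line {ln!r}")
        fmt = tok[1].split("x")[0].split(":")[0].split("+")[0]
        if fmt != "16":
            raise FormatError(f"unsupported WFDB signal format {tok[1]!r} (only 16)")
        gain, baseline = _parse_gain(tok[2])
        sig_files.append(tok[0])
        gains.append(gain)
        baselines.append(baseline)
        names.append(tok[-1] if len(tok) >= 9 else f"sig{i}")

    # group signals by file; within one file samples are interleaved
    signals = np.empty((n_sig, n_samples), dtype=float)
    order: dict[str, list[int]] = {}
    for i, f in enumerate(sig_files):
        order.setdefault(f, []).append(i)
    for fname, idxs in order.items():
        raw = np.fromfile(hea.parent / fname, dtype="<i2")
        k = len(idxs)
        if raw.size < k * n_samples:
            raise FormatError(
                f"{fname}: expected {k * n_samples} samples, found {raw.size}"
            )
        block = raw[: k * n_samples].reshape(n_samples, k).T
        for j, i in enumerate(idxs):
            signals[i] = (block[j] - baselines[i]) / gains[i]

    if leads is not None:
        sel = []
        for name in leads:
            if name not in names:
                raise LeadLookupError(
                    f"lead {name!r} not in record; available leads: {names}"
                )
            sel.append(names.index(name))
        signals = signals[sel]
        names = list(leads)
    return EcgRecord(signals=signals, fs=fs, lead_names=names, record_id=record_id)


def write_record(record: EcgRecord, path: str | Path, gain: float = 200.0) -> None:
    """Write ``record`` as a WFDB header + one format-16 signal file.

    Amplitudes are quantized as ``round(mV * gain)`` and clipped to the
    int16 range; ``read_record`` inverts the scaling.
    """
    path = Path(path)
    stem = path.with_suffix("") if path.suffix == ".hea" else path
    stem.parent.mkdir(parents=True, exist_ok=True)
    dat_name = stem.name + ".dat"
    n_sig, n_samples = record.signals.shape
    digital = np.clip(np.round(record.signals * gain), -32768, 32767).astype("<i2")
    digital.T.reshape(-1).tofile(stem.parent / dat_name)
    lines = [f"{stem.name} {n_sig} {record.fs:g} {n_samples}"]
    for i, name in enumerate(record.lead_names):
        init = int(digital[i, 0]) if n_samples else 0
        lines.append(f"{dat_name} 16 {gain:g}(0)/mV 16 0 {init} 0 0 {name}")
    (stem.parent / (stem.name + ".hea")).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# JSON annotation dialect
# ---------------------------------------------------------------------------


def read_annotations(path: str | Path) -> AnnotationTrack:
    """Read a JSON annotation file into an :class:`AnnotationTrack`.

    The dialect is ``{"beats": [[sample, symbol], ...],
    "rhythms": [[onset, label], ...]}``; both keys optional.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no annotation file {path}")
    text = path.read_text()
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as e:
        offset = e.pos
        raise FormatError(f"unparseable annotation file at byte offset {offset}: {e.msg}")
    try:
        beats = [(int(s), str(sym)) for s, sym in obj.get("beats", [])]
        rhythms = [(int(s), str(lab)) for s, lab in obj.get("rhythms", [])]
    except (TypeError, ValueError) as e:
        raise FormatError(f"malformed annotation entry: {e}")
    return AnnotationTrack(beats=beats, rhythms=rhythms)


def write_annotations(ann: AnnotationTrack, path: str | Path) -> None:
    """Write annotations in the JSON dialect read by :func:`read_annotations`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    obj = {
        "beats": [[int(s), sym] for s, sym in ann.beats],
        "rhythms": [[int(s), lab] for s, lab in ann.rhythms],
    }
    path.write_text(json.dumps(obj, indent=1) + "\n")


# ---------------------------------------------------------------------------
# Feature tables (CSV)
# ---------------------------------------------------------------------------


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV with a ``# task=`` comment header.

    Numeric columns keep full precision (round-trip relative error
    <= 1e-9 guaranteed by 17-significant-digit formatting).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# task={table.task}\n")
        table.df.to_csv(fh, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a CSV feature table written by :func:`write_feature_table`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no feature table {path}")
    task = "PVC"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            m = re.search(r"task\s*=\s*(\w+)", first)
            if m:
                task = m.group(1)
            df = pd.read_csv(fh, dtype={"label": str, "lead": str, "record_id": str})
        else:
            fh.seek(0)
            df = pd.read_csv(fh, dtype={"label": str, "lead": str, "record_id": str})
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"feature table {path} missing columns {missing}")
    if len(df) == 0:
        df = df.astype({"rr_feature": float, "qrs_feature": float})
    return FeatureTable(df=df, task=task)
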