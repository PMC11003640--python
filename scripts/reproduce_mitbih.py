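#!/usr/bin/env python
"""Optional: run the pipeline on real MIT-BIH records.

Requires the ``wfdb`` package (``pip install wfdb``) and locally
downloaded MITDB / AFDB records (e.g. via ``wfdb.dl_database``); nothing
here is needed for the test suite or the synthetic benchmark.

For each record: read the two leads and the reference annotations with
``wfdb``, convert beat/rhythm annotations to this package's track
format, extract task features, and run the scenario-1 comparison.

Usage::

    python scripts/reproduce_mitbih.py --data-dir mitdb/ --task PVC \
        --records 106 119 200 --out mitbih_pvc.csv
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import pandas as pd

from ecgkit.evaluate import run_scenario
from ecgkit.features import build_feature_table
from ecgkit.record_io import AnnotationTrack, EcgRecord


def load_with_wfdb(data_dir: Path, name: str):
    import wfdb

    rec = wfdb.rdrecord(str(data_dir / name))
    record = EcgRecord(
        signals=rec.p_signal.T,
        fs=float(rec.fs),
        lead_names=list(rec.sig_name),
        record_id=name,
    )
    ann = wfdb.rdann(str(data_dir / name), "atr")
    beats = []
    rhythms = []
    for sample, symbol, aux in zip(ann.sample, ann.symbol, ann.aux_note):
        if symbol == "+":
            label = aux.strip("\x00 ").lstrip("(")
            rhythms.append((int(sample), "AFIB" if label == "AFIB" else "N"))
        elif symbol in "NAV":
            beats.append((int(sample), symbol))
    return record, AnnotationTrack(beats=beats, rhythms=rhythms)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, required=True)
    parser.add_argument("--task", choices=["AF", "PVC", "PAC"], required=True)
    parser.add_argument("--records", nargs="+", required=True)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()

    try:
        import wfdb  # noqa: F401
    except ImportError:
        sys.exit("this script needs the optional 'wfdb' package: pip install wfdb")

    frames = []
    for name in args.records:
        record, ann = load_with_wfdb(args.data_dir, name)
        tables = build_feature_table(record, ann, args.task)
        merged = {}
        for lead, table in tables.items():
            merged[lead] = table
        frames.append(run_scenario(1, merged, seed=args.seed))
        print(f"{name}: {', '.join(f'{k}={len(v)} rows' for k, v in merged.items())}")
    report = pd.concat(frames, ignore_index=True)
    report.to_csv(args.out, index=False)
    print(report.groupby(["lead", "model"])[["sensitivity", "specificity", "accuracy"]].mean())


if __name__ == "__main__":
    main()
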