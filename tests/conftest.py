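"""Shared fixtures: small synthetic records and feature tables."""

import numpy as np
import pytest

from ecgkit.features import build_feature_table
from ecgkit.synth_ecg import SynthConfig, synthesize


@pytest.fixture(scope="session")
def clean_record():
    """60 s noiseless two-lead record, all sinus beats."""
    return synthesize(SynthConfig(duration_s=60.0, seed=1))


@pytest.fixture(scope="session")
def pvc_record():
    """60 s record with 20 % PVCs and mild noise."""
    return synthesize(SynthConfig(duration_s=60.0, seed=2, pvc_rate=0.2, noise_sd_mv=0.02))


@pytest.fixture(scope="session")
def pvc_table(pvc_record):
    """Single-lead PVC feature table from the PVC record."""
    record, ann, _ = pvc_record
    return build_feature_table(record, ann, "PVC", lead="MLII")["MLII"]


def make_xy(seed: int, n: int = 200, n_classes: int = 2, spread: float = 1.2):
    """Gaussian blobs: a small labeled dataset for classifier tests."""
    rng = np.random.default_rng(seed)
    centers = rng.uniform(-3, 3, size=(n_classes, 2))
    y = rng.integers(0, n_classes, size=n)
    X = centers[y] + rng.normal(0, spread, size=(n, 2))
    labels = np.array(["c%d" % k for k in range(n_classes)], dtype=object)
    return X, labels[y]
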