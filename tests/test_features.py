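"""Windowing, aggregation, labeling, and the max-sum scan utility."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgkit.errors import ParameterError
from ecgkit.features import (
    af_features,
    af_segments,
    beat_windows,
    build_feature_table,
    label_segment,
    label_window,
    pvc_pac_features,
    sliding_window_max_sum,
)
from ecgkit.fiducials import FiducialSet
from ecgkit.record_io import AnnotationTrack
from ecgkit.synth_ecg import SynthConfig, synthesize


def brute_force_max_sum(a, k):
    return max(sum(a[i : i + k]) for i in range(len(a) - k + 1))


def make_fids(rr_list_s, fs=360.0, qrs_ms=90.0):
    peaks = np.cumsum([100] + [int(round(r * fs)) for r in rr_list_s])
    half = int(qrs_ms / 2000 * fs)
    return FiducialSet(
        r_peaks=peaks, qrs_onsets=peaks - half, qrs_offsets=peaks + half, fs=fs
    )


class TestMaxSum:
    @pytest.mark.parametrize(
        "a,k,expected",
        [([1, 2, 3, 4, 5], 2, 9), ([7, -1, 3], 3, 9), ([-3, -1, -2], 1, -1)],
    )
    def test_examples(self, a, k, expected):
        assert sliding_window_max_sum(a, k) == expected

    def test_matches_brute_force_exhaustively(self):
        # every integer array with entries in {-2..2} up to length 5, all k
        for n in range(1, 6):
            for a in itertools.product(range(-2, 3), repeat=n):
                for k in range(1, n + 1):
                    assert sliding_window_max_sum(list(a), k) == brute_force_max_sum(a, k)

    @given(
        st.lists(st.integers(min_value=-1000, max_value=1000), min_size=1, max_size=40),
        st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_property(self, a, data):
        k = data.draw(st.integers(min_value=1, max_value=len(a)))
        assert sliding_window_max_sum(a, k) == brute_force_max_sum(a, k)

    @pytest.mark.parametrize("k", [0, 6, -1])
    def test_invalid_k(self, k):
        with pytest.raises(ParameterError):
            sliding_window_max_sum([1, 2, 3, 4, 5], k)


class TestWindows:
    def test_window_counts(self):
        fids = make_fids([0.8] * 9)  # 10 peaks
        assert len(beat_windows(fids, k=5, stride=1)) == 6
        assert len(beat_windows(fids, k=5, stride=5)) == 2

    def test_too_few_peaks_gives_empty(self):
        fids = make_fids([0.8] * 3)  # 4 peaks
        assert beat_windows(fids, k=5) == []

    def test_window_members(self):
        fids = make_fids([0.8, 0.5, 0.8, 1.1, 0.9])
        w = beat_windows(fids, k=5)[0]
        assert len(w.r_peaks) == 5
        assert len(w.rr_s) == 4
        assert len(w.qrs_ms) == 5

    def test_pvc_pac_features_take_maxima(self):
        fids = make_fids([0.8, 0.5, 0.8, 1.1])
        w = beat_windows(fids, k=5)[0]
        w.qrs_ms = np.array([90.0, 90.0, 140.0, 90.0, 90.0])
        assert pvc_pac_features(w) == (pytest.approx(1.1, abs=0.01), 140.0)

    def test_all_equal_window_is_identity(self):
        fids = make_fids([0.8] * 4)
        w = beat_windows(fids, k=5)[0]
        rr_f, qrs_f = pvc_pac_features(w)
        assert rr_f == pytest.approx(0.8, abs=0.01)
        assert qrs_f == pytest.approx(w.qrs_ms[0])


class TestAfSegments:
    def test_segment_tiling(self):
        fids = make_fids([0.8] * 70)
        assert len(af_segments(fids, 60.0)) == 6
        assert af_segments(fids, 60.0)[0] == (0.0, 10.0)

    def test_mean_features(self):
        fids = make_fids([1.0, 1.0, 1.0])
        rr_f, qrs_f = af_features(fids, (0.0, 10.0))
        assert rr_f == pytest.approx(1.0, abs=0.01)
        fids2 = make_fids([0.5, 1.0])
        rr_f2, _ = af_features(fids2, (0.0, 10.0))
        assert rr_f2 == pytest.approx(0.75, abs=0.01)

    def test_sparse_segment_skipped(self):
        fids = make_fids([0.8])
        assert af_features(fids, (50.0, 60.0)) is None


class TestLabeling:
    def test_any_ectopic_rule(self):
        fids = make_fids([0.8] * 4)
        w = beat_windows(fids, k=5)[0]
        beats = [(int(s), sym) for s, sym in zip(w.r_peaks, ["N", "N", "V", "N", "N"])]
        assert label_window(AnnotationTrack(beats=beats), w, "PVC") == "V"
        assert label_window(AnnotationTrack(beats=beats), w, "PAC") == "N"
        all_n = [(int(s), "N") for s in w.r_peaks]
        assert label_window(AnnotationTrack(beats=all_n), w, "PVC") == "N"

    def test_majority_rhythm_rule(self):
        fs = 360.0
        ann = AnnotationTrack(rhythms=[(0, "N"), (int(3 * fs), "AFIB")])
        assert label_segment(ann, (0.0, 10.0), fs) == "AFIB"  # 7 s of 10
        ann2 = AnnotationTrack(rhythms=[(0, "N"), (int(6 * fs), "AFIB")])
        assert label_segment(ann2, (0.0, 10.0), fs) == "N"  # 4 s of 10


class TestBuildFeatureTable:
    def test_af_tiling_all_normal(self, clean_record):
        record, ann, _ = clean_record
        table = build_feature_table(record, ann, "AF", lead="MLII")["MLII"]
        assert len(table) == 6
        assert set(table.y) == {"N"}

    def test_af_episode_aligned_to_tiles(self):
        cfg = SynthConfig(duration_s=60.0, seed=8, af_episodes=((10.0, 40.0),))
        record, ann, _ = synthesize(cfg)
        table = build_feature_table(record, ann, "AF", lead="MLII")["MLII"]
        labels = list(table.y)
        assert labels.count("AFIB") == 3
        assert labels.count("N") == 3

    def test_window_count_matches_peaks(self, pvc_table):
        # n windows = n detected peaks - k + 1 on a fully detected record
        assert len(pvc_table) > 0
        ids = pvc_table.df.window_id
        assert list(ids) == list(range(len(ids)))

    def test_amplitude_scaling_invariance(self, pvc_record):
        from ecgkit.record_io import EcgRecord

        record, ann, _ = pvc_record
        table1 = build_feature_table(record, ann, "PVC", lead="MLII")["MLII"]
        scaled = EcgRecord(
            signals=record.signals * 3.0,
            fs=record.fs,
            lead_names=list(record.lead_names),
            record_id=record.record_id,
        )
        table2 = build_feature_table(scaled, ann, "PVC", lead="MLII")["MLII"]
        np.testing.assert_allclose(table1.X, table2.X, rtol=1e-9)
        assert list(table1.y) == list(table2.y)

    def test_separability_of_planted_classes(self, pvc_table):
        df = pvc_table.df
        mean_v = df[df.label == "V"].qrs_feature.mean()
        mean_n = df[df.label == "N"].qrs_feature.mean()
        assert mean_v > mean_n
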