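"""Membranous-staining features, classification rule, consensus protocol."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

from tps3d import (
    ClassifierRule,
    PipelineConfig,
    classify_pdl1,
    classify_pdl1_frame,
    consensus_label,
    consensus_labels,
    extract_membrane_features,
    run_pipeline,
    segment_nuclei_plane,
)
from tps3d.nuclei import NucleusLabelMap
from tps3d.pdl1 import VOTE_COLUMNS


def ring_plane(shape=(64, 64), center=(32, 32), r_in=6, r_out=9, amp=100.0, bg=0.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    img = np.full(shape, bg, dtype=np.float32)
    img[(d2 > r_in**2) & (d2 <= r_out**2)] = amp
    return img


def nucleus_label_map(shape=(64, 64), center=(32, 32), radius=6):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    labels = (((yy - center[0]) ** 2 + (xx - center[1]) ** 2) <= radius**2).astype(np.int32)
    return NucleusLabelMap(0, labels, np.array([[float(center[0]), float(center[1])]]),
                           np.array([int(labels.sum())]))


class TestFeatureExtraction:
    def test_bright_ring_features(self):
        lm = nucleus_label_map()
        feats = extract_membrane_features(lm, ring_plane(), annulus_width_um=3.0)
        row = feats.iloc[0]
        assert row.feature_ok
        assert row.annulus_to_nucleus_ratio > 1.0
        assert row.ring_coverage_fraction > 0.5

    def test_zero_marker_channel(self):
        lm = nucleus_label_map()
        feats = extract_membrane_features(lm, np.zeros((64, 64)), annulus_width_um=3.0)
        row = feats.iloc[0]
        assert row.annulus_mean == 0.0
        assert row.ring_coverage_fraction == 0.0

    def test_border_nucleus_with_empty_annulus_is_flagged(self):
        # a nucleus filling the whole image leaves no room for an annulus
        labels = np.ones((16, 16), dtype=np.int32)
        lm = NucleusLabelMap(0, labels, np.array([[8.0, 8.0]]), np.array([256]))
        feats = extract_membrane_features(lm, np.zeros((16, 16)), annulus_width_um=2.0)
        assert not feats.iloc[0].feature_ok
        assert np.isnan(feats.iloc[0].annulus_mean)

    def test_requires_positive_annulus_width(self):
        lm = nucleus_label_map()
        with pytest.raises(ValueError):
            extract_membrane_features(lm, np.zeros((64, 64)), annulus_width_um=0.0)

    def test_phantom_positive_cell_ring_detected(self, noise_free_phantom):
        volume, truth = noise_free_phantom
        pos = truth.cells[truth.cells.is_pdl1_positive]
        cell = pos.iloc[0]
        z = int(round(cell.z_um))
        lm = segment_nuclei_plane(volume.plane("nucleus", z), (1.0, 1.0), plane_index=z)
        feats = extract_membrane_features(lm, volume.plane("pdl1", z), (1.0, 1.0), 1.5)
        d = np.hypot(lm.centroids_um[:, 0] - cell.y_um, lm.centroids_um[:, 1] - cell.x_um)
        row = feats.iloc[int(np.argmin(d))]
        assert row.annulus_to_nucleus_ratio > 1.0
        assert row.ring_coverage_fraction > 0.5


class TestClassifier:
    def test_boundary_values_are_positive(self):
        rule = ClassifierRule(coverage_min=0.3, ratio_min=1.2)
        feats = {"ring_coverage_fraction": 0.3, "annulus_to_nucleus_ratio": 1.2}
        assert classify_pdl1(feats, rule)

    def test_all_zero_features_negative(self):
        assert not classify_pdl1(
            {"ring_coverage_fraction": 0.0, "annulus_to_nucleus_ratio": 0.0}
        )

    def test_nan_features_rejected(self):
        with pytest.raises(ValueError):
            classify_pdl1({"ring_coverage_fraction": np.nan, "annulus_to_nucleus_ratio": 1.0})
        with pytest.raises(ValueError):
            classify_pdl1_frame(
                pd.DataFrame({"ring_coverage_fraction": [np.nan],
                              "annulus_to_nucleus_ratio": [1.0]})
            )

    @settings(max_examples=200, derandomize=True)
    @given(
        cov=st.floats(0, 1),
        ratio=st.floats(0, 5),
        c1=st.floats(0, 1),
        c2=st.floats(0, 5),
        dc1=st.floats(0, 1),
        dc2=st.floats(0, 5),
    )
    def test_raising_thresholds_never_flips_negative_to_positive(self, cov, ratio, c1, c2, dc1, dc2):
        feats = {"ring_coverage_fraction": cov, "annulus_to_nucleus_ratio": ratio}
        low = classify_pdl1(feats, ClassifierRule(c1, c2))
        high = classify_pdl1(feats, ClassifierRule(c1 + dc1, c2 + dc2))
        assert not (high and not low)

    def test_noise_free_phantom_calls_match_truth(self, noise_free_phantom):
        volume, truth = noise_free_phantom
        result = run_pipeline(volume, PipelineConfig(masker="constant"))
        cells = result.cells[~result.cells.excluded]
        tree = cKDTree(truth.cells[["z_um", "y_um", "x_um"]].to_numpy())
        _, idx = tree.query(cells[["z_um", "y_um", "x_um"]].to_numpy())
        truth_pos = truth.cells.is_pdl1_positive.to_numpy()[idx]
        calls = cells.is_pdl1_positive.fillna(False).astype(bool).to_numpy()
        assert (calls == truth_pos).all()


class TestConsensus:
    def test_exhaustive_truth_table(self):
        # the oracle is the explicit AND over all 16 vote combinations
        for votes in itertools.product([0, 1], repeat=4):
            expected = votes == (1, 1, 1, 1)
            assert consensus_label(votes) is expected

    def test_wrong_vote_count_rejected(self):
        with pytest.raises(ValueError):
            consensus_label([1, 1, 1])
        with pytest.raises(ValueError):
            consensus_label([1, 1, 1, 1, 1])

    def test_annotation_table(self):
        frame = pd.DataFrame(
            [[1, 1, 1, 1], [1, 1, 1, 0], [0, 0, 0, 0], [1, 0, 1, 1]],
            columns=list(VOTE_COLUMNS),
        )
        assert consensus_labels(frame).tolist() == [True, False, False, False]

    def test_missing_votes_rejected(self):
        frame = pd.DataFrame([[1, 1, 1, None]], columns=list(VOTE_COLUMNS))
        with pytest.raises(ValueError):
            consensus_labels(frame)
        with pytest.raises(ValueError):
            consensus_labels(pd.DataFrame({"vote_a1": [1]}))
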