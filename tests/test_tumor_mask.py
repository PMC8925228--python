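"""Tumor-region masking and the cell-instance accuracy metric."""

import numpy as np
import pytest

from tps3d import (
    BaselineMasker,
    ConstantMasker,
    PhantomConfig,
    TumorMask,
    UndefinedMetricError,
    assign_tumor_status,
    cell_instance_accuracy,
    generate_phantom,
)
from tps3d.image import ShapeMismatchError
from tps3d.nuclei import NucleusLabelMap


def label_map_with_centroids(centroids_um, shape=(64, 64)):
    labels = np.zeros(shape, dtype=np.int32)
    for i, (y, x) in enumerate(centroids_um, start=1):
        labels[int(y), int(x)] = i
    return NucleusLabelMap(
        plane_index=0,
        labels=labels,
        centroids_um=np.asarray(centroids_um, dtype=float),
        areas_px=np.ones(len(centroids_um), dtype=int),
    )


@pytest.fixture(scope="module")
def half_plane_phantom():
    # thin slab so every plane sees the full cell density (as in tissue);
    # dense tumor confined to the left half (x < 128), right half empty
    cfg = PhantomConfig(
        field_size_um=(256.0, 256.0),
        depth_um=20.0,
        n_cells=90,
        tumor_fraction=1.0,
        tumor_region_um=(0.0, 256.0, 0.0, 128.0),
        seed=21,
    )
    return (cfg, *generate_phantom(cfg))


class TestBaselineMasker:
    def test_half_plane_iou(self, half_plane_phantom):
        cfg, volume, truth = half_plane_phantom
        z = volume.n_planes // 2
        mask = BaselineMasker().predict(volume.multichannel_plane(z), (1.0, 1.0), z).mask
        # the generating region, rasterized from the phantom geometry: the
        # tumor box intersected with the placement margin
        m = cfg.max_radius_um + cfg.membrane_thickness_um + 1.0
        region = np.zeros(mask.shape, dtype=bool)
        region[int(np.ceil(m)) : int(256 - m), int(np.ceil(m)) : 128] = True
        iou = (mask & region).sum() / (mask | region).sum()
        assert iou >= 0.8

    def test_empty_plane_all_false(self):
        mask = BaselineMasker().predict(np.zeros((3, 64, 64)), (1.0, 1.0), 0)
        assert not mask.mask.any()

    def test_dense_plane_covers_centroid_hull(self):
        from scipy.spatial import ConvexHull, Delaunay

        cfg = PhantomConfig(field_size_um=(160.0, 160.0), depth_um=20.0,
                            n_cells=70, tumor_fraction=1.0, seed=8)
        volume, truth = generate_phantom(cfg)
        z = volume.n_planes // 2
        mask = BaselineMasker().predict(volume.multichannel_plane(z), (1.0, 1.0), z).mask
        pts = truth.cells[["y_um", "x_um"]].to_numpy()
        hull = Delaunay(pts[ConvexHull(pts).vertices])
        yy, xx = np.mgrid[: mask.shape[0], : mask.shape[1]]
        inside = hull.find_simplex(np.c_[yy.ravel(), xx.ravel()]) >= 0
        covered = mask.ravel()[inside].mean()
        assert covered >= 0.95

    def test_deterministic(self, small_phantom):
        volume, _ = small_phantom
        plane = volume.multichannel_plane(5)
        m1 = BaselineMasker().predict(plane, (1.0, 1.0), 5).mask
        m2 = BaselineMasker().predict(plane, (1.0, 1.0), 5).mask
        assert np.array_equal(m1, m2)


class TestAssignTumorStatus:
    def test_all_true_and_all_false_masks(self):
        lm = label_map_with_centroids([(10.0, 10.0), (30.0, 50.0)])
        all_true = TumorMask(0, np.ones((64, 64), dtype=bool))
        all_false = TumorMask(0, np.zeros((64, 64), dtype=bool))
        assert assign_tumor_status(lm, all_true).all()
        assert not assign_tumor_status(lm, all_false).any()

    def test_half_mask_centroid_rule(self):
        lm = label_map_with_centroids([(32.0, 10.0), (32.0, 50.0)])
        mask = np.zeros((64, 64), dtype=bool)
        mask[:, :32] = True
        flags = assign_tumor_status(lm, TumorMask(0, mask))
        assert flags.tolist() == [True, False]

    def test_shape_mismatch_raises(self):
        lm = label_map_with_centroids([(10.0, 10.0)])
        with pytest.raises(ShapeMismatchError):
            assign_tumor_status(lm, TumorMask(0, np.zeros((32, 32), dtype=bool)))

    def test_idempotent_and_order_independent(self):
        pts = [(5.0, 7.0), (20.0, 41.0), (50.0, 12.0)]
        mask = TumorMask(0, np.random.default_rng(3).random((64, 64)) > 0.5)
        lm = label_map_with_centroids(pts)
        ref = assign_tumor_status(lm, mask)
        assert np.array_equal(ref, assign_tumor_status(lm, mask))
        perm = [2, 0, 1]
        lm_perm = label_map_with_centroids([pts[i] for i in perm])
        assert np.array_equal(assign_tumor_status(lm_perm, mask), ref[perm])


class TestMaskTypes:
    def test_mask_must_be_boolean(self):
        with pytest.raises(ValueError):
            TumorMask(0, np.zeros((8, 8), dtype=np.uint8))

    def test_constant_masker(self):
        m = ConstantMasker().predict(np.zeros((3, 8, 8)))
        assert m.mask.all() and m.mask.shape == (8, 8)


class TestCellInstanceAccuracy:
    def test_perfect_agreement(self):
        primary, overall = cell_instance_accuracy([True, False, True], [True, False, True])
        assert primary == 1.0 and overall == 1.0

    def test_nine_of_ten(self):
        pred = [True] * 10 + [False] * 5
        truth = [True] * 9 + [False] * 6
        primary, _ = cell_instance_accuracy(pred, truth)
        assert primary == pytest.approx(0.9)

    def test_undefined_when_no_predictions(self):
        with pytest.raises(UndefinedMetricError):
            cell_instance_accuracy([False, False], [True, False])

    def test_range_and_symmetric_component(self):
        pred = [True, True, False, False]
        truth = [True, False, True, False]
        primary, overall = cell_instance_accuracy(pred, truth)
        assert 0.0 <= primary <= 1.0
        assert overall == pytest.approx(0.5)
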