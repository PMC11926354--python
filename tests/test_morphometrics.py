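"""Morphometric parameters: closed-form shapes, oracles, invariances."""

import math

import numpy as np
import pytest

from mgmorph.imaging_io import CellRecord, encode_rle
from mgmorph.morphometrics import (
    ALL_FEATURES,
    CLASSIFIER_FEATURES,
    FEATURE_REGISTRY,
    brenner_focus,
    extract_soma,
    fractal_features,
    intercellular_distances,
    shape_features,
)


def disk(shape, cy, cx, r):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


class TestRegistry:
    def test_25_classifier_inputs_28_parameters(self):
        assert len(CLASSIFIER_FEATURES) == 25
        named = {f.name for f in FEATURE_REGISTRY}
        # 28 = 25 classifier inputs + mDS + mDP + FM; hull_span is the
        # documented redundant extra
        assert {"mDS", "mDP", "FM", "hull_span"} <= named
        assert len(ALL_FEATURES) == 29


class TestSoma:
    def test_solid_disk_soma_nearly_whole_cell(self):
        m = disk((64, 64), 32, 32, 20)
        soma = extract_soma(m)
        assert soma.sum() >= 0.9 * m.sum()
        assert (soma & ~m).sum() == 0

    def test_soma_subset_and_contains_distance_argmax(self, rng):
        from scipy import ndimage

        for _ in range(10):
            m = disk((80, 80), 40, 40, int(rng.integers(6, 18)))
            # add a random process
            y = int(rng.integers(10, 70))
            m[y, 10:70] = True
            soma = extract_soma(m)
            assert not (soma & ~m).any()
            d = ndimage.distance_transform_edt(m)
            assert soma[np.unravel_index(np.argmax(d), d.shape)]

    def test_soma_much_smaller_than_ramified_cell(self):
        # soma blob + long thin processes: SArea well below CArea
        m = disk((160, 160), 80, 80, 6)
        m[80, 10:150] = True
        m[10:150, 80] = True
        soma = extract_soma(m)
        assert soma.sum() < 0.5 * m.sum()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_soma(np.zeros((8, 8), bool))


class TestShapeFeatures:
    def test_solid_square_identities(self):
        m = np.zeros((120, 120), bool)
        m[10:110, 10:110] = True
        f = shape_features(m, extract_soma(m), 1.0)
        assert f["CArea"] == 10000
        assert f["CHArea"] == 10000
        assert f["DEN"] == pytest.approx(1.0)
        assert f["extent"] == pytest.approx(1.0)
        # marching-squares perimeter of an n-px square is close to 4n
        assert f["cell_circ"] == pytest.approx(4 * math.pi * 10000 / 400 ** 2,
                                               rel=0.03)

    def test_disk_circularity_near_one(self):
        m = disk((128, 128), 64, 64, 50)
        f = shape_features(m, extract_soma(m), 1.0)
        assert 0.95 <= f["cell_circ"] <= 1.05

    def test_order_relations_on_synthetic_cells(self, featurized_scene):
        _, annset = featurized_scene
        for c in annset.cells:
            f = c.features
            assert f["CArea"] <= f["CHArea"] + 1e-9
            # discrete contour estimation allows ~1% slack on convex cells
            assert f["CPM"] >= 0.98 * f["CHPM"]
            assert f["min_span"] <= f["max_span"] + 1e-9
            assert f["DEN"] <= 1 + 1e-9
            assert f["soma_fraction"] <= 1 + 1e-9
            assert f["CHSR"] >= 1 - 1e-9
            assert 0 < f["cell_circ"] <= 1.05

    def test_pixel_counting_oracle(self, rng):
        # CArea, CHArea, Feret diameters vs brute force on random blobs
        from scipy import ndimage
        from skimage import morphology as skmorph

        for _ in range(20):
            m = np.zeros((96, 96), bool)
            for _ in range(int(rng.integers(1, 4))):
                m |= disk((96, 96), *rng.integers(25, 70, 2), int(rng.integers(5, 14)))
            lab, _ = ndimage.label(m)
            m = lab == 1
            if m.sum() < 30:
                continue
            f = shape_features(m, extract_soma(m), 1.0)
            assert f["CArea"] == m.sum()
            assert f["CHArea"] == skmorph.convex_hull_image(m).sum()
            pts = np.column_stack(np.nonzero(m)).astype(float)
            d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
            assert f["max_span"] == pytest.approx(max(d.max(), 1.0), rel=0.01)

    def test_scale_invariance(self):
        m = disk((100, 100), 50, 50, 30)
        m[50, 10:90] = True
        soma = extract_soma(m)
        f1 = shape_features(m, soma, 1.0)
        f2 = shape_features(m, soma, 2.0)
        assert f2["CArea"] == pytest.approx(4 * f1["CArea"])
        assert f2["CPM"] == pytest.approx(2 * f1["CPM"])
        for ratio in ("DEN", "CHSR", "cell_circ", "eccentricity", "extent"):
            assert f2[ratio] == pytest.approx(f1[ratio])

    def test_translation_and_rot90_invariance(self):
        m = np.zeros((120, 120), bool)
        m |= disk((120, 120), 50, 40, 12)
        m[50, 20:100] = True
        base = shape_features(m, extract_soma(m), 1.0)
        shifted = np.roll(m, (7, 13), axis=(0, 1))
        rot = np.rot90(m)
        for other in (shifted, rot):
            f = shape_features(other, extract_soma(other), 1.0)
            for k in ("CArea", "CHArea", "CPM", "max_span", "min_span", "DEN"):
                assert f[k] == pytest.approx(base[k], rel=1e-6)


class TestFractal:
    def test_filled_square_fd_two(self):
        m = np.ones((128, 128), bool)
        fd, lc, std_lc = fractal_features(m)
        assert fd == pytest.approx(2.0, abs=0.05)
        assert lc == pytest.approx(1.0, abs=0.01)
        assert std_lc == pytest.approx(0.0, abs=0.01)

    def test_line_fd_one(self):
        m = np.zeros((1, 128), bool)
        m[0, :] = True
        fd, _, _ = fractal_features(m)
        assert fd == pytest.approx(1.0, abs=0.05)

    def test_tiny_mask_flagged_undefined(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        fd, lc, std_lc = fractal_features(m)
        assert np.isnan(fd)

    def test_branched_mask_fd_between_line_and_plane(self, small_scene):
        _, _, truth = small_scene
        from mgmorph.imaging_io import global_mask

        for c in truth.cells:
            fd, lc, _ = fractal_features(global_mask(c, truth.image_shape))
            assert 0.9 <= fd <= 2.05
            assert lc >= 1.0 - 1e-9


class TestBrenner:
    def test_constant_patch_zero(self):
        assert brenner_focus(np.full((32, 32), 100, np.uint8), (0, 0, 32, 32)) == 0.0

    def test_unit_ramp_gives_four(self):
        ramp = np.tile(np.arange(64, dtype=np.uint8), (64, 1))
        assert brenner_focus(ramp, (0, 0, 64, 64), expand=1.0) == pytest.approx(4.0)

    def test_blur_strictly_decreases_fm(self, small_scene):
        from scipy import ndimage

        _, image, truth = small_scene
        for sigma_pair in [(0, 1), (1, 2), (2, 4)]:
            blurred = [ndimage.gaussian_filter(image.gray.astype(float), s)
                       .astype(np.uint8) if s else image.gray
                       for s in sigma_pair]
            for c in truth.cells:
                f_sharp = brenner_focus(blurred[0], c.box)
                f_blur = brenner_focus(blurred[1], c.box)
                assert f_blur < f_sharp

    def test_tiny_box_rejected(self):
        with pytest.raises(ValueError):
            brenner_focus(np.zeros((32, 32), np.uint8), (0, 0, 2, 2))


class TestIntercellular:
    def _two_disks(self, d_px):
        shape = (256, 256)
        cells = []
        for i, cx in enumerate([100, 100 + d_px]):
            m = disk(shape, 100, cx, 10)
            ys, xs = np.nonzero(m)
            cells.append(CellRecord(i + 1, encode_rle(m),
                                    (int(xs.min()), int(ys.min()),
                                     int(xs.max()) + 1, int(ys.max()) + 1),
                                    provenance={"crop_origin": (int(xs.min()), int(ys.min())),
                                                "soma_centroid": (100.0, float(cx))}))
        return shape, cells

    def test_two_disks_mds(self):
        shape, cells = self._two_disks(50)
        out = intercellular_distances(cells, shape, 0.464)
        for cid in (1, 2):
            assert out[cid][0] == pytest.approx(50 * 0.464)  # 23.2 um

    def test_touching_masks_mdp_zero(self):
        shape, cells = self._two_disks(19)  # overlapping disks of r=10
        out = intercellular_distances(cells, shape, 0.464)
        assert out[1][1] == 0.0

    def test_single_cell_undefined(self):
        shape, cells = self._two_disks(50)
        out = intercellular_distances(cells[:1], shape, 0.464)
        assert np.isnan(out[1][0]) and np.isnan(out[1][1])

    def test_three_collinear_equidistant(self):
        shape = (256, 512)
        cells = []
        for i, cx in enumerate([100, 200, 300]):
            m = disk(shape, 128, cx, 8)
            ys, xs = np.nonzero(m)
            cells.append(CellRecord(i + 1, encode_rle(m),
                                    (int(xs.min()), int(ys.min()),
                                     int(xs.max()) + 1, int(ys.max()) + 1),
                                    provenance={"crop_origin": (int(xs.min()), int(ys.min())),
                                                "soma_centroid": (128.0, float(cx))}))
        out = intercellular_distances(cells, shape, 1.0)
        assert out[2][0] == pytest.approx(100.0)  # middle cell: both at spacing


class TestFeaturize:
    def test_all_cells_complete(self, featurized_scene):
        _, annset = featurized_scene
        for c in annset.cells:
            if c.area_um2(annset.pixel_size) < 30:
                continue
            for name in CLASSIFIER_FEATURES + ["mDS", "mDP", "FM"]:
                assert name in c.features
                assert not np.isnan(c.features[name]), (c.id, name)
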