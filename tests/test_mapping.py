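"""Activation score, region tables, map rendering, 3D interpolation."""

import numpy as np
import pandas as pd
import pytest

from mgmorph.classification import MORPHOTYPE_COLORS, MORPHOTYPES
from mgmorph.imaging_io import AnnotationSet, CellRecord, SlideImage, encode_rle, global_mask
from mgmorph.mapping_quant import (
    ACTIVATION_WEIGHTS,
    RegionLabelMap,
    activation_score,
    interpolate_3d,
    region_stats,
    render_morphotype_map,
    render_parameter_map,
)


class TestActivationScore:
    def test_pure_populations(self):
        assert activation_score({"R": 100}) == 0.0
        assert activation_score({"A": 100}) == 1.0
        assert activation_score({"RD": 10}) == 0.0

    def test_mixed_hand_computed(self):
        counts = {"R": 50, "H": 10, "B": 20, "A": 10, "RD": 5, "HR": 5}
        # (0.33*10 + 0.66*20 + 1*10 + 0.66*5) / 100
        assert activation_score(counts) == pytest.approx(0.298)

    def test_zero_total_undefined(self):
        assert np.isnan(activation_score({}))

    def test_convex_bounds_and_scale_invariance(self, rng):
        for _ in range(1000):
            counts = dict(zip(MORPHOTYPES, rng.integers(0, 50, 6)))
            if sum(counts.values()) == 0:
                continue
            s = activation_score(counts)
            assert 0.0 <= s <= 1.0
            scaled = {k: 3 * v for k, v in counts.items()}
            assert activation_score(scaled) == pytest.approx(s)

    def test_moving_one_cell_r_to_a_raises_score(self):
        counts = {"R": 40, "H": 10, "B": 10, "A": 10, "RD": 5, "HR": 5}
        total = sum(counts.values())
        s0 = activation_score(counts)
        counts2 = dict(counts, R=39, A=11)
        assert activation_score(counts2) == pytest.approx(s0 + 1.0 / total)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            activation_score({"R": -1, "A": 2})


def _toy_annset(positions, shape=(200, 200), px=10.0):
    """Cells as 10x10 squares; px=10 um/px so each region is easy to size."""
    annset = AnnotationSet(shape, px)
    for i, (y, x, cls) in enumerate(positions):
        m = np.zeros(shape, bool)
        m[y:y + 10, x:x + 10] = True
        c = CellRecord(i + 1, encode_rle(m), (x, y, x + 10, y + 10))
        c.morphotype = cls
        c.provenance["crop_origin"] = (x, y)
        c.provenance["soma_centroid"] = (y + 5.0, x + 5.0)
        c.features = {"CArea": float(100 * (i + 1))}
        annset.cells.append(c)
    return annset


class TestRegionStats:
    def test_density_arithmetic(self):
        # one region of 100x100 px at 10 um/px = 1 mm^2 with 3 cells
        labels = np.zeros((200, 200), np.int32)
        labels[:100, :100] = 1
        lm = RegionLabelMap(labels, {1: "ctx"}, 10.0)
        annset = _toy_annset([(10, 10, "R"), (30, 30, "A"), (50, 50, "A")])
        t = region_stats(annset, lm)
        row = t[t["region"] == "ctx"].iloc[0]
        assert row["area_mm2"] == pytest.approx(1.0)
        assert row["total_count"] == 3
        assert row["density_total"] == pytest.approx(3.0)
        assert row["activation_score"] == pytest.approx(2 / 3)

    def test_empty_region_zero_density_undefined_score(self):
        labels = np.ones((100, 100), np.int32)
        labels[:50] = 2
        lm = RegionLabelMap(labels, {1: "a", 2: "b"}, 10.0)
        annset = _toy_annset([(60, 60, "R")], shape=(100, 100))
        t = region_stats(annset, lm)
        row = t[t["region"] == "b"].iloc[0]
        assert row["total_count"] == 0
        assert row["density_total"] == 0.0
        assert np.isnan(row["activation_score"])

    def test_count_conservation_with_unparcellated(self):
        labels = np.zeros((200, 200), np.int32)
        labels[:100, :100] = 1
        lm = RegionLabelMap(labels, {1: "ctx"}, 10.0)
        annset = _toy_annset([(10, 10, "R"), (150, 150, "A"), (120, 30, "B")])
        t = region_stats(annset, lm)
        assert t["total_count"].sum() == 3
        assert t[t["region"] == "unparcellated"].iloc[0]["total_count"] == 2

    def test_unfocused_cells_excluded(self):
        labels = np.ones((200, 200), np.int32)
        lm = RegionLabelMap(labels, {1: "ctx"}, 10.0)
        annset = _toy_annset([(10, 10, "R"), (30, 30, "A")])
        annset.cells[1].unfocused = True
        t = region_stats(annset, lm)
        assert t[t["region"] == "ctx"].iloc[0]["total_count"] == 1


class TestRendering:
    def _scene(self):
        annset = _toy_annset([(10, 10, "R"), (40, 40, "R"), (80, 80, "A")],
                             shape=(128, 128))
        img = SlideImage(np.full((128, 128), 200, np.uint8), 10.0)
        return img, annset

    def test_only_ramified_only_green(self):
        annset = _toy_annset([(10, 10, "R"), (40, 40, "R")], shape=(128, 128))
        img = SlideImage(np.full((128, 128), 200, np.uint8), 10.0)
        out = render_morphotype_map(img, annset)
        green = MORPHOTYPE_COLORS["R"]
        colored = np.any(out != out[0, 0], axis=-1)
        assert np.all(out[colored] == green)

    def test_unfocused_rendered_gray(self):
        img, annset = self._scene()
        annset.cells[2].unfocused = True
        out = render_morphotype_map(img, annset)
        m = global_mask(annset.cells[2], annset.image_shape)
        assert np.all(out[m] == MORPHOTYPE_COLORS["UF"])

    def test_overlay_pixel_counts_match_masks(self):
        img, annset = self._scene()
        out = render_morphotype_map(img, annset)
        n_red = int(np.all(out == MORPHOTYPE_COLORS["A"], axis=-1).sum())
        assert n_red == global_mask(annset.cells[2], annset.image_shape).sum()

    def test_parameter_map_extremes_and_range(self):
        img, annset = self._scene()
        out, (vmin, vmax) = render_parameter_map(annset, "CArea", img,
                                                 value_range=(100.0, 300.0))
        assert (vmin, vmax) == (100.0, 300.0)
        from matplotlib import colormaps

        jet = colormaps["jet"]
        lo = tuple(int(round(255 * c)) for c in jet(0.0)[:3])
        hi = tuple(int(round(255 * c)) for c in jet(1.0)[:3])
        m1 = global_mask(annset.cells[0], annset.image_shape)
        m3 = global_mask(annset.cells[2], annset.image_shape)
        assert tuple(out[m1][0]) == lo
        assert tuple(out[m3][0]) == hi

    def test_all_equal_values_single_color(self):
        img, annset = self._scene()
        for c in annset.cells:
            c.features["CArea"] = 42.0
        out, _ = render_parameter_map(annset, "CArea", img)
        cols = {tuple(out[global_mask(c, annset.image_shape)][0])
                for c in annset.cells}
        assert len(cols) == 1

    def test_unknown_parameter_rejected(self):
        img, annset = self._scene()
        with pytest.raises(KeyError):
            render_parameter_map(annset, "nope", img)


def _table(region_density):
    rows = []
    for region, dens in region_density.items():
        row = {"region": region, "density_total": dens,
               "activation_score": 0.5}
        for c in MORPHOTYPES:
            row[f"density_{c}"] = dens / 6
        rows.append(row)
    return pd.DataFrame(rows)


class TestInterpolate3D:
    def test_midpoint_linear(self):
        tables = [_table({"ctx": 100.0}), _table({"ctx": 200.0})]
        vg = interpolate_3d(tables, [0.0, 1.0], query_positions=[0.5])
        ci = vg.channels.index("density_total")
        assert vg.values[0, 0, ci] == pytest.approx(150.0)

    def test_slice_position_exact(self):
        tables = [_table({"ctx": 100.0}), _table({"ctx": 200.0})]
        vg = interpolate_3d(tables, [0.0, 1.0], query_positions=[0.0, 1.0])
        ci = vg.channels.index("density_total")
        assert vg.values[0, 0, ci] == pytest.approx(100.0)
        assert vg.values[0, 1, ci] == pytest.approx(200.0)

    def test_constant_everywhere(self):
        tables = [_table({"ctx": 120.0})] * 3
        vg = interpolate_3d(tables, [0.0, 0.5, 1.0], step_mm=0.1)
        ci = vg.channels.index("density_total")
        assert np.allclose(vg.values[0, :, ci], 120.0)

    def test_bounded_by_neighbors(self):
        tables = [_table({"ctx": 100.0}), _table({"ctx": 300.0})]
        vg = interpolate_3d(tables, [0.0, 1.0], step_mm=0.05)
        ci = vg.channels.index("density_total")
        assert vg.values[0, :, ci].min() >= 100.0 - 1e-9
        assert vg.values[0, :, ci].max() <= 300.0 + 1e-9

    def test_thickness_converts_to_volumetric(self):
        tables = [_table({"ctx": 100.0}), _table({"ctx": 100.0})]
        vg = interpolate_3d(tables, [0.0, 1.0], query_positions=[0.5],
                            thickness_mm=0.05)
        ci = vg.channels.index("density_total")
        assert vg.values[0, 0, ci] == pytest.approx(2000.0)  # cells/mm^3

    def test_mismatched_regions_warn_and_intersect(self):
        tables = [_table({"ctx": 100.0, "th": 50.0}), _table({"ctx": 200.0})]
        with pytest.warns(UserWarning, match="skipped"):
            vg = interpolate_3d(tables, [0.0, 1.0], step_mm=0.5)
        assert vg.regions == ["ctx"]

    def test_non_monotonic_rejected(self):
        tables = [_table({"ctx": 1.0})] * 3
        with pytest.raises(ValueError):
            interpolate_3d(tables, [0.0, 1.0, 0.5])

    def test_save_round_trip(self, tmp_path):
        tables = [_table({"ctx": 100.0}), _table({"ctx": 200.0})]
        vg = interpolate_3d(tables, [0.0, 1.0], step_mm=0.25)
        vg.save(tmp_path / "vol")
        df = pd.read_csv(tmp_path / "vol.csv")
        assert len(df) == len(vg.positions)
        assert df["density_total"].iloc[0] == pytest.approx(100.0)
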