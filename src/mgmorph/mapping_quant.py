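"""Region-wise quantification and 2D/3D activation maps.

The microglial activation score of a region is the weighted frequency of
its morphotypes,

    MA = (0*R + 0.33*H + 0.66*B + 1*A + 0*RD + 0.66*HR) / total,

a convex combination in [0, 1]: 0 means a fully ramified (resting)
population, 1 a fully ameboid (maximally activated) one; rod cells count
as resting and hypertrophic rods as moderately activated, covering white
matter. Densities are cell counts divided by region areas; unfocused
cells are excluded from all quantification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mgmorph.classification import MORPHOTYPES, MORPHOTYPE_COLORS, UNFOCUSED
from mgmorph.imaging_io import AnnotationSet, CellRecord, SlideImage, global_mask
from mgmorph.morphometrics import CLASSIFIER_FEATURES, extract_soma

ACTIVATION_WEIGHTS = {"R": 0.0, "H": 0.33, "B": 0.66, "A": 1.0,
                      "RD": 0.0, "HR": 0.66}


def activation_score(counts: dict[str, float]) -> float:
    """Microglial activation score of a morphotype count vector.

    Returns NaN when the total count is zero (score undefined).
    """
    total = float(sum(counts.get(c, 0) for c in MORPHOTYPES))
    if any(counts.get(c, 0) < 0 for c in MORPHOTYPES):
        raise ValueError("negative counts")
    if total == 0:
        return float("nan")
    return sum(ACTIVATION_WEIGHTS[c] * counts.get(c, 0)
               for c in MORPHOTYPES) / total


# ---------------------------------------------------------------------------
# region tables


@dataclass
class RegionLabelMap:
    """Integer region labels aligned to a slide; label 0 = background."""

    labels: np.ndarray
    names: dict[int, str]
    pixel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label raster must be 2D")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = set(self.names) - present - {0}
        for m in sorted(missing):
            self.names[m] = self.names[m]  # kept; flagged empty in the table


UNPARCELLATED = "unparcellated"


def region_stats(annset: AnnotationSet, labelmap: RegionLabelMap,
                 parameters: list[str] | None = None) -> pd.DataFrame:
    """Per-region counts, densities, activation score, parameter summaries.

    Cells are assigned to the region under their soma centroid; a cell
    over background (label 0) goes to the "unparcellated" bucket.
    Unfocused (UF) cells are excluded. Densities are cells/mm^2 using the
    label-raster pixel area.
    """
    params = parameters if parameters is not None else \
        [p for p in CLASSIFIER_FEATURES]
    px_mm2 = (labelmap.pixel_size ** 2) / 1e6
    region_ids = sorted(set(np.unique(labelmap.labels).tolist()) - {0})
    areas = {rid: float(np.count_nonzero(labelmap.labels == rid)) * px_mm2
             for rid in region_ids}
    buckets: dict[object, list[CellRecord]] = {rid: [] for rid in region_ids}
    buckets[UNPARCELLATED] = []
    h, w = labelmap.labels.shape
    for cell in annset.cells:
        if cell.unfocused:
            continue
        cy, cx = cell.provenance.get("soma_centroid", (None, None))
        if cy is None:
            m = global_mask(cell, annset.image_shape)
            soma = extract_soma(m)
            ys, xs = np.nonzero(soma)
            cy, cx = float(ys.mean()), float(xs.mean())
        iy, ix = int(round(cy)), int(round(cx))
        rid = int(labelmap.labels[iy, ix]) if 0 <= iy < h and 0 <= ix < w else 0
        buckets[rid if rid in buckets else UNPARCELLATED].append(cell)
    rows = []
    for rid in region_ids + [UNPARCELLATED]:
        cells = buckets[rid]
        name = labelmap.names.get(rid, str(rid)) if rid != UNPARCELLATED else rid
        area = areas.get(rid, float("nan"))
        counts = {c: sum(1 for x in cells if x.morphotype == c)
                  for c in MORPHOTYPES}
        total = sum(counts.values())
        row = {"region_id": rid if rid != UNPARCELLATED else 0,
               "region": name, "area_mm2": area, "total_count": total,
               "activation_score": activation_score(counts)}
        for c in MORPHOTYPES:
            row[f"count_{c}"] = counts[c]
            row[f"density_{c}"] = counts[c] / area if area and area > 0 else float("nan")
        row["density_total"] = total / area if area and area > 0 else float("nan")
        for p in params:
            vals = np.array([x.features.get(p, np.nan) for x in cells], dtype=float)
            vals = vals[~np.isnan(vals)]
            row[f"{p}_mean"] = float(vals.mean()) if vals.size else float("nan")
            row[f"{p}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def write_region_table(table: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV export of a region table."""
    table.to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# map rendering


def render_morphotype_map(image: SlideImage, annset: AnnotationSet,
                          dim: float = 0.5) -> np.ndarray:
    """Class-colored cell overlay on the dimmed source image.

    Each mask is filled with its morphotype color; unfocused cells are
    gray. Returns an (H, W, 3) uint8 raster.
    """
    base = (image.gray.astype(np.float64) * dim).astype(np.uint8)
    out = np.stack([base] * 3, axis=-1)
    for cell in annset.cells:
        color = MORPHOTYPE_COLORS[UNFOCUSED] if cell.unfocused else \
            MORPHOTYPE_COLORS.get(cell.morphotype, (255, 255, 255))
        m = global_mask(cell, annset.image_shape)
        out[m] = color
    return out


def render_parameter_map(annset: AnnotationSet, parameter: str,
                         image: SlideImage | None = None,
                         value_range: tuple[float, float] | None = None,
                         dim: float = 0.5) -> tuple[np.ndarray, tuple[float, float]]:
    """Cells colored by a morphometric parameter through the jet colormap.

    The color range defaults to the 1st-99th percentile of the values
    (the parameter's dynamic range); an explicit ``value_range`` is used
    verbatim. Returns the RGB raster and the (vmin, vmax) actually used.
    """
    from matplotlib import colormaps

    if annset.cells and parameter not in annset.cells[0].features:
        raise KeyError(f"unknown parameter '{parameter}'")
    vals = np.array([c.features.get(parameter, np.nan) for c in annset.cells],
                    dtype=float)
    finite = vals[~np.isnan(vals)]
    if value_range is not None:
        vmin, vmax = map(float, value_range)
    elif finite.size:
        vmin, vmax = (float(np.percentile(finite, 1)),
                      float(np.percentile(finite, 99)))
    else:
        vmin, vmax = 0.0, 1.0
    if vmax <= vmin:
        vmax = vmin + 1e-12
    cmap = colormaps["jet"]
    h, w = annset.image_shape
    if image is not None:
        base = (image.gray.astype(np.float64) * dim).astype(np.uint8)
        out = np.stack([base] * 3, axis=-1)
    else:
        out = np.zeros((h, w, 3), dtype=np.uint8)
    for cell, v in zip(annset.cells, vals):
        if np.isnan(v):
            color = MORPHOTYPE_COLORS[UNFOCUSED]
        else:
            t = min(max((v - vmin) / (vmax - vmin), 0.0), 1.0)
            color = tuple(int(round(255 * c)) for c in cmap(t)[:3])
        out[global_mask(cell, annset.image_shape)] = color
    return out, (vmin, vmax)


def save_png(raster: np.ndarray, path: str | Path) -> None:
    from PIL import Image as PILImage

    PILImage.fromarray(raster).save(Path(path))


# ---------------------------------------------------------------------------
# 3D interpolation


@dataclass
class VolumeGrid:
    """Per-region densities interpolated along the slice axis.

    ``values`` has shape (n_regions, n_positions, n_channels) with
    channels = per-morphotype densities, total density and activation
    score; areal densities (cells/mm^2) are converted to volumetric ones
    (cells/mm^3) by dividing by ``thickness_mm`` (the effective section
    thickness; an atlas-volume normalisation can be folded in here).
    """

    regions: list[str]
    positions: np.ndarray              # mm, strictly increasing query grid
    channels: list[str]
    values: np.ndarray

    def save(self, prefix: str | Path) -> None:
        """Plain-text export: CSV of flattened values + JSON sidecar."""
        prefix = Path(prefix)
        n_r, n_p, n_c = self.values.shape
        flat = self.values.reshape(n_r * n_p, n_c)
        df = pd.DataFrame(flat, columns=self.channels)
        df.insert(0, "position_mm", np.tile(self.positions, n_r))
        df.insert(0, "region", np.repeat(self.regions, n_p))
        df.to_csv(prefix.with_suffix(".csv"), index=False, float_format="%.6g")
        sidecar = {"regions": self.regions, "channels": self.channels,
                   "positions_mm": self.positions.tolist(),
                   "shape": [n_r, n_p, n_c]}
        prefix.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True))


def interpolate_3d(tables: list[pd.DataFrame], positions: list[float],
                   step_mm: float = 0.1, thickness_mm: float = 1.0,
                   query_positions: np.ndarray | None = None) -> VolumeGrid:
    """Linear inter-slice interpolation of per-region class densities.

    ``tables`` are per-slice region tables at strictly monotonic slice
    ``positions`` (mm). Regions present on every slice are interpolated;
    regions missing from some slice are dropped with a warning. At a
    queried slice position the slice's own values are returned exactly;
    between slices values are linear, hence bounded by their neighbours.
    """
    import warnings

    if len(tables) < 2:
        raise ValueError("need at least two slices to interpolate")
    pos = np.asarray(positions, dtype=float)
    d = np.diff(pos)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("slice positions must be strictly monotonic")
    if np.all(d < 0):
        pos = pos[::-1]
        tables = list(tables)[::-1]
    region_sets = [set(t["region"]) - {UNPARCELLATED} for t in tables]
    shared = sorted(set.intersection(*region_sets))
    dropped = sorted(set.union(*region_sets) - set(shared))
    if dropped:
        warnings.warn(f"regions not on every slice, skipped: {dropped}")
    channels = [f"density_{c}" for c in MORPHOTYPES] + ["density_total",
                                                        "activation_score"]
    if query_positions is not None:
        query = np.asarray(query_positions, dtype=float)
    else:
        query = np.arange(pos[0], pos[-1] + 0.5 * step_mm, step_mm)
        query[-1] = min(query[-1], pos[-1])
    values = np.zeros((len(shared), len(query), len(channels)))
    for ri, region in enumerate(shared):
        for ci, ch in enumerate(channels):
            y = np.array([float(t.loc[t["region"] == region, ch].iloc[0])
                          for t in tables])
            v = np.interp(query, pos, y)
            if ch.startswith("density"):
                v = v / thickness_mm
            values[ri, :, ci] = v
    return VolumeGrid(shared, query, channels, values)
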