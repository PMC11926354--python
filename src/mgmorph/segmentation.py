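"""Cell detection/segmentation backends and rule-based mask reconciliation.

The detector/segmenter is pluggable: any object implementing
:class:`SegmenterBackend` can stand behind the pipeline (e.g. wrappers
around trained neural models). Two backends ship with the package:

* :class:`ThresholdBackend` — a classical adaptive-threshold proposal
  generator plus Otsu segmentation, usable on dark-on-light staining.
* :class:`OracleBackend` — ground-truth passthrough for testing: its
  detections are the true boxes and its masks the true masks.

Reconciliation of a raw multi-component mask follows fixed rules: the
largest connected component is the cell body; other components closer
than 3.25 um are attached as processes; non-attached components larger
than 107.65 um^2 are spawned as separate candidate cells; the rest is
debris. Instances overlapping with mask IoU > 0.7 are merged
(transitively), and A/B tile duplicates are resolved in favour of unit A
for interior cells and unit B for boundary-crossing cells.
"""

from __future__ import annotations

import warnings
from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters

from mgmorph.config import PipelineConfig
from mgmorph.evaluation import iou
from mgmorph.imaging_io import (
    AnnotationSet,
    Box,
    CellRecord,
    SlideImage,
    TileGrid,
    _tight_record,
    encode_rle,
    global_mask,
    make_tiles,
)


@dataclass
class Detection:
    """One candidate cell in tile-local coordinates."""

    box: Box
    score: float
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass
class CropContext:
    """Provenance handed to a backend's segment() call."""

    origin: tuple[int, int]            # global (x, y) of the crop
    detection: Detection | None = None
    pixel_size: float = 0.464


class SegmenterBackend(ABC):
    """Plug-in contract: deterministic detect + segment."""

    @abstractmethod
    def detect(self, tile: np.ndarray, *,
               origin: tuple[int, int] = (0, 0)) -> list[Detection]:
        """Propose cell boxes (tile-local, half-open) with Pr(cell) scores."""

    @abstractmethod
    def segment(self, crop: np.ndarray, context: CropContext) -> np.ndarray:
        """Binary mask of putative cell pixels within the crop."""


# ---------------------------------------------------------------------------
# classical fallback backend


def _drop_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Remove connected components with fewer than ``min_px`` pixels."""
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def fallback_detect(tile: np.ndarray, min_blob_px: int = 40,
                    smooth_sigma: float = 1.0) -> list[Detection]:
    """Adaptive-threshold blob proposals on dark-on-light staining.

    The stain-intensity view (255 - gray) is smoothed, Otsu-thresholded,
    despeckled, and each connected component becomes one proposal box;
    the score is the component's contrast against the tile background,
    normalised to [0, 1].
    """
    tile = np.asarray(tile)
    if tile.ndim == 3:
        tile = SlideImage(tile, 1.0).gray
    signal = (255 - tile.astype(np.int16)).astype(np.uint8)
    if int(signal.max()) - int(signal.min()) < 20:
        return []
    sm = ndimage.gaussian_filter(signal.astype(np.float64), smooth_sigma)
    thr = filters.threshold_otsu(sm)
    binary = _drop_small(sm > thr, min_blob_px)
    if not binary.any():
        return []
    labels, n = ndimage.label(binary)
    background = float(np.median(signal[~binary]))
    dets = []
    for sl in ndimage.find_objects(labels):
        comp = labels[sl] > 0
        contrast = float(np.mean(signal[sl][comp])) - background
        score = float(np.clip(contrast / 255.0, 0.0, 1.0))
        dets.append(Detection((sl[1].start, sl[0].start, sl[1].stop, sl[0].stop),
                              score))
    dets.sort(key=lambda d: (-d.score, d.box[1], d.box[0]))
    return dets


class ThresholdBackend(SegmenterBackend):
    """Classical detector/segmenter for dark-on-light brightfield stains."""

    def __init__(self, min_blob_px: int = 40, smooth_sigma: float = 1.0,
                 despeckle_px: int = 20):
        self.min_blob_px = min_blob_px
        self.smooth_sigma = smooth_sigma
        self.despeckle_px = despeckle_px

    def detect(self, tile, *, origin=(0, 0)) -> list[Detection]:
        return fallback_detect(tile, self.min_blob_px, self.smooth_sigma)

    def segment(self, crop, context: CropContext) -> np.ndarray:
        crop = np.asarray(crop)
        if crop.ndim == 3:
            crop = SlideImage(crop, 1.0).gray
        signal = (255 - crop.astype(np.int16)).astype(np.uint8)
        if int(signal.max()) - int(signal.min()) < 20:
            # flat crop: fully stained or fully background
            return (np.ones_like(signal, dtype=bool)
                    if float(np.median(signal)) > 127
                    else np.zeros_like(signal, dtype=bool))
        thr = filters.threshold_otsu(signal)
        return _drop_small(signal > thr, self.despeckle_px)


# ---------------------------------------------------------------------------
# ground-truth oracle backend


class OracleBackend(SegmenterBackend):
    """Ground-truth passthrough: detections and masks come from a truth set.

    detect() emits one unit-score detection per truth cell whose box lies
    fully inside the queried tile; segment() returns the matched cell's
    true mask restricted to the crop.
    """

    def __init__(self, truth: AnnotationSet):
        self.truth = truth
        self._masks = {c.id: global_mask(c, truth.image_shape)
                       for c in truth.cells}

    def detect(self, tile, *, origin=(0, 0)) -> list[Detection]:
        # a truth cell belongs to the tile containing its box centre, so
        # every cell is claimed by exactly one A and one B tile; the full
        # (untruncated) box is emitted in tile-local coordinates
        ox, oy = origin
        h, w = np.asarray(tile).shape[:2]
        dets = []
        for c in self.truth.cells:
            x0, y0, x1, y1 = c.box
            cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
            if ox <= cx < ox + w and oy <= cy < oy + h:
                dets.append(Detection((x0 - ox, y0 - oy, x1 - ox, y1 - oy),
                                      1.0, {"cell_id": c.id}))
        dets.sort(key=lambda d: (d.box[1], d.box[0]))
        return dets

    def segment(self, crop, context: CropContext) -> np.ndarray:
        if context.detection is None or "cell_id" not in context.detection.extras:
            raise ValueError("oracle segment() needs the originating detection")
        ox, oy = context.origin
        h, w = np.asarray(crop).shape[:2]
        full = self._masks[context.detection.extras["cell_id"]]
        H, W = full.shape
        out = np.zeros((h, w), dtype=bool)
        y0, x0 = max(oy, 0), max(ox, 0)
        y1, x1 = min(oy + h, H), min(ox + w, W)
        if y1 > y0 and x1 > x0:
            out[y0 - oy:y1 - oy, x0 - ox:x1 - ox] = full[y0:y1, x0:x1]
        return out


# ---------------------------------------------------------------------------
# operations


def detect_cells(tile: np.ndarray, backend: SegmenterBackend,
                 min_score: float = 0.5, *,
                 origin: tuple[int, int] = (0, 0)) -> list[Detection]:
    """Detections with score strictly above ``min_score``, best first."""
    dets = [d for d in backend.detect(tile, origin=origin) if d.score > min_score]
    dets.sort(key=lambda d: (-d.score, d.box[1], d.box[0]))
    return dets


def segment_cell(crop: np.ndarray, backend: SegmenterBackend,
                 context: CropContext) -> np.ndarray:
    """All putative cell pixels in a crop (possibly several components)."""
    mask = np.asarray(backend.segment(crop, context)).astype(bool)
    if mask.shape != np.asarray(crop).shape[:2]:
        raise ValueError("backend returned a mask of the wrong shape")
    return mask


def reconcile_fragments(raw_mask: np.ndarray, pixel_size: float,
                        attach_dist_um: float = 3.25,
                        spawn_area_um2: float = 107.65,
                        ) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Split a raw multi-component mask into (cell, spawned, debris).

    The largest connected component is the cell body. Components whose
    minimum distance to the growing cell is below ``attach_dist_um`` are
    attached as processes (iterated to a fixed point, so chains of nearby
    fragments attach). Non-attached components larger than
    ``spawn_area_um2`` become separate candidate cells; the remainder is
    debris. Every raw foreground pixel ends up in exactly one of the
    three outputs.
    """
    m = np.asarray(raw_mask).astype(bool)
    if not m.any():
        return np.zeros_like(m), [], []
    labels, n = ndimage.label(m)
    if n == 1:
        return m, [], []
    sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
    order = np.argsort(-sizes, kind="stable")  # ties: lower label first
    main_label = int(order[0]) + 1
    cell = labels == main_label
    pending = [int(i) + 1 for i in order[1:]]
    attach_px = attach_dist_um / pixel_size
    changed = True
    while changed and pending:
        changed = False
        dist = ndimage.distance_transform_edt(~cell)
        still = []
        for lab in pending:
            comp = labels == lab
            if float(dist[comp].min()) < attach_px:
                cell |= comp
                changed = True
            else:
                still.append(lab)
        pending = still
    spawned, debris = [], []
    area_px = spawn_area_um2 / (pixel_size * pixel_size)
    for lab in pending:
        comp = labels == lab
        if float(sizes[lab - 1]) > area_px:
            spawned.append(comp)
        else:
            debris.append(comp)
    return cell, spawned, debris


def merge_overlaps(cells: list[CellRecord], image_shape: tuple[int, int],
                   iou_merge: float = 0.7) -> list[CellRecord]:
    """Union instances whose mask IoU exceeds ``iou_merge``, transitively.

    The merged record keeps the higher detection score (ties: larger
    mask, then lower (y, x) box origin) and the unioned mask.
    """
    n = len(cells)
    if n <= 1:
        return list(cells)
    masks = [global_mask(c, image_shape) for c in cells]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    boxes = [c.box for c in cells]
    for i in range(n):
        for j in range(i + 1, n):
            bi, bj = boxes[i], boxes[j]
            if bi[2] <= bj[0] or bj[2] <= bi[0] or bi[3] <= bj[1] or bj[3] <= bi[1]:
                continue
            if iou(masks[i], masks[j]) > iou_merge:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        if len(members) == 1:
            out.append(cells[members[0]])
            continue
        rep = min(members, key=lambda i: (-cells[i].score,
                                          -int(masks[i].sum()),
                                          cells[i].box[1], cells[i].box[0]))
        union = np.zeros(image_shape, dtype=bool)
        for i in members:
            union |= masks[i]
        rec = _tight_record(union, cells[rep].id, cells[rep].score,
                            cells[rep].provenance)
        rec.provenance["merged_from"] = sorted(cells[i].id for i in members)
        out.append(rec)
    out.sort(key=lambda c: (c.box[1], c.box[0], c.id))
    return out


def dedup_units(cells_a: list[CellRecord], cells_b: list[CellRecord],
                grid: TileGrid, image_shape: tuple[int, int],
                dedup_iou: float = 0.5) -> list[CellRecord]:
    """Resolve duplicates between unit-A and unit-B passes.

    Unit A keeps cells whose boxes lie strictly inside one A tile; unit B
    contributes cells whose boxes cross an internal A boundary. Residual
    duplicates (mask IoU above ``dedup_iou``) are resolved in favour of
    the higher detection score (ties: larger mask, then lower (y, x)).
    """
    kept = [c for c in cells_a if not grid.box_crosses_a_boundary(c.box)]
    kept += [c for c in cells_b if grid.box_crosses_a_boundary(c.box)]
    if not kept:
        return []
    masks = [global_mask(c, image_shape) for c in kept]
    areas = [int(m.sum()) for m in masks]
    order = sorted(range(len(kept)),
                   key=lambda i: (-kept[i].score, -areas[i],
                                  kept[i].box[1], kept[i].box[0]))
    selected: list[int] = []
    for i in order:
        dup = False
        for j in selected:
            bi, bj = kept[i].box, kept[j].box
            if bi[2] <= bj[0] or bj[2] <= bi[0] or bi[3] <= bj[1] or bj[3] <= bi[1]:
                continue
            if iou(masks[i], masks[j]) > dedup_iou:
                dup = True
                break
        if not dup:
            selected.append(i)
    out = [kept[i] for i in sorted(selected,
                                   key=lambda i: (kept[i].box[1], kept[i].box[0]))]
    return out


# ---------------------------------------------------------------------------
# orchestration


def _process_unit(image: SlideImage, rects, backend: SegmenterBackend,
                  cfg: PipelineConfig, unit_name: str) -> list[CellRecord]:
    crop_cap = int(round(cfg.crop_um / image.pixel_size))
    records: list[CellRecord] = []
    next_id = 0
    h, w = image.shape
    for rect in rects:
        rx0, ry0, rx1, ry1 = rect
        tile = image.pixels[ry0:ry1, rx0:rx1]
        try:
            dets = detect_cells(tile, backend, cfg.min_score, origin=(rx0, ry0))
        except Exception as exc:
            raise RuntimeError(f"{unit_name} tile at {(rx0, ry0)}: detect failed") from exc
        for det in dets:
            x0, y0, x1, y1 = det.box
            # double the box about its centre, cap at crop_um; the crop is
            # read from the full image (it may extend past the tile), so
            # boundary cells are segmented whole
            cx, cy = rx0 + (x0 + x1) / 2.0, ry0 + (y0 + y1) / 2.0
            bw = min((x1 - x0) * 2, crop_cap)
            bh = min((y1 - y0) * 2, crop_cap)
            gx0 = max(int(round(cx - bw / 2)), 0)
            gy0 = max(int(round(cy - bh / 2)), 0)
            gx1 = min(int(round(cx + bw / 2)), w)
            gy1 = min(int(round(cy + bh / 2)), h)
            if gx1 - gx0 < 2 or gy1 - gy0 < 2:
                continue
            crop = image.pixels[gy0:gy1, gx0:gx1]
            ctx = CropContext((gx0, gy0), det, image.pixel_size)
            try:
                raw = segment_cell(crop, backend, ctx)
            except Exception as exc:
                raise RuntimeError(
                    f"{unit_name} tile at {(rx0, ry0)}: segment failed") from exc
            if not raw.any():
                continue
            cell, spawned, _ = reconcile_fragments(
                raw, image.pixel_size, cfg.attach_dist_um, cfg.spawn_area_um2)
            for mask_local in [cell] + spawned:
                if not mask_local.any():
                    continue
                full = np.zeros((h, w), dtype=bool)
                full[gy0:gy0 + mask_local.shape[0],
                     gx0:gx0 + mask_local.shape[1]] = mask_local
                rec = _tight_record(full, next_id, det.score,
                                    {"unit": unit_name, "tile": (rx0, ry0)})
                records.append(rec)
                next_id += 1
    return records


def run_segmentation(image: SlideImage, backend: SegmenterBackend,
                     config: PipelineConfig | None = None) -> AnnotationSet:
    """Full instance pipeline: tile -> detect -> crop -> segment ->
    reconcile -> merge -> A/B dedup -> area filter.

    Returns an :class:`AnnotationSet` in global coordinates with
    deterministic ordering and ids; cells below ``min_cell_area_um2``
    are removed.
    """
    cfg = config or PipelineConfig(pixel_size=image.pixel_size)
    grid = make_tiles(image, cfg.tile_side_um)
    cells_a = _process_unit(image, grid.a_rects, backend, cfg, "A")
    cells_b = _process_unit(image, grid.b_rects, backend, cfg, "B")
    shape = image.shape
    cells_a = merge_overlaps(cells_a, shape, cfg.iou_merge)
    cells_b = merge_overlaps(cells_b, shape, cfg.iou_merge)
    cells = dedup_units(cells_a, cells_b, grid, shape, cfg.dedup_iou)
    min_area_px = cfg.min_cell_area_um2 / (image.pixel_size ** 2)
    cells = [c for c in cells if c.area_px >= min_area_px]
    cells.sort(key=lambda c: (c.box[1], c.box[0], -c.score))
    for i, c in enumerate(cells):
        c.id = i + 1
    annset = AnnotationSet(shape, image.pixel_size, cells,
                           identifier=image.identifier,
                           slice_position=image.slice_position)
    annset.validate()
    return annset
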