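"""Image I/O, tiling geometry, and COCO-style RLE annotations.

Conventions
-----------
* Coordinates are 0-based with the origin at the top-left pixel; boxes are
  half-open ``(x0, y0, x1, y1)`` rectangles.
* Masks are 2D boolean rasters indexed ``[y, x]``.
* RLE is COCO-compatible: the mask is flattened in column-major order and
  stored as alternating run lengths starting with background. Uncompressed
  integer counts are used so annotation files stay plain JSON.
* Grayscale conversion of RGB uses fixed Rec. 601 luminance weights so it
  is deterministic across image libraries. Staining is dark-on-light, so
  the "signal" view is ``255 - gray``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

#: COCO category table: fixed ids 1-6 for the six morphotypes. Id 0 is the
#: reserved "unclassified" placeholder used before a classifier has run.
CATEGORY_IDS = {"R": 1, "H": 2, "B": 3, "A": 4, "RD": 5, "HR": 6}
CATEGORY_NAMES = {v: k for k, v in CATEGORY_IDS.items()}
EXTRA_KEY = "mgmorph"  # namespaced per-annotation payload


# ---------------------------------------------------------------------------
# images


@dataclass
class SlideImage:
    """A single brightfield slide (or tile thereof) with physical scale."""

    pixels: np.ndarray                 # (H, W) or (H, W, 3) uint8
    pixel_size: float                  # um / pixel
    identifier: str = "slide"
    slice_position: float | None = None  # anterior-posterior position, mm

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.pixels.ndim not in (2, 3) or min(self.pixels.shape[:2]) < 1:
            raise ValueError(f"bad image shape {self.pixels.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def physical_size_um(self) -> tuple[float, float]:
        return (self.height * self.pixel_size, self.width * self.pixel_size)

    @property
    def gray(self) -> np.ndarray:
        """Rec. 601 luminance as uint8 (identity for grayscale input)."""
        if self.pixels.ndim == 2:
            return self.pixels
        rgb = self.pixels[..., :3].astype(np.float64)
        y = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
        return np.clip(np.round(y), 0, 255).astype(np.uint8)

    @property
    def signal(self) -> np.ndarray:
        """Stain-intensity view (dark-on-light inverted): 255 - gray."""
        return (255 - self.gray.astype(np.int16)).astype(np.uint8)


def load_image(path: str | Path, pixel_size: float = 0.464,
               identifier: str | None = None) -> SlideImage:
    """Load a single-plane TIFF or PNG as a :class:`SlideImage`.

    Non-8-bit data are rescaled to the 0-255 range with a warning.
    """
    if pixel_size <= 0:
        raise ValueError(f"pixel_size must be > 0, got {pixel_size}")
    p = Path(path)
    if not p.exists():
        raise IOError(f"cannot read image: {p}")
    if p.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(p)
    else:
        with PILImage.open(p) as im:
            if im.mode not in ("L", "RGB"):
                im = im.convert("RGB" if "A" in im.mode or im.mode == "P" else "L")
            arr = np.asarray(im)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        warnings.warn(f"{p.name}: {arr.dtype} data rescaled to 8-bit")
        arr = arr.astype(np.float64)
        lo, hi = arr.min(), arr.max()
        arr = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo) * 255
        arr = np.round(arr).astype(np.uint8)
    return SlideImage(arr, pixel_size, identifier or p.stem)


def pixel_area(pixel_size: float) -> float:
    """Physical area of one pixel in um^2 (e.g. 0.464 -> 0.215)."""
    if pixel_size <= 0:
        raise ValueError(f"pixel_size must be > 0, got {pixel_size}")
    return pixel_size * pixel_size


# ---------------------------------------------------------------------------
# tiling

Box = tuple[int, int, int, int]


@dataclass
class TileGrid:
    """A/B sub-image units over a slide.

    Unit-A tiles partition the image on a regular grid. Unit-B tiles are
    the same grid shifted diagonally by half a tile side and clipped at
    the borders, so every internal A boundary lies in the interior of a
    B tile; cells straddling A boundaries are recovered from unit B.
    """

    image_shape: tuple[int, int]       # (H, W)
    tile_side_px: int
    a_rects: list[Box] = field(default_factory=list)
    b_rects: list[Box] = field(default_factory=list)

    @property
    def unit_a_origins(self) -> list[tuple[int, int]]:
        return [(x0, y0) for x0, y0, _, _ in self.a_rects]

    @property
    def unit_b_origins(self) -> list[tuple[int, int]]:
        return [(x0, y0) for x0, y0, _, _ in self.b_rects]

    def internal_boundaries(self) -> tuple[list[int], list[int]]:
        """Internal A-grid boundary coordinates as (x_lines, y_lines)."""
        h, w = self.image_shape
        s = self.tile_side_px
        return ([x for x in range(s, w, s)], [y for y in range(s, h, s)])

    def box_crosses_a_boundary(self, box: Box) -> bool:
        """True if a half-open box straddles any internal A boundary."""
        x0, y0, x1, y1 = box
        xs, ys = self.internal_boundaries()
        return any(x0 < x < x1 for x in xs) or any(y0 < y < y1 for y in ys)


def make_tiles(image: SlideImage | tuple[int, int], tile_side_um: float = 238.0,
               pixel_size: float | None = None) -> TileGrid:
    """Build the A/B tile grid for an image.

    The tile side is ``round(tile_side_um / pixel_size)`` rounded to the
    nearest even integer (512 px at 0.464 um/px); the B shift is half a
    side. A tile larger than the whole image yields a single A tile and
    an empty B grid.
    """
    if isinstance(image, SlideImage):
        h, w = image.shape
        pixel_size = image.pixel_size
    else:
        h, w = image
        if pixel_size is None:
            raise ValueError("pixel_size required when passing a raw shape")
    side_f = tile_side_um / pixel_size
    side = int(round(side_f / 2.0) * 2)  # nearest even integer
    if side < 2:
        raise ValueError(f"tile side {side_f:.2f} px is below 2 px")
    grid = TileGrid((h, w), side)
    if side >= w and side >= h:
        grid.a_rects = [(0, 0, w, h)]
        return grid
    for y0 in range(0, h, side):
        for x0 in range(0, w, side):
            grid.a_rects.append((x0, y0, min(x0 + side, w), min(y0 + side, h)))
    half = side // 2
    ys = [y for y in range(-half, h, side) if y + side > 0]
    xs = [x for x in range(-half, w, side) if x + side > 0]
    for y0 in ys:
        for x0 in xs:
            grid.b_rects.append((max(x0, 0), max(y0, 0),
                                 min(x0 + side, w), min(y0 + side, h)))
    return grid


# ---------------------------------------------------------------------------
# RLE


def encode_rle(mask: np.ndarray) -> dict:
    """Encode a 2D binary mask as COCO column-major RLE counts."""
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2D, got shape {m.shape}")
    h, w = m.shape
    flat = m.flatten(order="F")
    n = flat.size
    if n == 0:
        return {"size": [h, w], "counts": []}
    change = np.flatnonzero(flat[1:] != flat[:-1]) + 1
    starts = np.concatenate(([0], change, [n]))
    counts = np.diff(starts).tolist()
    if flat[0]:  # COCO runs start with a (possibly zero) background run
        counts = [0] + counts
    return {"size": [h, w], "counts": counts}


def decode_rle(rle: dict) -> np.ndarray:
    """Decode COCO column-major RLE counts back to a 2D boolean mask."""
    h, w = rle["size"]
    counts = rle["counts"]
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for c in counts:
        if val:
            flat[pos:pos + c] = True
        pos += c
        val = not val
    if pos != h * w:
        raise ValueError(f"RLE counts sum to {pos}, expected {h * w}")
    return flat.reshape((h, w), order="F")


def rle_area(rle: dict) -> int:
    """Foreground pixel count directly from the counts (no decode)."""
    return int(sum(rle["counts"][1::2]))


# ---------------------------------------------------------------------------
# cell records and annotation sets


@dataclass
class CellRecord:
    """One detected cell in global slide coordinates."""

    id: int
    rle: dict                          # global-frame mask, COCO RLE
    box: Box                           # half-open global box
    score: float = 1.0                 # detection probability Pr(cell)
    morphotype: str | None = None      # one of R,H,B,A,RD,HR once classified
    unfocused: bool = False            # focus gate flag (UF)
    focus: float | None = None         # Brenner focus measure
    features: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)   # undefined-feature notes
    provenance: dict = field(default_factory=dict)

    def mask(self) -> np.ndarray:
        return decode_rle(self.rle)

    @property
    def area_px(self) -> int:
        return rle_area(self.rle)

    def area_um2(self, pixel_size: float) -> float:
        return self.area_px * pixel_size * pixel_size


def to_global_coords(cell: CellRecord, tile_origin: tuple[int, int],
                     image_shape: tuple[int, int] | None = None) -> CellRecord:
    """Translate a tile-local record into global slide coordinates.

    The stored mask raster is kept on the cell's tight crop; only its
    recorded origin and the box move. A translated box extending past the
    image is clipped with a warning. Translation by ``(0, 0)`` is the
    identity, so the operation is idempotent at the global origin.
    """
    ox, oy = tile_origin
    x0, y0, x1, y1 = cell.box
    box = (x0 + ox, y0 + oy, x1 + ox, y1 + oy)
    if image_shape is not None:
        h, w = image_shape
        clipped = (max(box[0], 0), max(box[1], 0), min(box[2], w), min(box[3], h))
        if clipped != box:
            warnings.warn(f"cell {cell.id}: translated box {box} clipped to image")
            box = clipped
    prov = dict(cell.provenance)
    prov["crop_origin"] = (prov.get("crop_origin", (0, 0))[0] + ox,
                           prov.get("crop_origin", (0, 0))[1] + oy)
    prov["global"] = True
    return CellRecord(cell.id, cell.rle, box, cell.score, cell.morphotype,
                      cell.unfocused, cell.focus, dict(cell.features),
                      list(cell.flags), prov)


@dataclass
class AnnotationSet:
    """All retained cells of one slide, plus image metadata."""

    image_shape: tuple[int, int]
    pixel_size: float
    cells: list[CellRecord] = field(default_factory=list)
    identifier: str = "slide"
    slice_position: float | None = None

    def __len__(self) -> int:
        return len(self.cells)

    def validate(self) -> None:
        h, w = self.image_shape
        seen: set[int] = set()
        for c in self.cells:
            if c.id in seen:
                raise ValueError(f"duplicate cell id {c.id}")
            seen.add(c.id)
            rh, rw = c.rle["size"]
            if rh > h or rw > w:
                raise ValueError(f"cell {c.id}: mask {rh}x{rw} exceeds image {h}x{w}")


def global_mask(cell: CellRecord, image_shape: tuple[int, int]) -> np.ndarray:
    """Paste a cell's stored mask into a full-image boolean raster."""
    out = np.zeros(image_shape, dtype=bool)
    m = decode_rle(cell.rle)
    if m.shape == tuple(image_shape):
        return m
    ox, oy = cell.provenance.get("crop_origin", (cell.box[0], cell.box[1]))
    h, w = image_shape
    mh, mw = m.shape
    y0, x0 = max(oy, 0), max(ox, 0)
    y1, x1 = min(oy + mh, h), min(ox + mw, w)
    if y1 > y0 and x1 > x0:
        out[y0:y1, x0:x1] = m[y0 - oy:y1 - oy, x0 - ox:x1 - ox]
    return out


def _tight_record(mask_global: np.ndarray, cell_id: int, score: float,
                  provenance: dict | None = None) -> CellRecord:
    """Build a CellRecord from a full-frame mask, storing the tight crop."""
    ys, xs = np.nonzero(mask_global)
    if ys.size == 0:
        raise ValueError("empty mask")
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    prov = dict(provenance or {})
    prov["crop_origin"] = (x0, y0)
    return CellRecord(cell_id, encode_rle(mask_global[y0:y1, x0:x1]),
                      (x0, y0, x1, y1), score, provenance=prov)


# ---------------------------------------------------------------------------
# COCO JSON round trip


def write_annotations(annset: AnnotationSet, path: str | Path) -> None:
    """Write an :class:`AnnotationSet` as a COCO JSON file.

    Categories are the six fixed morphotype ids; features, focus measure,
    flags and provenance ride along under the namespaced ``mgmorph`` key
    of each annotation. Output is deterministic (sorted keys).
    """
    annset.validate()
    h, w = annset.image_shape
    images = [{"id": 1, "file_name": annset.identifier, "height": h, "width": w,
               "pixel_size_um": annset.pixel_size,
               "slice_position_mm": annset.slice_position}]
    categories = [{"id": 0, "name": "unclassified", "supercategory": "microglia"}]
    categories += [{"id": i, "name": n, "supercategory": "microglia"}
                   for i, n in sorted(CATEGORY_NAMES.items())]
    annotations = []
    for c in annset.cells:
        x0, y0, x1, y1 = c.box
        feats = {k: (None if v is None or (isinstance(v, float) and np.isnan(v))
                     else float(f"{v:.6g}")) for k, v in c.features.items()}
        annotations.append({
            "id": int(c.id),
            "image_id": 1,
            "category_id": CATEGORY_IDS.get(c.morphotype, 0),
            "segmentation": {"size": [int(s) for s in c.rle["size"]],
                             "counts": [int(v) for v in c.rle["counts"]]},
            "bbox": [int(x0), int(y0), int(x1 - x0), int(y1 - y0)],
            "area": rle_area(c.rle),
            "iscrowd": 0,
            "score": float(c.score),
            EXTRA_KEY: {
                "focus": None if c.focus is None else float(f"{c.focus:.6g}"),
                "unfocused": bool(c.unfocused),
                "features": feats,
                "flags": list(c.flags),
                "provenance": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in c.provenance.items()},
            },
        })
    payload = {"images": images, "categories": categories,
               "annotations": annotations}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read a COCO JSON file written by :func:`write_annotations`."""
    payload = json.loads(Path(path).read_text())
    try:
        img = payload["images"][0]
        h, w = int(img["height"]), int(img["width"])
    except (KeyError, IndexError) as exc:
        raise ValueError(f"{path}: missing image metadata") from exc
    annset = AnnotationSet(
        (h, w), float(img.get("pixel_size_um", 1.0)),
        identifier=img.get("file_name", "slide"),
        slice_position=img.get("slice_position_mm"))
    valid_ids = {0} | set(CATEGORY_NAMES)
    for ann in payload.get("annotations", []):
        cid = ann.get("category_id")
        if cid not in valid_ids:
            raise ValueError(
                f"{path}: annotation id {ann.get('id')} has unknown category id {cid}")
        seg = ann["segmentation"]
        if not isinstance(seg, dict) or "counts" not in seg:
            raise ValueError(f"{path}: annotation id {ann.get('id')} lacks RLE")
        bx, by, bw, bh = ann["bbox"]
        extra = ann.get(EXTRA_KEY, {})
        prov = {k: (tuple(v) if isinstance(v, list) else v)
                for k, v in extra.get("provenance", {}).items()}
        feats = {k: (float("nan") if v is None else float(v))
                 for k, v in extra.get("features", {}).items()}
        annset.cells.append(CellRecord(
            int(ann["id"]),
            {"size": list(seg["size"]), "counts": list(seg["counts"])},
            (int(bx), int(by), int(bx + bw), int(by + bh)),
            float(ann.get("score", 1.0)),
            CATEGORY_NAMES.get(cid),
            bool(extra.get("unfocused", False)),
            extra.get("focus"),
            feats,
            list(extra.get("flags", [])),
            prov,
        ))
    annset.validate()
    return annset
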