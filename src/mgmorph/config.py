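"""Pipeline configuration.

All physically meaningful thresholds are stored in micrometre units and
converted to pixels per image, so the same configuration applies across
acquisition resolutions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    """Resolved configuration of a full pipeline run.

    Defaults correspond to 20x brightfield acquisition at 0.464 um/px:
    512 px sub-image tiles (238 um) with a 256 px diagonal shift, strict
    >0.5 detection-probability gate, fragment attachment below 3.25 um,
    fragment spawning above 107.65 um^2, >0.7 IoU mask merging, removal
    of cells below 30 um^2, and a Brenner focus gate at 600.
    """

    pixel_size: float = 0.464          # um / pixel, isotropic
    tile_side_um: float = 238.0        # A/B sub-image unit side
    crop_um: float = 119.0             # max side of the segmentation crop
    min_score: float = 0.5             # Pr(cell) gate, strict >
    iou_merge: float = 0.7             # mask IoU above which instances merge
    dedup_iou: float = 0.5             # residual A/B duplicate threshold
    attach_dist_um: float = 3.25       # fragment-to-body attachment distance
    spawn_area_um2: float = 107.65     # fragment area spawning a new cell
    min_cell_area_um2: float = 30.0    # cells below this are excluded
    fm_threshold: float = 600.0        # Brenner focus gate, strict >
    fm_expand: float = 1.2             # focus FOV scale about the cell box
    fm_lag: int = 2                    # Brenner difference lag in pixels
    seed: int = 0
    backend: str = "fallback"
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        payload = json.loads(p.read_text() if p.exists() else str(source))
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in payload.items() if k in known}
        unknown = {k: v for k, v in payload.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extra.update(unknown)
        return cfg
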