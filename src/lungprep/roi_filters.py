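"""Rule-based acceptance filtering of candidate lung masks.

Three filters run in a fixed order — border contact, object count, then
per-object area/proportion — and *all* violations are collected rather than
stopping at the first, so a rejection is fully auditable.  A mask is accepted
iff no filter fires; only then is the ROI bounding box (the extreme
foreground coordinates) computed.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
from scipy import ndimage

from .errors import LungPrepError, ValidationError
from .io_formats import BinaryMask, pair_dataset, read_image, write_mask

if TYPE_CHECKING:  # pragma: no cover
    from .config import PipelineConfig

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)


class Rejection(str, Enum):
    BORDER_TOUCH = "BORDER_TOUCH"
    OBJECT_COUNT = "OBJECT_COUNT"
    AREA_TOO_SMALL = "AREA_TOO_SMALL"
    BAD_ASPECT = "BAD_ASPECT"


@dataclass
class ComponentStats:
    """Per-component geometry used by the filters."""

    label: int
    area_px: int
    area_frac: float
    bbox: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max), inclusive
    aspect_ratio: float  # bbox width / bbox height
    touches_border: bool


@dataclass
class FilterConfig:
    min_area_frac: float = 0.05
    aspect_min: float = 0.2
    aspect_max: float = 3.0
    max_objects: int = 2
    min_objects: int = 1
    border_margin_px: int = 1

    def validate(self) -> None:
        if not (0.0 < self.min_area_frac < 1.0):
            raise ValidationError("min_area_frac must lie in (0, 1)")
        if self.aspect_min >= self.aspect_max:
            raise ValidationError("aspect_min must be < aspect_max")
        if self.min_objects > self.max_objects:
            raise ValidationError("min_objects must be <= max_objects")
        if self.border_margin_px < 0:
            raise ValidationError("border_margin_px must be >= 0")


@dataclass
class PipelineResult:
    """Filter verdict for one mask: accepted iff ``reasons`` is empty."""

    mask: BinaryMask
    accepted: bool
    reasons: list[Rejection]
    components: list[ComponentStats]
    roi_bbox: tuple[int, int, int, int] | None


def component_stats(mask: BinaryMask) -> list[ComponentStats]:
    """Stats for each 8-connected component, sorted by area descending.

    Ties in area break by label order (raster scan), so the output is
    deterministic.
    """
    labels, n = ndimage.label(mask.as_bool(), structure=_STRUCT8)
    if n == 0:
        return []
    h, w = mask.pixels.shape
    areas = np.bincount(labels.ravel())
    slices = ndimage.find_objects(labels)
    out: list[ComponentStats] = []
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        r0, r1 = sl[0].start, sl[0].stop - 1
        c0, c1 = sl[1].start, sl[1].stop - 1
        out.append(
            ComponentStats(
                label=lab,
                area_px=int(areas[lab]),
                area_frac=float(areas[lab]) / (h * w),
                bbox=(r0, c0, r1, c1),
                aspect_ratio=(c1 - c0 + 1) / (r1 - r0 + 1),
                touches_border=bool(r0 == 0 or c0 == 0 or r1 == h - 1 or c1 == w - 1),
            )
        )
    out.sort(key=lambda s: (-s.area_px, s.label))
    return out


def boundary_filter(mask: BinaryMask, cfg: FilterConfig) -> Rejection | None:
    """BORDER_TOUCH iff any foreground pixel lies within the border margin."""
    m = cfg.border_margin_px
    if m == 0:
        return None
    px = mask.pixels
    band = (
        px[:m, :].any() or px[-m:, :].any() or px[:, :m].any() or px[:, -m:].any()
    )
    return Rejection.BORDER_TOUCH if band else None


def object_count_filter(
    components: list[ComponentStats], cfg: FilterConfig
) -> Rejection | None:
    n = len(components)
    if n < cfg.min_objects or n > cfg.max_objects:
        return Rejection.OBJECT_COUNT
    return None


def shape_filter(
    components: list[ComponentStats], cfg: FilterConfig
) -> list[Rejection]:
    """Per-component checks; area test is inclusive at the cutoff (>=)."""
    out: list[Rejection] = []
    for c in components:
        if c.area_frac < cfg.min_area_frac:
            out.append(Rejection.AREA_TOO_SMALL)
        if not (cfg.aspect_min <= c.aspect_ratio <= cfg.aspect_max):
            out.append(Rejection.BAD_ASPECT)
    return out


def compute_roi_bbox(mask: BinaryMask) -> tuple[int, int, int, int]:
    """Extreme foreground coordinates: (row_min, col_min, row_max, col_max)."""
    rows, cols = np.nonzero(mask.pixels)
    if rows.size == 0:
        raise ValidationError("cannot compute ROI of an empty mask")
    return (int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max()))


def apply_filters(mask: BinaryMask, cfg: FilterConfig | None = None) -> PipelineResult:
    """Run boundary -> count -> shape, collecting all violations."""
    cfg = cfg or FilterConfig()
    cfg.validate()
    comps = component_stats(mask)
    reasons: list[Rejection] = []
    if (r := boundary_filter(mask, cfg)) is not None:
        reasons.append(r)
    if (r := object_count_filter(comps, cfg)) is not None:
        reasons.append(r)
    for r in shape_filter(comps, cfg):
        if r not in reasons:
            reasons.append(r)
    accepted = not reasons
    return PipelineResult(
        mask=mask,
        accepted=accepted,
        reasons=reasons,
        components=comps,
        roi_bbox=compute_roi_bbox(mask) if accepted else None,
    )


def process_directory(
    image_dir: str | Path,
    out_dir: str | Path,
    cfg: "PipelineConfig | None" = None,
) -> dict:
    """Segment + filter every image in a directory; write accepted masks.

    A failure on one image is logged and counted, never fatal for the run.
    Returns the summary dict that is also written to ``out_dir`` as JSON,
    alongside a per-image CSV report.
    """
    from .config import PipelineConfig
    from .preprocess_core import segment_slice

    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs = pair_dataset(image_dir)

    rows: list[dict] = []
    reason_counts: dict[str, int] = {}
    n_accepted = 0
    n_errors = 0
    for pair in pairs:
        row: dict = {"filename": Path(pair.image_path).name}
        try:
            img = read_image(pair.image_path)
            mask = segment_slice(img, cfg)
            result = apply_filters(mask, cfg.filters)
        except LungPrepError as exc:
            logger.error("%s: %s", pair.image_path, exc)
            n_errors += 1
            row.update(accepted=False, reasons="ERROR", error=str(exc))
            rows.append(row)
            continue
        row.update(
            accepted=result.accepted,
            reasons=";".join(r.value for r in result.reasons),
            n_components=len(result.components),
            roi_bbox=";".join(map(str, result.roi_bbox)) if result.roi_bbox else "",
        )
        rows.append(row)
        if result.accepted:
            n_accepted += 1
            write_mask(result.mask, out / f"{pair.stem}.{cfg.output_format}")
        for r in result.reasons:
            reason_counts[r.value] = reason_counts.get(r.value, 0) + 1

    summary = {
        "n_images": len(pairs),
        "n_accepted": n_accepted,
        "n_errors": n_errors,
        "pass_rate": n_accepted / len(pairs),
        "rejection_counts": reason_counts,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    fieldnames = ["filename", "accepted", "reasons", "n_components", "roi_bbox", "error"]
    with open(out / "report.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames, restval="")
        writer.writeheader()
        writer.writerows(rows)
    return summary
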