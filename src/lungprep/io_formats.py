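"""Grayscale image and binary-mask I/O plus dataset pairing.

Conventions
-----------
* Pixel grids are row-major, origin top-left, 0-based; rows are the in-slice
  vertical axis, columns the horizontal axis.
* Binary masks live in memory as ``{0, 1}`` (uint8) and on disk as 8-bit
  single-channel images with foreground 255 / background 0.  The decode
  threshold is ``> 127``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

SUPPORTED_EXTENSIONS = {".png", ".tif", ".tiff"}


@dataclass
class RawImage:
    """A 2-D grayscale intensity grid as stored on disk (any bit depth)."""

    pixels: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"RawImage requires a 2-D grid, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValidationError("RawImage must be at least 1x1")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class BinaryMask:
    """A 2-D grid of {0, 1} values."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValidationError(
                f"BinaryMask requires a 2-D grid, got shape {arr.shape}"
            )
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        else:
            vals = np.unique(arr)
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError(
                    f"BinaryMask pixels must be 0 or 1, found values {vals[:8]}"
                )
            arr = arr.astype(np.uint8)
        self.pixels = arr

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    def as_bool(self) -> np.ndarray:
        return self.pixels.astype(bool)

    def __eq__(self, other: object) -> bool:  # value semantics for round trips
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.pixels.shape == other.pixels.shape and bool(
            (self.pixels == other.pixels).all()
        )


@dataclass
class DatasetPair:
    """An image path and its (optional) matching mask path."""

    image_path: str
    mask_path: str | None = None
    stem: str = field(default="")


def _check_path(path: str | Path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    if p.suffix.lower() not in SUPPORTED_EXTENSIONS:
        raise FormatError(
            f"unsupported format {p.suffix!r}; expected one of "
            f"{sorted(SUPPORTED_EXTENSIONS)}"
        )
    return p


def read_image(path: str | Path) -> RawImage:
    """Read a PNG/TIFF grayscale image; multi-channel input is averaged.

    Bit depth is preserved as stored (8- or 16-bit integers stay integers).
    """
    p = _check_path(path)
    arr = iio.imread(p)
    if arr.ndim == 3:
        logger.warning("%s is multi-channel; averaging channels to grayscale", p)
        orig_dtype = arr.dtype
        arr = arr.mean(axis=-1)
        if np.issubdtype(orig_dtype, np.integer):
            arr = np.rint(arr).astype(orig_dtype)
    if arr.ndim != 2:
        raise FormatError(f"{p}: expected a 2-D image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValidationError(f"{p}: zero-sized image")
    return RawImage(pixels=arr, source_path=str(p))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit single-channel image (foreground 255)."""
    p = Path(path)
    if p.suffix.lower() not in SUPPORTED_EXTENSIONS:
        raise FormatError(f"masks are written as PNG or TIFF, not {p.suffix!r}")
    p.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(p, (mask.pixels * np.uint8(255)).astype(np.uint8))


def read_mask(path: str | Path) -> BinaryMask:
    """Read an 8-bit single-channel mask; values > 127 map to foreground."""
    p = _check_path(path)
    arr = iio.imread(p)
    if arr.ndim != 2:
        raise FormatError(
            f"{p}: masks must be single-channel, got shape {arr.shape}"
        )
    return BinaryMask(pixels=(arr > 127).astype(np.uint8))


def _list_images(directory: Path) -> dict[str, Path]:
    out: dict[str, Path] = {}
    for f in sorted(directory.iterdir()):
        if f.is_file() and f.suffix.lower() in SUPPORTED_EXTENSIONS:
            if f.stem in out:
                raise ValidationError(
                    f"filename stem collision in {directory}: "
                    f"{out[f.stem].name} vs {f.name}"
                )
            out[f.stem] = f
    return out


def pair_dataset(
    image_dir: str | Path, mask_dir: str | Path | None = None
) -> list[DatasetPair]:
    """Pair images with masks by filename stem, sorted lexicographically.

    Images lacking a mask get ``mask_path=None``; masks without an image are
    logged and skipped.  An empty image directory is an error.
    """
    img_dir = Path(image_dir)
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no such directory: {img_dir}")
    images = _list_images(img_dir)
    if not images:
        raise ValidationError(f"no PNG/TIFF images found in {img_dir}")

    masks: dict[str, Path] = {}
    if mask_dir is not None:
        masks = _list_images(Path(mask_dir))
        for stem in sorted(set(masks) - set(images)):
            logger.warning("mask %s has no matching image; ignored", masks[stem])

    return [
        DatasetPair(
            image_path=str(images[stem]),
            mask_path=str(masks[stem]) if stem in masks else None,
            stem=stem,
        )
        for stem in sorted(images)
    ]
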