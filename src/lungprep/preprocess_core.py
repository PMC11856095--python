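"""Raw CT slice -> candidate lung mask.

The chain implemented by :func:`segment_slice` is: min-max normalization,
percentile contrast stretch, Otsu binarization (lung candidates are the
*low*-intensity class — lungs are air-filled and dark on CT), body isolation
as the largest filled dense-tissue component, removal of everything outside
the body, and morphological refinement (iterated closing, hole filling,
small-object removal).

Border convention for all morphology: pixels outside the image are
background, for dilation and erosion alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import ndimage

from .errors import NoBodyError, ValidationError
from .io_formats import BinaryMask, RawImage

if TYPE_CHECKING:  # pragma: no cover
    from .config import PipelineConfig

logger = logging.getLogger(__name__)

#: 8-connectivity for foreground components (4-connected background is the
#: dual used in hole filling).
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class NormalizedImage:
    """2-D grid of floats in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValidationError(f"expected 2-D grid, got shape {arr.shape}")
        if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
            raise ValidationError("NormalizedImage values must lie in [0, 1]")
        self.pixels = arr

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class OtsuResult:
    """Otsu threshold plus the objective it maximized."""

    threshold: float
    between_class_variance: float
    histogram: np.ndarray


@dataclass
class StructuringElement:
    """Binary neighborhood for dilation/erosion, with an anchor pixel."""

    pixels: np.ndarray
    anchor: tuple[int, int]

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels).astype(bool)
        if arr.ndim != 2:
            raise ValidationError("structuring element must be 2-D")
        r, c = self.anchor
        if not (0 <= r < arr.shape[0] and 0 <= c < arr.shape[1]):
            raise ValidationError("anchor must lie inside the element")
        self.pixels = arr

    @classmethod
    def square(cls, size: int = 5) -> "StructuringElement":
        if size < 1 or size % 2 == 0:
            raise ValidationError("square element size must be odd and >= 1")
        return cls(np.ones((size, size), dtype=bool), (size // 2, size // 2))

    def _origin(self) -> tuple[int, int]:
        # scipy 'origin' is the anchor offset from the element center
        return (
            self.anchor[0] - self.pixels.shape[0] // 2,
            self.anchor[1] - self.pixels.shape[1] // 2,
        )


def normalize_image(img: RawImage) -> NormalizedImage:
    """Min-max rescale to [0, 1]; a constant image maps to all zeros."""
    arr = np.asarray(img.pixels, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        logger.warning("constant image %s: normalized to all zeros", img.source_path)
        return NormalizedImage(np.zeros_like(arr))
    return NormalizedImage((arr - lo) / (hi - lo))


def enhance_contrast(
    img: NormalizedImage, low_pct: float = 1.0, high_pct: float = 99.0
) -> NormalizedImage:
    """Linear stretch mapping the given percentiles to 0 and 1, clipping outside."""
    if not (0.0 <= low_pct < high_pct <= 100.0):
        raise ValidationError("need 0 <= low_pct < high_pct <= 100")
    lo, hi = np.percentile(img.pixels, [low_pct, high_pct])
    if hi == lo:
        logger.warning("degenerate percentiles (%g == %g); contrast left unchanged", lo, hi)
        return img
    return NormalizedImage(np.clip((img.pixels - lo) / (hi - lo), 0.0, 1.0))


def otsu_threshold(img: NormalizedImage, bins: int = 256) -> OtsuResult:
    """Exhaustive Otsu scan over all internal bin edges of a [0, 1] histogram.

    The between-class variance ``w0*w1*(mu0-mu1)**2`` is evaluated at every
    cut ``k`` (class 0 = bins below ``k``); ties break toward the smaller
    threshold.  The returned threshold is the bin edge ``k / bins``.
    """
    arr = img.pixels
    if arr.min() == arr.max():
        raise ValidationError("Otsu is undefined on a constant image")
    counts, _ = np.histogram(arr, bins=bins, range=(0.0, 1.0))
    counts = counts.astype(np.float64)
    total = counts.sum()
    centers = (np.arange(bins) + 0.5) / bins

    w0 = np.cumsum(counts)[:-1]  # pixels strictly below cut k, k = 1..bins-1
    w1 = total - w0
    m0 = np.cumsum(counts * centers)[:-1]
    m1 = m0[-1] + counts[-1] * centers[-1] - m0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(bins - 1)
    sigma_b[valid] = (
        w0[valid] * w1[valid] * (m0[valid] / w0[valid] - m1[valid] / w1[valid]) ** 2
    ) / total**2
    k = int(np.argmax(sigma_b))  # first maximum -> smallest threshold
    return OtsuResult(
        threshold=(k + 1) / bins,
        between_class_variance=float(sigma_b[k]),
        histogram=counts.astype(np.int64),
    )


def binarize_lungs(img: NormalizedImage, threshold: float) -> BinaryMask:
    """Foreground = pixels *below* the threshold (low density: air and lung)."""
    if not (0.0 < threshold < 1.0):
        raise ValidationError("threshold must lie strictly inside (0, 1)")
    return BinaryMask((img.pixels < threshold).astype(np.uint8))


def identify_body(dense: BinaryMask) -> BinaryMask:
    """Largest 8-connected dense-tissue component with its holes filled."""
    labels, n = ndimage.label(dense.as_bool(), structure=_STRUCT8)
    if n == 0:
        raise NoBodyError("no body found: dense-tissue mask is empty")
    areas = np.bincount(labels.ravel())[1:]
    body = labels == (int(np.argmax(areas)) + 1)
    return BinaryMask(ndimage.binary_fill_holes(body))


def clear_outside_body(lung_candidates: BinaryMask, body: BinaryMask) -> BinaryMask:
    """Keep only candidate pixels inside the body (pointwise AND)."""
    if lung_candidates.pixels.shape != body.pixels.shape:
        raise ValidationError("lung-candidate and body masks differ in shape")
    return BinaryMask(lung_candidates.pixels & body.pixels)


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Turn background components not 4-connected to the border into foreground."""
    return BinaryMask(ndimage.binary_fill_holes(mask.as_bool()))


def remove_small_objects(mask: BinaryMask, min_area_frac: float = 0.001) -> BinaryMask:
    """Delete 8-connected components with area < min_area_frac * image area."""
    if not (0.0 <= min_area_frac < 1.0):
        raise ValidationError("min_area_frac must be in [0, 1)")
    if min_area_frac == 0.0:
        return BinaryMask(mask.pixels.copy())
    cutoff = min_area_frac * mask.pixels.size
    labels, n = ndimage.label(mask.as_bool(), structure=_STRUCT8)
    if n == 0:
        return BinaryMask(mask.pixels.copy())
    areas = np.bincount(labels.ravel())
    keep = areas >= cutoff
    keep[0] = False
    return BinaryMask(keep[labels])


def dilate(mask: BinaryMask, se: StructuringElement) -> BinaryMask:
    out = ndimage.binary_dilation(
        mask.as_bool(), structure=se.pixels, origin=se._origin()
    )
    return BinaryMask(out)


def erode(mask: BinaryMask, se: StructuringElement) -> BinaryMask:
    # border_value=0: foreground touching the image edge erodes away
    out = ndimage.binary_erosion(
        mask.as_bool(), structure=se.pixels, origin=se._origin(), border_value=0
    )
    return BinaryMask(out)


def close(mask: BinaryMask, se: StructuringElement) -> BinaryMask:
    """Morphological closing: dilation then erosion."""
    return erode(dilate(mask, se), se)


def refine_morphology(
    mask: BinaryMask,
    se: StructuringElement | None = None,
    iterations: int = 3,
    min_area_frac: float = 0.001,
) -> BinaryMask:
    """Iterated closing, then hole filling, then small-object removal."""
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    if se is None:
        se = StructuringElement.square(5)
    out = mask
    for _ in range(iterations):
        out = close(out, se)
    out = fill_holes(out)
    return remove_small_objects(out, min_area_frac=min_area_frac)


def segment_slice(img: RawImage, config: "PipelineConfig | None" = None) -> BinaryMask:
    """Full preprocessing chain producing the unfiltered candidate lung mask.

    Raises :class:`NoBodyError` when the slice has no dense-tissue region.
    """
    from .config import PipelineConfig

    cfg = config or PipelineConfig()
    norm = normalize_image(img) if cfg.normalization else NormalizedImage(
        np.clip(np.asarray(img.pixels, dtype=np.float64), 0.0, 1.0)
    )
    if norm.pixels.min() == norm.pixels.max():
        raise NoBodyError("no body found: image is constant")
    enhanced = enhance_contrast(norm, cfg.contrast_low_pct, cfg.contrast_high_pct)
    otsu = otsu_threshold(enhanced, bins=cfg.otsu_bins)
    lung_candidates = binarize_lungs(enhanced, otsu.threshold)
    dense = BinaryMask(1 - lung_candidates.pixels)
    body = identify_body(dense)
    inside = clear_outside_body(lung_candidates, body)
    se = StructuringElement.square(cfg.se_size)
    return refine_morphology(
        inside,
        se=se,
        iterations=cfg.morph_iterations,
        min_area_frac=cfg.small_object_frac,
    )
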