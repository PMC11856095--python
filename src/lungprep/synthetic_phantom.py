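"""Seeded CT-slice phantoms with exact ground-truth masks.

A phantom is a dark background, a bright elliptical "body", two dark lung
ellipses inside it, and optionally an elongated bright "scanning table" bar
near the bottom edge.  Ground-truth masks are the analytic ellipse
rasterizations (center-of-pixel inclusion), computed before noise is added,
so expected areas follow from ellipse arithmetic.

Injectable defects (each maps to a designed pipeline rejection):

* ``BORDER_TOUCH``  — geometry shifted up until the lungs reach row 0
* ``EXTRA_OBJECT``  — a third dark disc inside the body (~1% of image area)
* ``TINY_LUNGS``    — lungs shrunk below the 5% per-object area cutoff
* ``MERGED_LUNGS``  — overlapping lung ellipses forming one component
* ``TABLE_ARTIFACT``— bright bar (bbox aspect > 5) below the body
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io_formats import BinaryMask, RawImage, write_mask

BORDER_TOUCH = "BORDER_TOUCH"
EXTRA_OBJECT = "EXTRA_OBJECT"
TINY_LUNGS = "TINY_LUNGS"
MERGED_LUNGS = "MERGED_LUNGS"
TABLE_ARTIFACT = "TABLE_ARTIFACT"
ALL_DEFECTS = (BORDER_TOUCH, EXTRA_OBJECT, TINY_LUNGS, MERGED_LUNGS, TABLE_ARTIFACT)


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]  # (row, col)
    semi: tuple[float, float]  # (semi-axis along rows, along cols)

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        cr, cl = self.center
        ar, ac = self.semi
        return ((rr - cr) / ar) ** 2 + ((cc - cl) / ac) ** 2 <= 1.0

    @property
    def area(self) -> float:
        return float(np.pi * self.semi[0] * self.semi[1])


@dataclass
class Intensities:
    background: float = 0.05
    body_tissue: float = 0.65
    lung: float = 0.15
    table: float = 0.75


@dataclass
class PhantomSpec:
    size: tuple[int, int] = (512, 512)
    body: Ellipse | None = None
    lungs: tuple[Ellipse, Ellipse] | None = None
    intensities: Intensities = field(default_factory=Intensities)
    noise_sigma: float = 0.01
    defects: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 32 or w < 32:
            raise ValidationError("phantom size must be at least 32x32")
        for d in self.defects:
            if d not in ALL_DEFECTS:
                raise ValidationError(f"unknown defect {d!r}")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        sr, sc = h / 512.0, w / 512.0
        if self.body is None:
            self.body = Ellipse((h / 2, w / 2), (190 * sr, 225 * sc))
        if self.lungs is None:
            self.lungs = (
                Ellipse((h / 2, w / 2 - 100 * sc), (120 * sr, 70 * sc)),
                Ellipse((h / 2, w / 2 + 100 * sc), (120 * sr, 70 * sc)),
            )


@dataclass
class Phantom:
    """Rendered slice plus exact pre-noise ground truth.

    ``candidate_mask`` is the analytic prediction of the low-density regions
    inside the body (lungs plus any injected dark artifact): the mask the
    segmentation stage is expected to hand to the acceptance filters.
    """

    image: RawImage
    lung_mask: BinaryMask
    body_mask: BinaryMask
    candidate_mask: BinaryMask
    spec: PhantomSpec
    defect_labels: tuple[str, ...]

    @property
    def lung_area_frac(self) -> float:
        return float(np.count_nonzero(self.lung_mask.pixels)) / self.lung_mask.pixels.size


def _shift(e: Ellipse, dr: float, dc: float = 0.0) -> Ellipse:
    return Ellipse((e.center[0] + dr, e.center[1] + dc), e.semi)


def _scale(e: Ellipse, f: float) -> Ellipse:
    return Ellipse(e.center, (e.semi[0] * f, e.semi[1] * f))


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render one phantom; same spec (incl. seed) gives bit-identical output."""
    h, w = spec.size
    sr, sc = h / 512.0, w / 512.0
    body = spec.body
    lungs = list(spec.lungs)
    ity = spec.intensities

    if TINY_LUNGS in spec.defects:
        lungs = [_scale(e, 0.45) for e in lungs]
    if MERGED_LUNGS in spec.defects:
        mid = (lungs[0].center[1] + lungs[1].center[1]) / 2.0
        lungs = [
            Ellipse((lungs[0].center[0], mid - 50 * sc), (lungs[0].semi[0], 84 * sc)),
            Ellipse((lungs[1].center[0], mid + 50 * sc), (lungs[1].semi[0], 84 * sc)),
        ]

    extra: Ellipse | None = None
    if EXTRA_OBJECT in spec.defects:
        extra = Ellipse(
            (body.center[0] + 0.55 * body.semi[0], body.center[1]),
            (30 * sr, 30 * sc),
        )

    if BORDER_TOUCH in spec.defects:
        # shift geometry up so the lungs overlap the top edge by 2 px
        # (an exact tangency leaves no rasterized pixel on row 0)
        dy = -min(e.center[0] - e.semi[0] for e in lungs) - 2.0
        body = _shift(body, dy)
        lungs = [_shift(e, dy) for e in lungs]
        if extra is not None:
            extra = _shift(extra, dy)

    body_px = body.rasterize((h, w))
    lung_px = np.zeros((h, w), dtype=bool)
    for e in lungs:
        lung_px |= e.rasterize((h, w))

    if BORDER_TOUCH not in spec.defects and (lung_px & ~body_px).any():
        raise ValidationError("lung ellipses exceed the body without BORDER_TOUCH")

    img = np.full((h, w), ity.background, dtype=np.float64)
    img[body_px] = ity.body_tissue
    img[lung_px] = ity.lung
    candidate_px = lung_px.copy()
    if extra is not None:
        extra_px = extra.rasterize((h, w))
        img[extra_px] = ity.lung
        candidate_px |= extra_px
    if TABLE_ARTIFACT in spec.defects:
        r0, r1 = int(round(h - 32 * sr)), int(round(h - 18 * sr))
        c0, c1 = int(round(0.12 * w)), int(round(0.88 * w))
        img[r0:r1, c0:c1] = ity.table

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    quantized = np.rint(img * 255.0).astype(np.uint8)

    return Phantom(
        image=RawImage(pixels=quantized, source_path=""),
        lung_mask=BinaryMask(lung_px),
        body_mask=BinaryMask(body_px),
        candidate_mask=BinaryMask(candidate_px),
        spec=spec,
        defect_labels=tuple(spec.defects),
    )


def generate_cohort(
    n: int,
    defect_rates: dict[str, float] | None = None,
    seed: int = 0,
    size: tuple[int, int] = (512, 512),
    noise_sigma: float = 0.01,
) -> list[Phantom]:
    """Generate ``n`` phantoms with jittered geometry and independent defects.

    A pure function of its arguments: the same seed reproduces the cohort
    bit-for-bit.  Each listed defect is injected independently per phantom
    with its stated probability, so a phantom can carry several defects.
    """
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    rates = dict(defect_rates or {})
    for name, rate in rates.items():
        if name not in ALL_DEFECTS:
            raise ValidationError(f"unknown defect {name!r}")
        if not (0.0 <= rate <= 1.0):
            raise ValidationError(f"rate for {name} must be in [0, 1]")

    rng = np.random.default_rng(seed)
    h, w = size
    sr, sc = h / 512.0, w / 512.0
    phantoms: list[Phantom] = []
    for _ in range(n):
        jit = rng.uniform(0.95, 1.05, size=4)
        dcr, dcc = rng.uniform(-5.0, 5.0, size=2)
        body = Ellipse(
            (h / 2 + dcr * sr, w / 2 + dcc * sc),
            (190 * sr * jit[0], 225 * sc * jit[1]),
        )
        lungs = (
            Ellipse(
                (body.center[0], body.center[1] - 100 * sc),
                (120 * sr * jit[2], 70 * sc * jit[3]),
            ),
            Ellipse(
                (body.center[0], body.center[1] + 100 * sc),
                (120 * sr * jit[2], 70 * sc * jit[3]),
            ),
        )
        defects = tuple(
            name for name in ALL_DEFECTS
            if rates.get(name, 0.0) > 0.0 and rng.random() < rates[name]
        )
        child_seed = int(rng.integers(0, 2**31 - 1))
        spec = PhantomSpec(
            size=size,
            body=body,
            lungs=lungs,
            noise_sigma=noise_sigma,
            defects=defects,
            seed=child_seed,
        )
        phantoms.append(generate_phantom(spec))
    return phantoms


def write_cohort(
    phantoms: list[Phantom],
    image_dir: str | Path,
    mask_dir: str | Path,
    image_format: str = "png",
) -> None:
    """Write images, ground-truth lung masks, and a manifest CSV.

    Files share a zero-padded stem; the manifest (``manifest.csv`` in
    ``image_dir``) records stem, seed, defects, and lung area fraction.
    """
    img_dir = Path(image_dir)
    msk_dir = Path(mask_dir)
    img_dir.mkdir(parents=True, exist_ok=True)
    msk_dir.mkdir(parents=True, exist_ok=True)
    ext = image_format.lstrip(".")

    import imageio.v3 as iio

    rows = []
    for i, ph in enumerate(phantoms):
        stem = f"phantom_{i:04d}"
        iio.imwrite(img_dir / f"{stem}.{ext}", ph.image.pixels)
        write_mask(ph.lung_mask, msk_dir / f"{stem}.{ext}")
        rows.append(
            {
                "stem": stem,
                "seed": ph.spec.seed,
                "defects": ";".join(ph.defect_labels),
                "lung_area_frac": f"{ph.lung_area_frac:.6f}",
            }
        )
    with open(img_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["stem", "seed", "defects", "lung_area_frac"])
        writer.writeheader()
        writer.writerows(rows)
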