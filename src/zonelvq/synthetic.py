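"""Seeded CT-like brain phantom generator.

Clinical CT slices are rarely shareable, so the pipeline is exercised
on synthetic phantoms that reproduce the features the screening chain
actually consumes: a bright elliptical skull ring that binarizes to
white, a darker brain interior that binarizes to black, and an
optional hyperdense lesion disc placed at the center of a chosen zone
of the 8 x 8 grid.  Additive Gaussian noise (clipped to [0, 255])
stands in for acquisition noise.

Default intensities sit on opposite sides of the fixed threshold 128:
skull 230 and lesion 200 are white after thresholding, the interior at
90 is black.  The skull ring geometry (outer semi-axes ~0.461/0.441 of
the image size, ring ~8 px thick at size 512) is chosen so that the
ring's spill-over into interior zones stays below the white-pixel
count of the smallest default lesion; the dominant interior zone is
then always the lesion zone, which makes localization exactly
recoverable at zero noise.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PhantomSpecError
from .zoning import ZoneGridSpec

__all__ = [
    "PhantomSpec",
    "CohortJitter",
    "PhantomRecord",
    "generate_phantom",
    "candidate_lesion_zones",
    "generate_cohort",
]

# skull ellipse semi-axes as fractions of image size: (vertical, horizontal)
_OUTER_FRAC = (0.461, 0.441)
_INNER_FRAC = (0.445, 0.426)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensities of one phantom slice.

    ``lesion_zone`` is a 1-based (row, col) cell of the zone grid, or
    ``None`` for a normal slice; ``lesion_offset`` shifts the lesion
    center from the zone center by (dy, dx) pixels.  Semi-axes default
    to fractions of ``size`` (see module docstring).
    """

    size: int = 512
    skull_outer: tuple[float, float] | None = None  # (semi_y, semi_x) px
    skull_inner: tuple[float, float] | None = None
    skull_intensity: int = 230
    interior_intensity: int = 90
    lesion_zone: tuple[int, int] | None = None
    lesion_radius: float = 20.0
    lesion_intensity: int = 200
    lesion_offset: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 8.0
    seed: int = 0
    grid: ZoneGridSpec = field(default_factory=ZoneGridSpec)

    @property
    def outer_axes(self) -> tuple[float, float]:
        if self.skull_outer is not None:
            return self.skull_outer
        return (_OUTER_FRAC[0] * self.size, _OUTER_FRAC[1] * self.size)

    @property
    def inner_axes(self) -> tuple[float, float]:
        if self.skull_inner is not None:
            return self.skull_inner
        return (_INNER_FRAC[0] * self.size, _INNER_FRAC[1] * self.size)

    def lesion_center(self) -> tuple[float, float]:
        """Lesion center in (y, x) pixel coordinates."""
        if self.lesion_zone is None:
            raise PhantomSpecError("spec has no lesion")
        r, c = self.lesion_zone
        zh = self.size / self.grid.rows
        zw = self.size / self.grid.cols
        return ((r - 0.5) * zh + self.lesion_offset[0], (c - 0.5) * zw + self.lesion_offset[1])


def _validate(spec: PhantomSpec) -> None:
    ay, ax = spec.inner_axes
    oy, ox = spec.outer_axes
    if ay >= oy or ax >= ox:
        raise PhantomSpecError("inner skull ellipse must lie inside the outer ellipse")
    if spec.lesion_zone is None:
        return
    r, c = spec.lesion_zone
    if not (1 <= r <= spec.grid.rows and 1 <= c <= spec.grid.cols):
        raise PhantomSpecError(f"lesion zone {spec.lesion_zone} outside the zone grid")
    cy, cx = spec.lesion_center()
    center = (spec.size - 1) / 2.0
    sy, sx = ay - spec.lesion_radius, ax - spec.lesion_radius
    if sy <= 0 or sx <= 0:
        raise PhantomSpecError("lesion radius exceeds the brain interior")
    if ((cy - center) / sy) ** 2 + ((cx - center) / sx) ** 2 > 1.0:
        raise PhantomSpecError(
            f"lesion at zone {spec.lesion_zone} (center {cy:.0f},{cx:.0f}) "
            "does not fit inside the inner skull ellipse"
        )


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render one phantom as a 2-D uint8 grayscale image.

    Identical specs (including seed) give bit-identical images.
    """
    _validate(spec)
    n = spec.size
    center = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - center, xx - center

    oy, ox = spec.outer_axes
    iy, ix = spec.inner_axes
    in_outer = (dy / oy) ** 2 + (dx / ox) ** 2 <= 1.0
    in_inner = (dy / iy) ** 2 + (dx / ix) ** 2 <= 1.0

    img = np.zeros((n, n), dtype=np.float64)
    img[in_inner] = spec.interior_intensity
    img[in_outer & ~in_inner] = spec.skull_intensity

    if spec.lesion_zone is not None:
        cy, cx = spec.lesion_center()
        lesion = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.lesion_radius**2
        img[lesion] = spec.lesion_intensity

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def candidate_lesion_zones(spec: PhantomSpec, max_extent: float | None = None) -> list[tuple[int, int]]:
    """Interior zones whose centered lesion disc fits inside the brain.

    ``max_extent`` is the largest radius-plus-offset a jittered lesion
    may reach; defaults to the spec's radius.  Zones on the border ring
    of the grid are excluded (localization searches interior zones
    only).
    """
    if max_extent is None:
        max_extent = spec.lesion_radius
    ay, ax = spec.inner_axes
    sy, sx = ay - max_extent, ax - max_extent
    center = (spec.size - 1) / 2.0
    zh = spec.size / spec.grid.rows
    zw = spec.size / spec.grid.cols
    out = []
    for r in range(2, spec.grid.rows):
        for c in range(2, spec.grid.cols):
            cy, cx = (r - 0.5) * zh, (c - 0.5) * zw
            if ((cy - center) / sy) ** 2 + ((cx - center) / sx) ** 2 <= 1.0:
                out.append((r, c))
    return out


@dataclass(frozen=True)
class CohortJitter:
    """Per-phantom variability for cohort generation (all in pixels / intensity units)."""

    radius: float = 3.0  # lesion radius drawn uniformly within +/- this
    intensity: int = 15  # lesion intensity jitter, +/- (kept above threshold + 10)
    offset: float = 8.0  # lesion center offset from the zone center, per axis


@dataclass(frozen=True)
class PhantomRecord:
    """A generated slice with its label and, if suspected, its seeded lesion zone."""

    image: np.ndarray
    label: str
    lesion_zone: tuple[int, int] | None
    spec: PhantomSpec


def generate_cohort(
    n_normal: int,
    n_suspected: int,
    seed: int,
    jitter: CohortJitter | None = None,
    base: PhantomSpec | None = None,
) -> list[PhantomRecord]:
    """Generate a labeled cohort of phantoms, normals first.

    Suspected phantoms carry a lesion in a randomly chosen interior
    zone with jittered radius, intensity and sub-zone position; normal
    phantoms carry none.  Deterministic per seed: the same seed
    reproduces the cohort bit-exactly, and a different seed changes
    pixels but never the label counts.
    """
    if n_normal < 0 or n_suspected < 0:
        raise ValueError("cohort counts must be non-negative")
    if jitter is None:
        jitter = CohortJitter()
    if base is None:
        base = PhantomSpec()
    rng = np.random.default_rng(seed)
    max_extent = base.lesion_radius + jitter.radius + jitter.offset * np.sqrt(2)
    zones = candidate_lesion_zones(base, max_extent=max_extent)
    if n_suspected > 0 and not zones:
        raise PhantomSpecError("no interior zone can hold the jittered lesion")

    records: list[PhantomRecord] = []
    for _ in range(n_normal):
        spec = PhantomSpec(
            size=base.size,
            skull_outer=base.skull_outer,
            skull_inner=base.skull_inner,
            skull_intensity=base.skull_intensity,
            interior_intensity=base.interior_intensity,
            lesion_zone=None,
            noise_sd=base.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            grid=base.grid,
        )
        records.append(PhantomRecord(generate_phantom(spec), "normal", None, spec))
    for _ in range(n_suspected):
        zone = zones[int(rng.integers(len(zones)))]
        radius = base.lesion_radius + rng.uniform(-jitter.radius, jitter.radius)
        # keep the lesion comfortably hyperdense relative to the threshold
        intensity = int(
            np.clip(
                base.lesion_intensity + rng.integers(-jitter.intensity, jitter.intensity + 1),
                140,
                255,
            )
        )
        offset = tuple(rng.uniform(-jitter.offset, jitter.offset, size=2))
        spec = PhantomSpec(
            size=base.size,
            skull_outer=base.skull_outer,
            skull_inner=base.skull_inner,
            skull_intensity=base.skull_intensity,
            interior_intensity=base.interior_intensity,
            lesion_zone=zone,
            lesion_radius=float(radius),
            lesion_intensity=intensity,
            lesion_offset=offset,
            noise_sd=base.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            grid=base.grid,
        )
        records.append(PhantomRecord(generate_phantom(spec), "suspected", zone, spec))
    return records
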