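"""Fixed-tissue morphometrics: binarization, Sholl profiles, soma metrics, density.

Sholl analysis quantifies process-arbor ramification as the number of times
the binarized arbor crosses concentric circles centered on the soma.  On a
discrete image a "crossing" is a maximal 8-connected run of foreground pixels
along the rasterized (midpoint/Bresenham) sampling circle; runs wrapping the
0°/360° seam are merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import draw, morphology as skmorph

from .colocalization import triangle_threshold_value

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryMask",
    "ShollProfile",
    "SomaMetrics",
    "binarize",
    "circle_pixels",
    "count_ring_crossings",
    "sholl",
    "soma_metrics",
    "cell_density",
    "density_ratio",
]


@dataclass
class BinaryMask:
    """A thresholded 2D image plus its calibration and provenance."""

    mask: np.ndarray
    pixel_size: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class ShollProfile:
    """Intersection counts per concentric sampling radius for one cell."""

    radii: np.ndarray  # µm, increasing
    crossings: np.ndarray  # non-negative ints
    soma_center: tuple[int, int]

    def as_dict(self) -> dict[float, int]:
        return {float(r): int(c) for r, c in zip(self.radii, self.crossings)}


@dataclass
class SomaMetrics:
    area: float  # µm²
    mean_intensity_bg_subtracted: float


def binarize(
    image: np.ndarray,
    method: str = "triangle",
    value: float | None = None,
    min_size: int = 0,
    pixel_size: float = 1.0,
) -> BinaryMask:
    """Threshold a grayscale image into a process-arbor outline.

    ``method='triangle'`` derives the threshold from the image histogram;
    ``method='fixed'`` uses ``value``.  The threshold is applied strictly
    (``pixel > threshold``).  Connected components smaller than ``min_size``
    pixels are removed as artefacts.  A constant image under the triangle
    method yields an empty mask with a logged warning rather than an error.
    """
    image = np.asarray(image)
    if method == "fixed":
        if value is None:
            raise ValueError("fixed method requires a threshold value")
        threshold = float(value)
    elif method == "triangle":
        threshold = triangle_threshold_value(image)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = image > threshold
    if min_size > 1:
        # components strictly smaller than min_size are artefacts
        mask = skmorph.remove_small_objects(mask, max_size=min_size - 1)
    return BinaryMask(mask, pixel_size=pixel_size, provenance=f"{method}:{threshold}")


def circle_pixels(center: tuple[int, int], radius_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Midpoint-circle pixels around ``center``, ordered by angle.

    The returned ``(rows, cols)`` trace the discrete circle once; consecutive
    entries (including last→first) are 8-adjacent.  Coordinates may fall
    outside any particular image and must be bounds-checked by the caller.
    """
    if radius_px < 1:
        raise ValueError("radius must be at least 1 px")
    rr, cc = draw.circle_perimeter(center[0], center[1], radius_px, method="bresenham")
    angles = np.arctan2(rr - center[0], cc - center[1])
    order = np.argsort(angles, kind="stable")
    return rr[order], cc[order]


def count_ring_crossings(mask: np.ndarray, center: tuple[int, int], radius_px: int) -> int:
    """Number of maximal foreground runs along one sampling circle.

    Out-of-image circle pixels count as background.  The run structure is
    circular: a run spanning the angular seam is counted once.
    """
    rr, cc = circle_pixels(center, radius_px)
    inside = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
    fg = np.zeros(rr.shape, dtype=bool)
    fg[inside] = mask[rr[inside], cc[inside]]
    if not fg.any():
        return 0
    if fg.all():
        return 1
    # a run starts wherever foreground follows background (circularly)
    return int(np.sum(fg & ~np.roll(fg, 1)))


def sholl(
    mask: BinaryMask,
    soma_center: tuple[int, int],
    radius_step: float,
    max_radius: float,
) -> ShollProfile:
    """Sholl ramification profile of a binarized arbor.

    Sampling circles are placed every ``radius_step`` µm out to ``max_radius``
    µm; radii are converted to pixels through the mask's calibration.  The
    profile is computed on the 2D projection the mask came from.
    """
    if radius_step <= 0:
        raise ValueError("radius_step must be positive")
    r0, c0 = soma_center
    if not (0 <= r0 < mask.mask.shape[0] and 0 <= c0 < mask.mask.shape[1]):
        raise ValueError("soma_center outside image")
    if not mask.mask[r0, c0]:
        logger.warning("soma_center lies on background; profile computed anyway")
    radii_um = np.arange(radius_step, max_radius + radius_step / 2, radius_step)
    crossings = np.empty(radii_um.size, dtype=int)
    for i, r_um in enumerate(radii_um):
        r_px = max(1, int(round(r_um / mask.pixel_size)))
        crossings[i] = count_ring_crossings(mask.mask, soma_center, r_px)
    return ShollProfile(radii=radii_um, crossings=crossings, soma_center=(r0, c0))


def soma_metrics(
    image: np.ndarray,
    soma_mask: np.ndarray,
    background_mask: np.ndarray,
    pixel_size: float = 1.0,
) -> SomaMetrics:
    """Soma area and background-subtracted mean intensity.

    Area is the soma pixel count × pixel_size²; intensity is the soma mean
    minus the background-region mean (not clipped — a soma darker than
    background yields a negative value).
    """
    image = np.asarray(image, dtype=float)
    soma = np.asarray(soma_mask, dtype=bool)
    bg = np.asarray(background_mask, dtype=bool)
    if not soma.any():
        raise ValueError("empty soma region")
    if not bg.any():
        raise ValueError("empty background region")
    area = float(soma.sum()) * pixel_size**2
    intensity = float(image[soma].mean() - image[bg].mean())
    return SomaMetrics(area=area, mean_intensity_bg_subtracted=intensity)


def cell_density(
    body_positions: list[tuple[int, int, int]] | int,
    section_areas: list[float] | np.ndarray,
) -> float:
    """Cell bodies per unit area, pooled over all analyzed planes.

    ``body_positions`` may be the marked ``(z, row, col)`` positions or a
    plain count.  Density = count / sum of section areas.
    """
    areas = np.asarray(section_areas, dtype=float)
    if areas.size == 0 or areas.sum() <= 0:
        raise ValueError("total section area must be positive")
    if np.any(areas <= 0):
        raise ValueError("section areas must be positive")
    count = body_positions if isinstance(body_positions, int) else len(body_positions)
    return count / float(areas.sum())


def density_ratio(day_n_density: float, day0_density: float) -> float:
    """Density on a later day relative to day 0 in the same animal."""
    if day0_density <= 0:
        raise ValueError("day-0 density must be positive")
    return day_n_density / day0_density
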