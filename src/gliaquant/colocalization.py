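"""Two-channel engulfment scoring.

Quantifies internalized puncta (e.g. GluA1 receptor label inside microglia)
from two-channel confocal stacks: each channel is smoothed and binarized with
the triangle auto-threshold, the binary stacks are multiplied (logical AND),
and connected components of the product larger than one pixel are counted as
internalized puncta.  The result is normalized by the total area occupied by
the cell channel, giving puncta per µm².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

logger = logging.getLogger(__name__)

__all__ = [
    "triangle_threshold",
    "triangle_threshold_value",
    "PunctaResult",
    "colocalize",
    "compare_density",
]


def triangle_threshold(histogram: np.ndarray) -> int:
    """Triangle auto-threshold on an intensity histogram.

    Draws the straight line from the histogram peak to the farthest non-empty
    tail bin (the side of the longer tail; mirrored automatically when the
    tail lies below the peak) and returns the bin index that maximizes the
    perpendicular distance between the histogram curve and that line.  Ties
    are broken toward the peak, i.e. the more inclusive threshold.  The
    threshold is meant to be applied as *strictly greater than*.

    Raises
    ------
    ValueError
        If fewer than two bins are non-empty (no line can be drawn).
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1:
        raise ValueError("histogram must be 1D")
    nonzero = np.nonzero(hist)[0]
    if nonzero.size < 2:
        raise ValueError("triangle threshold needs at least two non-empty bins")
    peak = int(np.argmax(hist))
    left, right = int(nonzero[0]), int(nonzero[-1])
    # pick the farther tail; for a peak at the low end this is the right tail,
    # for a tail on the left the geometry is mirrored by the same formula
    tail = right if (right - peak) >= (peak - left) else left
    lo, hi = (peak, tail) if peak < tail else (tail, peak)
    xs = np.arange(lo, hi + 1)
    # unnormalized perpendicular distance: |cross((tail-peak, Δh), (x-peak, h[x]-h[peak]))|
    num = np.abs(
        (hist[tail] - hist[peak]) * (xs - peak) - (tail - peak) * (hist[xs] - hist[peak])
    )
    best = num.max()
    candidates = xs[num == best]
    # tie rule: the candidate closest to the peak
    threshold = int(candidates[np.argmin(np.abs(candidates - peak))])
    return threshold


def triangle_threshold_value(image: np.ndarray, nbins: int = 256) -> float:
    """Triangle threshold expressed on the image's intensity scale.

    Integer images use one bin per gray level; float images are histogrammed
    into ``nbins`` bins and the threshold is the selected bin's center.
    Returns ``inf`` for constant images (empty mask fallback; a warning is
    logged) so that ``image > value`` is empty.
    """
    image = np.asarray(image)
    if image.min() == image.max():
        logger.warning("constant image: triangle threshold undefined, returning inf")
        return float("inf")
    if np.issubdtype(image.dtype, np.integer):
        offset = int(image.min())
        hist = np.bincount((image - offset).ravel())
        return float(triangle_threshold(hist) + offset)
    hist, edges = np.histogram(image, bins=nbins)
    idx = triangle_threshold(hist)
    return float((edges[idx] + edges[idx + 1]) / 2)


@dataclass
class PunctaResult:
    """Internalized-puncta quantification for one image or stack pair."""

    n_internal_puncta: int
    microglia_area: float  # µm²
    density: float  # puncta per µm²
    cell_threshold: float
    puncta_threshold: float


def colocalize(
    cell_channel: np.ndarray,
    puncta_channel: np.ndarray,
    min_punctum_px: int = 1,
    pixel_size: float = 1.0,
    smooth_sigma: float = 1.0,
) -> PunctaResult:
    """Count puncta internalized by the cell channel.

    Both channels are Gaussian-smoothed (``smooth_sigma`` in px; 0 disables),
    triangle-thresholded, and multiplied.  Connected components of the product
    mask with size strictly greater than ``min_punctum_px`` pixels (default 1,
    i.e. "particles larger than 1 pixel") are counted.  3D stacks use
    26-connectivity so puncta spanning z-planes count once; 2D images use
    8-connectivity.  Density is the count divided by the summed per-plane
    foreground area of the cell channel in µm².
    """
    cell = np.asarray(cell_channel)
    puncta = np.asarray(puncta_channel)
    if cell.shape != puncta.shape:
        raise ValueError("channel shapes differ")
    if cell.ndim not in (2, 3):
        raise ValueError("expected 2D images or 3D stacks")
    if smooth_sigma > 0:
        cell_s = ndimage.gaussian_filter(cell.astype(float), smooth_sigma)
        puncta_s = ndimage.gaussian_filter(puncta.astype(float), smooth_sigma)
    else:
        cell_s, puncta_s = cell, puncta
    t_cell = triangle_threshold_value(cell_s)
    t_puncta = triangle_threshold_value(puncta_s)
    cell_mask = cell_s > t_cell
    puncta_mask = puncta_s > t_puncta
    if not cell_mask.any():
        raise ValueError("empty cell-channel mask: area normalizer is zero")
    product = cell_mask & puncta_mask
    labels = measure.label(product, connectivity=product.ndim)
    sizes = np.bincount(labels.ravel())[1:]
    n = int(np.sum(sizes > min_punctum_px))
    area = float(cell_mask.sum()) * pixel_size**2
    return PunctaResult(
        n_internal_puncta=n,
        microglia_area=area,
        density=n / area,
        cell_threshold=t_cell,
        puncta_threshold=t_puncta,
    )


def compare_density(
    group_a: list[PunctaResult], group_b: list[PunctaResult]
) -> dict[str, float]:
    """Descriptive per-group summary of puncta densities (mean ± s.e.m.)."""
    if not group_a or not group_b:
        raise ValueError("each group needs at least one result")

    def _summary(group: list[PunctaResult]) -> tuple[float, float]:
        vals = np.array([r.density for r in group], dtype=float)
        sem = 0.0 if vals.size < 2 else float(vals.std(ddof=1) / np.sqrt(vals.size))
        return float(vals.mean()), sem

    mean_a, sem_a = _summary(group_a)
    mean_b, sem_b = _summary(group_b)
    return {
        "mean_a": mean_a,
        "sem_a": sem_a,
        "mean_b": mean_b,
        "sem_b": sem_b,
        "difference": mean_a - mean_b,
    }
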