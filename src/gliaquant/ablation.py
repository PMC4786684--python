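"""Focal-injury chemotaxis quantification.

After a point laser ablation, microglial processes converge on the lesion.
The response is measured on thresholded time-lapse projections as the
accumulation of process pixels inside an inner disc (radius X, ~40 µm)
normalized by the process material initially available in the surrounding
annulus (X < r ≤ Y, Y ~80 µm):

    R(t) = (Rx(t) − Rx(0)) / Ry(0)

The inner compartment is the full disc of radius X, with a small core around
the lesion itself excluded (saturated/damaged pixels); Ry(0) is counted in
the annulus between X and Y at the first timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .thresholds import movie_thresholds

__all__ = [
    "AblationGeometry",
    "AblationResponseCurve",
    "ablation_response",
    "compare_response_curves",
]


@dataclass
class AblationGeometry:
    """Lesion-centered measurement geometry, in µm."""

    center: tuple[int, int]  # (row, col), px
    inner_radius: float  # µm (X)
    outer_radius: float  # µm (Y)
    core_exclusion: float = 5.0  # µm around the lesion excluded from Rx

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("require 0 < inner_radius < outer_radius")
        if not 0 <= self.core_exclusion < self.inner_radius:
            raise ValueError("core exclusion must be smaller than the inner radius")

    def region_masks(
        self, shape: tuple[int, int], pixel_size: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """(inner-disc mask, outer-annulus mask) for an image of ``shape``.

        Membership uses center-of-pixel distance in µm.  Raises if the outer
        annulus extends beyond the image.
        """
        rows = np.arange(shape[0])[:, None]
        cols = np.arange(shape[1])[None, :]
        dist = pixel_size * np.hypot(rows - self.center[0], cols - self.center[1])
        r_out_px = self.outer_radius / pixel_size
        if (
            self.center[0] - r_out_px < 0
            or self.center[1] - r_out_px < 0
            or self.center[0] + r_out_px > shape[0] - 1
            or self.center[1] + r_out_px > shape[1] - 1
        ):
            raise ValueError("annular regions extend beyond the image")
        inner = (dist <= self.inner_radius) & (dist > self.core_exclusion)
        outer = (dist > self.inner_radius) & (dist <= self.outer_radius)
        return inner, outer


@dataclass
class AblationResponseCurve:
    times: np.ndarray  # min
    R: np.ndarray
    Rx_counts: np.ndarray
    Ry0_count: int


def ablation_response(
    frames: list[np.ndarray],
    geometry: AblationGeometry,
    pixel_size: float = 1.0,
    frame_interval: float = 5.0,
    threshold: str = "isodata",
    per_frame_threshold: bool = False,
    fixed_threshold: float | None = None,
) -> AblationResponseCurve:
    """Compute R(t) for a thresholded time-lapse around a lesion.

    Thresholding follows the motility-module convention (one first-frame
    threshold by default; see :func:`gliaquant.thresholds.movie_thresholds`).
    R(0) = 0 by construction; Ry(0) = 0 raises because the normalizer is
    undefined.
    """
    if len(frames) < 2:
        raise ValueError("need at least two timepoints")
    frames = [np.asarray(f) for f in frames]
    inner, outer = geometry.region_masks(frames[0].shape, pixel_size)
    thresholds = movie_thresholds(frames, threshold, per_frame_threshold, fixed_threshold)
    masks = [f > t for f, t in zip(frames, thresholds)]
    rx = np.array([int(m[inner].sum()) for m in masks])
    ry0 = int(masks[0][outer].sum())
    if ry0 == 0:
        raise ValueError("Ry(0) = 0: no process material in the outer annulus")
    times = frame_interval * np.arange(len(frames), dtype=float)
    R = (rx - rx[0]) / ry0
    return AblationResponseCurve(times=times, R=R, Rx_counts=rx, Ry0_count=ry0)


def compare_response_curves(
    curves: list[AblationResponseCurve], group_labels: list[str]
) -> dict[str, dict[str, np.ndarray]]:
    """Per-timepoint group means ± s.e.m. of response curves.

    Curves within a group must share a common time grid.  Returns
    ``{group: {"times": ..., "mean": ..., "sem": ...}}``.
    """
    if len(curves) != len(group_labels):
        raise ValueError("one label per curve required")
    out: dict[str, dict[str, np.ndarray]] = {}
    for group in dict.fromkeys(group_labels):
        members = [c for c, g in zip(curves, group_labels) if g == group]
        times = members[0].times
        if not all(np.array_equal(c.times, times) for c in members):
            raise ValueError(f"group {group!r}: curves not on a common time grid")
        stack = np.stack([c.R for c in members])
        mean = stack.mean(axis=0)
        sem = (
            np.zeros_like(mean)
            if stack.shape[0] < 2
            else stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
        )
        out[group] = {"times": times, "mean": mean, "sem": sem}
    return out
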