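"""Image I/O, z-projection and translational registration.

All imagery is carried as an :class:`ImageStack`: a plain numpy array plus
physical calibration (pixel size in µm/px, frame interval in minutes for
time-lapse data).  Arrays use 0-based ``(row, col)`` indexing with the row
axis increasing downward; physical quantities are converted at the boundary
only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "read_stack",
    "write_stack",
    "max_project",
    "register_translation",
    "RegistrationResult",
]


@dataclass
class ImageStack:
    """A calibrated grayscale image stack.

    Parameters
    ----------
    data
        2D ``(y, x)``, 3D ``(z, y, x)`` or ``(t, y, x)``, or 4D
        ``(t, z, y, x)`` array.
    pixel_size
        Lateral calibration in µm per pixel.
    frame_interval
        Time between frames in minutes (time-lapse stacks only).
    axes
        Axis labels, e.g. ``"ZYX"`` or ``"TZYX"``.
    """

    data: np.ndarray
    pixel_size: float = 1.0
    frame_interval: float | None = None
    axes: str = field(default="")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim < 2 or self.data.ndim > 4:
            raise ValueError(f"expected 2-4 dimensional data, got {self.data.ndim}D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not self.axes:
            self.axes = {2: "YX", 3: "ZYX", 4: "TZYX"}[self.data.ndim]

    @property
    def n_planes(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[-2], self.data.shape[-1]


def read_stack(
    path: str | Path,
    pixel_size: float = 1.0,
    frame_interval: float | None = None,
) -> ImageStack:
    """Read a single- or multi-page TIFF into a calibrated stack.

    Page order is preserved; all pages must share one shape.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise IOError(f"inconsistent page shapes in {path}: {sorted(shapes)}")
        data = tif.asarray()
    if data.ndim == 2:
        data = data[np.newaxis]
    logger.info("read_stack(%s): shape=%s dtype=%s", path, data.shape, data.dtype)
    return ImageStack(data, pixel_size=pixel_size, frame_interval=frame_interval)


def write_stack(path: str | Path, stack: ImageStack | np.ndarray) -> None:
    """Write a stack as a multi-page TIFF, one page per leading-axis plane."""
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    tifffile.imwrite(path, data)


def max_project(stack: ImageStack | np.ndarray, z_range: slice | None = None) -> np.ndarray:
    """Maximum-intensity projection over a range of z planes.

    Mirrors the per-timepoint z-projections used ahead of every pixel-based
    analysis; ``z_range`` selects the planes (default: all).
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError("max_project expects a (z, y, x) stack")
    planes = data[z_range] if z_range is not None else data
    if planes.shape[0] == 0:
        raise ValueError("empty z_range")
    return planes.max(axis=0)


@dataclass
class RegistrationResult:
    """Aligned frames plus per-frame integer shifts and confidence."""

    frames: list[np.ndarray]
    shifts: list[tuple[int, int]]
    peak_ratios: list[float]
    validity_masks: list[np.ndarray]
    low_confidence: list[bool]


def _phase_correlation(reference: np.ndarray, frame: np.ndarray) -> tuple[tuple[int, int], float]:
    """Integer-pixel phase cross-correlation of ``frame`` against ``reference``.

    Returns the shift ``(dy, dx)`` such that ``frame ≈ np.roll(reference,
    (dy, dx))``, and the correlation peak ratio: the peak value divided by the
    largest value outside a 5×5 exclusion zone around the peak.  A ratio near
    1 means the peak is not distinguished from the background of the
    correlation surface (e.g. pure noise input).
    """
    a = np.asarray(reference, dtype=float)
    b = np.asarray(frame, dtype=float)
    fa = np.fft.fft2(a - a.mean())
    fb = np.fft.fft2(b - b.mean())
    cross = fa * np.conj(fb)
    mag = np.abs(cross)
    mag[mag == 0] = 1.0
    surface = np.real(np.fft.ifft2(cross / mag))
    peak_flat = int(np.argmax(surface))
    py, px = np.unravel_index(peak_flat, surface.shape)
    peak = surface[py, px]
    masked = surface.copy()
    ys = np.arange(surface.shape[0])[:, None]
    xs = np.arange(surface.shape[1])[None, :]
    dy = np.minimum(np.abs(ys - py), surface.shape[0] - np.abs(ys - py))
    dx = np.minimum(np.abs(xs - px), surface.shape[1] - np.abs(xs - px))
    masked[(dy <= 2) & (dx <= 2)] = -np.inf
    runner_up = masked.max()
    ratio = float("inf") if runner_up <= 0 else float(peak / runner_up)
    # peak index p corresponds to frame ≈ roll(reference, -p)
    sy = -py if py <= surface.shape[0] // 2 else surface.shape[0] - py
    sx = -px if px <= surface.shape[1] // 2 else surface.shape[1] - px
    return (int(sy), int(sx)), ratio


def _validity_mask(shape: tuple[int, int], shift: tuple[int, int]) -> np.ndarray:
    """Pixels that remain in-frame after undoing an integer shift."""
    mask = np.ones(shape, dtype=bool)
    dy, dx = shift
    # np.roll(a, k) wraps a[-k:] into rows [0:k] for k > 0 and a[:|k|] into
    # the last |k| rows for k < 0; wrapped content is invalid.
    if dy > 0:
        mask[:dy, :] = False
    elif dy < 0:
        mask[dy:, :] = False
    if dx > 0:
        mask[:, :dx] = False
    elif dx < 0:
        mask[:, dx:] = False
    return mask


def register_translation(
    frames: Sequence[np.ndarray],
    reference: int = 0,
    peak_ratio_threshold: float = 1.5,
    strategy: str = "previous",
) -> RegistrationResult:
    """Correct lateral motion by translation-only registration.

    Each frame's integer offset to the reference frame is estimated by phase
    cross-correlation and undone with a circular shift; pixels wrapped in from
    the opposite border are marked invalid in the per-frame validity mask and
    must be excluded from downstream pixel counts.  Frames whose correlation
    peak ratio falls below ``peak_ratio_threshold`` are flagged low-confidence
    (the estimate is still returned).

    ``strategy='previous'`` (default) correlates consecutive frames and
    composes the shifts — robust when the scene itself remodels over the
    session, because adjacent frames stay similar; ``strategy='fixed'``
    correlates every frame directly against the reference frame.
    """
    frames = [np.asarray(f) for f in frames]
    if len(frames) == 0:
        raise ValueError("no frames to register")
    if not all(f.shape == frames[0].shape for f in frames):
        raise ValueError("all frames must share one shape")
    if strategy not in ("previous", "fixed"):
        raise ValueError(f"unknown registration strategy {strategy!r}")
    ref = frames[reference]
    aligned: list[np.ndarray] = []
    shifts: list[tuple[int, int]] = []
    ratios: list[float] = []
    masks: list[np.ndarray] = []
    flags: list[bool] = []
    # offsets of every frame relative to its predecessor, composed later
    for i, frame in enumerate(frames):
        if i == reference:
            shift, ratio = (0, 0), float("inf")
        elif strategy == "fixed":
            shift, ratio = _phase_correlation(ref, frame)
        else:
            step = 1 if i > reference else -1
            shift, ratio = (0, 0), float("inf")
            j = reference
            while j != i:
                d, r = _phase_correlation(frames[j], frames[j + step])
                shift = (shift[0] + d[0], shift[1] + d[1])
                ratio = min(ratio, r)
                j += step
        aligned.append(np.roll(frame, (-shift[0], -shift[1]), axis=(0, 1)))
        shifts.append(shift)
        ratios.append(ratio)
        masks.append(_validity_mask(frame.shape, (-shift[0], -shift[1])))
        flags.append(ratio < peak_ratio_threshold)
        logger.info("register frame %d: shift=%s peak_ratio=%.3g", i, shift, ratio)
    return RegistrationResult(aligned, shifts, ratios, masks, flags)
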