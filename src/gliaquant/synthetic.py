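"""Seeded synthetic inputs with known ground truth for every analysis stage.

Real microglia imaging from this kind of study is rarely deposited, so each
generator here emulates the statistical structure one analysis stage assumes
and records the exact ground truth it planted:

- branching arbors on a dark background with analytic Sholl crossing counts;
- time-lapse movies whose per-interval extended/retracted pixel sets are
  known exactly;
- post-ablation movies of processes converging on a lesion, with per-frame
  inner-compartment pixel counts;
- two-channel images with planted internal/external puncta;
- stimulus-locked sinusoidal reflectance sessions with planted per-pixel
  amplitudes per eye;
- per-process EM event tables with planted group densities.

Every generator is a pure function of its parameters and seed.  Generated
binary content uses 0 background and max-intensity foreground; grayscale
variants add Gaussian noise and clip to the dtype range.  The planted ground
truth always equals what brute-force recomputation from the generated arrays
gives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .ablation import AblationGeometry

__all__ = [
    "draw_line_4connected",
    "SyntheticArbor",
    "generate_arbor",
    "SyntheticTimelapse",
    "generate_timelapse",
    "SyntheticAblationMovie",
    "generate_ablation_movie",
    "SyntheticPunctaImage",
    "generate_puncta_image",
    "SyntheticIosSession",
    "generate_ios_session",
    "SyntheticEventTable",
    "generate_event_table",
]

FOREGROUND = 255

_CROSS = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=int)  # 4-neighborhood


def _to_grayscale(mask: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Binary content is 0/255; noisy variants sit on a detector-style baseline.

    The baseline keeps the background noise distribution unimodal instead of
    clipping half of it onto the zero bin, which would degenerate the
    histogram shape every auto-threshold method assumes.
    """
    if noise_sd <= 0:
        return np.where(mask, FOREGROUND, 0).astype(np.uint8)
    baseline = 30.0
    img = np.where(mask, float(FOREGROUND), baseline)
    img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def draw_line_4connected(r0: int, c0: int, r1: int, c1: int) -> list[tuple[int, int]]:
    """Rasterize a 1-px-wide 4-connected line from (r0, c0) to (r1, c1).

    Consecutive pixels differ in exactly one coordinate, so the line cannot
    slip diagonally through an 8-connected ring — circle crossings stay
    unambiguous.
    """
    dr, dc = r1 - r0, c1 - c0
    sr = 1 if dr > 0 else -1
    sc = 1 if dc > 0 else -1
    pts = [(r0, c0)]
    r, c = r0, c0
    for _ in range(abs(dr) + abs(dc)):
        if r == r1:
            c += sc
        elif c == c1:
            r += sr
        else:
            # pick the axis step deviating least from the ideal line
            err_r = abs((r + sr - r0) * dc - (c - c0) * dr)
            err_c = abs((r - r0) * dc - (c + sc - c0) * dr)
            if err_r <= err_c:
                r += sr
            else:
                c += sc
        pts.append((r, c))
    return pts


# ---------------------------------------------------------------------------
# arbors


@dataclass
class SyntheticArbor:
    """A rasterized radial arbor with analytic Sholl ground truth."""

    image: np.ndarray
    soma_center: tuple[int, int]
    ground_truth_crossings: dict[float, int]  # radius µm -> count
    pixel_size: float
    branch_lengths_um: list[float] = field(default_factory=list)

    @property
    def mask(self) -> np.ndarray:
        return self.image > 0


def generate_arbor(
    n_branches: int,
    branch_radii: list[float],
    pixel_size: float = 1.0,
    seed: int = 0,
    soma_radius_px: int = 2,
    noise_sd: float = 0.0,
) -> SyntheticArbor:
    """A soma with straight radial branches and known circle crossings.

    Branch lengths are drawn between the smallest sampling radius and a bit
    beyond the largest, kept at least 2 px away from every sampling radius so
    the analytic crossing count at radius r — the number of branches longer
    than r — is unambiguous after rasterization.  Branch angles are evenly
    spaced with jitter and far enough apart that runs on the innermost
    sampling circle cannot merge.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if n_branches < 0:
        raise ValueError("n_branches must be non-negative")
    radii = [float(r) for r in branch_radii]
    if any(r <= 0 for r in radii) or any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("branch_radii must be positive and strictly increasing")
    rng = np.random.default_rng(seed)
    max_r = max(radii) if radii else 20.0 * pixel_size
    min_r = min(radii) if radii else 5.0 * pixel_size
    if n_branches > 0:
        min_gap_px = 2 * np.pi * (min_r / pixel_size) / n_branches
        if min_gap_px < 4:
            raise ValueError(
                "too many branches for the smallest sampling radius: "
                "circle runs would merge"
            )
    margin_um = 2.0 * pixel_size
    half = int(np.ceil((max_r + 6 * pixel_size) / pixel_size)) + 4
    size = 2 * half + 1
    center = (half, half)
    image = np.zeros((size, size), dtype=bool)
    rows = np.arange(size)[:, None]
    cols = np.arange(size)[None, :]
    image[np.hypot(rows - half, cols - half) <= soma_radius_px] = True

    lengths: list[float] = []
    if n_branches == 1:
        lengths = [max_r + 3 * pixel_size]
    else:
        for _ in range(n_branches):
            length = rng.uniform(min_r + margin_um, max_r + 4 * pixel_size)
            for r in radii:  # keep a safe band around every sampling circle
                if abs(length - r) < margin_um:
                    length = r + margin_um
            lengths.append(length)
    base = rng.uniform(0, 2 * np.pi)
    spacing = 2 * np.pi / max(n_branches, 1)
    for i, length in enumerate(lengths):
        theta = base + i * spacing + rng.uniform(-0.15, 0.15) * spacing
        end_r = center[0] + int(round(np.sin(theta) * length / pixel_size))
        end_c = center[1] + int(round(np.cos(theta) * length / pixel_size))
        for r, c in draw_line_4connected(center[0], center[1], end_r, end_c):
            image[r, c] = True
    crossings = {r: int(sum(length > r for length in lengths)) for r in radii}
    return SyntheticArbor(
        image=_to_grayscale(image, noise_sd, rng),
        soma_center=center,
        ground_truth_crossings=crossings,
        pixel_size=pixel_size,
        branch_lengths_um=lengths,
    )


# ---------------------------------------------------------------------------
# time-lapse movies


@dataclass
class SyntheticTimelapse:
    """A movie with exactly known per-interval extension/retraction sets."""

    frames: list[np.ndarray]  # grayscale
    masks: list[np.ndarray]  # exact boolean foreground per frame
    frame_interval: float  # min
    planted_fractions: tuple[float, float]
    added: list[np.ndarray]  # boolean array per interval
    removed: list[np.ndarray]
    seed: int


def _tips(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at most one 4-connected foreground neighbor."""
    neighbors = ndimage.convolve(mask.astype(int), _CROSS, mode="constant")
    return mask & (neighbors <= 1)


def generate_timelapse(
    base_arbor: SyntheticArbor,
    T: int = 12,
    extension_fraction: float = 0.1,
    retraction_fraction: float = 0.1,
    frame_interval: float = 4.0,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> SyntheticTimelapse:
    """Evolve an arbor tip-wise for T frames with planted change fractions.

    Per interval, ``retraction_fraction`` of the current foreground is removed
    tip-by-tip (pixels with ≤1 foreground neighbor) and ``extension_fraction``
    is added pixel-by-pixel onto background 4-neighbors of the foreground,
    never re-adding a pixel removed in the same interval.  The exact
    added/removed pixel sets are recorded per interval.
    """
    if T < 2:
        raise ValueError("T must be at least 2")
    if not (0 <= extension_fraction <= 1 and 0 <= retraction_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = base_arbor.mask.copy()
    masks = [mask.copy()]
    added_sets: list[np.ndarray] = []
    removed_sets: list[np.ndarray] = []
    for _ in range(T - 1):
        fg_count = int(mask.sum())
        n_ret = int(round(retraction_fraction * fg_count))
        n_ext = int(round(extension_fraction * fg_count))
        if fg_count - n_ret <= 0:
            raise ValueError("retraction fraction would empty the foreground")
        removed = np.zeros_like(mask)
        current = mask.copy()
        for _ in range(n_ret):
            tips = np.argwhere(_tips(current))
            if tips.size == 0:
                break
            r, c = tips[rng.integers(len(tips))]
            current[r, c] = False
            removed[r, c] = True
        added = np.zeros_like(mask)
        for _ in range(n_ext):
            border = ndimage.binary_dilation(current, structure=_CROSS.astype(bool))
            candidates = np.argwhere(border & ~current & ~removed)
            if candidates.size == 0:
                break
            r, c = candidates[rng.integers(len(candidates))]
            current[r, c] = True
            added[r, c] = True
        mask = current
        masks.append(mask.copy())
        added_sets.append(added)
        removed_sets.append(removed)
    frames = [_to_grayscale(m, noise_sd, rng) for m in masks]
    return SyntheticTimelapse(
        frames=frames,
        masks=masks,
        frame_interval=frame_interval,
        planted_fractions=(extension_fraction, retraction_fraction),
        added=added_sets,
        removed=removed_sets,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ablation movies


@dataclass
class SyntheticAblationMovie:
    frames: list[np.ndarray]
    geometry: AblationGeometry
    pixel_size: float
    frame_interval: float  # min
    planted_Rx_counts: np.ndarray  # inner-compartment foreground per frame
    planted_Ry0: int


def generate_ablation_movie(
    T: int = 12,
    converge_rate: float = 4.0,
    seed: int = 0,
    n_processes: int = 12,
    inner_radius_um: float = 40.0,
    outer_radius_um: float = 80.0,
    pixel_size: float = 1.0,
    frame_interval: float = 5.0,
    noise_sd: float = 0.0,
) -> SyntheticAblationMovie:
    """Radial process fronts stepping toward a central lesion.

    Each process is a short 1-px radial segment that advances inward by
    ``converge_rate`` px per frame and parks at a stop radius inside the
    inner compartment (outside the excluded lesion core).  Total foreground
    stays approximately constant — chemotactic translocation, not growth.
    The planted per-frame inner counts are recomputed from the generated
    frames with the same disc-membership rule the analysis uses.
    """
    if converge_rate < 0:
        raise ValueError("converge_rate must be non-negative")
    if T < 2:
        raise ValueError("T must be at least 2")
    rng = np.random.default_rng(seed)
    r_out_px = outer_radius_um / pixel_size
    half = int(np.ceil(r_out_px)) + 14
    size = 2 * half + 1
    center = (half, half)
    geometry = AblationGeometry(
        center=center, inner_radius=inner_radius_um, outer_radius=outer_radius_um
    )
    seg_len = 6
    # park each segment fully inside the inner compartment (margin from the
    # boundary, clear of the excluded lesion core); processes translate as
    # rigid pixel sets so the foreground count per process never fluctuates
    park_px = max(
        geometry.core_exclusion / pixel_size + 4,
        inner_radius_um / pixel_size - seg_len - 4,
    )
    base = rng.uniform(0, 2 * np.pi)
    spacing = 2 * np.pi / n_processes
    angles = base + spacing * np.arange(n_processes) + rng.uniform(
        -0.15, 0.15, n_processes
    ) * spacing
    start_radii = rng.uniform(r_out_px * 0.55, r_out_px * 1.05, n_processes)
    segments = []
    for theta, r0 in zip(angles, start_radii):
        p0 = (
            center[0] + int(round(np.sin(theta) * r0)),
            center[1] + int(round(np.cos(theta) * r0)),
        )
        p1 = (
            center[0] + int(round(np.sin(theta) * (r0 + seg_len))),
            center[1] + int(round(np.cos(theta) * (r0 + seg_len))),
        )
        pixels = np.array(draw_line_4connected(p0[0], p0[1], p1[0], p1[1]))
        segments.append((theta, r0, pixels))
    frames_masks: list[np.ndarray] = []
    for t in range(T):
        mask = np.zeros((size, size), dtype=bool)
        for theta, r0, pixels in segments:
            travel = min(converge_rate * t, max(0.0, r0 - park_px))
            dr = int(round(np.sin(theta) * travel))
            dc = int(round(np.cos(theta) * travel))
            moved = pixels - (dr, dc)
            mask[moved[:, 0], moved[:, 1]] = True
        frames_masks.append(mask)
    inner, outer = geometry.region_masks((size, size), pixel_size)
    rx = np.array([int(m[inner].sum()) for m in frames_masks])
    ry0 = int(frames_masks[0][outer].sum())
    frames = [_to_grayscale(m, noise_sd, rng) for m in frames_masks]
    return SyntheticAblationMovie(
        frames=frames,
        geometry=geometry,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        planted_Rx_counts=rx,
        planted_Ry0=ry0,
    )


# ---------------------------------------------------------------------------
# two-channel puncta images


@dataclass
class SyntheticPunctaImage:
    channel_cell: np.ndarray
    channel_puncta: np.ndarray
    cell_mask: np.ndarray
    planted_internal_puncta: int
    planted_external_puncta: int
    planted_single_pixel_overlaps: int
    puncta_size_px: int
    pixel_size: float


def _blob_offsets(size_px: int) -> np.ndarray:
    """The ``size_px`` most compact pixel offsets around the origin."""
    span = np.arange(-4, 5)
    offs = np.array([(r, c) for r in span for c in span])
    order = np.argsort(np.hypot(offs[:, 0], offs[:, 1]), kind="stable")
    return offs[order][:size_px]


def generate_puncta_image(
    n_internal: int,
    n_external: int,
    puncta_size_px: int = 4,
    seed: int = 0,
    image_size: int = 128,
    pixel_size: float = 1.0,
    n_single_pixel_overlaps: int = 0,
    noise_sd: float = 0.0,
) -> SyntheticPunctaImage:
    """Two-channel image with planted internal and external puncta.

    Internal puncta lie wholly inside the cell mask with a safety margin;
    external puncta are well clear of it; optional boundary puncta overlap
    the cell mask by exactly one pixel (so the ">1 pixel" rule must reject
    them).  Puncta are compact multi-pixel blobs kept ≥4 px apart.
    """
    if puncta_size_px < 2:
        raise ValueError("puncta_size_px must be at least 2")
    rng = np.random.default_rng(seed)
    half = image_size // 2
    rows = np.arange(image_size)[:, None]
    cols = np.arange(image_size)[None, :]
    dist = np.hypot(rows - half, cols - half)
    cell_radius = image_size * 0.28
    cell_mask = dist <= cell_radius
    interior = dist <= cell_radius - 4  # margin keeps blobs fully internal
    offs = _blob_offsets(puncta_size_px)
    puncta_mask = np.zeros_like(cell_mask)
    occupied = np.zeros_like(cell_mask)  # puncta dilated by the separation

    def _try_place(valid_region: np.ndarray) -> bool:
        candidates = np.argwhere(valid_region & ~occupied)
        if candidates.size == 0:
            return False
        for _ in range(200):
            r, c = candidates[rng.integers(len(candidates))]
            pix = offs + (r, c)
            if (pix < 0).any() or (pix >= image_size).any():
                continue
            if occupied[pix[:, 0], pix[:, 1]].any():
                continue
            if not valid_region[pix[:, 0], pix[:, 1]].all():
                continue
            puncta_mask[pix[:, 0], pix[:, 1]] = True
            tmp = np.zeros_like(cell_mask)
            tmp[pix[:, 0], pix[:, 1]] = True
            occupied[:] = occupied | ndimage.binary_dilation(tmp, iterations=4)
            return True
        return False

    for _ in range(n_internal):
        if not _try_place(interior):
            raise ValueError("could not place all internal puncta; reduce n_internal")
    exterior = dist >= cell_radius + 5
    exterior[:6, :] = exterior[-6:, :] = False
    exterior[:, :6] = exterior[:, -6:] = False
    for _ in range(n_external):
        if not _try_place(exterior):
            raise ValueError("could not place all external puncta; reduce n_external")

    # boundary puncta with exactly one pixel inside the cell mask: one pixel
    # on the rim, the rest extending radially outward
    placed_boundary = 0
    rim = cell_mask & ~ndimage.binary_erosion(cell_mask)
    rim_pts = np.argwhere(rim)
    attempts = 0
    while placed_boundary < n_single_pixel_overlaps and attempts < 500:
        attempts += 1
        r, c = rim_pts[rng.integers(len(rim_pts))]
        vr, vc = r - half, c - half
        norm = np.hypot(vr, vc)
        step = (vr / norm, vc / norm)
        pix = [(int(r), int(c))]
        rr, cc = float(r), float(c)
        while len(pix) < puncta_size_px:
            rr += step[0]
            cc += step[1]
            p = (int(round(rr)), int(round(cc)))
            if p != pix[-1]:
                pix.append(p)
        pix = np.array(pix[:puncta_size_px])
        if (pix < 0).any() or (pix >= image_size).any():
            continue
        if occupied[pix[:, 0], pix[:, 1]].any():
            continue
        if int(cell_mask[pix[:, 0], pix[:, 1]].sum()) != 1:
            continue
        puncta_mask[pix[:, 0], pix[:, 1]] = True
        tmp = np.zeros_like(cell_mask)
        tmp[pix[:, 0], pix[:, 1]] = True
        occupied |= ndimage.binary_dilation(tmp, iterations=4)
        placed_boundary += 1
    if placed_boundary < n_single_pixel_overlaps:
        raise ValueError("could not place all single-pixel-overlap puncta")

    cell_img = np.where(cell_mask, 200.0, 10.0)
    puncta_img = np.where(puncta_mask, 220.0, 10.0)
    if noise_sd > 0:
        cell_img = cell_img + rng.normal(0, noise_sd, cell_img.shape)
        puncta_img = puncta_img + rng.normal(0, noise_sd, puncta_img.shape)
    return SyntheticPunctaImage(
        channel_cell=np.clip(np.round(cell_img), 0, 255).astype(np.uint8),
        channel_puncta=np.clip(np.round(puncta_img), 0, 255).astype(np.uint8),
        cell_mask=cell_mask,
        planted_internal_puncta=n_internal,
        planted_external_puncta=n_external,
        planted_single_pixel_overlaps=n_single_pixel_overlaps,
        puncta_size_px=puncta_size_px,
        pixel_size=pixel_size,
    )


# ---------------------------------------------------------------------------
# intrinsic-signal sessions


@dataclass
class SyntheticIosSession:
    """Per-eye, per-direction reflectance movies with planted amplitudes."""

    series: dict[str, dict[str, np.ndarray]]  # eye -> direction -> (t, y, x)
    sampling_rate: float  # Hz
    stim_frequency: float  # Hz
    planted_amplitude_contra: np.ndarray
    planted_amplitude_ipsi: np.ndarray
    noise_sd: float

    def planted_odi(self, roi: np.ndarray) -> float:
        roi = np.asarray(roi, dtype=bool)
        c = float(self.planted_amplitude_contra[roi].mean())
        i = float(self.planted_amplitude_ipsi[roi].mean())
        return (c - i) / (c + i)


def generate_ios_session(
    amp_contra: float | np.ndarray,
    amp_ipsi: float | np.ndarray,
    stim_frequency: float = 0.05,
    duration: float = 360.0,
    sampling_rate: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (8, 8),
    dc: float = 100.0,
) -> SyntheticIosSession:
    """Sinusoidal stimulus-locked sessions for both eyes and directions.

    Each pixel's signal is DC + A·sin(2π·f·t + φ) + Gaussian noise with the
    planted per-pixel amplitude A and a random phase.  The duration must be
    an integer number of stimulus periods (and of samples) so the stimulus
    frequency falls on an exact FFT bin.
    """
    if stim_frequency >= sampling_rate / 2:
        raise ValueError("stimulus frequency must be below Nyquist")
    n_cycles = stim_frequency * duration
    if abs(n_cycles - round(n_cycles)) > 1e-9 or round(n_cycles) < 1:
        raise ValueError("duration must be a positive integer multiple of the stimulus period")
    n = sampling_rate * duration
    if abs(n - round(n)) > 1e-9:
        raise ValueError("duration must span an integer number of samples")
    n = int(round(n))
    rng = np.random.default_rng(seed)
    contra = np.broadcast_to(np.asarray(amp_contra, dtype=float), shape).copy()
    ipsi = np.broadcast_to(np.asarray(amp_ipsi, dtype=float), shape).copy()
    if (contra < 0).any() or (ipsi < 0).any():
        raise ValueError("planted amplitudes must be non-negative")
    t = np.arange(n) / sampling_rate
    series: dict[str, dict[str, np.ndarray]] = {}
    for eye, amp in (("contra", contra), ("ipsi", ipsi)):
        series[eye] = {}
        for direction in ("up", "down"):
            phase = rng.uniform(0, 2 * np.pi, shape)
            sig = dc + amp[None] * np.sin(
                2 * np.pi * stim_frequency * t[:, None, None] + phase[None]
            )
            if noise_sd > 0:
                sig = sig + rng.normal(0, noise_sd, sig.shape)
            series[eye][direction] = sig
    return SyntheticIosSession(
        series=series,
        sampling_rate=sampling_rate,
        stim_frequency=stim_frequency,
        planted_amplitude_contra=contra,
        planted_amplitude_ipsi=ipsi,
        noise_sd=noise_sd,
    )


# ---------------------------------------------------------------------------
# EM event tables


@dataclass
class SyntheticEventTable:
    table: pd.DataFrame
    planted_densities: dict[str, dict[str, float]]  # group -> category -> events/µm²


def generate_event_table(
    group_densities: dict[str, float | dict[str, float]],
    n_processes: int = 60,
    area_range: tuple[float, float] = (1.0, 8.0),
    n_animals: int = 3,
    seed: int = 0,
) -> SyntheticEventTable:
    """Per-process event-count tables with planted group-mean densities.

    Process areas are uniform over ``area_range`` (µm²) and event counts are
    Poisson with mean density × area, so the planted density is the expected
    events/µm² of every process.  ``group_densities`` maps each group either
    to a single density (category ``events``) or to per-category densities.
    """
    if n_processes < 1 or n_animals < 1:
        raise ValueError("need at least one process and one animal per group")
    lo, hi = area_range
    if not 0 < lo <= hi:
        raise ValueError("area_range must be positive with lo <= hi")
    rng = np.random.default_rng(seed)
    planted: dict[str, dict[str, float]] = {}
    for group, dens in group_densities.items():
        planted[group] = dict(dens) if isinstance(dens, dict) else {"events": float(dens)}
        if any(v < 0 for v in planted[group].values()):
            raise ValueError("densities must be non-negative")
    categories = sorted({c for d in planted.values() for c in d})
    rows = []
    for group, dens in planted.items():
        for a in range(n_animals):
            areas = rng.uniform(lo, hi, n_processes)
            counts = {
                cat: rng.poisson(dens.get(cat, 0.0) * areas) for cat in categories
            }
            for p in range(n_processes):
                row = {
                    "animal": f"{group}_animal{a}",
                    "group": group,
                    "process": p,
                    "area_um2": areas[p],
                }
                row.update({cat: int(counts[cat][p]) for cat in categories})
                rows.append(row)
    return SyntheticEventTable(table=pd.DataFrame(rows), planted_densities=planted)
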