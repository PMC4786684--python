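"""Time-lapse pixel-classification motility analysis.

Consecutive thresholded z-projections are compared pixel-by-pixel, mirroring
the red/green/yellow overlay convention of in-vivo two-photon microglia
imaging: *stable* pixels are foreground at both timepoints, *extended* pixels
appear only in the later frame, *retracted* pixels only in the earlier one.

From a sequence of such change maps the module computes:

- motility index: (extension + retraction pixels) / stable pixels per
  interval, averaged across intervals (a per-interval quantity, e.g. "change
  over 4 min");
- extension and retraction indices (each component over stable pixels);
- stability index: fraction of newly extended pixels that are stable in the
  next overlay;
- instability index: fraction of stable pixels retracted in the next overlay;
- stability histogram: survival of newly stabilized pixels over subsequent
  overlays, excluding pixels stable for the whole session;
- traced-process motility: mean |ΔL|/Δt for manually traced process lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .io import register_translation
from .morphology import BinaryMask
from .thresholds import movie_thresholds

logger = logging.getLogger(__name__)

__all__ = [
    "Label",
    "ChangeMap",
    "MotilityResult",
    "TracedProcessSeries",
    "classify_changes",
    "motility_index",
    "stability_index",
    "instability_index",
    "stability_histogram",
    "traced_motility",
    "analyze_movie",
]


class Label(IntEnum):
    BACKGROUND = 0
    STABLE = 1
    EXTENDED = 2
    RETRACTED = 3


@dataclass
class ChangeMap:
    """Per-pixel three-way classification for one consecutive frame pair."""

    labels: np.ndarray  # values from Label
    interval_index: int = 0
    validity_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.validity_mask is None:
            self.validity_mask = np.ones(self.labels.shape, dtype=bool)

    def count(self, label: Label) -> int:
        return int(np.sum((self.labels == label) & self.validity_mask))

    @property
    def counts(self) -> dict[str, int]:
        return {lab.name.lower(): self.count(lab) for lab in Label}


@dataclass
class MotilityResult:
    motility_index: float
    extension_index: float
    retraction_index: float
    per_interval_motility: list[float] = field(default_factory=list)
    stability_index: float | None = None
    instability_index: float | None = None
    per_pair_stability: list[float] = field(default_factory=list)
    per_pair_instability: list[float] = field(default_factory=list)
    stability_histogram: list[float] = field(default_factory=list)


def classify_changes(
    mask_t1: BinaryMask | np.ndarray,
    mask_t2: BinaryMask | np.ndarray,
    validity: np.ndarray | None = None,
    interval_index: int = 0,
) -> ChangeMap:
    """Classify each pixel of a registered frame pair.

    stable = foreground in both frames; extended = only in the later frame;
    retracted = only in the earlier frame.  Pixels outside ``validity`` keep
    their label but are excluded from every count.
    """
    m1 = mask_t1.mask if isinstance(mask_t1, BinaryMask) else np.asarray(mask_t1, bool)
    m2 = mask_t2.mask if isinstance(mask_t2, BinaryMask) else np.asarray(mask_t2, bool)
    if m1.shape != m2.shape:
        raise ValueError("mask shapes differ")
    labels = np.full(m1.shape, Label.BACKGROUND, dtype=np.uint8)
    labels[m1 & m2] = Label.STABLE
    labels[~m1 & m2] = Label.EXTENDED
    labels[m1 & ~m2] = Label.RETRACTED
    if validity is not None and validity.shape != m1.shape:
        raise ValueError("validity mask shape differs")
    return ChangeMap(labels, interval_index=interval_index, validity_mask=validity)


def motility_index(change_maps: list[ChangeMap]) -> MotilityResult:
    """Motility, extension and retraction indices averaged across overlays.

    Per overlay: motility = (extended + retracted) / stable.  An overlay with
    zero stable pixels makes the ratio undefined and raises, naming the
    interval.
    """
    if not change_maps:
        raise ValueError("need at least one change map")
    mot, ext, ret = [], [], []
    for cm in change_maps:
        s = cm.count(Label.STABLE)
        if s == 0:
            raise ValueError(
                f"interval {cm.interval_index}: zero stable pixels, motility undefined"
            )
        e, r = cm.count(Label.EXTENDED), cm.count(Label.RETRACTED)
        mot.append((e + r) / s)
        ext.append(e / s)
        ret.append(r / s)
    return MotilityResult(
        motility_index=float(np.mean(mot)),
        extension_index=float(np.mean(ext)),
        retraction_index=float(np.mean(ret)),
        per_interval_motility=[float(v) for v in mot],
    )


def _valid_both(a: ChangeMap, b: ChangeMap) -> np.ndarray:
    if a.labels.shape != b.labels.shape:
        raise ValueError("overlay shapes differ")
    return a.validity_mask & b.validity_mask


def stability_index(overlay_k: ChangeMap, overlay_k1: ChangeMap) -> float:
    """Fraction of extension pixels in overlay k stable in overlay k+1.

    Undefined (NaN) when overlay k has no extension pixels; the missing value
    propagates and is omitted from averages rather than counted as 0.
    """
    valid = _valid_both(overlay_k, overlay_k1)
    ext = (overlay_k.labels == Label.EXTENDED) & valid
    n_ext = int(ext.sum())
    if n_ext == 0:
        return float("nan")
    persisted = int((ext & (overlay_k1.labels == Label.STABLE)).sum())
    return persisted / n_ext


def instability_index(overlay_k: ChangeMap, overlay_k1: ChangeMap) -> float:
    """Fraction of stable pixels in overlay k retracted in overlay k+1."""
    valid = _valid_both(overlay_k, overlay_k1)
    stable = (overlay_k.labels == Label.STABLE) & valid
    n_stable = int(stable.sum())
    if n_stable == 0:
        return float("nan")
    lost = int((stable & (overlay_k1.labels == Label.RETRACTED)).sum())
    return lost / n_stable


def stability_histogram(change_maps: list[ChangeMap]) -> list[float]:
    """Survival of newly stabilized pixels over subsequent overlays.

    A pixel enters the cohort at its first extension→stable transition
    (extended in overlay k, stable in overlay k+1).  The histogram reports,
    for each offset j, the fraction of cohort pixels that remained stable in
    every overlay from k+1 through k+1+j.  Offset 0 is the stabilization
    overlay itself (fraction 1 by construction).  Pixels stable in every
    overlay of the session (somas, primary processes) are excluded.  Each
    offset's denominator counts only cohort pixels whose remaining session is
    long enough to observe that offset.  Returns an empty list (and logs a
    warning) if no pixel ever newly stabilizes.
    """
    if len(change_maps) < 3:
        raise ValueError("stability histogram needs at least 3 overlays")
    shape = change_maps[0].labels.shape
    stable_stack = np.stack([cm.labels == Label.STABLE for cm in change_maps])
    ext_stack = np.stack([cm.labels == Label.EXTENDED for cm in change_maps])
    valid_all = np.logical_and.reduce([cm.validity_mask for cm in change_maps])
    always_stable = stable_stack.all(axis=0)
    n_overlays = len(change_maps)
    # first extension->stable transition per pixel
    first_stab = np.full(shape, -1, dtype=int)
    for k in range(n_overlays - 1):
        newly = ext_stack[k] & stable_stack[k + 1] & (first_stab < 0)
        first_stab[newly] = k + 1
    cohort = (first_stab >= 0) & ~always_stable & valid_all
    if not cohort.any():
        logger.warning("no newly stabilized pixels; empty stability histogram")
        return []
    max_offset = n_overlays - 1 - int(first_stab[cohort].min())
    fractions: list[float] = []
    for offset in range(max_offset + 1):
        observable = cohort & (first_stab + offset <= n_overlays - 1)
        n_obs = int(observable.sum())
        if n_obs == 0:
            break
        surviving = 0
        for k in np.unique(first_stab[observable]):
            members = observable & (first_stab == k)
            run = stable_stack[k : k + offset + 1].all(axis=0)
            surviving += int((members & run).sum())
        fractions.append(surviving / n_obs)
    return fractions


@dataclass
class TracedProcessSeries:
    """Length of one manually traced process at evenly spaced timepoints."""

    process_id: str
    lengths: np.ndarray  # µm
    interval: float  # min

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.any(self.lengths < 0):
            raise ValueError("lengths must be non-negative")
        if self.interval <= 0:
            raise ValueError("interval must be positive")


def traced_motility(series: TracedProcessSeries) -> float:
    """Mean |ΔL|/interval over consecutive timepoints, in µm/min."""
    if series.lengths.size < 2:
        raise ValueError("need at least two timepoints")
    rates = np.abs(np.diff(series.lengths)) / series.interval
    return float(rates.mean())


def analyze_movie(
    frames: list[np.ndarray],
    register: bool = True,
    threshold: str = "isodata",
    per_frame_threshold: bool = False,
    fixed_threshold: float | None = None,
) -> tuple[MotilityResult, list[ChangeMap]]:
    """End-to-end pixel-classification pipeline for a projected movie.

    Frames are registered (translation only), thresholded, classified
    pairwise, and summarized.  A single threshold derived from the first
    frame is reused for the whole movie by default, so index differences
    reflect morphology rather than threshold drift; see
    :func:`gliaquant.thresholds.movie_thresholds` for the schemes.
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    if register:
        reg = register_translation(frames)
        frames = reg.frames
        validity = np.logical_and.reduce(reg.validity_masks)
    else:
        validity = np.ones(frames[0].shape, dtype=bool)
    thresholds = movie_thresholds(frames, threshold, per_frame_threshold, fixed_threshold)
    masks = [f > t for f, t in zip(frames, thresholds)]
    change_maps = [
        classify_changes(masks[i], masks[i + 1], validity=validity, interval_index=i)
        for i in range(len(masks) - 1)
    ]
    result = motility_index(change_maps)
    stab = [
        stability_index(change_maps[i], change_maps[i + 1])
        for i in range(len(change_maps) - 1)
    ]
    instab = [
        instability_index(change_maps[i], change_maps[i + 1])
        for i in range(len(change_maps) - 1)
    ]
    result.per_pair_stability = stab
    result.per_pair_instability = instab
    defined = [v for v in stab if not np.isnan(v)]
    result.stability_index = float(np.mean(defined)) if defined else None
    defined = [v for v in instab if not np.isnan(v)]
    result.instability_index = float(np.mean(defined)) if defined else None
    if len(change_maps) >= 3:
        result.stability_histogram = stability_histogram(change_maps)
    return result, change_maps
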