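"""Threshold-scheme selection shared by the movie-based analyses.

Movies are binarized with a single threshold derived from the first frame by
default, so index differences between intervals reflect morphology rather
than threshold drift.  The default method is IsoData (iterative
intermeans, the midpoint of the two class means): it places the cut deep in
the intensity gap between background and labeled processes, which keeps
per-pixel change classification stable against background noise.  The
triangle method — which by construction sits at the shoulder of the
background peak and is the right tool for dim-object segmentation such as
puncta — is available as an option, as is a user-fixed value.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_isodata

from .colocalization import triangle_threshold_value

__all__ = ["movie_thresholds"]


def _single_threshold(frame: np.ndarray, method: str) -> float:
    if method == "isodata":
        return float(threshold_isodata(np.asarray(frame)))
    if method == "triangle":
        return triangle_threshold_value(frame)
    raise ValueError(f"unknown threshold method {method!r}")


def movie_thresholds(
    frames: list[np.ndarray],
    method: str = "isodata",
    per_frame: bool = False,
    fixed_threshold: float | None = None,
) -> list[float]:
    """One threshold per frame under the requested scheme.

    ``method`` is ``'isodata'`` (default), ``'triangle'`` or ``'fixed'``
    (requires ``fixed_threshold``).  Auto methods use the first frame only
    unless ``per_frame`` is set.
    """
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed threshold scheme requires fixed_threshold")
        return [float(fixed_threshold)] * len(frames)
    if per_frame:
        return [_single_threshold(f, method) for f in frames]
    return [_single_threshold(frames[0], method)] * len(frames)
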