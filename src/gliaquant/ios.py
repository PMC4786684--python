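"""Intrinsic-optical-signal analysis and the ocular dominance index.

During periodic visual stimulation, cortical reflectance at 700 nm modulates
at the stimulus repetition frequency.  The response strength of each pixel is
the amplitude of its time series at the stimulus frequency's discrete-Fourier
bin, normalized so a pure sinusoid of amplitude A reports A (2·|X[k]|/N).
Eye-specific responses averaged over a binocular-zone ROI and over both
stimulus directions yield the ocular dominance index

    ODI = (C − I) / (C + I)

with C and I the mean contralateral and ipsilateral ROI responses; positive
values indicate a contralateral bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

__all__ = [
    "AmplitudeMap",
    "OdiResult",
    "amplitude_map",
    "roi_response",
    "compute_odi",
    "default_roi",
]


@dataclass
class AmplitudeMap:
    """Per-pixel stimulus-locked response amplitude (and phase)."""

    amplitude: np.ndarray
    phase: np.ndarray
    stim_frequency: float  # Hz
    eye: str = ""
    direction: str = ""


@dataclass
class OdiResult:
    contra_response: float
    ipsi_response: float
    odi: float


def amplitude_map(
    pixel_timeseries: np.ndarray,
    sampling_rate: float,
    stim_frequency: float,
    detrend: bool = False,
    eye: str = "",
    direction: str = "",
) -> AmplitudeMap:
    """Fourier amplitude of each pixel at the stimulus frequency.

    The amplitude is taken at the FFT bin nearest ``stim_frequency`` and
    normalized by 2/N.  ``detrend`` removes a per-pixel linear trend first
    (hemodynamic drift; off by default).

    Raises for stimulus frequencies at or above Nyquist, or ones that round
    to the DC bin.
    """
    ts = np.asarray(pixel_timeseries, dtype=float)
    if ts.ndim != 3:
        raise ValueError("expected a (t, y, x) array")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if stim_frequency >= sampling_rate / 2:
        raise ValueError("stimulus frequency must be below Nyquist")
    n = ts.shape[0]
    k = int(round(stim_frequency * n / sampling_rate))
    if k == 0:
        raise ValueError("stimulus frequency rounds to the DC bin")
    if detrend:
        ts = _signal.detrend(ts, axis=0)
    spectrum = np.fft.rfft(ts, axis=0)[k]
    amplitude = 2.0 * np.abs(spectrum) / n
    phase = np.angle(spectrum)
    return AmplitudeMap(
        amplitude=amplitude,
        phase=phase,
        stim_frequency=stim_frequency,
        eye=eye,
        direction=direction,
    )


def roi_response(map_up: AmplitudeMap, map_down: AmplitudeMap, roi: np.ndarray) -> float:
    """Mean ROI amplitude for one eye, averaged over both stimulus directions."""
    roi = np.asarray(roi, dtype=bool)
    if map_up.amplitude.shape != map_down.amplitude.shape:
        raise ValueError("direction maps differ in shape")
    if roi.shape != map_up.amplitude.shape:
        raise ValueError("ROI shape differs from the maps")
    if not roi.any():
        raise ValueError("empty ROI")
    both = (map_up.amplitude + map_down.amplitude) / 2.0
    return float(both[roi].mean())


def compute_odi(contra_response: float, ipsi_response: float) -> float:
    """Ocular dominance index (C − I)/(C + I)."""
    if contra_response < 0 or ipsi_response < 0:
        raise ValueError("responses must be non-negative")
    total = contra_response + ipsi_response
    if total == 0:
        raise ValueError("contra + ipsi responses are zero; ODI undefined")
    return (contra_response - ipsi_response) / total


def default_roi(maps: list[AmplitudeMap], fraction_of_max: float = 0.5) -> np.ndarray:
    """Responsive-pixel ROI: amplitude above a fraction of the joint maximum.

    A fallback when no user-supplied binocular-zone mask is available; the
    mean amplitude across all supplied maps is compared against
    ``fraction_of_max`` × its maximum.
    """
    if not maps:
        raise ValueError("need at least one amplitude map")
    mean_amp = np.mean([m.amplitude for m in maps], axis=0)
    peak = mean_amp.max()
    if peak <= 0:
        raise ValueError("all-zero amplitude maps; cannot derive an ROI")
    return mean_amp >= fraction_of_max * peak
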