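"""Gait-cycle segmentation of a filtered SVM series.

A cycle is the interval between two successive prominent SVM peaks
(peak-to-peak).  With a lumbar-mounted sensor each prominent peak
corresponds to one foot impact, so a peak-to-peak cycle is approximately
one step; the package does not attribute steps to a foot and does not
distinguish step from stride.  Peaks are detected on the processed
series with a prominence threshold relative to the series SD and a
minimum separation, then cycles with implausible durations are dropped
(and counted in the log), not merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import InsufficientGaitError, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    """Peak-detection and plausibility parameters.

    min_peak_separation_s : minimum spacing between cycle-defining peaks.
    prominence_sd : peak prominence threshold as a multiple of the series SD.
    min_duration_s, max_duration_s : plausible bounds for one cycle.
    """

    min_peak_separation_s: float = 0.4
    prominence_sd: float = 0.5
    min_duration_s: float = 0.4
    max_duration_s: float = 2.5

    def __post_init__(self):
        if self.min_peak_separation_s <= 0:
            raise ValidationError("min_peak_separation_s must be positive")
        if not 0 < self.min_duration_s < self.max_duration_s:
            raise ValidationError("need 0 < min_duration_s < max_duration_s")


@dataclass
class GaitCycle:
    """One segmented cycle: half-open sample window [start_idx, end_idx)."""

    start_idx: int
    end_idx: int
    values: np.ndarray
    start_distance_m: float
    duration_s: float

    def __post_init__(self):
        if self.end_idx <= self.start_idx:
            raise ValidationError("end_idx must exceed start_idx")


def detect_peaks(series, params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Indices of cycle-defining peaks in a (filtered) SVM series."""
    x = np.asarray(series.values, dtype=np.float64)
    sd = float(np.std(x))
    if sd == 0.0:
        return np.empty(0, dtype=int)
    distance = max(1, int(round(params.min_peak_separation_s * series.sample_rate_hz)))
    peaks, _ = find_peaks(x, distance=distance, prominence=params.prominence_sd * sd)
    return peaks


def segment_cycles(series, recording=None,
                   params: SegmentationParams = SegmentationParams()) -> list[GaitCycle]:
    """Split an SVM series into peak-to-peak gait cycles.

    ``recording`` supplies the time and cumulative-distance channels; if
    omitted, time is taken from the series sample rate and distances are
    zero.  Raises :class:`InsufficientGaitError` when fewer than three
    plausible cycles are found (flat signal included).
    """
    x = np.asarray(series.values, dtype=np.float64)
    if recording is not None:
        if len(recording.t) != x.size:
            raise ValidationError("series length does not match recording")
        t = np.asarray(recording.t, dtype=np.float64)
        dist = np.asarray(recording.distance_m, dtype=np.float64)
    else:
        t = np.arange(x.size) / series.sample_rate_hz
        dist = np.zeros(x.size)

    peaks = detect_peaks(series, params)
    cycles: list[GaitCycle] = []
    dropped = 0
    for s, e in zip(peaks[:-1], peaks[1:]):
        duration = float(t[e] - t[s])
        if not params.min_duration_s <= duration <= params.max_duration_s:
            dropped += 1
            continue
        cycles.append(GaitCycle(start_idx=int(s), end_idx=int(e), values=x[s:e],
                                start_distance_m=float(dist[s]), duration_s=duration))
    log.info("segmentation: %d peaks, %d cycles kept, %d dropped (duration bounds)",
             peaks.size, len(cycles), dropped)
    if len(cycles) < 3:
        raise InsufficientGaitError(
            f"only {len(cycles)} plausible gait cycles detected (need >= 3)"
        )
    return cycles


def n_distance_bins(bin_width_m: float, total_m: float) -> int:
    return int(np.ceil(total_m / bin_width_m))


def cycle_distance_bin(cycle, bin_width_m: float, total_m: float) -> int:
    """Distance-bin index of a cycle: floor(start / width), clamped to the last bin.

    The study design of 1,200 m walks in 200 m increments yields bin
    indices 0..5 (six sections).  Accepts a GaitCycle or a bare start
    distance in metres.
    """
    d = float(getattr(cycle, "start_distance_m", cycle))
    if bin_width_m <= 0 or total_m <= 0:
        raise ValidationError("bin width and total distance must be positive")
    if d < 0:
        raise ValidationError(f"negative start distance {d}")
    if d > total_m:
        raise ValidationError(f"start distance {d} exceeds total {total_m}")
    return min(int(d // bin_width_m), n_distance_bins(bin_width_m, total_m) - 1)


def intervals_frame(cycles: list[GaitCycle]):
    """BED-like interval table (start_idx, end_idx, start_distance_m, duration_s)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "start_idx": [c.start_idx for c in cycles],
            "end_idx": [c.end_idx for c in cycles],
            "start_distance_m": [c.start_distance_m for c in cycles],
            "duration_s": [c.duration_s for c in cycles],
        }
    )
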