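"""Tri-axial IMU signals to scalar signal-vector-magnitude (SVM) series.

SVM collapses the three orthogonal axes of an accelerometer or gyroscope
sample to a single orientation-robust scalar, sqrt(ax^2 + ay^2 + az^2).
The processing order is fixed: compute SVM, low-pass filter, then z-score
normalise per recording.  Filtering and normalisation only commute for
linear filters, so the order is part of the contract, not a convenience.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import ValidationError

SOURCES = ("accel", "gyro")


@dataclass(frozen=True)
class FilterSpec:
    """Noise-filter parameters.

    ``butter_lowpass`` (default) is a 4th-order zero-phase Butterworth
    low-pass at 6 Hz: gait energy for the lumbar SVM lies below ~6 Hz,
    and zero-phase filtering (forward-backward) does not shift cycle
    boundaries.  ``moving_average`` is a simple centred window fallback.
    Edges are handled by reflect padding so the output keeps the input
    length.
    """

    kind: str = "butter_lowpass"
    cutoff_hz: float = 6.0
    order: int = 4
    window: int = 5

    def __post_init__(self):
        if self.kind not in ("butter_lowpass", "moving_average"):
            raise ValidationError(f"unknown filter kind {self.kind!r}")
        if self.cutoff_hz <= 0 or self.order < 1 or self.window < 1:
            raise ValidationError("filter parameters must be positive")


@dataclass
class SvmSeries:
    """A scalar SVM series on the same time base as its source recording."""

    values: np.ndarray
    source: str
    sample_rate_hz: float
    normalized: bool = False
    filter_spec: FilterSpec | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.source not in SOURCES:
            raise ValidationError(f"source must be one of {SOURCES}, got {self.source!r}")
        if self.values.ndim != 1:
            raise ValidationError("SvmSeries values must be 1-D")
        if not self.normalized and np.any(self.values < 0):
            raise ValidationError("raw SVM values must be non-negative")

    def __len__(self) -> int:
        return self.values.size


def compute_svm(ax, ay, az):
    """Euclidean norm sqrt(ax^2 + ay^2 + az^2), elementwise.

    Accepts scalars or arrays; the same formula applies to gyroscope
    axes.  Invariant under axis permutation and per-axis sign flips.
    """
    ax = np.asarray(ax, dtype=np.float64)
    ay = np.asarray(ay, dtype=np.float64)
    az = np.asarray(az, dtype=np.float64)
    if not (np.all(np.isfinite(ax)) and np.all(np.isfinite(ay)) and np.all(np.isfinite(az))):
        raise ValidationError("non-finite axis values")
    out = np.sqrt(ax * ax + ay * ay + az * az)
    return float(out) if out.ndim == 0 else out


def svm_series(recording, source: str = "accel") -> SvmSeries:
    """Compute the SVM series of a recording's accelerometer or gyroscope."""
    if source == "accel":
        values = compute_svm(recording.ax, recording.ay, recording.az)
    elif source == "gyro":
        values = compute_svm(recording.gx, recording.gy, recording.gz)
    else:
        raise ValidationError(f"source must be one of {SOURCES}, got {source!r}")
    return SvmSeries(values=values, source=source, sample_rate_hz=recording.sample_rate_hz)


def filter_svm(series: SvmSeries, spec: FilterSpec = FilterSpec()) -> SvmSeries:
    """Low-pass filter an SVM series, preserving length and DC level."""
    x = series.values
    if spec.kind == "butter_lowpass":
        nyq = series.sample_rate_hz / 2.0
        if spec.cutoff_hz >= nyq:
            raise ValidationError(
                f"cutoff {spec.cutoff_hz} Hz >= Nyquist {nyq} Hz"
            )
        sos = signal.butter(spec.order, spec.cutoff_hz, btype="low",
                            fs=series.sample_rate_hz, output="sos")
        # sosfiltfilt needs > 3 * (order of each section) samples of padding
        padlen = 3 * (2 * len(sos) + 1)
        if x.size <= padlen:
            raise ValidationError(
                f"series of length {x.size} too short for order-{spec.order} zero-phase filter"
            )
        y = signal.sosfiltfilt(sos, x, padtype="even")
    else:
        w = spec.window
        if x.size <= w:
            raise ValidationError(f"series of length {x.size} too short for window {w}")
        pad = w // 2
        xp = np.pad(x, (pad, w - 1 - pad), mode="reflect")
        y = np.convolve(xp, np.full(w, 1.0 / w), mode="valid")
    assert y.size == x.size
    return SvmSeries(values=y, source=series.source, sample_rate_hz=series.sample_rate_hz,
                     normalized=series.normalized, filter_spec=spec)


def normalize_svm(series: SvmSeries, eps: float = 1e-12) -> SvmSeries:
    """Z-score per recording (population SD): output mean 0, SD 1."""
    x = series.values
    sd = float(np.std(x))
    if sd <= eps:
        raise ValidationError("cannot normalise a zero-variance series")
    out = replace(series)
    out.values = (x - float(np.mean(x))) / sd
    out.normalized = True
    return out
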