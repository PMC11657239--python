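"""Plain-text I/O for IMU recordings and result tables.

A recording is a single CSV file with '#'-prefixed metadata lines before
the header::

    # participant_id: P001
    # material: wood
    # age_group: 20-30
    # sample_rate_hz: 100
    t,ax,ay,az,gx,gy,gz,distance_m
    0.0,0.1,...

Acceleration is in m/s^2, angular velocity in deg/s, time in seconds
from recording start, cumulative distance in metres.  ``distance_m`` is
optional; when absent it is synthesised as t x constant walking speed.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

MATERIALS = ("wood", "asphalt", "concrete_block", "cement")
AGE_GROUPS = ("20-30", "30-40", "40-50", "50-60", "60+")
SIGNAL_COLUMNS = ("ax", "ay", "az", "gx", "gy", "gz")
#: walking speed used to synthesise a missing distance channel (m/s),
#: inside the 1.2-1.5 m/s adult range reported for instrumented walks
DEFAULT_SPEED_M_S = 1.3


@dataclass
class ImuRecording:
    """One participant x material walk: tri-axial accel + gyro samples.

    Invariants (checked on construction): at least two samples, strictly
    increasing time with inter-sample spacing within 1% of the nominal
    rate, non-negative non-decreasing cumulative distance, and material /
    age-group labels drawn from the study's closed enums.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    distance_m: np.ndarray
    sample_rate_hz: float
    participant_id: str
    material: str
    age_group: str

    def __post_init__(self):
        arrays = [np.asarray(getattr(self, c), dtype=np.float64)
                  for c in ("t", *SIGNAL_COLUMNS, "distance_m")]
        for name, arr in zip(("t", *SIGNAL_COLUMNS, "distance_m"), arrays):
            setattr(self, name, arr)
        n = self.t.size
        if n < 2:
            raise ValidationError("recording needs at least 2 samples")
        for name in (*SIGNAL_COLUMNS, "distance_m"):
            if getattr(self, name).size != n:
                raise ValidationError(f"column {name} length differs from t")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValidationError("time must be strictly increasing")
        nominal = 1.0 / self.sample_rate_hz
        if np.any(np.abs(dt - nominal) > 0.01 * nominal):
            raise ValidationError(
                f"inter-sample spacing deviates more than 1% from 1/{self.sample_rate_hz} s"
            )
        if self.distance_m[0] < 0 or np.any(np.diff(self.distance_m) < 0):
            raise ValidationError("distance_m must be non-decreasing and start >= 0")
        if self.material not in MATERIALS:
            raise ValidationError(f"unknown material {self.material!r}; expected {MATERIALS}")
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(f"unknown age group {self.age_group!r}; expected {AGE_GROUPS}")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def recording_id(self) -> str:
        return f"{self.participant_id}_{self.material}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c)
                             for c in ("t", *SIGNAL_COLUMNS, "distance_m")})


def _parse_metadata(path: Path) -> tuple[dict, int]:
    meta: dict[str, str] = {}
    n_comment = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            body = line[1:].strip()
            if ":" in body:
                key, value = body.split(":", 1)
                meta[key.strip()] = value.strip()
    return meta, n_comment


def read_recording(path, schema: dict | None = None, meta: dict | None = None,
                   speed_m_s: float = DEFAULT_SPEED_M_S) -> ImuRecording:
    """Read and validate a recording CSV.

    ``schema`` maps file column names to the canonical names
    (t, ax..az, gx..gz, distance_m).  ``meta`` overrides or supplies the
    header metadata (participant_id, material, age_group,
    sample_rate_hz) for files carrying it in a sidecar config instead.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    file_meta, n_comment = _parse_metadata(path)
    if meta:
        file_meta.update({k: str(v) for k, v in meta.items()})
    for key in ("participant_id", "material", "age_group", "sample_rate_hz"):
        if key not in file_meta:
            raise ParseError(f"{path}: missing metadata {key!r}")

    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=False)
    if schema:
        df = df.rename(columns=schema)
    required = ("t", *SIGNAL_COLUMNS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")

    numeric = {}
    present = [c for c in (*required, "distance_m") if c in df.columns]
    for col in present:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            # metadata lines + header line + 1-based data row
            raise ParseError(f"{path}: malformed value {df[col].iloc[row]!r} in column {col!r}",
                             line=n_comment + 2 + row)
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ParseError(f"{path}: empty value in column {col!r}",
                             line=n_comment + 2 + row)
        # numpy's parser is correctly rounded (pandas' fast path is not),
        # so decimal strings written by write_recording round-trip exactly
        numeric[col] = df[col].to_numpy(dtype=np.float64)

    if "distance_m" not in numeric:
        numeric["distance_m"] = numeric["t"] * float(speed_m_s)

    return ImuRecording(
        **{c: numeric[c] for c in ("t", *SIGNAL_COLUMNS, "distance_m")},
        sample_rate_hz=float(file_meta["sample_rate_hz"]),
        participant_id=file_meta["participant_id"],
        material=file_meta["material"],
        age_group=file_meta["age_group"],
    )


def write_recording(recording: ImuRecording, path) -> Path:
    """Write a recording to the package CSV format (round-trips exactly)."""
    path = Path(path)
    buf = _stdio.StringIO()
    buf.write(f"# participant_id: {recording.participant_id}\n")
    buf.write(f"# material: {recording.material}\n")
    buf.write(f"# age_group: {recording.age_group}\n")
    buf.write(f"# sample_rate_hz: {recording.sample_rate_hz!r}\n")
    recording.to_frame().to_csv(buf, index=False)
    path.write_text(buf.getvalue())
    return path


SUMMARY_COLUMNS = ("material", "age_group", "distance_bin", "n", "mean", "sd", "min", "max")


def write_summary(summary, path, header_lines: list[str] | None = None) -> Path:
    """Write a cohort summary as a tidy long-format CSV.

    Accepts a :class:`~gaitwalk.walkability.CohortSummary` or its cells
    DataFrame.  Decimal strings round-trip bit-for-bit through
    :func:`read_summary`.
    """
    cells = getattr(summary, "cells", summary)
    if cells is None or len(cells) == 0:
        raise ValidationError("refusing to write an empty summary")
    missing = [c for c in SUMMARY_COLUMNS if c not in cells.columns]
    if missing:
        raise ValidationError(f"summary missing columns {missing}")
    path = Path(path)
    try:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            cells.to_csv(fh, index=False)
    except OSError as exc:
        raise OSError(f"cannot write summary to {path}: {exc}") from exc
    return path


def read_summary(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    return pd.read_csv(path, comment="#")
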