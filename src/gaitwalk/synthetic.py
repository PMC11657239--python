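"""Seeded simulator of quasi-periodic IMU gait recordings.

Emulates the study design — four sidewalk materials x five age groups,
16 participants per age group, 1,200 m walks recorded at 100 Hz by a
lumbar sensor — so that the full pipeline is exercisable without
hardware.  Each recording is a train of step cycles built from a
material-specific stride template (two Gaussian impact pulses per step;
harder materials are spikier) affine-mapped so the per-sample
accelerometer / gyroscope SVM matches the per-material mean and SD
observed in the study.  Per-step amplitude and timing jitter grows
linearly with walked distance (the fatigue model), at a material rate
scaled by an age-group gain, so DTW deviation from a reference cycle
rises across 200 m distance bins and with age.

All randomness flows from one seed; per-recording substreams are derived
by counter, so identical specs reproduce bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import AGE_GROUPS, MATERIALS, ImuRecording


@dataclass(frozen=True)
class MaterialProfile:
    """Generator parameters for one flooring material.

    ``accel_svm_mean/sd`` (m/s^2) and ``gyro_svm_mean/sd`` (deg/s) are the
    target per-sample SVM moments.  ``hardness`` (1 = softest) sharpens
    the impact pulses: harder floors transmit spikier impacts, which is
    what drives the wider SVM spread of cement and concrete block.
    ``jitter_base`` is the relative cycle-shape perturbation at the start
    of a walk and ``jitter_drift`` its increase over a full walk; these
    drive the DTW level and its growth with distance, and their default
    ordering (cement > asphalt > concrete_block > wood) follows the
    observed mean-DTW ordering of the materials, which is distinct from
    the physical-hardness ordering.
    """

    name: str
    accel_svm_mean: float
    accel_svm_sd: float
    gyro_svm_mean: float
    gyro_svm_sd: float
    hardness: int
    jitter_base: float
    jitter_drift: float

    def __post_init__(self):
        if self.accel_svm_sd <= 0 or self.gyro_svm_sd <= 0:
            raise ValidationError(f"{self.name}: SVM SDs must be positive")
        if self.accel_svm_mean <= 0 or self.gyro_svm_mean <= 0:
            raise ValidationError(f"{self.name}: SVM means must be positive")
        if self.jitter_base < 0 or self.jitter_drift < 0:
            raise ValidationError(f"{self.name}: jitter rates must be non-negative")


#: Default profiles; SVM moments follow the study's per-material figures.
DEFAULT_PROFILES: dict[str, MaterialProfile] = {
    "wood": MaterialProfile("wood", 14.2, 6.5, 2.6, 1.3,
                            hardness=1, jitter_base=0.010, jitter_drift=0.024),
    "asphalt": MaterialProfile("asphalt", 15.7, 7.1, 2.5, 1.2,
                               hardness=2, jitter_base=0.050, jitter_drift=0.023),
    "concrete_block": MaterialProfile("concrete_block", 18.3, 9.2, 2.8, 1.4,
                                      hardness=3, jitter_base=0.034, jitter_drift=0.027),
    "cement": MaterialProfile("cement", 19.1, 9.5, 2.9, 1.5,
                              hardness=4, jitter_base=0.096, jitter_drift=0.021),
}

#: Base step period per age group (s); older walkers step slower.
DEFAULT_STRIDE_PERIOD_S: dict[str, float] = {
    "20-30": 0.50, "30-40": 0.52, "40-50": 0.54, "50-60": 0.56, "60+": 0.60,
}

#: Multiplier on the fatigue-drift rate per age group.
DEFAULT_AGE_GAIN: dict[str, float] = {
    "20-30": 1.0, "30-40": 1.1, "40-50": 1.2, "50-60": 1.35, "60+": 1.6,
}


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for a simulated cohort.

    Defaults reproduce the study conditions: 16 participants in each of
    five age groups (80 in total), four materials, 1,200 m walks at
    100 Hz with ~0.7 m steps.  ``walk_scale`` < 1 simulates a
    representative subset of the walk's step cycles while keeping the
    distance channel spanning the full ``total_m`` (each emitted step
    covers proportionally more distance); it exists purely to bound
    runtime and leaves the fatigue trajectory over distance intact.
    """

    n_per_group: int = 16
    age_groups: tuple[str, ...] = AGE_GROUPS
    materials: tuple[str, ...] = MATERIALS
    profiles: Mapping[str, MaterialProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES))
    total_m: float = 1200.0
    sample_rate_hz: float = 100.0
    stride_period_s: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRIDE_PERIOD_S))
    fatigue_drift: float = 1.0
    age_gain: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_GAIN))
    step_length_m: float = 0.7
    walk_scale: float = 1.0
    noise_sd_frac: float = 0.03
    timing_jitter_frac: float = 0.4
    participant_sd_frac: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be >= 1")
        if self.total_m <= 0 or self.sample_rate_hz <= 0 or self.step_length_m <= 0:
            raise ValidationError("total_m, sample_rate_hz, step_length_m must be positive")
        if not 0 < self.walk_scale <= 1:
            raise ValidationError("walk_scale must be in (0, 1]")
        for rate in (self.fatigue_drift, self.noise_sd_frac, self.timing_jitter_frac,
                     self.participant_sd_frac):
            if not np.isfinite(rate) or rate < 0:
                raise ValidationError("rates must be finite and non-negative")
        for m in self.materials:
            if m not in self.profiles:
                raise ValidationError(f"no profile for material {m!r}")
        for g in self.age_groups:
            if g not in self.stride_period_s or g not in self.age_gain:
                raise ValidationError(f"missing period/gain for age group {g!r}")

    @property
    def cohort_size(self) -> int:
        return self.n_per_group * len(self.age_groups)

    @property
    def n_recordings(self) -> int:
        return self.cohort_size * len(self.materials)

    def n_steps(self) -> int:
        return max(8, int(round(self.walk_scale * self.total_m / self.step_length_m)))

    @classmethod
    def runtime_scaled(cls, seed: int = 0, walk_scale: float = 0.12, **kwargs) -> "CohortSpec":
        """The reduced preset used by the test suite and worked examples."""
        return cls(seed=seed, walk_scale=walk_scale, **kwargs)


def _stride_template(hardness: int, n: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance zero-mean one-cycle waveform on a phase grid [0, 1).

    A dominant impact pulse plus a broader secondary pulse; pulse width
    shrinks mildly with hardness so harder floors give spikier cycles.
    The coupling is kept weak because sharper peaks also inflate DTW
    residuals under timing jitter; the calibrated jitter rates, not the
    template shape, are meant to set each material's DTW level.
    """
    w = 0.155 - 0.007 * hardness
    phi = (np.arange(n) + 0.5) / n
    y = (np.exp(-0.5 * ((phi - 0.30) / w) ** 2)
         + 0.30 * np.exp(-0.5 * ((phi - 0.72) / (1.6 * w)) ** 2))
    z = (y - y.mean()) / y.std()
    return phi, z


def _template_l1(z: np.ndarray) -> float:
    """Mean absolute deviation of a unit-variance template.

    Amplitude jitter is expressed per unit of this quantity, so a given
    jitter SD perturbs every material's cycles by the same expected
    per-sample absolute deviation regardless of how spiky its template
    is; the jitter parameters then translate directly into DTW level.
    """
    return float(np.mean(np.abs(z)))


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, scale: float) -> np.ndarray:
    # slow wobble: white noise smoothed over ~1 s
    w = max(3, int(fs))
    kernel = np.hanning(w)
    kernel /= kernel.sum()
    x = rng.normal(0.0, 1.0, n + w)
    return scale * np.convolve(x, kernel, mode="same")[:n]


def _decompose_axes(rng: np.random.Generator, svm: np.ndarray, base: np.ndarray,
                    fs: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # split a scalar magnitude across three axes: fixed direction + slow
    # angular wobble, renormalised so the axes reproduce the SVM exactly
    n = svm.size
    u = np.empty((n, 3))
    for k in range(3):
        u[:, k] = base[k] + _smooth_noise(rng, n, fs, 0.05)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    comp = svm[:, None] * u
    return comp[:, 0], comp[:, 1], comp[:, 2]


def simulate_recording(profile: MaterialProfile, age_group: str, spec: CohortSpec,
                       participant_seed: int, participant_id: str = "sim") -> ImuRecording:
    """Simulate one participant x material walk.

    Deterministic in (profile, age_group, spec, participant_seed).  The
    per-sample accel/gyro SVM mean and SD land within a few percent of
    the profile targets; per-step amplitude/timing jitter SD grows
    linearly with distance at rate
    ``fatigue_drift * age_gain[age_group] * profile.jitter_drift``.
    """
    if age_group not in spec.age_groups:
        raise ValidationError(f"unknown age group {age_group!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(participant_seed)]))
    fs = spec.sample_rate_hz
    period = spec.stride_period_s[age_group]
    n_steps = spec.n_steps()

    # per-step jitter SD, linear in walked distance
    d_frac = (np.arange(n_steps) + 0.5) / n_steps
    sigma = (profile.jitter_base
             + spec.fatigue_drift * spec.age_gain[age_group] * profile.jitter_drift * d_frac)
    phi, z_a = _stride_template(profile.hardness)
    _, z_g = _stride_template(max(1, profile.hardness - 1))
    amp_a = 1.0 + rng.normal(0.0, 1.0, n_steps) * sigma / _template_l1(z_a)
    amp_g = 1.0 + rng.normal(0.0, 1.0, n_steps) * sigma / _template_l1(z_g)
    per = period * (1.0 + rng.normal(0.0, 1.0, n_steps) * sigma * spec.timing_jitter_frac)
    per = np.clip(per, 0.6 * period, 1.6 * period)
    bounds = np.concatenate(([0.0], np.cumsum(per)))
    total_t = bounds[-1]

    n = int(np.floor(total_t * fs))
    t = np.arange(n) / fs
    step = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, n_steps - 1)
    phase = (t - bounds[step]) / per[step]
    za = np.interp(phase, phi, z_a, period=1.0)
    zg = np.interp(phase, phi, z_g, period=1.0)

    accel_svm = profile.accel_svm_mean + profile.accel_svm_sd * (
        amp_a[step] * za + rng.normal(0.0, spec.noise_sd_frac, n))
    gyro_svm = profile.gyro_svm_mean + profile.gyro_svm_sd * (
        amp_g[step] * zg + rng.normal(0.0, spec.noise_sd_frac, n))
    accel_svm = np.clip(accel_svm, 0.0, None)
    gyro_svm = np.clip(gyro_svm, 0.0, None)

    ax, ay, az = _decompose_axes(rng, accel_svm, np.array([0.45, 0.20, 0.87]), fs)
    gx, gy, gz = _decompose_axes(rng, gyro_svm, np.array([0.55, 0.60, 0.58]), fs)

    distance = t * (spec.total_m / total_t)

    return ImuRecording(t=t, ax=ax, ay=ay, az=az, gx=gx, gy=gy, gz=gz,
                        distance_m=distance, sample_rate_hz=fs,
                        participant_id=participant_id, material=profile.name,
                        age_group=age_group)


def _participants(spec: CohortSpec) -> list[tuple[str, str]]:
    out = []
    i = 0
    for group in spec.age_groups:
        for _ in range(spec.n_per_group):
            i += 1
            out.append((f"P{i:03d}", group))
    return out


def simulate_cohort_iter(spec: CohortSpec) -> Iterator[tuple[ImuRecording, dict]]:
    """Yield (recording, manifest row) pairs one at a time (memory-light).

    Cohort-level heterogeneity: each participant carries a multiplicative
    movement-intensity factor ~ N(1, participant_sd_frac) applied to the
    SVM mean/SD targets of every material they walk, emulating
    between-subject differences in gait vigour.  Material-level target
    means are preserved in expectation.
    """
    participants = _participants(spec)
    factor_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 987654321]))
    factors = np.clip(1.0 + factor_rng.normal(0.0, 1.0, len(participants))
                      * spec.participant_sd_frac, 0.5, 1.5)
    counter = 0
    for (pid, group), factor in zip(participants, factors):
        for material in spec.materials:
            base = spec.profiles[material]
            profile = replace(base,
                              accel_svm_mean=base.accel_svm_mean * factor,
                              accel_svm_sd=base.accel_svm_sd * factor,
                              gyro_svm_mean=base.gyro_svm_mean * factor,
                              gyro_svm_sd=base.gyro_svm_sd * factor)
            rec = simulate_recording(profile, group, spec, counter, participant_id=pid)
            row = {
                "participant_id": pid,
                "material": material,
                "age_group": group,
                "participant_seed": counter,
                "participant_factor": float(factor),
                "stride_period_s": spec.stride_period_s[group],
                "age_gain": spec.age_gain[group],
                "hardness": profile.hardness,
                "jitter_base": profile.jitter_base,
                "jitter_drift": profile.jitter_drift,
                "accel_svm_mean_target": profile.accel_svm_mean,
                "accel_svm_sd_target": profile.accel_svm_sd,
                "gyro_svm_mean_target": profile.gyro_svm_mean,
                "gyro_svm_sd_target": profile.gyro_svm_sd,
                "n_steps": spec.n_steps(),
                "n_samples": rec.n_samples,
                "seed": spec.seed,
            }
            counter += 1
            yield rec, row


def simulate_cohort(spec: CohortSpec) -> tuple[list[ImuRecording], pd.DataFrame]:
    """Full cohort in memory plus the ground-truth manifest.

    One recording per participant x material (default 80 x 4 = 320).
    For full-scale cohorts prefer :func:`simulate_cohort_iter`.
    """
    recs, rows = [], []
    for rec, row in simulate_cohort_iter(spec):
        recs.append(rec)
        rows.append(row)
    return recs, pd.DataFrame(rows)


def distortion_ordering(spec: CohortSpec) -> list[str]:
    """Materials ranked by mean cycle-shape distortion over a walk, descending.

    This is the generator's ground-truth ordering that the pipeline's
    mean-DTW ranking should recover (default: cement, asphalt,
    concrete_block, wood).
    """
    def mean_sigma(m: str) -> float:
        p = spec.profiles[m]
        return p.jitter_base + 0.5 * spec.fatigue_drift * p.jitter_drift

    return sorted(spec.materials, key=mean_sigma, reverse=True)
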