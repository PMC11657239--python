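"""Walkability scoring: reference-cycle selection, DTW scoring, aggregation.

Every gait cycle is scored by its DTW distance to the "typical" cycle of
its (material, age group) stratum.  The typical cycle is the DTW medoid:
the observed cycle minimising the summed DTW distance to all other
cycles in the stratum — deterministic, outlier-robust, and always an
actually observed waveform rather than an average.  Scores are then
aggregated per 200 m distance bin (six sections of a 1,200 m walk), per
participant, per material and per age group.  Low, stable DTW deviation
means a stable gait and hence a walkable surface; rising DTW across
distance bins is the signature of accumulating fatigue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dtw import dtw_distance
from .errors import ValidationError

log = logging.getLogger(__name__)

SCORE_COLUMNS = ("participant_id", "material", "age_group", "distance_bin", "dtw")


@dataclass
class ReferenceCycle:
    """The baseline cycle of one (material, age group) stratum."""

    values: np.ndarray
    group_key: tuple = ()
    selection_method: str = "dtw_medoid"
    candidate_index: int = 0
    sum_distance: float = 0.0


def _cycle_values(c) -> np.ndarray:
    return np.asarray(getattr(c, "values", c), dtype=np.float64)


def select_reference(cycles, group_key: tuple = (), max_candidates: int | None = None,
                     seed: int = 0, local_cost: str = "abs") -> ReferenceCycle:
    """DTW medoid of a list of cycles.

    With more candidates than ``max_candidates`` a seeded subsample is
    drawn (order-preserving) before computing the pairwise DTW matrix.
    Ties break to the lowest candidate index, so selection is
    deterministic.  Requires at least three cycles.
    """
    values = [_cycle_values(c) for c in cycles]
    if len(values) < 3:
        raise ValidationError(f"need >= 3 cycles to select a reference, got {len(values)}")
    idx = np.arange(len(values))
    if max_candidates is not None and len(values) > max_candidates:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(idx, size=max_candidates, replace=False))
    cand = [values[i] for i in idx]
    k = len(cand)
    sums = np.zeros(k)
    for i in range(k):
        for j in range(i + 1, k):
            d = dtw_distance(cand[i], cand[j], local_cost=local_cost)
            sums[i] += d
            sums[j] += d
    best = int(np.argmin(sums))  # argmin returns the first minimum: lowest index wins
    return ReferenceCycle(values=cand[best], group_key=group_key,
                          candidate_index=int(idx[best]), sum_distance=float(sums[best]))


def score_cycles(cycles, ref: ReferenceCycle, local_cost: str = "abs") -> np.ndarray:
    """Per-cycle DTW distance to the stratum reference (ref itself scores 0)."""
    values = [_cycle_values(c) for c in cycles]
    if not values:
        raise ValidationError("no cycles to score")
    ref_values = np.asarray(ref.values, dtype=np.float64)
    return np.array([dtw_distance(v, ref_values, local_cost=local_cost) for v in values])


@dataclass
class CohortSummary:
    """Aggregated DTW statistics.

    ``cells``: long-format table keyed by (material, age_group,
    distance_bin) — plus a ``source`` column when several sensor streams
    are scored — with n, mean, sd, min, max of the per-cycle DTW values.
    ``participant_means``: mean DTW per (participant, material), the
    participant-level statistic reported alongside the bin statistics.
    """

    cells: pd.DataFrame
    participant_means: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if len(self.cells):
            bad = self.cells[(self.cells["n"] < 1) | (self.cells["sd"] < 0)
                             | (self.cells["min"] > self.cells["mean"])
                             | (self.cells["mean"] > self.cells["max"])]
            if len(bad):
                raise ValidationError("summary cells violate n/sd/min/mean/max invariants")


def aggregate(scores: pd.DataFrame, population_sd: bool = False) -> CohortSummary:
    """Cell and participant-level statistics from labelled per-cycle scores.

    ``scores`` must carry participant_id, material, age_group,
    distance_bin and dtw columns (a ``source`` column, if present, joins
    the grouping keys).  SDs are sample SDs by default (``ddof=1``; a
    single-value cell reports sd 0).
    """
    if scores is None or len(scores) == 0:
        raise ValidationError("no scores to aggregate")
    missing = [c for c in SCORE_COLUMNS if c not in scores.columns]
    if missing:
        raise ValidationError(f"scores missing columns {missing}")
    ddof = 0 if population_sd else 1
    extra = ["source"] if "source" in scores.columns else []

    def _sd(x):
        x = np.asarray(x, dtype=np.float64)
        return 0.0 if x.size <= ddof else float(np.std(x, ddof=ddof))

    cell_keys = extra + ["material", "age_group", "distance_bin"]
    cells = (scores.groupby(cell_keys, observed=True)["dtw"]
             .agg(n="size", mean="mean", sd=_sd, min="min", max="max")
             .reset_index())
    part_keys = extra + ["participant_id", "material"]
    participant_means = (scores.groupby(part_keys, observed=True)["dtw"]
                         .agg(n_cycles="size", mean_dtw="mean")
                         .reset_index())
    return CohortSummary(cells=cells, participant_means=participant_means)


def percent_change(baseline: float, comparison: float) -> float:
    """100 x (comparison - baseline) / baseline.

    Full precision; reported tables round to one decimal.  The baseline
    must be positive.
    """
    if baseline <= 0:
        raise ValidationError(f"baseline must be positive, got {baseline}")
    return 100.0 * (comparison - baseline) / baseline


def percent_lower(reference: float, value: float) -> float:
    """How many percent ``value`` lies below ``reference`` (the larger one)."""
    if reference <= 0:
        raise ValidationError(f"reference must be positive, got {reference}")
    return 100.0 * (reference - value) / reference


def score_cohort(cycle_records: list[dict], max_candidates: int | None = 40,
                 seed: int = 0, local_cost: str = "abs",
                 per_group_reference: bool = True) -> tuple[pd.DataFrame, dict]:
    """Score segmented cycles for a whole cohort.

    ``cycle_records`` are dicts with keys participant_id, material,
    age_group, distance_bin, values (one per cycle; an optional
    ``source`` key separates sensor streams).  A reference is selected
    per (source, material, age_group) stratum — the study design — or
    globally per source when ``per_group_reference`` is False
    (sensitivity analysis).  Returns the per-cycle score table and the
    references keyed by stratum.
    """
    if not cycle_records:
        raise ValidationError("no cycles to score")
    df = pd.DataFrame(cycle_records)
    if "source" not in df.columns:
        df["source"] = "accel"
    group_cols = ["source", "material", "age_group"] if per_group_reference else ["source"]
    references: dict[tuple, ReferenceCycle] = {}
    scored = []
    for key, sub in df.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        ref = select_reference(list(sub["values"]), group_key=key,
                               max_candidates=max_candidates, seed=seed,
                               local_cost=local_cost)
        references[key] = ref
        out = sub.drop(columns=["values"]).copy()
        out["dtw"] = score_cycles(list(sub["values"]), ref, local_cost=local_cost)
        scored.append(out)
        log.info("scored %d cycles in stratum %s (reference candidate %d)",
                 len(out), key, ref.candidate_index)
    return pd.concat(scored, ignore_index=True), references
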