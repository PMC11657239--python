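"""End-to-end orchestration: simulate/read -> preprocess -> segment -> score -> report.

The pipeline is configured by a single YAML-serialisable
:class:`PipelineConfig`; identical config + seed reproduces byte-identical
output tables.  Every written table carries the config hash and seed in a
'#' header comment.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gwio
from .errors import InsufficientGaitError, PipelineStageError, ValidationError
from .preprocess import FilterSpec, filter_svm, normalize_svm, svm_series
from .segment import SegmentationParams, cycle_distance_bin, segment_cycles
from .stats import anova_oneway, anova_table_rows, summarize_distribution
from .synthetic import CohortSpec, simulate_cohort_iter
from .walkability import aggregate, percent_change, score_cohort

log = logging.getLogger(__name__)

_SIMULATE_KEYS = {"n_per_group", "walk_scale", "fatigue_drift", "total_m",
                  "sample_rate_hz", "step_length_m"}


@dataclass
class PipelineConfig:
    """Everything run_pipeline needs; unknown keys are rejected on load."""

    seed: int = 0
    outdir: str = "out"
    cohort_dir: str | None = None
    sources: tuple[str, ...] = ("accel", "gyro")
    simulate: dict = field(default_factory=dict)
    filter: FilterSpec = field(default_factory=FilterSpec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    local_cost: str = "abs"
    bin_width_m: float = 200.0
    total_m: float = 1200.0
    population_sd: bool = False
    histogram_bins: int = 10
    max_reference_candidates: int = 40

    def __post_init__(self):
        unknown = set(self.simulate) - _SIMULATE_KEYS
        if unknown:
            raise ValidationError(f"unknown simulate keys {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        if "filter" in d and isinstance(d["filter"], dict):
            d["filter"] = FilterSpec(**d["filter"])
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        if "sources" in d:
            d["sources"] = tuple(d["sources"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sources"] = list(self.sources)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # where results land does not change them
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(seed=self.seed, total_m=self.total_m, **self.simulate)


def iter_recordings(config: PipelineConfig):
    """Simulated recordings, or CSVs read from ``cohort_dir`` when set."""
    if config.cohort_dir:
        paths = sorted(Path(config.cohort_dir).glob("*.csv"))
        paths = [p for p in paths if p.name != "manifest.csv"]
        if not paths:
            raise ValidationError(f"no recording CSVs in {config.cohort_dir}")
        for p in paths:
            yield gwio.read_recording(p)
    else:
        spec = config.cohort_spec()
        for rec, _ in simulate_cohort_iter(spec):
            yield rec


def segment_recordings(recordings, config: PipelineConfig):
    """Preprocess and segment every recording.

    Returns (cycle_records, svm_means, counts): per-cycle dicts ready for
    :func:`gaitwalk.walkability.score_cohort`, per-recording mean raw SVM
    (the material-classification feature), and stage counts for the log.
    """
    cycle_records: list[dict] = []
    svm_rows: list[dict] = []
    counts = {"recordings": 0, "cycles": 0}
    for rec in recordings:
        counts["recordings"] += 1
        for source in config.sources:
            try:
                raw = svm_series(rec, source=source)
                filtered = filter_svm(raw, config.filter)
                svm_rows.append({
                    "participant_id": rec.participant_id, "material": rec.material,
                    "age_group": rec.age_group, "source": source,
                    "svm_mean": float(np.mean(filtered.values)),
                    "svm_sd": float(np.std(filtered.values, ddof=1)),
                })
                normalized = normalize_svm(filtered)
                cycles = segment_cycles(normalized, rec, config.segmentation)
            except (ValidationError, InsufficientGaitError) as exc:
                raise PipelineStageError("preprocess/segment", rec.recording_id, exc) from exc
            for c in cycles:
                cycle_records.append({
                    "participant_id": rec.participant_id, "material": rec.material,
                    "age_group": rec.age_group, "source": source,
                    "start_distance_m": c.start_distance_m,
                    "distance_bin": cycle_distance_bin(c, config.bin_width_m, config.total_m),
                    "values": c.values,
                })
                counts["cycles"] += 1
    log.info("segmented %d recordings into %d cycles", counts["recordings"], counts["cycles"])
    return cycle_records, pd.DataFrame(svm_rows), counts


def analyze_cohort(config: PipelineConfig, recordings=None):
    """Run the full analysis in memory; returns a dict of result tables."""
    if recordings is None:
        recordings = iter_recordings(config)
    cycle_records, svm_means, counts = segment_recordings(recordings, config)
    scores, references = score_cohort(
        cycle_records, max_candidates=config.max_reference_candidates,
        seed=config.seed, local_cost=config.local_cost)
    summary = aggregate(scores, population_sd=config.population_sd)
    anova = _anova_tables(svm_means)
    pct = _percent_change_table(summary.cells)
    dists = _distribution_table(scores, config.histogram_bins)
    return {
        "scores": scores,
        "summary": summary,
        "svm_means": svm_means,
        "anova": anova,
        "percent_change": pct,
        "distributions": dists,
        "references": references,
        "counts": counts,
    }


def _anova_tables(svm_means: pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVA of per-(participant, material) mean SVM across materials."""
    rows = []
    for source, sub in svm_means.groupby("source", sort=True):
        groups = [g["svm_mean"].to_numpy() for _, g in sub.groupby("material", sort=True)]
        if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
            rows.extend(anova_table_rows(f"{source}_svm", anova_oneway(groups)))
    return pd.DataFrame(rows)


def _percent_change_table(cells: pd.DataFrame) -> pd.DataFrame:
    """First-to-last distance-bin and youngest-to-oldest changes, one decimal."""
    rows = []
    keys = ["source", "material"] if "source" in cells.columns else ["material"]
    for key, sub in cells.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        bins = sub.groupby("distance_bin")["mean"].mean().sort_index()
        if len(bins) >= 2 and bins.iloc[0] > 0:
            rows.append({**dict(zip(keys, key)), "comparison": "first_to_last_bin",
                         "baseline": bins.iloc[0], "value": bins.iloc[-1],
                         "percent_change": round(percent_change(bins.iloc[0], bins.iloc[-1]), 1)})
        ages = sub.groupby("age_group")["mean"].mean()
        ages = ages.reindex([g for g in gwio.AGE_GROUPS if g in ages.index])
        if len(ages) >= 2 and ages.iloc[0] > 0:
            rows.append({**dict(zip(keys, key)), "comparison": "youngest_to_oldest",
                         "baseline": ages.iloc[0], "value": ages.iloc[-1],
                         "percent_change": round(percent_change(ages.iloc[0], ages.iloc[-1]), 1)})
    return pd.DataFrame(rows)


def _distribution_table(scores: pd.DataFrame, bins: int) -> pd.DataFrame:
    rows = []
    for (source, group), sub in scores.groupby(["source", "age_group"], sort=True):
        s = summarize_distribution(sub["dtw"].to_numpy(), bins=bins)
        rows.append({"source": source, "group_by": "age_group", "group": group,
                     "n": s.n, "median": s.median, "q1": s.q1, "q3": s.q3,
                     "iqr": s.iqr, "whisker_lo": s.whisker_lo,
                     "whisker_hi": s.whisker_hi, "n_outliers": len(s.outliers)})
    for (source, material), sub in scores.groupby(["source", "material"], sort=True):
        s = summarize_distribution(sub["dtw"].to_numpy(), bins=bins)
        rows.append({"source": source, "group_by": "material", "group": material,
                     "n": s.n, "median": s.median, "q1": s.q1, "q3": s.q3,
                     "iqr": s.iqr, "whisker_lo": s.whisker_lo,
                     "whisker_hi": s.whisker_hi, "n_outliers": len(s.outliers)})
    return pd.DataFrame(rows)


def _write_table(df: pd.DataFrame, path: Path, header: list[str]) -> Path:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
    return path


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all stages and write the result tables under ``config.outdir``.

    Outputs: cohort_summary.csv, participant_means.csv, anova.csv,
    percent_change.csv, distribution_summary.csv and config_echo.yaml.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = analyze_cohort(config)
    header = [f"gaitwalk config_hash: {config.config_hash()}", f"seed: {config.seed}"]
    paths = {
        "cohort_summary": _write_table(results["summary"].cells,
                                       outdir / "cohort_summary.csv", header),
        "participant_means": _write_table(results["summary"].participant_means,
                                          outdir / "participant_means.csv", header),
        "anova": _write_table(results["anova"], outdir / "anova.csv", header),
        "percent_change": _write_table(results["percent_change"],
                                       outdir / "percent_change.csv", header),
        "distribution_summary": _write_table(results["distributions"],
                                             outdir / "distribution_summary.csv", header),
    }
    echo = outdir / "config_echo.yaml"
    echo.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    paths["config_echo"] = echo
    log.info("pipeline complete: %d recordings, %d cycles, %d summary cells",
             results["counts"]["recordings"], results["counts"]["cycles"],
             len(results["summary"].cells))
    return paths
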