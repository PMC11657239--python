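"""Reference-cycle selection, DTW scoring, aggregation, percent change."""

import numpy as np
import pandas as pd
import pytest

import gaitwalk as gw


def _pulse(amplitude=1.0, n=50):
    phi = np.arange(n) / n
    return amplitude * np.exp(-0.5 * ((phi - 0.4) / 0.12) ** 2)


class TestSelectReference:
    def test_identical_cycles_first_wins(self):
        cycles = [_pulse(), _pulse(), _pulse()]
        ref = gw.select_reference(cycles)
        assert ref.candidate_index == 0
        assert ref.sum_distance == pytest.approx(0.0)

    def test_outlier_never_selected(self):
        cycles = [_pulse(), _pulse(), _pulse(3.0)]
        ref = gw.select_reference(cycles)
        assert ref.candidate_index in (0, 1)
        # brute-force pairwise sums agree
        k = len(cycles)
        sums = np.zeros(k)
        for i in range(k):
            for j in range(i + 1, k):
                d = gw.dtw_distance(cycles[i], cycles[j])
                sums[i] += d
                sums[j] += d
        assert ref.sum_distance == pytest.approx(sums.min())

    def test_simulated_outlier_excluded(self, sim_cycles):
        cycles = [c.values for c in sim_cycles[:19]] + [2.0 * sim_cycles[19].values]
        ref = gw.select_reference(cycles)
        assert ref.candidate_index != 19

    def test_subsampling_is_deterministic(self, sim_cycles):
        r1 = gw.select_reference(sim_cycles, max_candidates=10, seed=3)
        r2 = gw.select_reference(sim_cycles, max_candidates=10, seed=3)
        assert r1.candidate_index == r2.candidate_index
        assert np.array_equal(r1.values, r2.values)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(gw.ValidationError):
            gw.select_reference([_pulse(), _pulse()])


class TestScoreCycles:
    def test_all_equal_to_reference_scores_zero(self):
        cycles = [_pulse()] * 5
        ref = gw.select_reference(cycles)
        assert np.allclose(gw.score_cycles(cycles, ref), 0.0)

    def test_scaled_cycle_matches_direct_dtw(self):
        ref = gw.ReferenceCycle(values=_pulse())
        doubled = 2.0 * _pulse()
        scores = gw.score_cycles([doubled], ref)
        assert scores[0] == pytest.approx(gw.dtw_distance(doubled, _pulse()))

    def test_fatigue_drift_raises_mean_score(self):
        base = gw.CohortSpec.runtime_scaled(seed=21, walk_scale=0.05)
        from dataclasses import replace
        flat = replace(base, fatigue_drift=0.0)
        profile = base.profiles["cement"]

        def mean_score(spec):
            rec = gw.simulate_recording(profile, "60+", spec, 4)
            series = gw.normalize_svm(gw.filter_svm(gw.svm_series(rec)))
            cycles = gw.segment_cycles(series, rec)
            ref = gw.select_reference(cycles, max_candidates=20, seed=0)
            return float(np.mean(gw.score_cycles(cycles, ref)))

        assert mean_score(base) > mean_score(flat)

    def test_empty_cycle_list_rejected(self):
        with pytest.raises(gw.ValidationError):
            gw.score_cycles([], gw.ReferenceCycle(values=_pulse()))

    def test_scoring_invariant_to_cycle_order(self, sim_cycles):
        ref = gw.select_reference(sim_cycles, max_candidates=15, seed=0)
        fwd = gw.score_cycles(sim_cycles[:10], ref)
        rev = gw.score_cycles(sim_cycles[:10][::-1], ref)
        assert np.allclose(fwd, rev[::-1])


def _score_frame(values, **labels):
    df = pd.DataFrame({"dtw": values})
    df["participant_id"] = labels.get("participant_id", "P001")
    df["material"] = labels.get("material", "wood")
    df["age_group"] = labels.get("age_group", "20-30")
    df["distance_bin"] = labels.get("distance_bin", 0)
    return df


class TestAggregate:
    def test_single_score_cell(self):
        summary = gw.aggregate(_score_frame([7.0]))
        cell = summary.cells.iloc[0]
        assert (cell["n"], cell["mean"], cell["sd"]) == (1, 7.0, 0.0)

    def test_hand_computed_mean_and_sample_sd(self):
        summary = gw.aggregate(_score_frame([2.0, 4.0, 6.0]))
        cell = summary.cells.iloc[0]
        assert cell["mean"] == pytest.approx(4.0)
        assert cell["sd"] == pytest.approx(2.0)  # sample SD
        pop = gw.aggregate(_score_frame([2.0, 4.0, 6.0]), population_sd=True)
        assert pop.cells.iloc[0]["sd"] == pytest.approx(np.sqrt(8.0 / 3.0))

    def test_identical_cycles_give_zero_mean_and_sd(self):
        summary = gw.aggregate(_score_frame([0.0, 0.0, 0.0]))
        cell = summary.cells.iloc[0]
        assert cell["mean"] == 0.0 and cell["sd"] == 0.0

    def test_invariant_to_row_permutation(self):
        df = pd.concat([_score_frame([1, 2, 3], distance_bin=0),
                        _score_frame([4, 5], distance_bin=1)], ignore_index=True)
        shuffled = df.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = gw.aggregate(df).cells
        b = gw.aggregate(shuffled).cells
        pd.testing.assert_frame_equal(a, b)

    def test_participant_means(self):
        df = pd.concat([_score_frame([1.0, 3.0], participant_id="P001"),
                        _score_frame([5.0], participant_id="P002")], ignore_index=True)
        pm = gw.aggregate(df).participant_means
        assert pm.set_index("participant_id")["mean_dtw"].to_dict() == {"P001": 2.0, "P002": 5.0}

    def test_empty_input_rejected(self):
        with pytest.raises(gw.ValidationError):
            gw.aggregate(pd.DataFrame())


class TestPercentChange:
    @pytest.mark.parametrize("a, b, expected", [
        (28.9, 35.2, 21.8),
        (3.1, 10.4, 235.5),
        (25.48, 29.50, 15.8),
        (11.82, 15.50, 31.1),
    ])
    def test_reported_one_decimal_convention(self, a, b, expected):
        assert round(gw.percent_change(a, b), 1) == expected

    def test_no_change_is_zero(self):
        assert gw.percent_change(4.2, 4.2) == 0.0

    def test_lower_than_reference_form(self):
        assert round(gw.percent_lower(41.50, 29.50), 1) == 28.9

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(gw.ValidationError):
            gw.percent_change(0.0, 5.0)
        with pytest.raises(gw.ValidationError):
            gw.percent_lower(-1.0, 5.0)


class TestScoreCohort:
    def test_per_group_references_and_zero_for_reference(self, tiny_spec):
        recs, _ = gw.simulate_cohort(tiny_spec)
        cfg = gw.PipelineConfig(seed=1, sources=("accel",), max_reference_candidates=10)
        from gaitwalk.pipeline import segment_recordings
        records, _, _ = segment_recordings(recs, cfg)
        scores, refs = gw.score_cohort(records, max_candidates=10, seed=1)
        # one reference per (source, material, age_group) stratum
        strata = {(r["source"], r["material"], r["age_group"]) for r in records}
        assert set(refs) == strata
        assert (scores["dtw"] >= 0).all()
        # the reference cycle itself is among the scored cycles with distance 0
        assert (scores.groupby(["source", "material", "age_group"])["dtw"].min() == 0).all()

    def test_global_reference_mode(self, tiny_spec):
        recs, _ = gw.simulate_cohort(tiny_spec)
        cfg = gw.PipelineConfig(seed=1, sources=("accel",), max_reference_candidates=10)
        from gaitwalk.pipeline import segment_recordings
        records, _, _ = segment_recordings(recs, cfg)
        scores, refs = gw.score_cohort(records, max_candidates=10, seed=1,
                                       per_group_reference=False)
        assert list(refs) == [("accel",)]
        assert len(scores) == len(records)
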