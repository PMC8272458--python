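import itertools

import numpy as np
import pandas as pd
import pytest

from phenoscreen.hit_calling import (
    HitRuleConfig,
    TriageConfig,
    call_hits,
    replicate_pass_threshold,
    summarize_target_classes,
    triage_plate,
    triage_well,
    validate_hits,
)

NC_SCORES = 10.0 + np.array([-1.5, -1.0, -0.5, 0.0, 0.0, 0.5, 1.0, 1.5])
# mean 10, sd ~1.07 -> pass threshold ~8.93


def scores_frame(compound_scores: dict[str, float]) -> pd.DataFrame:
    """A scored plate with a fixed NC score distribution plus given compounds."""
    rows = [
        {"well": f"N{i:02d}", "role": "negative_control", "compound_id": None,
         "mhd_ac": v, "mhd_nc": 2.0}
        for i, v in enumerate(NC_SCORES)
    ]
    rows += [
        {"well": f"A{i:02d}", "role": "active_control", "compound_id": None,
         "mhd_ac": 2.0, "mhd_nc": 10.0}
        for i in range(4)
    ]
    rows += [
        {"well": f"C{i:02d}", "role": "compound", "compound_id": cid,
         "mhd_ac": v, "mhd_nc": 9.0}
        for i, (cid, v) in enumerate(compound_scores.items())
    ]
    return pd.DataFrame(rows)


class TestTriage:
    def test_no_objects_means_dead(self):
        assert triage_well(0.5, 9.0, object_count=0, nc_mhd_ac_q=12, ac_mhd_nc_q=12) == "dead"

    def test_at_ac_model_mean_is_ac_like(self):
        assert triage_well(0.0, 9.0, object_count=50, nc_mhd_ac_q=12, ac_mhd_nc_q=12) == "ac_like"

    def test_far_from_both_models_is_disparate(self):
        assert (
            triage_well(20.0, 20.0, object_count=50, nc_mhd_ac_q=12, ac_mhd_nc_q=12)
            == "disparate"
        )

    def test_near_nc_is_nc_like(self):
        assert triage_well(10.0, 1.0, object_count=50, nc_mhd_ac_q=12, ac_mhd_nc_q=12) == "nc_like"

    def test_missing_control_distributions_raise(self):
        with pytest.raises(ValueError):
            triage_well(1.0, 1.0, 10, np.nan, 5.0)

    def test_plate_triage_conserves_wells(self):
        df = scores_frame({"C1": 5.0, "C2": 10.0, "C3": 30.0})
        df.loc[df["compound_id"] == "C3", "mhd_nc"] = 30.0  # disparate well
        counts = pd.Series(0, index=["dead", "disparate", "ac_like", "nc_like"])
        triage = triage_plate(df)
        counts = counts.add(triage.value_counts(), fill_value=0)
        assert counts.sum() == len(df)
        assert triage.loc[df["compound_id"] == "C3"].iloc[0] == "disparate"


class TestDuplicateRule:
    def test_threshold_is_nc_mean_minus_one_sd(self):
        df = scores_frame({})
        thr = replicate_pass_threshold(df)
        assert thr == pytest.approx(NC_SCORES.mean() - NC_SCORES.std(ddof=1))

    def test_exhaustive_replicate_pass_patterns(self):
        """A compound is a final hit iff it passes in every replicate."""
        passing, failing = 5.0, 10.0
        for p1, p2 in itertools.product([True, False], repeat=2):
            reps = {
                1: scores_frame({"C1": passing if p1 else failing}),
                2: scores_frame({"C1": passing if p2 else failing}),
            }
            hits, findings = call_hits(reps)
            assert findings == []
            assert bool(hits["final_hit"].iloc[0]) is (p1 and p2)

    def test_score_at_nc_mean_or_threshold_is_not_a_hit(self):
        thr = replicate_pass_threshold(scores_frame({}))
        for score in (NC_SCORES.mean(), thr):
            reps = {1: scores_frame({"C1": score}), 2: scores_frame({"C1": score})}
            hits, _ = call_hits(reps)
            assert not hits["final_hit"].iloc[0]

    def test_single_replicate_compound_excluded_with_finding(self):
        reps = {
            1: scores_frame({"C1": 5.0, "C2": 5.0}),
            2: scores_frame({"C1": 5.0}),
        }
        hits, findings = call_hits(reps)
        assert "compound_in_single_replicate:C2" in findings
        assert list(hits["compound_id"]) == ["C1"]

    def test_triage_gates_final_hits(self):
        reps = {1: scores_frame({"C1": 5.0}), 2: scores_frame({"C1": 5.0})}
        triage = {
            1: pd.Series(["ac_like"] * len(reps[1])),
            2: pd.Series(["ac_like"] * (len(reps[2]) - 1) + ["nc_like"]),
        }
        hits, _ = call_hits(reps, triage=triage)
        assert not hits["final_hit"].iloc[0]
        triage[2].iloc[-1] = "ac_like"
        hits, _ = call_hits(reps, triage=triage)
        assert hits["final_hit"].iloc[0]

    def test_lowering_score_is_monotone_toward_hit(self):
        """Decreasing mhd_ac can only flip a call from non-hit to hit."""
        was_hit = False
        for score in np.linspace(12.0, 2.0, 21):
            reps = {1: scores_frame({"C1": score}), 2: scores_frame({"C1": score})}
            hit = bool(call_hits(reps)[0]["final_hit"].iloc[0])
            assert hit or not was_hit  # once a hit, stays a hit as score drops
            was_hit = was_hit or hit

    def test_alternative_nc_distance_rule(self):
        df = scores_frame({"C1": 5.0})
        cfg = HitRuleConfig(rule="nc_distance")
        thr = replicate_pass_threshold(df, cfg)
        nc = df.loc[df["role"] == "negative_control", "mhd_nc"]
        assert thr == pytest.approx(nc.mean() + nc.std(ddof=1))


class TestDoseValidation:
    @staticmethod
    def pass_table(rep1: set[int], rep2: set[int], concs=None):
        concs = concs or [0.08, 0.16, 0.31, 0.63, 1.25, 2.5, 5.0, 10.0]
        rows = []
        for rep, passes in ((1, rep1), (2, rep2)):
            for i, c in enumerate(concs, start=1):
                rows.append(
                    {"compound_id": "C1", "concentration_uM": c, "replicate": rep,
                     "passed": i in passes}
                )
        return pd.DataFrame(rows)

    def test_all_concentrations_passing_validates(self):
        res = validate_hits(self.pass_table(set(range(1, 9)), set(range(1, 9))))
        assert res["validated"].iloc[0]
        assert res["n_consecutive_pass"].iloc[0] == 8

    def test_isolated_single_concentration_fails(self):
        res = validate_hits(self.pass_table({4}, {4}))
        assert not res["validated"].iloc[0]

    def test_replicates_must_pass_at_same_concentrations(self):
        res = validate_hits(self.pass_table({5, 6, 7}, {1}))
        assert not res["validated"].iloc[0]
        res = validate_hits(self.pass_table({5, 6, 7}, {6, 7}))
        assert res["validated"].iloc[0]

    def test_missing_concentration_points_raise(self):
        table = self.pass_table({1, 2}, {1, 2})
        with pytest.raises(ValueError, match="concentrations"):
            validate_hits(table[table["concentration_uM"] > 0.1])


class TestTargetClassSummary:
    ANNOTATION = pd.DataFrame(
        {"compound_id": ["a", "b", "c", "d"],
         "target_class": ["MEK1", "MEK1", "TNKS", "PKC"]}
    )

    @staticmethod
    def hits_frame(ids, final=True):
        return pd.DataFrame({"compound_id": ids, "final_hit": final})

    def test_fractions(self):
        out = summarize_target_classes(self.hits_frame(list("abcd")), self.ANNOTATION)
        assert list(out["target_class"]) == ["MEK1", "TNKS", "PKC"]
        assert list(out["fraction"]) == [0.5, 0.25, 0.25]
        assert out["fraction"].sum() == pytest.approx(1.0)

    def test_empty_hit_list(self):
        out = summarize_target_classes(self.hits_frame([]), self.ANNOTATION)
        assert out.empty

    def test_unannotated_hit_counted_as_unknown(self):
        with pytest.warns(UserWarning, match="not annotated"):
            out = summarize_target_classes(self.hits_frame(["a", "zz"]), self.ANNOTATION)
        assert set(out["target_class"]) == {"MEK1", "unknown"}

    def test_planted_actives_all_one_class_in_true_positive_calls(self):
        """Pipeline-level oracle: actives annotated MEK1 dominate true positives."""
        from phenoscreen.mpda_core import score_plate
        from phenoscreen.synthetic_screen import ScreenSimConfig, simulate_feature_screen

        tables, truth = simulate_feature_screen(ScreenSimConfig(), seed=17)
        scored = {r: score_plate(df).scores for r, df in tables.items()}
        hits, _ = call_hits(scored)
        ann = truth[["compound_id"]].copy()
        ann["target_class"] = np.where(truth["is_active"], "MEK1", "OTHER")
        active_ids = set(truth.loc[truth["is_active"], "compound_id"])
        true_pos = hits[hits["final_hit"] & hits["compound_id"].isin(active_ids)]
        assert len(true_pos) > 0
        out = summarize_target_classes(true_pos, ann)
        assert list(out["target_class"]) == ["MEK1"]
        assert out["fraction"].iloc[0] == 1.0
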