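"""Pipeline orchestration: class merging, election, grids, leakage, P1/P2."""

import numpy as np
import pandas as pd
import pytest

import cascadenode as cn
from cascadenode.cohort import DEFAULT_CLASS_SIZES
from cascadenode.pipelines import LeakageAudit

# --------------------------------------------------------------- merging


def test_merge_minority_counts():
    vals = sum(([c] * n for c, n in DEFAULT_CLASS_SIZES.items()), [])
    y = pd.Series(vals)
    merged = cn.merge_minority(y)
    assert merged.value_counts().to_dict() == {
        "OPC": 162, "NPC": 137, "Fusion": 38 + 63
    }


def test_merge_minority_leaves_majority_untouched():
    y = pd.Series(["OPC"] * 5 + ["NPC"] * 3)
    assert cn.merge_minority(y).tolist() == y.tolist()


def test_merge_minority_rejects_unknown_label():
    with pytest.raises(ValueError, match="unknown"):
        cn.merge_minority(pd.Series(["HL", "XYZ"]))


# --------------------------------------------------------------- election


def _cand(name, bal, gen, n):
    return cn.CandidateScore(name, bal, gen, n)


def test_election_general_accuracy_breaks_near_tie():
    """0.580/0.725 vs 0.574/0.750: balanced accuracies within one point,
    so the higher general accuracy wins."""
    winner = cn.elect_feature_set(
        [_cand("F20", 0.580, 0.725, 40), _cand("F25", 0.574, 0.750, 25)]
    )
    assert winner.frequency_threshold == "F25"


def test_election_clear_balanced_leader_wins_outright():
    winner = cn.elect_feature_set(
        [_cand("F15", 0.62, 0.60, 80), _cand("F30", 0.58, 0.99, 5)]
    )
    assert winner.frequency_threshold == "F15"


def test_election_full_tie_prefers_fewest_predictors():
    winner = cn.elect_feature_set(
        [_cand("F15", 0.60, 0.70, 30), _cand("F25", 0.60, 0.70, 12)]
    )
    assert winner.frequency_threshold == "F25"


def test_election_boundary_exactly_one_point_counts_as_tie():
    winner = cn.elect_feature_set(
        [_cand("F15", 0.61, 0.60, 30), _cand("F30", 0.60, 0.75, 10)]
    )
    assert winner.frequency_threshold == "F30"
    with pytest.raises(ValueError):
        cn.elect_feature_set([])


# ------------------------------------------------------------------ grids


def test_config_grid_sizes():
    assert len(cn.config_grid("P1")) == 75
    assert len(cn.config_grid("P2-S1")) == 75
    assert len(cn.config_grid("P2-S2")) == 15
    with pytest.raises(ValueError):
        cn.config_grid("P3")


def test_config_grid_spans_thresholds_and_selectors():
    grid = cn.config_grid("P1")
    assert {c.correlation_threshold for c in grid} == {0.75, 0.80, 0.85}
    assert {c.selector for c in grid} == {"sfs", "sbs", "sffs", "nca", "mrmr"}
    assert {c.frequency_threshold for c in grid} == {"F1", "F15", "F20", "F25", "F30"}


def test_pipeline_config_validation():
    with pytest.raises(ValueError):
        cn.PipelineConfig(pipeline="P3")
    with pytest.raises(ValueError):
        cn.PipelineConfig(correlation_threshold=1.5)
    with pytest.raises(ValueError):
        cn.PipelineConfig(selector="lasso")
    with pytest.raises(ValueError):
        cn.PipelineConfig(frequency_threshold="F7")
    assert cn.PipelineConfig(n_repetitions=5).repetition_seeds() == [1, 2, 3, 4, 5]


# ---------------------------------------------------------------- leakage


def test_leakage_audit_rejects_overlap():
    audit = LeakageAudit()
    audit.record("s", 1, ["a", "b"], ["c"])
    assert audit.verify()
    with pytest.raises(AssertionError):
        audit.record("s", 2, ["a", "b"], ["b"])


def test_pipelines_pass_instrumented_leakage_audit(p1_planted, p2_planted):
    assert p1_planted.audit.verify()
    assert p2_planted.audit.verify()
    assert len(p1_planted.audit.entries) >= 60  # selection + evaluation per rep


# --------------------------------------------------------------------- P1


def test_p1_structure_and_feature_set(p1_planted, planted_cohort):
    res = p1_planted
    assert len(res.eval.repetitions) == 30
    assert [r.seed for r in res.eval.repetitions] == list(range(1, 31))
    assert res.feature_set == res.selection.final_sets["F20"]
    assert res.feature_set <= set(planted_cohort.feature_names)
    assert res.eval.summed_confusion.to_numpy().sum() == 30 * 40
    # with 30 independent 10% held-out folds each patient is missed with
    # probability 0.9^30 ~= 4%, so coverage is near-complete but not total
    seen = set().union(*[set(r.predictions.index) for r in res.eval.repetitions])
    assert seen <= set(planted_cohort.patient_ids)
    assert len(seen) > 0.9 * planted_cohort.n_patients


def test_p1_deterministic(planted_cohort, base_config):
    import dataclasses
    cfg = dataclasses.replace(base_config, n_repetitions=3)
    a = cn.run_p1(cfg, planted_cohort)
    b = cn.run_p1(cfg, planted_cohort)
    assert a.feature_set == b.feature_set
    assert a.eval.median("balanced_acc") == b.eval.median("balanced_acc")
    for ra, rb in zip(a.eval.repetitions, b.eval.repetitions):
        assert (ra.predictions == rb.predictions).all()


def test_p1_requires_labels(planted_cohort, base_config):
    unlabeled = cn.FeatureTable(planted_cohort.features)
    with pytest.raises(ValueError, match="labels"):
        cn.run_p1(base_config, unlabeled)


def test_p1_clinical_only_mode(planted_cohort, base_config):
    import dataclasses
    cfg = dataclasses.replace(base_config, features_mode="clinical", n_repetitions=3)
    res = cn.run_p1(cfg, planted_cohort)
    assert res.feature_set == set()
    assert res.selection is None
    assert 0.0 <= res.eval.median("balanced_acc") <= 1.0


# --------------------------------------------------------------------- P2


def test_p2_stage_structure(p2_planted):
    res = p2_planted
    assert res.s1.classes == ["Fusion", "OPC", "NPC"]
    assert res.s2.classes == ["HL", "OC", "OPC", "NPC"]
    assert res.overall.classes == ["HL", "OC", "OPC", "NPC"]
    assert res.elected in ("F1", "F15", "F20", "F25", "F30")
    assert res.feature_set == res.selection.final_sets[res.elected]
    assert len(res.candidates) >= 1
    # the elected candidate must actually win its own election
    assert cn.elect_feature_set(res.candidates).frequency_threshold == res.elected


def test_p2_overall_confusion_rows_match_test_counts(p2_planted):
    conf = p2_planted.overall.summed_confusion
    # each patient is tested once per repetition; 30 reps x 40 test patients
    assert conf.to_numpy().sum() == 30 * 40
    row_sums = conf.sum(axis=1)
    assert row_sums["OPC"] / row_sums.sum() == pytest.approx(162 / 400, abs=0.02)


def test_p2_composition_consistency(p2_planted):
    """Overall predictions agree with S1 on non-Fusion routes and contain
    no transitory label; S2 predictions cover exactly the Fusion routes."""
    res = p2_planted
    s2_by_seed = {r.seed: r for r in res.s2.repetitions}
    for s1_rep, all_rep in zip(res.s1.repetitions, res.overall.repetitions):
        s1p = s1_rep.predictions
        allp = all_rep.predictions
        assert not (allp == "Fusion").any()
        non_fusion = s1p[s1p != "Fusion"]
        assert (allp.loc[non_fusion.index] == non_fusion).all()
        routed = s1p.index[s1p == "Fusion"]
        if s1_rep.seed in s2_by_seed:
            s2p = s2_by_seed[s1_rep.seed].predictions
            assert set(s2p.index) == set(routed)
            assert (allp.loc[s2p.index] == s2p).all()
        else:
            assert len(routed) == 0


def test_p2_s2_restricted_to_routed_samples(p2_planted):
    n_routed = sum((r.predictions == "Fusion").sum()
                   for r in p2_planted.s1.repetitions)
    n_s2 = sum(len(r.predictions) for r in p2_planted.s2.repetitions)
    assert n_s2 == n_routed
    assert n_routed > 0
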