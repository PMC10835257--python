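"""Seeded stratified partitions, SMOTE geometry, training-set balancing."""

import numpy as np
import pandas as pd
import pytest

import cascadenode as cn
from cascadenode.cohort import DEFAULT_CLASS_SIZES
from cascadenode.partitioning import Repetition, smote_oversample

# -------------------------------------------------------------- partitions


def _labels_400() -> pd.Series:
    vals = sum(([c] * n for c, n in DEFAULT_CLASS_SIZES.items()), [])
    return pd.Series(vals, index=[f"P{i}" for i in range(len(vals))])


def test_partitions_deterministic_and_distinct():
    y = _labels_400()
    a = cn.make_partitions(y)
    b = cn.make_partitions(y)
    assert a.repetitions == b.repetitions
    assert len(a.repetitions) == 30
    assert [r.seed for r in a.repetitions] == list(range(1, 31))
    assert len({r.test_indices for r in a.repetitions}) == 30


def test_partitions_stratified_holdout_fractions():
    y = _labels_400()
    plan = cn.make_partitions(y)
    arr = y.to_numpy()
    for rep in plan.repetitions:
        test_y = arr[list(rep.test_indices)]
        assert len(test_y) == 40
        for cls, n_cls in DEFAULT_CLASS_SIZES.items():
            n_test = (test_y == cls).sum()
            assert abs(n_test - n_cls / 10) < 1.0 + 1e-9
        # OC training count feeds the balancing reference
        train_oc = (arr[list(rep.train_indices)] == "OC").sum()
        assert train_oc in (56, 57)


def test_partitions_reject_class_smaller_than_k():
    y = pd.Series(["HL"] * 5 + ["OC"] * 50)
    with pytest.raises(ValueError, match="smaller than k"):
        cn.make_partitions(y, k=10)


def test_partition_plan_json_round_trip(tmp_path):
    plan = cn.make_partitions(_labels_400(), n_repetitions=3)
    path = tmp_path / "plan.json"
    plan.to_json(path)
    back = cn.PartitionPlan.from_json(path)
    assert back.repetitions == plan.repetitions
    assert (back.n_patients, back.k) == (plan.n_patients, plan.k)


def test_partition_plan_rejects_overlap():
    with pytest.raises(ValueError, match="overlap"):
        cn.PartitionPlan([Repetition(1, (0, 1, 2), (2, 3))], 4)
    with pytest.raises(ValueError, match="cover"):
        cn.PartitionPlan([Repetition(1, (0, 1), (2,))], 4)


# ------------------------------------------------------------------- SMOTE


def test_smote_convexity_on_segment():
    """1-D synthetic points from {0, 1} lie on the segment [0, 1]."""
    X = np.array([[0.0], [1.0]])
    rows, base, nbr, u = smote_oversample(X, 50, k=5, seed=0)
    assert rows.shape == (50, 1)
    synth = rows[2:]
    assert ((synth >= 0.0) & (synth <= 1.0)).all()
    np.testing.assert_allclose(
        synth[:, 0], X[base, 0] + u * (X[nbr, 0] - X[base, 0])
    )


def test_smote_identical_points_reproduce_themselves():
    X = np.tile([2.0, -1.0], (4, 1))
    rows, *_ = smote_oversample(X, 10, seed=1)
    np.testing.assert_allclose(rows, np.tile([2.0, -1.0], (10, 1)))


def test_smote_target_equal_to_minority_is_noop():
    X = np.random.default_rng(0).normal(size=(6, 3))
    rows, base, nbr, u = smote_oversample(X, 6)
    np.testing.assert_array_equal(rows, X)
    assert len(base) == len(nbr) == len(u) == 0


def test_smote_deterministic_and_validated():
    X = np.random.default_rng(1).normal(size=(8, 2))
    a = smote_oversample(X, 20, seed=5)[0]
    b = smote_oversample(X, 20, seed=5)[0]
    np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError):
        smote_oversample(X, 4)
    with pytest.raises(ValueError):
        smote_oversample(X[:1], 5)


def test_smote_rows_interpolate_between_true_neighbors():
    X = np.random.default_rng(2).normal(size=(12, 4))
    rows, base, nbr, u = smote_oversample(X, 30, k=3, seed=3)
    np.testing.assert_allclose(
        rows[12:], X[base] + u[:, None] * (X[nbr] - X[base]), atol=1e-12
    )
    assert (base != nbr).all()


# ------------------------------------------------------------- balancing


def test_balance_equalizes_to_reference_count(planted_cohort):
    """A typical training fold (90% of the cohort) balances to 57 per class."""
    y = planted_cohort.labels
    rng = np.random.default_rng(0)
    # build the fold with per-class test sizes 4/6/16/14 -> train 34/57/146/123
    test_sizes = {"HL": 4, "OC": 6, "OPC": 16, "NPC": 14}
    test_pos: list[int] = []
    for cls, n_test in test_sizes.items():
        pos = np.flatnonzero((y == cls).to_numpy())
        test_pos += list(rng.choice(pos, size=n_test, replace=False))
    train_pos = [i for i in range(len(y)) if i not in set(test_pos)]
    train = planted_cohort.subset_rows(train_pos)
    assert train.labels.value_counts().to_dict() == {
        "HL": 34, "OC": 57, "OPC": 146, "NPC": 123
    }

    balanced = cn.balance_training_set(train, cn.BalanceSpec(seed=7))
    counts = balanced.labels.value_counts()
    assert set(counts) == {57}
    assert balanced.n_patients == 4 * 57
    # undersampled classes contain only original patients
    orig = set(train.patient_ids)
    for cls in ("OPC", "NPC", "OC"):
        assert set(balanced.labels.index[balanced.labels == cls]) <= orig
    # oversampled HL gains synthetic ids; binary clinicals stay binary
    hl_ids = balanced.labels.index[balanced.labels == "HL"]
    assert sum(i.startswith("HL_syn") for i in hl_ids) == 57 - 34
    assert balanced.clinical["sex"].isin([0, 1]).all()
    assert balanced.clinical["hpv"].isin([0, 1]).all()
    amin, amax = train.clinical["age"].min(), train.clinical["age"].max()
    assert balanced.clinical["age"].between(amin, amax).all()


def test_balance_already_balanced_is_identity(tiny_table):
    out = cn.balance_training_set(tiny_table, cn.BalanceSpec(seed=0))
    assert sorted(out.patient_ids) == sorted(tiny_table.patient_ids)
    np.testing.assert_allclose(
        out.features.loc[tiny_table.patient_ids].to_numpy(),
        tiny_table.features.to_numpy(),
    )


def test_balance_deterministic(planted_cohort):
    spec = cn.BalanceSpec(seed=11)
    a = cn.balance_training_set(planted_cohort, spec)
    b = cn.balance_training_set(planted_cohort, spec)
    assert a == b


def test_balance_missing_reference_rejected(tiny_table):
    sub = tiny_table.subset_rows(
        np.flatnonzero((tiny_table.labels != "OC").to_numpy())
    )
    with pytest.raises(ValueError, match="reference class"):
        cn.balance_training_set(sub, cn.BalanceSpec())
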