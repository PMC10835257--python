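"""Shared fixtures.

The heavy end-to-end pipeline runs are session-scoped so that the unit,
property and acceptance tests can all interrogate the same results without
recomputing them.  Problem sizes are kept at desk scale: the cohort keeps
the design class imbalance (38/63/162/137, 400 patients) but carries 60
feature columns (15 informative, 4 correlated blocks of 5, the rest noise),
and the selector is MRMR with a budget of 15 so that selection capacity is
not the binding constraint.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import cascadenode as cn


@pytest.fixture(scope="session")
def planted_cohort() -> cn.FeatureTable:
    """400-patient cohort with 15 planted informative features."""
    spec = cn.CohortSpec(
        seed=11, n_features=60, n_informative=15,
        n_redundant_blocks=4, block_size=5,
    )
    return cn.generate_cohort(spec)


@pytest.fixture(scope="session")
def base_config() -> cn.PipelineConfig:
    return cn.PipelineConfig(
        pipeline="P1", selector="mrmr", frequency_threshold="F20",
        model=cn.ModelSpec(kind="SVM", svm_kernel="linear"), mrmr_m=15,
    )


@pytest.fixture(scope="session")
def p1_planted(planted_cohort, base_config):
    return cn.run_p1(base_config, planted_cohort)


@pytest.fixture(scope="session")
def p2_planted(planted_cohort, base_config):
    config = dataclasses.replace(base_config, pipeline="P2")
    return cn.run_p2(config, planted_cohort)


@pytest.fixture(scope="session")
def p1_permuted(planted_cohort, base_config):
    """Same pipeline on label-permuted data: the chance-level control."""
    rng = np.random.default_rng(123)
    perm = rng.permutation(planted_cohort.labels.to_numpy())
    shuffled = planted_cohort.with_labels(
        pd.Series(perm, index=planted_cohort.features.index)
    )
    return cn.run_p1(base_config, shuffled)


@pytest.fixture(scope="session")
def fusion_cohort() -> cn.FeatureTable:
    """Hierarchically structured cohort: the coarse HL+OC vs OPC vs NPC
    split and the fine HL-vs-OC split live on disjoint feature groups."""
    spec = cn.CohortSpec(
        seed=29, n_features=60, n_informative=15, effect_size=0.8,
        n_redundant_blocks=4, block_size=5,
        fusion_separable=True, fine_effect_ratio=1.5,
    )
    return cn.generate_cohort(spec)


@pytest.fixture(scope="session")
def fusion_pair(fusion_cohort, base_config):
    """P1 (quadratic SVM) and P2 (linear SVM) on the hierarchical cohort,
    mirroring the elected best model of each pipeline."""
    cfg1 = dataclasses.replace(
        base_config, model=cn.ModelSpec(kind="SVM", svm_kernel="quadratic")
    )
    cfg2 = dataclasses.replace(base_config, pipeline="P2")
    return cn.run_p1(cfg1, fusion_cohort), cn.run_p2(cfg2, fusion_cohort)


@pytest.fixture()
def tiny_table() -> cn.FeatureTable:
    """Deterministic 12-patient, 4-feature table for plumbing tests."""
    rng = np.random.default_rng(42)
    ids = [f"P{i}" for i in range(12)]
    feats = pd.DataFrame(
        rng.normal(size=(12, 4)), index=ids, columns=["f1", "f2", "f3", "f4"]
    )
    labels = pd.Series(["HL", "OC", "OPC", "NPC"] * 3, index=ids)
    clin = pd.DataFrame(
        {"sex": rng.integers(0, 2, 12), "age": rng.uniform(30, 80, 12).round(1),
         "hpv": rng.integers(0, 2, 12)},
        index=ids,
    )
    return cn.FeatureTable(feats, labels, clin)
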