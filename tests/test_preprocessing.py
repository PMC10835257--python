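"""ICC reliability filter, Spearman redundancy pruning, z-scoring."""

import numpy as np
import pandas as pd
import pytest

import cascadenode as cn
from cascadenode.preprocessing import zscore_apply, zscore_fit

# ---------------------------------------------------------------- ICC(2,1)


def _icc21_bruteforce(y: np.ndarray) -> float:
    """Independent route: ICC(2,1) from explicitly looped ANOVA sums."""
    n, k = y.shape
    grand = y.mean()
    msr = sum(k * (y[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sst = sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    mse = (sst - (n - 1) * msr - (k - 1) * msc) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def test_icc_perfect_agreement():
    y = np.column_stack([np.arange(10.0), np.arange(10.0)])
    est, lo, hi = cn.icc(y)
    assert est == pytest.approx(1.0)
    assert lo <= est <= hi


def test_icc_matches_anova_bruteforce():
    y = np.array([[9, 2], [1, 10], [8, 8], [2, 6], [7, 9], [3, 1.0]])
    est, _, _ = cn.icc(y)
    assert est == pytest.approx(_icc21_bruteforce(y), abs=1e-10)
    rng = np.random.default_rng(7)
    for _ in range(20):
        y = rng.normal(size=(rng.integers(4, 30), rng.integers(2, 5)))
        assert cn.icc(y)[0] == pytest.approx(_icc21_bruteforce(y), abs=1e-10)


def test_icc_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    subj = rng.normal(size=40)
    y = np.column_stack([subj + rng.normal(scale=0.5, size=40) for _ in range(2)])
    est, lo, hi = cn.icc(y)

    df = pd.DataFrame(
        {"subject": np.repeat(np.arange(40), 2),
         "rater": np.tile([0, 1], 40),
         "score": y.ravel()}
    )
    res = pg.intraclass_corr(df, targets="subject", raters="rater",
                             ratings="score").iloc[1]  # ICC(A,1) row
    assert est == pytest.approx(res["ICC"], abs=1e-8)
    ci = res["CI95"] if "CI95" in res.index else res["CI95%"]
    assert lo == pytest.approx(ci[0], abs=0.06)
    assert hi == pytest.approx(ci[1], abs=0.06)


def test_icc_penalizes_systematic_shift():
    """Absolute agreement: a constant reader bias lowers ICC(2,1)."""
    rng = np.random.default_rng(0)
    x = rng.normal(size=30)
    unbiased, _, _ = cn.icc(np.column_stack([x, x + rng.normal(scale=0.1, size=30)]))
    biased, _, _ = cn.icc(np.column_stack([x, x + 2.0]))
    assert biased < unbiased
    assert biased < 1.0


def test_icc_input_validation():
    with pytest.raises(ValueError):
        cn.icc(np.ones((2, 2)))
    with pytest.raises(ValueError):
        cn.icc(np.ones((5, 1)))
    with pytest.raises(ValueError):
        cn.icc(np.array([[1.0, np.nan], [2, 2], [3, 3]]))


# --------------------------------------------------------- stability filter


def test_stability_filter_keeps_reliable_drops_noisy():
    rng = np.random.default_rng(5)
    ids = [f"P{i}" for i in range(50)]
    base = rng.normal(size=(50, 3))
    feats = pd.DataFrame(base, index=ids, columns=["good", "ok", "bad"])
    rep = pd.DataFrame(
        np.column_stack([
            base[:, 0],                                        # identical
            base[:, 1] + rng.normal(scale=0.3, size=50),       # reliable
            rng.normal(size=50),                               # unrelated
        ]),
        index=ids, columns=["good", "ok", "bad"],
    )
    filtered, report = cn.stability_filter(
        cn.FeatureTable(feats), cn.FeatureTable(rep), icc_threshold=0.75
    )
    assert filtered.feature_names == ["good", "ok"]
    assert report.loc["good", "icc"] == pytest.approx(1.0)
    assert not report.loc["bad", "stable"]
    assert report.loc["bad", "icc"] < 0.5


def test_stability_filter_ci_low_is_stricter():
    rng = np.random.default_rng(8)
    ids = [f"P{i}" for i in range(25)]
    base = rng.normal(size=(25, 6))
    feats = pd.DataFrame(base, index=ids, columns=[f"f{j}" for j in range(6)])
    rep = feats + rng.normal(scale=0.45, size=(25, 6))
    t, trep = cn.FeatureTable(feats), cn.FeatureTable(rep)
    on_est, _ = cn.stability_filter(t, trep, 0.75, on="estimate")
    on_ci, _ = cn.stability_filter(t, trep, 0.75, on="ci_low")
    assert set(on_ci.feature_names) <= set(on_est.feature_names)


def test_stability_filter_idempotent():
    rng = np.random.default_rng(9)
    ids = [f"P{i}" for i in range(30)]
    feats = pd.DataFrame(rng.normal(size=(30, 5)), index=ids,
                         columns=[f"f{j}" for j in range(5)])
    rep = cn.FeatureTable(feats + rng.normal(scale=0.2, size=(30, 5)))
    t = cn.FeatureTable(feats)
    once, _ = cn.stability_filter(t, rep, 0.75)
    twice, _ = cn.stability_filter(
        once, rep.select_features(once.feature_names), 0.75
    )
    assert twice.feature_names == once.feature_names


# ------------------------------------------------------- correlation prune


def _prune_oracle(df: pd.DataFrame, threshold: float) -> set[str]:
    """Independent reimplementation of the greedy rule on a DataFrame."""
    from scipy import stats

    names = list(df.columns)
    rho = np.abs(stats.spearmanr(df.to_numpy()).statistic)
    np.fill_diagonal(rho, 0.0)
    kept = set(range(len(names)))
    while True:
        pairs = [(rho[a, b], a, b) for a in kept for b in kept
                 if a < b and rho[a, b] > threshold]
        if not pairs:
            return {names[i] for i in kept}
        _, a, b = max(pairs)
        others = [i for i in kept if i not in (a, b)]
        ma = np.mean([rho[a, o] for o in others]) if others else 0.0
        mb = np.mean([rho[b, o] for o in others]) if others else 0.0
        if ma > mb:
            kept.discard(a)
        elif mb > ma:
            kept.discard(b)
        else:
            kept.discard(b if names[a] < names[b] else a)


def test_prune_removes_duplicate_feature():
    rng = np.random.default_rng(1)
    x = rng.normal(size=40)
    df = pd.DataFrame({"a": x, "a_copy": x, "b": rng.normal(size=40)},
                      index=[f"P{i}" for i in range(40)])
    res = cn.correlation_prune(cn.FeatureTable(df), 0.85)
    assert "b" in res.kept_features
    assert sorted(res.kept_features + res.removed_features) == ["a", "a_copy", "b"]
    assert len(res.removed_features) == 1


def test_prune_threshold_one_is_noop_for_nondegenerate_data():
    rng = np.random.default_rng(2)
    df = pd.DataFrame(rng.normal(size=(30, 5)),
                      index=[f"P{i}" for i in range(30)],
                      columns=[f"f{j}" for j in range(5)])
    res = cn.correlation_prune(cn.FeatureTable(df), 1.0)
    assert res.kept_features == list(df.columns)


def test_prune_matches_bruteforce_oracle():
    rng = np.random.default_rng(4)
    z = rng.normal(size=(60, 2))
    cols = {
        "a": z[:, 0] + 0.1 * rng.normal(size=60),
        "b": z[:, 0] + 0.1 * rng.normal(size=60),
        "c": z[:, 0] + 0.3 * rng.normal(size=60),
        "d": z[:, 1] + 0.1 * rng.normal(size=60),
        "e": z[:, 1] + 0.1 * rng.normal(size=60),
        "f": rng.normal(size=60),
    }
    table = cn.FeatureTable(pd.DataFrame(cols, index=[f"P{i}" for i in range(60)]))
    for thr in (0.75, 0.80, 0.85):
        res = cn.correlation_prune(table, thr)
        assert set(res.kept_features) == _prune_oracle(table.features, thr)


def test_prune_monotone_in_threshold(planted_cohort):
    kept = [
        len(cn.correlation_prune(planted_cohort, t).kept_features)
        for t in (0.75, 0.80, 0.85)
    ]
    assert kept[0] <= kept[1] <= kept[2]
    # the four rho=0.9 blocks of five collapse at any of the study thresholds
    assert kept[0] < planted_cohort.n_features


def test_prune_rejects_bad_threshold(tiny_table):
    with pytest.raises(ValueError):
        cn.correlation_prune(tiny_table, 0.0)
    with pytest.raises(ValueError):
        cn.correlation_prune(tiny_table, 1.2)


# ----------------------------------------------------------------- z-score


def test_zscore_train_mean_zero_sd_one(tiny_table):
    params = zscore_fit(tiny_table)
    z = zscore_apply(tiny_table, params)
    np.testing.assert_allclose(z.features.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(z.features.std(axis=0, ddof=0), 1.0, atol=1e-12)


def test_zscore_constant_column_maps_to_zero():
    df = pd.DataFrame({"c": [3.0, 3.0, 3.0], "x": [1.0, 2.0, 3.0]},
                      index=["a", "b", "c"])
    t = cn.FeatureTable(df)
    params = zscore_fit(t)
    assert params.constant_features == ["c"]
    z = zscore_apply(t, params)
    np.testing.assert_allclose(z.features["c"], 0.0)


def test_zscore_test_rows_use_training_parameters(tiny_table):
    params = zscore_fit(tiny_table)
    mean_row = pd.DataFrame([params.mean.to_numpy()], index=["new"],
                            columns=tiny_table.feature_names)
    z = zscore_apply(cn.FeatureTable(mean_row), params)
    np.testing.assert_allclose(z.features.to_numpy(), 0.0, atol=1e-12)
    with pytest.raises(ValueError):
        zscore_apply(tiny_table.select_features(["f2", "f1"]), params)
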