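"""Welch/BH, permutation-FDR screening, variability, robustness, AB-size."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lineage4d.errors import ArgumentError
from lineage4d.groupstats import (
    ScreenConfig,
    anova_tukey,
    bin_lethality,
    permutation_fdr_alpha,
    robustness_screen,
    size_correlation,
    variability_stats,
    welch_bh,
)


def _table(rows_a, rows_b, columns=None):
    a = np.asarray(rows_a, float)
    b = np.asarray(rows_b, float)
    X = np.vstack([a, b])
    idx = [f"a{i}" for i in range(len(a))] + [f"b{i}" for i in range(len(b))]
    cols = columns or [f"f{j}" for j in range(X.shape[1])]
    table = pd.DataFrame(X, index=idx, columns=cols)
    labels = pd.Series(["A"] * len(a) + ["B"] * len(b), index=idx)
    return table, labels


def test_welch_hand_computed_oracle():
    # {1..5} vs {3..7}: t = -2, df = 8, p = 2*P(T_8 > 2)
    table, labels = _table([[v] for v in [1, 2, 3, 4, 5]],
                           [[v] for v in [3, 4, 5, 6, 7]])
    out = welch_bh(table, labels, "A", "B")
    assert out.loc[0, "t"] == pytest.approx(-2.0)
    p_oracle = 2 * sps.t.sf(2.0, 8)
    assert out.loc[0, "p"] == pytest.approx(p_oracle, rel=1e-10)
    # cross-check against scipy's own Welch implementation
    t_sp, p_sp = sps.ttest_ind([1, 2, 3, 4, 5], [3, 4, 5, 6, 7], equal_var=False)
    assert out.loc[0, "p"] == pytest.approx(p_sp, rel=1e-10)
    # relative effect versus group B
    assert out.loc[0, "effect"] == pytest.approx((3 - 5) / 5)


def test_bh_brute_force_oracle():
    raw = np.array([0.01, 0.02, 0.03, 0.04])
    # brute-force BH step-up
    m = len(raw)
    order = np.argsort(raw)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, raw[i] * m / rank)
        adj[i] = running
    np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    rng = np.random.default_rng(0)
    table, labels = _table(rng.normal(0, 1, (6, 4)), rng.normal(1.2, 1, (6, 4)))
    out = welch_bh(table, labels, "A", "B")
    # implementation BH equals the brute-force oracle on its own p-values
    raw2 = out["p"].to_numpy()
    order = np.argsort(raw2)
    adj2 = np.empty(len(raw2))
    running = 1.0
    for rank in range(len(raw2), 0, -1):
        i = order[rank - 1]
        running = min(running, raw2[i] * len(raw2) / rank)
        adj2[i] = running
    np.testing.assert_allclose(out["p_adj"].to_numpy(), adj2, rtol=1e-12)


def test_identical_groups_null():
    vals = np.tile(np.arange(1.0, 11.0), (8, 1))
    table, labels = _table(vals[:4], vals[4:])
    out = welch_bh(table, labels, "A", "B")
    assert (out["effect"] == 0).all()
    assert (out["p"] >= 0.99).all()


def test_bh_monotone_and_not_below_raw(rng):
    table, labels = _table(rng.normal(0, 1, (8, 40)), rng.normal(0.3, 1, (8, 40)))
    out = welch_bh(table, labels, "A", "B").sort_values("p")
    assert (out["p_adj"].to_numpy() >= out["p"].to_numpy() - 1e-15).all()
    assert (np.diff(out["p_adj"].to_numpy()) >= -1e-15).all()


def test_welch_type_one_error_calibrated(rng):
    # 2000 null features, alpha = 0.05 -> rejection rate 5% +- 2%
    table, labels = _table(
        rng.normal(0, 1, (15, 2000)), rng.normal(0, 1, (15, 2000))
    )
    out = welch_bh(table, labels, "A", "B")
    rate = float((out["p"] < 0.05).mean())
    assert 0.03 <= rate <= 0.07


def test_permutation_screen_null_passes_nothing(rng):
    table, labels = _table(
        rng.normal(0, 1, (30, 500)), rng.normal(0, 1, (30, 500))
    )
    cfg = ScreenConfig(seed=5, n_shuffles=40)
    alpha, res = permutation_fdr_alpha(table, labels, cfg)
    assert int(res.table["passes"].sum()) <= 2


def test_permutation_screen_zero_shuffles():
    cfg = ScreenConfig(n_shuffles=0)
    with pytest.raises(ArgumentError):
        cfg.validate()


def test_permutation_screen_recovers_planted(rng):
    # 20 features with a 30% group shift among 500 nulls, n = 30 per group
    base = rng.normal(1.0, 0.12, (60, 520))
    planted = [f"f{j}" for j in range(20)]
    table = pd.DataFrame(
        base, index=[f"e{i}" for i in range(60)],
        columns=planted + [f"n{j}" for j in range(500)],
    )
    labels = pd.Series(["dead"] * 30 + ["alive"] * 30, index=table.index)
    table.loc[labels == "dead", planted] *= 1.30
    cfg = ScreenConfig(seed=11, n_shuffles=50)
    alpha, res = permutation_fdr_alpha(table, labels, cfg)
    passing = set(res.passing_features)
    recovered = len(passing & set(planted)) / len(planted)
    false = len(passing - set(planted))
    fdr = false / max(len(passing), 1)
    assert recovered >= 0.9
    assert fdr <= 0.15


def test_variability_cv_arithmetic():
    table = pd.DataFrame(
        {"MS.LifeTime": [9.0, 10.0, 11.0], "E.LifeTime": [10.0, 10.0, 10.0]},
        index=["e1", "e2", "e3"],
    )
    groups = pd.Series("control", index=table.index)
    out = variability_stats(table, groups).set_index("feature")
    assert out.loc["MS.LifeTime", "cv"] == pytest.approx(0.1)  # SD 1, mean 10
    assert out.loc["E.LifeTime", "cv"] == 0.0


def test_cv_invariant_under_time_dilation(rng):
    vals = rng.normal(20, 2, (10, 5))
    table = pd.DataFrame(vals, index=[f"e{i}" for i in range(10)])
    groups = pd.Series("g", index=table.index)
    a = variability_stats(table, groups)
    b = variability_stats(table * 1.3, groups)
    np.testing.assert_allclose(a["cv"], b["cv"], rtol=1e-12)
    np.testing.assert_allclose(b["sd"], 1.3 * a["sd"], rtol=1e-12)


def test_cv_undefined_for_nonpositive_mean():
    table = pd.DataFrame({"x": [-1.0, -2.0, -3.0]})
    out = variability_stats(table, pd.Series("g", index=table.index))
    assert np.isnan(out.loc[0, "cv"])


def test_anova_tukey_separated_groups(rng):
    values = pd.Series(
        np.r_[rng.normal(0, 1, 20), rng.normal(5, 1, 20), rng.normal(10, 1, 20)]
    )
    groups = pd.Series(["a"] * 20 + ["b"] * 20 + ["c"] * 20)
    p, summary = anova_tukey(values, groups)
    assert p < 1e-10
    assert summary["reject"].all()


def test_robustness_screen_identical_groups(rng):
    vals = rng.normal(0, 1, (12, 30))
    table, labels = _table(vals[:6], vals[6:][::-1] * 0 + vals[:6])
    out = robustness_screen(table, labels, "A", "B")
    assert not out["flagged"].any()


def test_robustness_screen_detects_inflated_variance(rng):
    # equal means, 3x SD in group B, n = 20 per group: >= 80% power
    hits = 0
    for seed in range(10):
        r = np.random.default_rng(seed)
        a = r.normal(0, 1, (20, 1))
        b = r.normal(0, 3, (20, 1))
        table, labels = _table(a, b)
        out = robustness_screen(table, labels, "A", "B", min_embryos_per_group=5)
        hits += int(out["flagged"].iloc[0])
    assert hits >= 8


def test_robustness_screen_one_sided(rng):
    # group B variance smaller -> never flagged
    a = rng.normal(0, 3, (20, 5))
    b = rng.normal(0, 1, (20, 5))
    table, labels = _table(a, b)
    out = robustness_screen(table, labels, "A", "B", min_embryos_per_group=5)
    assert not out["flagged"].any()


def test_robustness_screen_levene_alternative(rng):
    a = rng.normal(0, 1, (20, 1))
    b = rng.normal(0, 3, (20, 1))
    table, labels = _table(a, b)
    out = robustness_screen(
        table, labels, "A", "B", min_embryos_per_group=5, variance_test="levene"
    )
    assert out["flagged"].iloc[0]
    # one-sided: deflated variance in B is never flagged
    out2 = robustness_screen(
        table,
        labels.map({"A": "B", "B": "A"}),
        "A",
        "B",
        min_embryos_per_group=5,
        variance_test="levene",
    )
    assert not out2["flagged"].any()


def test_absolute_effect_mode(rng):
    table, labels = _table(
        rng.normal(0.0, 0.5, (10, 3)), rng.normal(2.0, 0.5, (10, 3))
    )
    cfg = ScreenConfig(effect_mode="absolute", effect_threshold=0.5,
                       n_shuffles=10, seed=1, min_embryos_per_group=5)
    alpha, res = permutation_fdr_alpha(table, labels, cfg)
    # means near 0 make the relative effect unstable; the absolute mode
    # reports the plain difference (~ -2 here)
    assert (res.table["effect"] < -1.0).all()
    with pytest.raises(ArgumentError):
        ScreenConfig(effect_mode="log").validate()


def test_bin_lethality_labels_and_counts():
    meta = pd.DataFrame(
        {
            "relative_AB_size": [55.0, 54.0, 54.5, 49.0, 61.0],
            "outcome": ["alive", "dead", "dead", "dead", "alive"],
        },
        index=[f"e{i}" for i in range(5)],
    )
    out = bin_lethality(meta, bin_width=2.0, lo=46.0, hi=62.0).set_index("bin")
    row = out.loc["(56-54]"]
    assert row["n"] == 3  # 54 included, 56 excluded
    assert row["lethality"] == pytest.approx(2 / 3)
    assert out.loc["(50-48]", "lethality"] == 1.0
    empty = out[out["n"] == 0]
    assert len(empty) > 0 and empty["lethality"].isna().all()


def test_all_alive_zero_lethality():
    meta = pd.DataFrame(
        {"relative_AB_size": np.linspace(48, 60, 24), "outcome": ["alive"] * 24}
    )
    out = bin_lethality(meta)
    assert (out.loc[out["n"] > 0, "lethality"] == 0).all()


def test_pearson_closed_form_oracle(rng):
    size = pd.Series(np.linspace(48, 58, 10), index=[f"e{i}" for i in range(10)])
    q = pd.Series(
        2.0 * size.to_numpy() + rng.normal(0, 1.5, 10), index=size.index
    )
    meta = pd.DataFrame({"relative_AB_size": size, "outcome": "alive"})
    r, p, n = size_correlation(meta, q)
    # textbook formula: t = r * sqrt((n-2) / (1-r^2)), two-sided t_{n-2}
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p_oracle = 2 * sps.t.sf(abs(t), n - 2)
    assert p == pytest.approx(p_oracle, rel=1e-9)
    assert r > 0.9


def test_perfect_correlation():
    size = pd.Series(np.linspace(48, 58, 8))
    meta = pd.DataFrame({"relative_AB_size": size, "outcome": "alive"})
    r, p, n = size_correlation(meta, size * 0.5 + 1.0)
    assert r == pytest.approx(1.0)
    assert p < 1e-12
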