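import numpy as np
import pandas as pd
import pytest

from peristroma.graph import (
    N_PAIRS,
    anova_between_groups,
    build_region_graph,
    degree_summary,
    one_way_anova,
)
from peristroma.segmentation import REGION_NAMES

from _oracles import brute_anova, brute_auc, brute_pearson  # noqa: F401


def _table_from_means(means: dict[str, np.ndarray], label: str = "high") -> pd.DataFrame:
    n = len(next(iter(means.values())))
    data = {"case_id": [f"c{i}" for i in range(n)]}
    for name in REGION_NAMES:
        data[f"mean__{name}"] = means[name]
    data["ki67_label"] = [label] * n
    return pd.DataFrame(data)


def _random_table(rng, n=30, label="high"):
    base = rng.normal(1.0, 0.2, size=n)
    means = {
        name: base * rng.uniform(0, 1) + rng.normal(1.0, 0.2, size=n)
        for name in REGION_NAMES
    }
    return _table_from_means(means, label)


def test_graph_has_six_nodes_and_at_most_15_edges():
    table = _random_table(np.random.default_rng(0))
    g = build_region_graph(table, "high")
    assert len(g.graph.nodes) == 6
    assert len(g.edges) <= N_PAIRS
    assert sum(g.degrees.values()) == 2 * len(g.edges)


def test_identical_mean_vectors_give_certain_edge():
    rng = np.random.default_rng(1)
    v = rng.normal(1.0, 0.2, size=20)
    means = {name: rng.normal(1.0, 0.2, size=20) for name in REGION_NAMES}
    means["S_I"] = v
    means["S_T"] = v.copy()
    g = build_region_graph(_table_from_means(means), "high")
    row = g.pair_stats.query("region_a == 'S_I' and region_b == 'S_T'").iloc[0]
    assert row.r == pytest.approx(1.0)
    assert row.p_bonf < 1e-10
    assert ("S_I", "S_T") in g.edges


def test_bonferroni_arithmetic_and_monotonicity():
    rng = np.random.default_rng(2)
    g = build_region_graph(_random_table(rng), "high")
    ps = g.pair_stats
    np.testing.assert_allclose(ps.p_bonf, np.minimum(1.0, N_PAIRS * ps.p_raw))
    # the correction can only remove edges relative to the raw gate
    assert not (ps.edge & ~(ps.p_raw < 0.05)).any()
    # a pair significant raw but not after correction yields no edge
    borderline = ps[(ps.p_raw < 0.05) & (ps.p_bonf >= 0.05)]
    assert not borderline.edge.any()


def test_edge_decisions_match_brute_force():
    rng = np.random.default_rng(3)
    for _ in range(5):
        table = _random_table(rng, n=rng.integers(10, 40))
        g = build_region_graph(table, "high")
        for row in g.pair_stats.itertuples():
            x = table[f"mean__{row.region_a}"].to_numpy()
            y = table[f"mean__{row.region_b}"].to_numpy()
            r, p = brute_pearson(x, y)
            assert row.r == pytest.approx(r, rel=1e-10)
            assert row.p_raw == pytest.approx(p, rel=1e-8, abs=1e-300)
            assert row.edge == (min(1.0, N_PAIRS * p) < 0.05)


def test_missing_means_dropped_pairwise():
    rng = np.random.default_rng(4)
    table = _random_table(rng, n=20)
    table.loc[:4, "mean__S_D"] = np.nan
    g = build_region_graph(table, "high")
    ns = g.pair_stats.set_index(["region_a", "region_b"]).n
    assert ns[("S_I", "S_T")] == 20
    assert ns[("S_P", "S_D")] == 15


def test_zero_variance_region_gives_no_edge():
    rng = np.random.default_rng(5)
    table = _random_table(rng, n=15)
    table["mean__S_M"] = 1.0
    g = build_region_graph(table, "high")
    sm = g.pair_stats.query("region_a == 'S_M' or region_b == 'S_M'")
    assert sm.r.isna().all() and not sm.edge.any()


def test_degree_summary_empty_and_complete():
    rng = np.random.default_rng(6)
    # independent noise: (almost surely) no edges at n=10
    means = {name: rng.normal(1.0, 0.2, size=10) for name in REGION_NAMES}
    g0 = build_region_graph(_table_from_means(means), "high")
    if not g0.edges:
        assert all(d == 0 for d in g0.degrees.values())
    # six copies of one vector: complete graph, all degrees 5, total 30
    v = rng.normal(1.0, 0.2, size=10)
    gc = build_region_graph(
        _table_from_means({name: v.copy() for name in REGION_NAMES}), "high"
    )
    assert len(gc.edges) == 15
    assert all(d == 5 for d in gc.degrees.values())
    assert gc.total_degree == 30
    summary = degree_summary(gc)
    assert summary.loc[summary.region == "total", "degree"].item() == 30


def test_anova_null_by_construction():
    groups = {
        "a": np.array([1.0, 2.0, 3.0]),
        "b": np.array([1.0, 2.0, 3.0]),
        "c": np.array([2.0, 1.0, 3.0]),
    }
    res = one_way_anova(groups)
    assert res["F"] < 0.01
    assert res["p"] > 0.99


def test_anova_matches_brute_force_sums_of_squares():
    res = one_way_anova({"a": np.array([1.0, 2, 3]), "b": np.array([7.0, 8, 9])})
    f, p = brute_anova([[1.0, 2, 3], [7.0, 8, 9]])
    assert f == pytest.approx(54.0)  # SSB=54, SSW=4, df=(1,4)
    assert res["F"] == pytest.approx(f, rel=1e-12)
    assert res["p"] == pytest.approx(p, rel=1e-10)
    rng = np.random.default_rng(7)
    for _ in range(5):
        gs = [rng.normal(rng.uniform(0, 1), 1.0, size=rng.integers(3, 12))
              for _ in range(3)]
        res = one_way_anova({str(i): g for i, g in enumerate(gs)})
        f, p = brute_anova([list(g) for g in gs])
        assert res["F"] == pytest.approx(f, rel=1e-10)
        assert res["p"] == pytest.approx(p, rel=1e-8)


def test_anova_permutation_type_i_error():
    rng = np.random.default_rng(8)
    values = rng.normal(0, 1, size=24)
    hits = 0
    n_perm = 1000
    for _ in range(n_perm):
        perm = rng.permutation(values)
        res = one_way_anova({"a": perm[:12], "b": perm[12:]})
        hits += res["p"] < 0.05
    assert 0.03 <= hits / n_perm <= 0.07


def test_anova_small_group_excluded():
    res = one_way_anova(
        {"a": np.array([1.0, 2, 3]), "b": np.array([4.0, 5, 6]), "c": np.array([9.0])}
    )
    assert res["excluded_groups"] == ["c"]


def test_null_edge_rate_controlled():
    """Identity-correlation latents: expected edges/group = 15 x 0.05 = 0.75;
    the observed mean over 200 seeded cohorts stays below 1.5."""
    from peristroma.synthetic import CohortConfig, generate_cohort

    total_edges = 0
    n_seeds = 200
    for seed in range(n_seeds):
        config = CohortConfig(
            n_cases=40, high_fraction=1.0, seed=seed,
            region_corr_low=np.eye(6), region_corr_high=np.eye(6),
        )
        latents = np.array(
            [c.ground_truth_region_means for c in generate_cohort(config)]
        )
        table = _table_from_means(
            {name: latents[:, i] for i, name in enumerate(REGION_NAMES)}
        )
        total_edges += len(build_region_graph(table, "high").edges)
    assert total_edges / n_seeds < 1.5


def test_group_anova_on_feature_table(small_table):
    res = anova_between_groups(small_table, "mean__S_T")
    assert res["df_between"] == 1
    assert 0 <= res["p"] <= 1
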