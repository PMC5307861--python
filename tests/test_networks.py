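"""Co-expression pair computation, classification schemes, sub-networks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lncpop import (classify_pairs, population_stats, responsive_network,
                    spearman_pairs, spearman_rho, subnetworks_by_degree,
                    network_summary, ratio_stats)
from lncpop.errors import ConfigurationError, InputError

from conftest import toy_matrix


def rank_pearson_oracle(x, y):
    """Independent oracle: rank with average ties, then plain Pearson."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


def test_spearman_trivial_cases():
    assert spearman_rho([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)
    assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)


def test_spearman_matches_rank_pearson_oracle():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        n = int(rng.integers(4, 40))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if rng.random() < 0.5:  # inject ties
            x = np.round(x, 1)
            y = np.round(y, 1)
        assert spearman_rho(x, y) == pytest.approx(
            rank_pearson_oracle(x, y), abs=1e-12)


def _pair_table(**cols):
    base = {"lncRNA_id": ["l1"], "mRNA_id": ["m1"],
            "rho_env1": [0.0], "rho_env2": [0.0],
            "p_env1": [1e-6], "p_env2": [1e-6]}
    base.update({k: [v] for k, v in cols.items()})
    return pd.DataFrame(base)


@pytest.mark.parametrize(
    "r1, r2, scheme, expected",
    [
        (0.95, 0.95, "robust", "robust"),
        (0.95, 0.95, "robust_strict", "none"),   # not strictly above 0.95
        (0.96, 0.96, "robust_strict", "robust"),
        (0.96, 0.05, "specific_0.95_0.1", "env1_specific"),
        (0.05, 0.96, "specific_0.95_0.1", "env2_specific"),
        (0.96, 0.65, "specific_0.95_0.7", "env1_specific"),
        (0.3, 0.3, "robust", "none"),
        (0.3, 0.3, "specific_0.95_0.7", "none"),
        (0.3, 0.3, "responsive", "none"),
        (0.71, 0.49, "responsive", "responsive"),
        (0.71, 0.51, "responsive", "none"),
        (-0.71, 0.49, "responsive", "responsive"),  # |rho| convention
    ],
)
def test_classification_schemes(r1, r2, scheme, expected):
    out = classify_pairs(_pair_table(rho_env1=r1, rho_env2=r2), scheme)
    assert out.loc[0, "category"] == expected


def test_significance_gate_blocks_classification():
    t = _pair_table(rho_env1=0.95, rho_env2=0.95, p_env1=0.5)
    assert classify_pairs(t, "robust").loc[0, "category"] == "none"


def test_unknown_scheme_is_a_configuration_error():
    with pytest.raises(ConfigurationError):
        classify_pairs(_pair_table(), "no_such_scheme")


def test_scheme_nestedness_strict_robust_subset_of_robust():
    rng = np.random.default_rng(1)
    n = 500
    t = pd.DataFrame({
        "lncRNA_id": [f"l{i}" for i in range(n)],
        "mRNA_id": [f"m{i}" for i in range(n)],
        "rho_env1": rng.uniform(-1, 1, n),
        "rho_env2": rng.uniform(-1, 1, n),
        "p_env1": rng.uniform(0, 0.002, n),
        "p_env2": rng.uniform(0, 0.002, n),
    })
    strict = classify_pairs(t, "robust_strict")["category"] == "robust"
    loose = classify_pairs(t, "robust")["category"] == "robust"
    assert (loose[strict]).all()


def test_spearman_pairs_computes_both_envs_and_gates_on_ed():
    rng = np.random.default_rng(2)
    n = 12
    shared = rng.lognormal(0, 1, 2 * n)
    lnc = shared * rng.lognormal(0, 0.05, 2 * n)
    mrna = shared * rng.lognormal(0, 0.05, 2 * n)
    flat = np.full(2 * n, 5.0)  # E_d ~ 0 -> gated out
    m = toy_matrix([lnc, mrna, flat], ["lncRNA", "mRNA", "mRNA"],
                   ["e1"] * n + ["e2"] * n)
    stats = population_stats(m)
    table = spearman_pairs(m, stats, ed_threshold=0.6)
    assert set(zip(table["lncRNA_id"], table["mRNA_id"])) == {("f0", "f1")}
    row = table.iloc[0]
    e1 = m.individuals_in("e1")
    assert row["rho_env1"] == pytest.approx(
        rank_pearson_oracle(m.values.loc["f0", e1], m.values.loc["f1", e1]),
        abs=1e-12)
    assert row["p_env1"] < 0.001


def test_spearman_pairs_zero_variance_reported_missing():
    n = 10
    rng = np.random.default_rng(3)
    lnc = np.full(2 * n, 7.0)
    lnc[0] = 7.0  # constant in both envs
    mrna = rng.lognormal(0, 1, 2 * n)
    m = toy_matrix([lnc, mrna], ["lncRNA", "mRNA"], ["e1"] * n + ["e2"] * n)
    stats = population_stats(m)
    table = spearman_pairs(m, stats, ed_threshold=-1.0)
    assert np.isnan(table.loc[0, "rho_env1"])


def test_responsive_network_threshold_boundaries():
    ratios = pd.DataFrame({"feature_id": ["l1", "m1"],
                           "class": ["lncRNA", "mRNA"],
                           "e_d_ratio": [2.0, 2.0]})
    inc = _pair_table(rho_env1=0.71, rho_env2=0.49)
    exc = _pair_table(rho_env1=0.71, rho_env2=0.51)
    assert len(responsive_network(inc, ratios)) == 1
    assert len(responsive_network(exc, ratios)) == 0
    # the diversity-ratio gate excludes pairs with low-ratio endpoints
    low = ratios.assign(e_d_ratio=[1.2, 2.0])
    assert len(responsive_network(inc, low)) == 0


def test_responsive_network_recovers_planted_env2_module(small_dataset):
    matrix, truth = small_dataset
    stats = population_stats(matrix)
    table = spearman_pairs(matrix, stats)
    edges = responsive_network(table, ratio_stats(stats))
    got = set(zip(edges["lncRNA_id"], edges["mRNA_id"]))
    true_any = truth.module_pairs("env1") | truth.module_pairs("env2")
    if got:
        precision = len(got & true_any) / len(got)
        assert precision >= 0.8
    true_env2 = truth.module_pairs("env2")
    assert len(got & true_env2) / len(true_env2) > 0


def test_subnetworks_star_hub_retained_with_its_edges():
    edges = pd.DataFrame({
        "lncRNA_id": ["hub"] * 12,
        "mRNA_id": [f"m{i}" for i in range(12)],
    })
    subs, summary = subnetworks_by_degree(edges, min_degree=10)
    assert len(subs) == 1
    assert len(subs[0]) == 12
    assert summary["max_degree_lncRNA"] == 12
    assert summary["n_mRNA"] == 12


def test_subnetworks_empty_when_min_degree_exceeds_max():
    edges = pd.DataFrame({"lncRNA_id": ["a", "a"], "mRNA_id": ["x", "y"]})
    subs, _ = subnetworks_by_degree(edges, min_degree=5)
    assert subs == []


def test_subnetworks_rejects_empty_edge_list():
    with pytest.raises(InputError):
        subnetworks_by_degree(pd.DataFrame(columns=["lncRNA_id", "mRNA_id"]))


def test_degrees_match_bruteforce_count():
    rng = np.random.default_rng(5)
    edges = pd.DataFrame({
        "lncRNA_id": rng.choice([f"l{i}" for i in range(8)], 60),
        "mRNA_id": rng.choice([f"m{i}" for i in range(10)], 60),
    }).drop_duplicates()
    summary = network_summary(edges)
    counts = {}
    for l, m in edges.itertuples(index=False):
        counts[l] = counts.get(l, 0) + 1
        counts[m] = counts.get(m, 0) + 1
    assert summary["max_degree_lncRNA"] == max(
        v for k, v in counts.items() if k.startswith("l"))
    assert summary["max_degree_mRNA"] == max(
        v for k, v in counts.items() if k.startswith("m"))
    assert summary["n_edges"] == len(edges)
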