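"""Environment-wise lncRNA-mRNA co-expression networks.

All (lncRNA, mRNA) pairs among features passing an expression-diversity
gate (E_d > 0.6 in at least one environment) get a Spearman rank
correlation per environment.  Pairs are then classified with named
threshold schemes:

* ``robust``            — R > 0.9 in both environments
* ``robust_strict``     — R > 0.95 in both environments
* ``specific_0.95_0.7`` — R > 0.95 in one environment, < 0.7 in the other
* ``specific_0.95_0.1`` — R > 0.95 in one environment, < 0.1 in the other
* ``responsive``        — |R| > 0.7 in exactly one environment and
  |R| < 0.5 in the other (signed R for the first four schemes, |R| for
  this one; both conventions are switchable)

A significance gate (p < 0.001 by default) is applied before
classification.  The environment-responsive network additionally
restricts features to those whose E_d ratio (env2/env1) exceeds a
threshold, targeting features whose population diversity grew in the
stress environment.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats as sps

from .errors import ConfigurationError, InputError
from .matrix import ExpressionMatrix, LNCRNA, MRNA

__all__ = [
    "spearman_rho",
    "spearman_pairs",
    "classify_pairs",
    "table2_scheme_counts",
    "responsive_network",
    "subnetworks_by_degree",
    "network_summary",
    "SCHEMES",
]


# -- Spearman engine --------------------------------------------------------

def _rank_rows(a: np.ndarray) -> np.ndarray:
    """Average ranks along the last axis (ties get the mean rank)."""
    return sps.rankdata(a, axis=-1)


def _standardize_rows(r: np.ndarray) -> np.ndarray:
    """Center/scale rank rows; zero-variance rows become all-NaN."""
    c = r - r.mean(axis=-1, keepdims=True)
    sd = np.sqrt((c ** 2).sum(axis=-1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sd > 0, c / np.where(sd > 0, sd, 1.0), np.nan)
    return out


def spearman_rho(x, y) -> float:
    """Spearman correlation with average ranks on ties (rank-then-Pearson)."""
    rx = _standardize_rows(_rank_rows(np.asarray(x, dtype=float)))
    ry = _standardize_rows(_rank_rows(np.asarray(y, dtype=float)))
    return float((rx * ry).sum())

def _exact_spearman_p(rho_obs: float, n: int) -> float:
    """Two-sided exact p by enumerating all n! rank permutations (n <= 9)."""
    base = np.arange(1, n + 1, dtype=float)
    c = base - base.mean()
    denom = (c ** 2).sum()
    count = 0
    total = 0
    for perm in permutations(range(n)):
        rho = (c[list(perm)] * c).sum() / denom
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the large-sample t approximation."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho ** 2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    return np.where(np.isnan(rho), np.nan, np.clip(p, 0.0, 1.0))


def spearman_pairs(
    matrix: ExpressionMatrix,
    stats: pd.DataFrame,
    ed_threshold: float = 0.6,
) -> pd.DataFrame:
    """Per-environment Spearman rho and p for all gated lncRNA-mRNA pairs.

    Features enter when their E_d exceeds ``ed_threshold`` in at least
    one environment.  Zero-variance features yield NaN coefficients for
    their pairs (reported as missing, never fabricated).  p-values come
    from the t approximation, or exact rank-permutation enumeration when
    an environment has <= 9 individuals and the feature vectors are
    tie-free.

    Returns a DataFrame with ``lncRNA_id``, ``mRNA_id``, ``rho_env1``,
    ``rho_env2``, ``p_env1``, ``p_env2``.
    """
    env1, env2 = matrix.env_names
    for env in (env1, env2):
        if len(matrix.individuals_in(env)) < 4:
            raise ConfigurationError(
                f"environment {env!r} needs >= 4 individuals")
    ed = stats.pivot(index="feature_id", columns="env", values="e_d")
    gate = (ed > ed_threshold).any(axis=1)
    gated = ed.index[gate]
    lnc = [f for f in gated if matrix.feature_class[f] == LNCRNA]
    mrna = [f for f in gated if matrix.feature_class[f] == MRNA]
    if not lnc or not mrna:
        return pd.DataFrame(columns=["lncRNA_id", "mRNA_id", "rho_env1",
                                     "rho_env2", "p_env1", "p_env2"])
    out = {"lncRNA_id": np.repeat(lnc, len(mrna)),
           "mRNA_id": np.tile(mrna, len(lnc))}
    for label, env in (("env1", env1), ("env2", env2)):
        sub = matrix.env_values(env)
        n = sub.shape[1]
        rl = _standardize_rows(_rank_rows(sub.loc[lnc].to_numpy()))
        rm = _standardize_rows(_rank_rows(sub.loc[mrna].to_numpy()))
        rho = rl @ rm.T  # standardized-rank inner products
        rho = np.clip(rho, -1.0, 1.0)
        # restore NaN for zero-variance rows (matmul of NaN rows is NaN already)
        p = _t_approx_p(rho, n)
        if n <= 9:
            ties_l = np.array([len(np.unique(v)) < n
                               for v in sub.loc[lnc].to_numpy()])
            ties_m = np.array([len(np.unique(v)) < n
                               for v in sub.loc[mrna].to_numpy()])
            for i in range(len(lnc)):
                for j in range(len(mrna)):
                    if not (ties_l[i] or ties_m[j]) and np.isfinite(rho[i, j]):
                        p[i, j] = _exact_spearman_p(rho[i, j], n)
        out[f"rho_{label}"] = rho.ravel()
        out[f"p_{label}"] = p.ravel()
    return pd.DataFrame(out)


# -- classification schemes -------------------------------------------------

def _both_above(r1, r2, hi):
    return (r1 > hi) & (r2 > hi)


SCHEMES = {
    # scheme -> (predicate(r1, r2) -> (env1_specific?, env2_specific?, both?), signed?)
    "robust": dict(kind="both", hi=0.9, signed=True),
    "robust_strict": dict(kind="both", hi=0.95, signed=True),
    "specific_0.95_0.7": dict(kind="split", hi=0.95, lo=0.7, signed=True),
    "specific_0.95_0.1": dict(kind="split", hi=0.95, lo=0.1, signed=True),
    "responsive": dict(kind="split", hi=0.7, lo=0.5, signed=False),
}


def classify_pairs(
    table: pd.DataFrame,
    scheme: str,
    p_max: float = 0.001,
    signed: bool | None = None,
) -> pd.DataFrame:
    """Attach a category to every pair under one named threshold scheme.

    Categories are ``robust`` (high in both environments),
    ``env1_specific`` / ``env2_specific`` (high in one, low in the
    other), ``responsive`` (the |rho| 0.7/0.5 rule) or ``none``.  Pairs
    failing the significance gate (p <= ``p_max`` required in every
    environment where the scheme demands a high coefficient) are
    ``none``.  ``signed`` overrides the scheme's default convention
    (signed rho for the threshold-table schemes, |rho| for
    ``responsive``).
    """
    if scheme not in SCHEMES:
        raise ConfigurationError(
            f"unknown scheme {scheme!r}; have {sorted(SCHEMES)}")
    spec = SCHEMES[scheme]
    use_signed = spec["signed"] if signed is None else signed
    r1 = table["rho_env1"].to_numpy(dtype=float)
    r2 = table["rho_env2"].to_numpy(dtype=float)
    p1 = table["p_env1"].to_numpy(dtype=float)
    p2 = table["p_env2"].to_numpy(dtype=float)
    v1 = r1 if use_signed else np.abs(r1)
    v2 = r2 if use_signed else np.abs(r2)
    ok1 = p1 <= p_max
    ok2 = p2 <= p_max
    category = np.full(len(table), "none", dtype=object)
    if spec["kind"] == "both":
        hit = _both_above(v1, v2, spec["hi"]) & ok1 & ok2
        category[hit] = "robust"
    else:
        hi, lo = spec["hi"], spec["lo"]
        e1 = (v1 > hi) & (v2 < lo) & ok1
        e2 = (v2 > hi) & (v1 < lo) & ok2
        label1, label2 = ("env1_specific", "env2_specific")
        if scheme == "responsive":
            label1 = label2 = "responsive"
        category[e1] = label1
        category[e2] = label2
    out = table.copy()
    out["category"] = category
    return out


def table2_scheme_counts(table: pd.DataFrame, p_max: float = 0.001) -> pd.DataFrame:
    """Pair/node counts for the six standard threshold predicates.

    One row per predicate: both-high at 0.9 and 0.95, one-high/one-low
    at (0.95, 0.7) and (0.95, 0.1) in each direction; columns report the
    pair count, distinct lncRNA/mRNA counts, and max node degrees.
    """
    rows = []
    defs = [
        ("R1>0.9 & R2>0.9", "robust", ("robust",)),
        ("R1>0.95 & R2>0.95", "robust_strict", ("robust",)),
        ("R1>0.95 & R2<0.7", "specific_0.95_0.7", ("env1_specific",)),
        ("R2>0.95 & R1<0.7", "specific_0.95_0.7", ("env2_specific",)),
        ("R1<0.1 & R2>0.95", "specific_0.95_0.1", ("env2_specific",)),
        ("R2<0.1 & R1>0.95", "specific_0.95_0.1", ("env1_specific",)),
    ]
    for label, scheme, cats in defs:
        cl = classify_pairs(table, scheme, p_max=p_max)
        edges = cl[cl["category"].isin(cats)]
        summ = network_summary(edges)
        rows.append({"predicate": label, **summ})
    return pd.DataFrame(rows)


def responsive_network(
    table: pd.DataFrame,
    ratios: pd.DataFrame,
    ed_ratio_min: float = 1.5,
    rho_high: float = 0.7,
    rho_low: float = 0.5,
    p_max: float = 0.05,
    de_calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Environment-responsive edges among diversity-elevated features.

    Features are first restricted to ``e_d_ratio > ed_ratio_min``
    (diversity grew in environment 2); retained pairs must have
    |rho| > ``rho_high`` in exactly one environment and |rho| <
    ``rho_low`` in the other.  Each edge is annotated with its
    responsive environment and, when DE results are supplied, the DE
    call of both endpoints.
    """
    keep = set(ratios.loc[ratios["e_d_ratio"] > ed_ratio_min, "feature_id"])
    sub = table[table["lncRNA_id"].isin(keep) & table["mRNA_id"].isin(keep)]
    cl = classify_pairs(sub, "responsive", p_max=p_max, signed=False)
    # rebuild with caller thresholds when they differ from the named scheme
    if (rho_high, rho_low) != (0.7, 0.5):
        a1 = np.abs(sub["rho_env1"].to_numpy(dtype=float))
        a2 = np.abs(sub["rho_env2"].to_numpy(dtype=float))
        ok1 = sub["p_env1"].to_numpy(dtype=float) <= p_max
        ok2 = sub["p_env2"].to_numpy(dtype=float) <= p_max
        cat = np.full(len(sub), "none", dtype=object)
        cat[(a1 > rho_high) & (a2 < rho_low) & ok1] = "responsive"
        cat[(a2 > rho_high) & (a1 < rho_low) & ok2] = "responsive"
        cl = sub.copy()
        cl["category"] = cat
    edges = cl[cl["category"] == "responsive"].copy()
    a1 = np.abs(edges["rho_env1"].to_numpy(dtype=float))
    a2 = np.abs(edges["rho_env2"].to_numpy(dtype=float))
    edges["responsive_env"] = np.where(a1 > a2, "env1", "env2")
    if de_calls is not None:
        calls = de_calls.set_index("feature_id")["call"]
        edges["lncRNA_de"] = calls.reindex(edges["lncRNA_id"]).to_numpy()
        edges["mRNA_de"] = calls.reindex(edges["mRNA_id"]).to_numpy()
    return edges.reset_index(drop=True)


def network_summary(edges: pd.DataFrame) -> dict:
    """Edge/node counts and per-class max degrees of a bipartite edge list."""
    if len(edges) == 0:
        return {"n_edges": 0, "n_lncRNA": 0, "n_mRNA": 0,
                "max_degree_lncRNA": 0, "max_degree_mRNA": 0}
    deg_l = edges["lncRNA_id"].value_counts()
    deg_m = edges["mRNA_id"].value_counts()
    return {
        "n_edges": int(len(edges)),
        "n_lncRNA": int(deg_l.size),
        "n_mRNA": int(deg_m.size),
        "max_degree_lncRNA": int(deg_l.max()),
        "max_degree_mRNA": int(deg_m.max()),
    }


def write_graphml(edges: pd.DataFrame, path) -> None:
    """Export a bipartite edge list as GraphML for external viewers."""
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        d = row._asdict()
        l, m = d.pop("lncRNA_id"), d.pop("mRNA_id")
        g.add_node(l, kind="lncRNA")
        g.add_node(m, kind="mRNA")
        g.add_edge(l, m, **{k: v for k, v in d.items()
                            if np.isscalar(v) and not pd.isna(v)})
    nx.write_graphml(g, path)


def subnetworks_by_degree(
    edges: pd.DataFrame, min_degree: int = 10
) -> tuple[list[pd.DataFrame], dict]:
    """Hub sub-networks: edges incident to a node with degree > min_degree.

    Degree is counted on the bipartite edge list.  The filtered graph's
    connected components are returned largest-first, each as an edge
    DataFrame; the summary describes the full input network.
    """
    if len(edges) == 0:
        raise InputError("edge list is empty")
    g = nx.Graph()
    for l, m in edges[["lncRNA_id", "mRNA_id"]].itertuples(index=False):
        g.add_edge(("lncRNA", l), ("mRNA", m))
    hubs = {n for n in g.nodes if g.degree[n] > min_degree}
    kept = [(u, v) for u, v in g.edges if u in hubs or v in hubs]
    sub = nx.Graph(kept)
    comps = sorted(nx.connected_components(sub), key=len, reverse=True)
    out = []
    for comp in comps:
        mask = edges.apply(
            lambda row: ("lncRNA", row["lncRNA_id"]) in comp
            and ("mRNA", row["mRNA_id"]) in comp, axis=1)
        out.append(edges[mask].reset_index(drop=True))
    return out, network_summary(edges)
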