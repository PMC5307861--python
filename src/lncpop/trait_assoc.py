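"""Trait association via all-combinations ratio matrices and a Mantel test.

For each gene, an (n_env2 x n_env1) ratio matrix is built: entry (i, j)
is the gene's FPKM in environment-2 individual i divided by its FPKM in
environment-1 individual j (all combinations).  The same construction
applied to a per-individual trait (water use efficiency in the
motivating study) yields a trait ratio matrix.  Association is the
Spearman correlation between the two flattened matrices (row-major),
with significance from a permutation null that shuffles the
environment-2 individual labels (rows) of the gene matrix — breaking the
gene-trait linkage while preserving each matrix's marginal structure.
The permutation p-value uses the add-one estimator
``(1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1)`` and is two-sided on
|rho|.  Genes with ``p < 0.01`` are trait candidates; the trait network
then links lncRNAs to candidate genes by pooled-individual Spearman
correlation and keeps hub lncRNAs with degree above a cutoff.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, InputError
from .matrix import ExpressionMatrix, LNCRNA, MRNA
from .networks import _rank_rows, _standardize_rows, network_summary

__all__ = [
    "ratio_matrix",
    "mantel_spearman",
    "mantel_screen",
    "wue_lmn",
]


def ratio_matrix(values_env2, values_env1, pseudo: float = 0.01) -> np.ndarray:
    """All-combinations ratio matrix: entry (i, j) = (v2_i + pseudo) / (v1_j + pseudo)."""
    v2 = np.asarray(values_env2, dtype=float)
    v1 = np.asarray(values_env1, dtype=float)
    if v1.size == 0 or v2.size == 0:
        raise InputError("ratio_matrix needs non-empty vectors")
    if pseudo < 0:
        raise ConfigurationError(f"pseudo must be >= 0, got {pseudo}")
    if pseudo == 0 and np.all(v1 == 0):
        raise InputError("denominator vector is all zero and pseudo is 0")
    den = v1 + pseudo
    if np.any(den == 0):
        raise InputError("zero denominator entry; use a positive pseudo")
    return (v2[:, None] + pseudo) / den[None, :]


def mantel_spearman(
    gene_matrix: np.ndarray,
    trait_matrix: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.01,
) -> dict:
    """Mantel test of one gene ratio matrix against the trait ratio matrix.

    Returns ``{"rho", "p_perm", "n_permutations", "candidate"}``.  The
    null permutes the rows (environment-2 individuals) of the gene
    matrix; the observed and permuted statistics are Spearman
    correlations of the row-major flattened entries, compared on |rho|.
    """
    g = np.asarray(gene_matrix, dtype=float)
    t = np.asarray(trait_matrix, dtype=float)
    if g.shape != t.shape:
        raise InputError(f"matrix shapes differ: {g.shape} vs {t.shape}")
    if n_perm < 1:
        raise ConfigurationError(f"n_perm must be >= 1, got {n_perm}")
    rng = np.random.default_rng(seed)
    t_std = _standardize_rows(_rank_rows(t.ravel()))
    # ranks of the gene entries are permutation-equivariant under row
    # shuffles (same multiset of values), so rank once and re-index
    g_ranks = _standardize_rows(_rank_rows(g.ravel())).reshape(g.shape)
    rho_obs = float(g_ranks.ravel() @ t_std)
    n_rows = g.shape[0]
    perms = np.array([rng.permutation(n_rows) for _ in range(n_perm)])
    permuted = g_ranks[perms].reshape(n_perm, -1)  # (n_perm, n_entries)
    rho_perm = permuted @ t_std
    k = int((np.abs(rho_perm) >= abs(rho_obs) - 1e-12).sum())
    p = (1 + k) / (n_perm + 1)
    return {
        "rho": rho_obs,
        "p_perm": p,
        "n_permutations": n_perm,
        "candidate": bool(p < alpha),
    }


def mantel_screen(
    matrix: ExpressionMatrix,
    trait: pd.Series,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.01,
    pseudo: float = 0.01,
    feature_ids=None,
) -> pd.DataFrame:
    """Mantel screen of every eligible mRNA against the trait.

    Eligibility: median FPKM over all individuals strictly positive
    (genes that are mostly silent produce degenerate ratio matrices).
    The per-gene permutation stream is derived deterministically from
    ``seed`` and the gene's position so results are order-independent
    and reproducible.  Returns ``gene_id``, ``rho``, ``p_perm``,
    ``n_permutations``, ``candidate``.
    """
    missing = trait.index.difference(matrix.values.columns)
    if len(missing) or len(trait) != matrix.n_individuals:
        raise InputError("trait vector must cover exactly the matrix individuals")
    env1, env2 = matrix.env_names
    id1 = matrix.individuals_in(env1)
    id2 = matrix.individuals_in(env2)
    t_mat = ratio_matrix(trait.loc[id2].to_numpy(),
                         trait.loc[id1].to_numpy(), pseudo=0.0)
    if feature_ids is None:
        feature_ids = matrix.features_of_class(MRNA)
    sub = matrix.values.loc[feature_ids]
    eligible = sub.median(axis=1) > 0
    ids = sub.index[eligible]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(ids))
    rows = []
    for gene, child in zip(ids, children):
        g_mat = ratio_matrix(matrix.values.loc[gene, id2].to_numpy(),
                             matrix.values.loc[gene, id1].to_numpy(),
                             pseudo=pseudo)
        res = mantel_spearman(
            g_mat, t_mat, n_perm=n_perm,
            seed=np.random.default_rng(child).integers(2**31),
            alpha=alpha)
        rows.append({"gene_id": gene, **res})
    out = pd.DataFrame(rows, columns=["gene_id", "rho", "p_perm",
                                      "n_permutations", "candidate"])
    return out


def wue_lmn(
    candidates: pd.DataFrame,
    matrix: ExpressionMatrix,
    rho_min: float = 0.7,
    min_degree: int = 5,
    de_calls: pd.DataFrame | None = None,
    env: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Trait-lncRNA-mRNA network: lncRNAs linked to trait-candidate genes.

    Edges are (lncRNA, candidate gene) pairs with |Spearman| >=
    ``rho_min`` across all individuals pooled (the default, matching the
    network's cross-environment purpose) or within one environment when
    ``env`` is given; the hub table keeps lncRNAs whose degree is
    strictly greater than ``min_degree``, annotated with their DE
    direction when DE results are supplied.

    Returns ``(edges, hubs, summary)``.
    """
    cand = candidates.loc[candidates["candidate"], "gene_id"].tolist()
    if not cand:
        raise InputError("candidate gene set is empty")
    vals = matrix.values if env is None else matrix.env_values(env)
    lnc = list(matrix.features_of_class(LNCRNA))
    if not lnc:
        return (pd.DataFrame(columns=["lncRNA_id", "mRNA_id", "rho"]),
                pd.DataFrame(columns=["lncRNA_id", "degree", "de_call"]),
                network_summary(pd.DataFrame(columns=["lncRNA_id", "mRNA_id"])))
    rl = _standardize_rows(_rank_rows(vals.loc[lnc].to_numpy()))
    rc = _standardize_rows(_rank_rows(vals.loc[cand].to_numpy()))
    rho = np.clip(rl @ rc.T, -1.0, 1.0)
    li, ci = np.nonzero(np.abs(rho) >= rho_min)
    edges = pd.DataFrame({
        "lncRNA_id": np.array(lnc, dtype=object)[li],
        "mRNA_id": np.array(cand, dtype=object)[ci],
        "rho": rho[li, ci],
    })
    deg = edges["lncRNA_id"].value_counts()
    hub_ids = deg.index[deg > min_degree]
    hubs = pd.DataFrame({"lncRNA_id": hub_ids,
                         "degree": deg.loc[hub_ids].to_numpy()})
    if de_calls is not None:
        calls = de_calls.set_index("feature_id")["call"]
        hubs["de_call"] = calls.reindex(hubs["lncRNA_id"]).to_numpy()
    else:
        hubs["de_call"] = pd.NA
    return edges.reset_index(drop=True), hubs.reset_index(drop=True), \
        network_summary(edges)
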