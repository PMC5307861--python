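"""Between-environment differential expression and diversity-change calls.

Per feature the two environments are compared with a two-sample test
chosen by a per-group Shapiro-Wilk normality check (t-test when both
groups look normal at alpha 0.05, Wilcoxon rank-sum otherwise),
p-values are adjusted by Benjamini-Hochberg within each feature class,
and a feature is called differentially expressed when its FDR is below
``alpha_fdr`` (default 0.01) AND its population-mean fold change
|E_p(env2)/E_p(env1)| passes ``min_fold`` (default 2) in either
direction.  A separate rule flags "diversity responsive" features whose
E_d ratio changes more than ``min_ed_fold``-fold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InputError, InsufficientDataError
from .matrix import ExpressionMatrix
from .popstats import population_stats, ratio_stats

__all__ = [
    "choose_test",
    "two_sample_test",
    "benjamini_hochberg",
    "differential_expression",
    "diversity_responsive",
]

_SHAPIRO_ALPHA = 0.05


def choose_test(values_env1, values_env2) -> str:
    """Pick ``"t"`` or ``"wilcoxon"`` by per-group Shapiro-Wilk normality.

    Returns ``"t"`` only when both groups pass the Shapiro-Wilk check at
    alpha 0.05; degenerate (constant) groups always fall through to the
    rank test.
    """
    a = np.asarray(values_env1, dtype=float)
    b = np.asarray(values_env2, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError(
            f"choose_test needs >= 3 per group, got {a.size} and {b.size}")
    for grp in (a, b):
        if np.ptp(grp) == 0:  # Shapiro undefined on constant data
            return "wilcoxon"
        if sps.shapiro(grp).pvalue < _SHAPIRO_ALPHA:
            return "wilcoxon"
    return "t"


def two_sample_test(values_env1, values_env2,
                    force: str | None = None) -> tuple[str, float, float]:
    """(test name, statistic, two-sided p) for one feature.

    ``force`` overrides the adaptive normality-based choice with ``"t"``
    or ``"wilcoxon"``.  Zero-variance identical groups are untestable:
    the statistic is NaN and p is reported as 1 (the conservative
    contract).
    """
    a = np.asarray(values_env1, dtype=float)
    b = np.asarray(values_env2, dtype=float)
    if force is not None and force not in ("t", "wilcoxon"):
        raise ConfigurationError(f"force must be 't' or 'wilcoxon', got {force!r}")
    test = force if force is not None else choose_test(a, b)
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return "wilcoxon", float("nan"), 1.0
    if test == "t":
        res = sps.ttest_ind(a, b, equal_var=False)
        return "t", float(res.statistic), float(res.pvalue)
    try:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
    except ValueError:
        return "wilcoxon", float("nan"), 1.0
    return "wilcoxon", float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (monotone, >= raw p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    matrix: ExpressionMatrix,
    alpha_fdr: float = 0.01,
    min_fold: float = 2.0,
    pseudo: float = 0.01,
    pool_classes: bool = False,
    stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Call up/down/none per feature with the FDR + fold-change rule.

    FDR is adjusted within lncRNAs and within mRNAs separately by
    default (``pool_classes=True`` adjusts jointly).  Returns one row
    per feature: ``feature_id``, ``class``, ``test``, ``stat``, ``p``,
    ``fdr``, ``e_p_ratio``, ``log2_ratio``, ``call``.
    """
    if not 0 < alpha_fdr <= 1:
        raise ConfigurationError(f"alpha_fdr must be in (0,1], got {alpha_fdr}")
    if min_fold < 1:
        raise ConfigurationError(f"min_fold must be >= 1, got {min_fold}")
    env1, env2 = matrix.env_names
    sub1 = matrix.env_values(env1).to_numpy()
    sub2 = matrix.env_values(env2).to_numpy()
    if sub1.shape[1] < 3 or sub2.shape[1] < 3:
        raise InsufficientDataError("each environment needs >= 3 individuals")

    tests, stats_out, pvals = [], [], []
    for f in range(matrix.n_features):
        name, stat, p = two_sample_test(sub1[f], sub2[f])
        tests.append(name)
        stats_out.append(stat)
        pvals.append(p)
    pvals = np.array(pvals)

    if stats is None:
        stats = population_stats(matrix)
    ratios = ratio_stats(stats, pseudo=pseudo).set_index("feature_id")
    ratios = ratios.loc[matrix.feature_ids]

    classes = matrix.feature_class.to_numpy()
    fdr = np.empty_like(pvals)
    if pool_classes:
        fdr[:] = benjamini_hochberg(pvals)
    else:
        for cls in np.unique(classes):
            mask = classes == cls
            fdr[mask] = benjamini_hochberg(pvals[mask])

    e_p_ratio = ratios["e_p_ratio"].to_numpy()
    sig = fdr < alpha_fdr
    call = np.full(matrix.n_features, "none", dtype=object)
    call[sig & (e_p_ratio >= min_fold)] = "up"
    call[sig & (e_p_ratio <= 1.0 / min_fold)] = "down"

    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "class": classes,
            "test": tests,
            "stat": stats_out,
            "p": pvals,
            "fdr": fdr,
            "e_p_ratio": e_p_ratio,
            "log2_ratio": ratios["log2_e_p_ratio"].to_numpy(),
            "call": call,
        }
    ).reset_index(drop=True)


def diversity_responsive(
    ratios: pd.DataFrame,
    min_ed_fold: float = 2.0,
    two_sided: bool = True,
) -> tuple[pd.Index, dict]:
    """Features whose expression diversity changed more than
    ``min_ed_fold``-fold between environments (strict inequality).

    ``two_sided=True`` (default) counts both increases
    (``e_d_ratio > min_ed_fold``) and decreases
    (``e_d_ratio < 1/min_ed_fold``).  Features with an undefined E_d
    ratio are excluded and tallied in the returned exclusion report.
    """
    if min_ed_fold <= 1:
        raise ConfigurationError(f"min_ed_fold must be > 1, got {min_ed_fold}")
    r = ratios.set_index("feature_id")["e_d_ratio"]
    defined = r.notna()
    flag = r > min_ed_fold
    if two_sided:
        flag |= r < 1.0 / min_ed_fold
    flag &= defined
    report = {
        "n_features": int(len(r)),
        "n_undefined_excluded": int((~defined).sum()),
        "n_flagged": int(flag.sum()),
        "two_sided": two_sided,
        "min_ed_fold": min_ed_fold,
    }
    return r.index[flag], report
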