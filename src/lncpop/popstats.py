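r"""Population expression statistics per feature and environment.

Three per-feature, per-environment quantities drive the whole analysis:

* the population expression level, the arithmetic mean over individuals

  .. math:: E_p = \frac{\sum_{i=1}^n E_i}{n}

* the expression diversity, a scale-invariant dispersion measure built
  from the mean absolute deviation and normalised by the level

  .. math:: E_d = \frac{\sum_{i=1}^n |E_i - E_p|}{(n-1)\,E_p}

* the expression frequency, the fraction of individuals in which the
  feature is detected (FPKM strictly above a detection threshold,
  0 by default).

``E_i`` is the FPKM of individual ``i``.  Between-environment contrasts
use the env2/env1 ratios of :math:`E_p` and :math:`E_d` and the
difference of frequencies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError
from .matrix import ExpressionMatrix

__all__ = [
    "expression_level",
    "expression_diversity",
    "expression_frequency",
    "population_stats",
    "population_frequency_filter",
    "ratio_stats",
]


def _as_vector(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    return arr


def expression_level(values) -> float:
    """Population expression level E_p: the mean FPKM over individuals."""
    arr = _as_vector(values)
    if arr.size == 0:
        raise InsufficientDataError("expression_level needs at least 1 value")
    return float(arr.mean())


def expression_diversity(values) -> float:
    """Expression diversity E_d = sum |E_i - E_p| / ((n-1) * E_p).

    Returns ``nan`` (the explicit undefined marker) when E_p is 0, since
    the statistic divides by the level.  Scale-invariant: E_d(c*x) = E_d(x)
    for any c > 0.
    """
    arr = _as_vector(values)
    if arr.size < 2:
        raise InsufficientDataError("expression_diversity needs n >= 2 values")
    e_p = arr.mean()
    if e_p == 0:
        return float("nan")
    return float(np.abs(arr - e_p).sum() / ((arr.size - 1) * e_p))


def expression_frequency(values, detect_threshold: float = 0.0) -> tuple[float, int]:
    """Fraction and count of individuals with FPKM strictly above threshold."""
    if detect_threshold < 0:
        raise ConfigurationError(
            f"detect_threshold must be >= 0, got {detect_threshold}"
        )
    arr = _as_vector(values)
    if arr.size == 0:
        raise InsufficientDataError("expression_frequency needs at least 1 value")
    n_expressed = int((arr > detect_threshold).sum())
    return n_expressed / arr.size, n_expressed


def population_stats(
    matrix: ExpressionMatrix, detect_threshold: float = 0.0
) -> pd.DataFrame:
    """Per-(feature, environment) table of E_p, E_d, frequency and counts.

    Returns a tidy DataFrame with columns ``feature_id``, ``class``,
    ``env``, ``e_p``, ``e_d``, ``freq``, ``n_expressed``, ``n``.  E_d is
    ``NaN`` where undefined (all-zero feature in that environment).
    """
    if detect_threshold < 0:
        raise ConfigurationError(
            f"detect_threshold must be >= 0, got {detect_threshold}"
        )
    frames = []
    for env in matrix.env_names:
        sub = matrix.env_values(env).to_numpy()
        n = sub.shape[1]
        if n < 2:
            raise InsufficientDataError(
                f"environment {env!r} has {n} individual(s); need >= 2"
            )
        e_p = sub.mean(axis=1)
        abs_dev = np.abs(sub - e_p[:, None]).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            e_d = np.where(e_p > 0, abs_dev / ((n - 1) * np.maximum(e_p, 1e-300)), np.nan)
        n_expressed = (sub > detect_threshold).sum(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": matrix.feature_ids,
                    "class": matrix.feature_class.to_numpy(),
                    "env": env,
                    "e_p": e_p,
                    "e_d": e_d,
                    "freq": n_expressed / n,
                    "n_expressed": n_expressed,
                    "n": n,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def population_frequency_filter(
    matrix: ExpressionMatrix,
    min_individuals: int = 20,
    detect_threshold: float = 0.0,
    per_environment: bool = False,
) -> pd.Index:
    """Features expressed in at least ``min_individuals`` individuals.

    Both environments are pooled by default (the population-level rule
    "discard candidates expressed in fewer than 20 of the 80
    individuals"); ``per_environment=True`` requires the count within
    each environment instead.
    """
    if min_individuals > matrix.n_individuals:
        raise ConfigurationError(
            f"min_individuals={min_individuals} exceeds the "
            f"{matrix.n_individuals} individuals present"
        )
    if per_environment:
        keep = np.ones(matrix.n_features, dtype=bool)
        for env in matrix.env_names:
            sub = matrix.env_values(env).to_numpy()
            keep &= (sub > detect_threshold).sum(axis=1) >= min_individuals
    else:
        arr = matrix.values.to_numpy()
        keep = (arr > detect_threshold).sum(axis=1) >= min_individuals
    return matrix.feature_ids[keep]


def ratio_stats(stats: pd.DataFrame, pseudo: float = 0.01) -> pd.DataFrame:
    """Between-environment ratio statistics, oriented env2/env1.

    ``e_p_ratio = E_p(env2) / E_p(env1)``, with the pseudocount added to
    both numerator and denominator only when either level is zero (exact
    ratios are preserved whenever they are well defined).  ``e_d_ratio``
    uses no pseudocount and is ``NaN`` when either E_d is undefined or
    zero.  ``freq_difference = freq(env2) - freq(env1)``.

    Parameters
    ----------
    stats
        The tidy table from :func:`population_stats`; must contain
        exactly two environments per feature.
    pseudo
        Additive FPKM pseudocount for zero-level ratios (>= 0).
    """
    if pseudo < 0:
        raise ConfigurationError(f"pseudo must be >= 0, got {pseudo}")
    envs = list(dict.fromkeys(stats["env"]))
    if len(envs) != 2:
        raise ConfigurationError(f"need exactly 2 environments, got {envs}")
    env1, env2 = envs
    wide = stats.pivot(index="feature_id", columns="env",
                       values=["e_p", "e_d", "freq"])
    classes = stats.drop_duplicates("feature_id").set_index("feature_id")["class"]
    ep1 = wide[("e_p", env1)].to_numpy()
    ep2 = wide[("e_p", env2)].to_numpy()
    ed1 = wide[("e_d", env1)].to_numpy()
    ed2 = wide[("e_d", env2)].to_numpy()

    zero = (ep1 == 0) | (ep2 == 0)
    num = np.where(zero, ep2 + pseudo, ep2)
    den = np.where(zero, ep1 + pseudo, ep1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e_p_ratio = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
        log2_e_p_ratio = np.where(e_p_ratio > 0, np.log2(np.maximum(e_p_ratio, 1e-300)), np.nan)
        bad_ed = np.isnan(ed1) | np.isnan(ed2) | (ed1 == 0) | (ed2 == 0)
        e_d_ratio = np.where(bad_ed, np.nan, ed2 / np.where(bad_ed, 1.0, np.maximum(ed1, 1e-300)))
        log2_e_d_ratio = np.where(np.isnan(e_d_ratio), np.nan,
                                  np.log2(np.where(np.isnan(e_d_ratio), 1.0, np.maximum(e_d_ratio, 1e-300))))
    out = pd.DataFrame(
        {
            "feature_id": wide.index,
            "class": classes.loc[wide.index].to_numpy(),
            "e_p_ratio": e_p_ratio,
            "log2_e_p_ratio": log2_e_p_ratio,
            "e_d_ratio": e_d_ratio,
            "log2_e_d_ratio": log2_e_d_ratio,
            "freq_difference": (wide[("freq", env2)] - wide[("freq", env1)]).to_numpy(),
        }
    )
    return out.reset_index(drop=True)
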