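"""The FPKM expression matrix and its sample/feature annotations.

The whole pipeline operates on one in-memory container: a feature x
individual matrix of non-negative FPKM values, a feature -> class map
(``lncRNA`` / ``mRNA``) and an individual -> environment map with exactly
two environments (in the motivating field experiment these are the
near-native site JH and the transplanted stress site QG).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

LNCRNA = "lncRNA"
MRNA = "mRNA"
FEATURE_CLASSES = (LNCRNA, MRNA)


@dataclass
class ExpressionMatrix:
    """FPKM values for features (rows) x individuals (columns).

    Parameters
    ----------
    values
        Non-negative FPKM values, features as the index, individuals as
        columns.
    feature_class
        Series mapping every feature id to ``"lncRNA"`` or ``"mRNA"``.
    environment
        Series mapping every individual id to one of exactly two
        environment labels.
    """

    values: pd.DataFrame
    feature_class: pd.Series
    environment: pd.Series
    env_names: tuple[str, str] = field(init=False)

    def __post_init__(self) -> None:
        vals = self.values
        if vals.index.has_duplicates:
            dup = vals.index[vals.index.duplicated()][0]
            raise InputError(f"duplicate feature id: {dup!r}")
        if vals.columns.has_duplicates:
            dup = vals.columns[vals.columns.duplicated()][0]
            raise InputError(f"duplicate individual id: {dup!r}")
        arr = vals.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise InputError("expression values must be numeric")
        if np.isnan(arr).any():
            raise InputError("expression values must not be missing")
        if (arr < 0).any():
            f, i = np.argwhere(arr < 0)[0]
            raise InputError(
                f"negative FPKM for feature {vals.index[f]!r}, "
                f"individual {vals.columns[i]!r}"
            )
        missing = vals.index.difference(self.feature_class.index)
        if len(missing):
            raise InputError(f"feature without class annotation: {missing[0]!r}")
        bad = set(self.feature_class.loc[vals.index]) - set(FEATURE_CLASSES)
        if bad:
            raise InputError(f"unknown feature class: {sorted(bad)[0]!r}")
        unmapped = vals.columns.difference(self.environment.index)
        if len(unmapped):
            raise InputError(f"individual not in sample table: {unmapped[0]!r}")
        envs = pd.unique(self.environment.loc[vals.columns])
        if len(envs) != 2:
            raise InputError(
                f"expected exactly 2 environments, found {len(envs)}: {list(envs)}"
            )
        # align annotation order with the matrix; environment order follows
        # first appearance in the sample table so env1/env2 is stable
        self.feature_class = self.feature_class.loc[vals.index]
        self.environment = self.environment.loc[vals.columns]
        self.env_names = (str(envs[0]), str(envs[1]))

    # -- convenience accessors -------------------------------------------

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    def individuals_in(self, env: str) -> pd.Index:
        """Individual ids assigned to environment ``env``."""
        if env not in self.env_names:
            raise InputError(f"unknown environment {env!r}; have {self.env_names}")
        return self.environment.index[self.environment == env]

    def env_values(self, env: str) -> pd.DataFrame:
        """Sub-matrix restricted to one environment's individuals."""
        return self.values.loc[:, self.individuals_in(env)]

    def features_of_class(self, cls: str) -> pd.Index:
        if cls not in FEATURE_CLASSES:
            raise InputError(f"unknown feature class {cls!r}")
        return self.feature_class.index[self.feature_class == cls]

    def subset_features(self, ids) -> "ExpressionMatrix":
        """New matrix restricted to the given feature ids (order preserved)."""
        ids = pd.Index(ids)
        missing = ids.difference(self.values.index)
        if len(missing):
            raise InputError(f"unknown feature id: {missing[0]!r}")
        return ExpressionMatrix(
            values=self.values.loc[ids],
            feature_class=self.feature_class.loc[ids],
            environment=self.environment.copy(),
        )
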