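"""Covariate encoding: standardized continuous columns, one-hot categoricals.

Builds the numeric design matrix fed to the propensity and survival networks:
continuous covariates are z-scored (population standard deviation), categorical
covariates are one-hot encoded against a reference level (the most frequent
level in the fitting data), and binary condition indicators pass through as 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DesignMatrix", "CovariateEncoder", "CONDITION_COLUMNS"]

#: the 20 comorbid-condition indicator columns of the analysis cohort
CONDITION_COLUMNS = [
    "chf", "arrhythmia", "valvular", "coronary", "diabetes", "hypertension",
    "copd", "lower_extremity_vascular", "renal_atherosclerosis",
    "vascular_intestine", "renal_failure", "other_renal", "kidney_transplant",
    "liver", "cerebrovascular", "other_neuro", "hyperlipidemia", "cancer",
    "rheumatoid", "prior_aaa",
]


@dataclass
class DesignMatrix:
    """Encoded numeric covariate matrix with its column provenance.

    Attributes
    ----------
    X : (n, p) float array
    columns : encoded column names (e.g. ``age``, ``race=black``)
    column_map : encoded column -> (source covariate, level or None)
    standardization : continuous column -> (mean, sd) used for z-scoring
    degenerate : encoded columns with zero variance in the fitting data
    """

    X: np.ndarray
    columns: list
    column_map: dict
    standardization: dict = field(default_factory=dict)
    degenerate: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def with_rows(self, idx: np.ndarray) -> "DesignMatrix":
        return DesignMatrix(self.X[idx], self.columns, self.column_map,
                            self.standardization, self.degenerate)

    def drop_degenerate(self, min_count: int = 1) -> "DesignMatrix":
        """Drop zero-variance encoded columns (needed e.g. for Cox fits).

        ``min_count`` additionally drops binary indicator columns carried by
        fewer than that many subjects in either state; ultra-rare indicators
        make partial-likelihood fits and residual diagnostics unstable.
        """
        sds = self.X.std(axis=0)
        keep = sds > 0.0
        if min_count > 1:
            is_binary = np.all((self.X == 0) | (self.X == 1), axis=0)
            pos = self.X.sum(axis=0)
            rare = is_binary & ((pos < min_count)
                                | (self.X.shape[0] - pos < min_count))
            keep &= ~rare
        cols = [c for c, k in zip(self.columns, keep) if k]
        return DesignMatrix(self.X[:, keep], cols,
                            {c: self.column_map[c] for c in cols},
                            self.standardization,
                            [c for c in self.columns if c not in cols])


class CovariateEncoder:
    """Fit/transform encoder from a cohort table to a :class:`DesignMatrix`.

    Parameters
    ----------
    continuous : continuous covariate columns (z-scored with population sd)
    categorical : categorical columns (one-hot, reference = most frequent level)
    binary : 0/1 passthrough columns
    """

    def __init__(self, continuous=("age",), categorical=("sex", "race", "repair_year"),
                 binary=tuple(CONDITION_COLUMNS)):
        self.continuous = list(continuous)
        self.categorical = list(categorical)
        self.binary = list(binary)
        self.fitted_ = False

    def fit(self, cohort: pd.DataFrame) -> "CovariateEncoder":
        for col in self.continuous + self.categorical + self.binary:
            if cohort[col].isna().any():
                raise ValueError(f"missing values in covariate {col!r}; "
                                 "run drop_incomplete first")
        self.standardization_ = {}
        for col in self.continuous:
            x = cohort[col].to_numpy(dtype=float)
            self.standardization_[col] = (float(x.mean()), float(x.std()))
        self.levels_ = {}
        self.reference_ = {}
        for col in self.categorical:
            counts = cohort[col].value_counts()
            ref = counts.index[0]  # most frequent level is the reference
            self.reference_[col] = ref
            self.levels_[col] = [lv for lv in counts.index if lv != ref]
        self.fitted_ = True
        return self

    def transform(self, cohort: pd.DataFrame) -> DesignMatrix:
        if not self.fitted_:
            raise RuntimeError("encoder not fitted")
        cols, colmap, arrays, degenerate = [], {}, [], []
        for col in self.continuous:
            mean, sd = self.standardization_[col]
            x = cohort[col].to_numpy(dtype=float)
            if sd == 0.0:
                degenerate.append(col)
                arrays.append(np.zeros_like(x))
            else:
                arrays.append((x - mean) / sd)
            cols.append(col)
            colmap[col] = (col, None)
        for col in self.categorical:
            vals = cohort[col]
            known = set(self.levels_[col]) | {self.reference_[col]}
            unseen = set(vals.unique()) - known
            if unseen:
                raise ValueError(f"unseen level(s) {sorted(map(str, unseen))} "
                                 f"for covariate {col!r}")
            if not self.levels_[col]:
                degenerate.append(col)
            for lv in self.levels_[col]:
                name = f"{col}={lv}"
                arrays.append((vals == lv).to_numpy(dtype=float))
                cols.append(name)
                colmap[name] = (col, lv)
        for col in self.binary:
            x = cohort[col].to_numpy(dtype=float)
            if x.std() == 0.0:
                degenerate.append(col)
            arrays.append(x)
            cols.append(col)
            colmap[col] = (col, None)
        X = np.column_stack(arrays) if arrays else np.empty((len(cohort), 0))
        return DesignMatrix(X, cols, colmap, dict(self.standardization_), degenerate)

    def fit_transform(self, cohort: pd.DataFrame) -> DesignMatrix:
        return self.fit(cohort).transform(cohort)


def encode_covariates(cohort: pd.DataFrame, **kwargs) -> DesignMatrix:
    """One-shot fit+transform convenience wrapper."""
    return CovariateEncoder(**kwargs).fit_transform(cohort)
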