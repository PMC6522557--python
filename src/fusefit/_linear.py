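"""Ordinary-least-squares plumbing shared by the expression and drug stages.

Both stages fit the same kind of model: a continuous response (log2 RPKM or
log IC50) regressed on categorical covariates plus one binary feature of
interest, with the feature's significance taken from the type-II sum of
squares.  For a single term with no interactions the type-II F statistic is
exactly the nested-model F comparing the full fit against the fit with the
feature dropped, which is how it is computed here (from the two residual sums
of squares of the statsmodels OLS fits).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm


class RankDeficientDesignError(ValueError):
    """Raised when the covariate design is rank deficient; names the columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(map(str, self.columns))
        )


def build_design(covariates: pd.DataFrame | None, index: pd.Index) -> pd.DataFrame:
    """Intercept + dummy-coded covariate columns aligned to ``index``.

    Each covariate column is treated as categorical; the first observed level
    is the reference.  Levels absent from the data produce no column, and
    columns that end up constant (a covariate with a single observed level)
    are dropped so single-tissue drug screens lose the tissue term
    automatically.
    """
    design = pd.DataFrame({"Intercept": 1.0}, index=index)
    if covariates is None or covariates.shape[1] == 0:
        return design
    covariates = covariates.loc[index]
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_bool_dtype(col) or pd.api.types.is_numeric_dtype(col):
            col = col.astype(float)
            if col.nunique() > 1:
                design[name] = col
            continue
        dummies = pd.get_dummies(col.astype("category"), prefix=name, drop_first=True)
        for dcol in dummies.columns:
            if dummies[dcol].nunique() > 1:
                design[dcol] = dummies[dcol].astype(float)
    return design


def collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns flagged by pivoted QR as beyond the numerical rank (empty if full rank)."""
    A = X.to_numpy(float)
    rank = np.linalg.matrix_rank(A)
    if rank == A.shape[1]:
        return []
    _, _, piv = scipy.linalg.qr(A, pivoting=True)
    return [X.columns[i] for i in sorted(piv[rank:])]


def feature_term_test(
    y: pd.Series, design: pd.DataFrame, feature: pd.Series
) -> tuple[object, float, float]:
    """Fit ``y ~ design + feature`` and test the feature term.

    Returns ``(full_fit, f_stat, p_value)`` where the p-value is the type-II
    (nested-model) F test of the feature term.  Raises
    :class:`RankDeficientDesignError` if the covariate design itself is rank
    deficient.  Collinearity of the feature with the covariates must be
    checked by the caller (semantics differ between stages).
    """
    bad = collinear_columns(design)
    if bad:
        raise RankDeficientDesignError(bad)
    X_full = design.copy()
    X_full["feature"] = feature.astype(float)
    yv = y.to_numpy(float)
    full = sm.OLS(yv, X_full.to_numpy(float)).fit()
    reduced = sm.OLS(yv, design.to_numpy(float)).fit()
    df_resid = full.df_resid
    if df_resid <= 0 or full.ssr <= 0:
        return full, np.nan, np.nan
    f_stat = (reduced.ssr - full.ssr) / (full.ssr / df_resid)
    p = float(scipy.stats.f.sf(f_stat, 1, df_resid))
    return full, float(f_stat), p
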