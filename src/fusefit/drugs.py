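"""Two-stage covariate-adjusted ANOVA linking binary features to drug response.

Stage 1 screens cancer functional events (CFEs: recurrent driver mutations,
copy-number segments, methylation states) against log IC50s with tissue and
MSI covariates; CFE-drug associations passing FDR < 25%, p < 0.001 and both
Glass deltas > 1 become per-drug covariates.  Stage 2 tests recurrent
fusion events with those confounders included, so a fusion that merely
co-occurs with a driver mutation (the classic one-sensitive-line artifact)
loses its spurious association.  Effect sizes are dual Glass deltas —
|mean difference| over each group's own standard deviation, computed on the
raw (unadjusted) IC50 groups — and significance requires FDR < 25% with
both deltas > 1.  Negative feature effects mean sensitization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._linear import RankDeficientDesignError, build_design, feature_term_test
from ._stats import bh_fdr


def glass_deltas(pos, neg) -> tuple[float, float]:
    """Dual Glass deltas: |mean_pos - mean_neg| / sd of each group.

    Standard deviations use the n-1 denominator.  A group of size 1, or a
    group with zero spread, has no usable sd; its delta is NaN, which fails
    the effect-size gate downstream.  Empty groups are an error.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    diff = abs(pos.mean() - neg.mean())

    def _delta(group):
        if group.size < 2:
            return np.nan
        sd = group.std(ddof=1)
        return diff / sd if sd > 0 else np.nan

    return _delta(pos), _delta(neg)


@dataclass
class DrugAssociationResult:
    feature: str
    drug: str
    effect_size: float  # feature coefficient, log IC50 units; negative = sensitizing
    f_stat: float
    p_value: float
    glass_delta_pos: float
    glass_delta_neg: float
    n_pos: int
    n_neg: int
    covariates_used: tuple = ()
    testable: bool = True
    reason: str | None = None
    fdr: float = np.nan

    def passes_effect_gate(self, delta_min: float = 1.0) -> bool:
        return (
            np.isfinite(self.glass_delta_pos)
            and np.isfinite(self.glass_delta_neg)
            and self.glass_delta_pos > delta_min
            and self.glass_delta_neg > delta_min
        )


class DrugAssociationModel:
    """OLS of log IC50 on covariates plus one binary feature.

    ``feature`` and ``response`` are Series indexed by cell line; only
    lines screened for the drug (present in ``response``) enter the fit.
    """

    def __init__(
        self,
        feature: pd.Series,
        response: pd.Series,
        covariates: pd.DataFrame | None = None,
        feature_name: str = "",
        drug_name: str = "",
        min_group: int = 2,
    ):
        self.response = response.dropna().astype(float)
        self.feature = feature.reindex(self.response.index).fillna(False).astype(bool)
        self.covariates = (
            covariates.reindex(self.response.index) if covariates is not None else None
        )
        self.feature_name = feature_name
        self.drug_name = drug_name
        self.min_group = min_group

    def _untestable(self, reason: str, n_pos: int, n_neg: int) -> DrugAssociationResult:
        return DrugAssociationResult(
            feature=self.feature_name, drug=self.drug_name,
            effect_size=np.nan, f_stat=np.nan, p_value=np.nan,
            glass_delta_pos=np.nan, glass_delta_neg=np.nan,
            n_pos=n_pos, n_neg=n_neg, testable=False, reason=reason,
        )

    def fit(self) -> DrugAssociationResult:
        y = self.response
        pos_mask = self.feature.to_numpy()
        n_pos, n_neg = int(pos_mask.sum()), int((~pos_mask).sum())
        if n_pos < self.min_group or n_neg < self.min_group:
            return self._untestable("insufficient group size", n_pos, n_neg)
        design = build_design(self.covariates, y.index)
        # Feature collinear with the covariates (e.g. perfect co-occurrence
        # with a selected CFE) -> not testable, logged, rather than an error.
        X_aug = design.copy()
        X_aug["feature"] = self.feature.astype(float)
        if np.linalg.matrix_rank(X_aug.to_numpy(float)) <= np.linalg.matrix_rank(
            design.to_numpy(float)
        ):
            return self._untestable("feature collinear with covariates", n_pos, n_neg)
        try:
            full, f_stat, p = feature_term_test(y, design, self.feature)
        except RankDeficientDesignError as exc:
            return self._untestable(str(exc), n_pos, n_neg)
        d_pos, d_neg = glass_deltas(y[pos_mask], y[~pos_mask])
        covnames = tuple(c for c in design.columns if c != "Intercept")
        return DrugAssociationResult(
            feature=self.feature_name,
            drug=self.drug_name,
            effect_size=float(full.params[design.shape[1]]),
            f_stat=f_stat,
            p_value=p,
            glass_delta_pos=d_pos,
            glass_delta_neg=d_neg,
            n_pos=n_pos,
            n_neg=n_neg,
            covariates_used=covnames,
        )


def fit_feature_drug_anova(
    feature: pd.Series,
    response: pd.Series,
    covariates: pd.DataFrame | None = None,
    feature_name: str = "",
    drug_name: str = "",
    min_group: int = 2,
) -> DrugAssociationResult:
    """Functional wrapper over :class:`DrugAssociationModel`."""
    return DrugAssociationModel(
        feature, response, covariates, feature_name, drug_name, min_group
    ).fit()


def _results_frame(results: Sequence[DrugAssociationResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "feature": r.feature,
                "drug": r.drug,
                "effect_size": r.effect_size,
                "f_stat": r.f_stat,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "glass_delta_pos": r.glass_delta_pos,
                "glass_delta_neg": r.glass_delta_neg,
                "n_pos": r.n_pos,
                "n_neg": r.n_neg,
                "covariates_used": ";".join(r.covariates_used),
                "testable": r.testable,
                "reason": r.reason or "",
            }
            for r in results
        ],
        columns=[
            "feature", "drug", "effect_size", "f_stat", "p_value", "fdr",
            "glass_delta_pos", "glass_delta_neg", "n_pos", "n_neg",
            "covariates_used", "testable", "reason",
        ],
    )
    return df


def _adjust(results: list[DrugAssociationResult]) -> list[DrugAssociationResult]:
    pvals = np.array([r.p_value for r in results], dtype=float)
    qvals = bh_fdr(pvals) if len(results) else np.array([])
    for r, q in zip(results, qvals):
        r.fdr = float(q)
    return results


@dataclass
class DrugScreenResults:
    """One screening stage: tidy association table plus the gate."""

    results: list
    fdr_max: float = 0.25
    delta_min: float = 1.0
    frame: pd.DataFrame = field(init=False)

    def __post_init__(self):
        self.frame = _results_frame(self.results)
        gate = [
            r.testable and np.isfinite(r.fdr) and r.fdr < self.fdr_max
            and r.passes_effect_gate(self.delta_min)
            for r in self.results
        ]
        self.frame["significant"] = gate

    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["significant"]].reset_index(drop=True)

    def summary(self) -> str:
        tested = int(self.frame["testable"].sum())
        return (
            f"Drug association screen: {len(self.frame)} feature-drug pairs, "
            f"{tested} testable, {int(self.frame['significant'].sum())} significant "
            f"(FDR<{self.fdr_max:.0%}, both Glass deltas>{self.delta_min:g})"
        )


def _response_by_drug(drug_table: pd.DataFrame) -> dict[str, pd.Series]:
    out = {}
    for drug, grp in drug_table.groupby("drug"):
        if grp["cell_line"].duplicated().any():
            raise ValueError(f"duplicate IC50 for drug {drug!r}")
        out[str(drug)] = grp.set_index("cell_line")["ic50"].astype(float)
    return out


def run_cfe_drug_screen(
    cfe_matrix: pd.DataFrame,
    drug_table: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    min_group: int = 2,
    fdr_max: float = 0.25,
    delta_min: float = 1.0,
) -> DrugScreenResults:
    """Stage 1: every (CFE, drug) pair, BH FDR across the whole stage.

    ``cfe_matrix`` is features x cell lines (binary); ``drug_table`` has
    columns drug / cell_line / ic50 (log scale); ``covariates`` holds
    tissue and MSI labels per cell line.
    """
    responses = _response_by_drug(drug_table)
    results = []
    for drug, y in responses.items():
        for feat in cfe_matrix.index:
            results.append(
                fit_feature_drug_anova(
                    cfe_matrix.loc[feat].astype(bool), y, covariates,
                    feature_name=str(feat), drug_name=drug, min_group=min_group,
                )
            )
    _adjust(results)
    return DrugScreenResults(results, fdr_max=fdr_max, delta_min=delta_min)


def select_cfe_covariates(
    stage1: DrugScreenResults | pd.DataFrame,
    fdr_max: float = 0.25,
    p_max: float = 0.001,
    delta_min: float = 1.0,
) -> dict[str, list[str]]:
    """Per-drug confounder lists from the stage-1 screen.

    A CFE becomes a stage-2 covariate for drug D iff its (CFE, D)
    association has FDR < ``fdr_max``, p < ``p_max`` and both Glass deltas
    > ``delta_min``.
    """
    df = stage1.frame if isinstance(stage1, DrugScreenResults) else stage1
    out: dict[str, list[str]] = {}
    if df.empty:
        return out
    mask = (
        df["testable"]
        & (df["fdr"] < fdr_max)
        & (df["p_value"] < p_max)
        & (df["glass_delta_pos"] > delta_min)
        & (df["glass_delta_neg"] > delta_min)
    )
    for row in df[mask].itertuples(index=False):
        out.setdefault(str(row.drug), []).append(str(row.feature))
    return {d: sorted(v) for d, v in out.items()}


def run_fusion_drug_screen(
    fusion_features: pd.DataFrame,
    drug_table: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    cfe_covariates: Mapping[str, Sequence[str]] | None = None,
    cfe_matrix: pd.DataFrame | None = None,
    min_group: int = 2,
    fdr_max: float = 0.25,
    delta_min: float = 1.0,
) -> DrugScreenResults:
    """Stage 2: recurrent fusion events vs drugs with CFE confounders.

    ``fusion_features`` is fusions x cell lines (binary, each positive in
    >= ``min_group`` screened lines to be testable); ``cfe_covariates``
    maps drug -> selected CFE ids, whose binary profiles are taken from
    ``cfe_matrix`` and appended to the covariates for that drug.
    """
    cfe_covariates = dict(cfe_covariates or {})
    responses = _response_by_drug(drug_table)
    results = []
    for drug, y in responses.items():
        cov = covariates.reindex(y.index) if covariates is not None else pd.DataFrame(
            index=y.index
        )
        for cfe in cfe_covariates.get(drug, []):
            if cfe_matrix is None:
                raise ValueError("cfe_covariates given without cfe_matrix")
            cov = cov.assign(
                **{f"cfe_{cfe}": cfe_matrix.loc[cfe].reindex(y.index).fillna(False).astype(bool)}
            )
        for fusion in fusion_features.index:
            results.append(
                fit_feature_drug_anova(
                    fusion_features.loc[fusion].astype(bool), y, cov,
                    feature_name=str(fusion), drug_name=drug, min_group=min_group,
                )
            )
    _adjust(results)
    return DrugScreenResults(results, fdr_max=fdr_max, delta_min=delta_min)
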