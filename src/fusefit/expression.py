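"""Fusion status vs partner-gene expression.

For each gene recurrently fused at one end (5' or 3') across enough cell
lines, expression (log2 RPKM) is regressed on a binary fused/unfused
indicator plus covariates — cancer type (pan-cancer analyses), MSI status
and the gene's copy-number category:

    G = beta_covariates * X_covariates + beta_fusion * X_fusion + psi

The fusion coefficient ``beta_fusion`` measures the log2 expression shift
attributable to fusion status and its significance is a type-II F test,
which for a single term without interactions is the nested-model F (full
vs fusion-dropped fit).  Separately, each individual event is screened for
outlier 3'-gene overexpression: the carrier line's expression above the
95th percentile of all other lines, and not explained by amplification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._linear import RankDeficientDesignError, build_design, feature_term_test
from ._stats import bh_fdr
from .catalog import FusionEvent

CNA_CATEGORIES = ("loss", "neutral", "amplified")


def build_fused_gene_sets(
    events: Sequence[FusionEvent], min_samples: int = 3
) -> dict[str, dict[str, set]]:
    """Per-gene carrier sets at each end, restricted to testable genes.

    A gene is testable at an end iff it is fused at that end in at least
    ``min_samples`` cell lines.  Returns ``{gene: {"5p": lines, "3p": lines}}``
    with only the testable ends present.
    """
    carriers: dict[tuple[str, str], set] = {}
    for e in events:
        carriers.setdefault((e.gene5, "5p"), set()).add(e.cell_line)
        carriers.setdefault((e.gene3, "3p"), set()).add(e.cell_line)
    out: dict[str, dict[str, set]] = {}
    for (gene, end), lines in carriers.items():
        if len(lines) >= min_samples:
            out.setdefault(gene, {})[end] = lines
    return out


@dataclass
class ExpressionModelFit:
    """OLS fit of expression on fusion status and covariates."""

    gene: str
    end: str
    beta_fusion: float
    beta_covariates: pd.Series
    f_stat: float
    p_value: float
    n_fused: int
    nobs: int
    conf_int: tuple[float, float]
    testable: bool = True
    reason: str | None = None
    fdr: float = np.nan

    def summary(self) -> str:
        if not self.testable:
            return f"{self.gene} ({self.end}): not testable ({self.reason})"
        lo, hi = self.conf_int
        return (
            f"{self.gene} ({self.end}): beta_fusion={self.beta_fusion:+.3f} "
            f"log2 units [95% CI {lo:+.3f}, {hi:+.3f}], "
            f"F={self.f_stat:.3f}, p={self.p_value:.3g}, "
            f"n_fused={self.n_fused}/{self.nobs}"
        )


class FusionExpressionModel:
    """OLS model of one gene's expression on fusion status plus covariates.

    Parameters
    ----------
    expression
        log2 RPKM values indexed by cell line.
    fused
        Boolean fusion indicator aligned to the same cell lines.
    covariates
        Optional DataFrame of categorical covariates (cancer type, MSI
        status, CNA category), aligned to the same cell lines.
    """

    def __init__(
        self,
        expression: pd.Series,
        fused: pd.Series,
        covariates: pd.DataFrame | None = None,
        gene: str = "",
        end: str = "",
    ):
        idx = expression.index
        self.expression = expression.astype(float)
        self.fused = fused.reindex(idx).astype(bool)
        self.covariates = covariates.reindex(idx) if covariates is not None else None
        self.gene = gene
        self.end = end

    @classmethod
    def from_matrix(
        cls,
        gene: str,
        end: str,
        carrier_lines: Iterable[str],
        expression_matrix: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
    ) -> "FusionExpressionModel":
        """Build from a genes x samples expression matrix and carrier set."""
        expr = expression_matrix.loc[gene]
        fused = pd.Series(expr.index.isin(set(carrier_lines)), index=expr.index)
        return cls(expr, fused, covariates, gene=gene, end=end)

    def fit(self) -> ExpressionModelFit:
        n_fused = int(self.fused.sum())
        nobs = len(self.expression)
        if n_fused == 0 or n_fused == nobs:
            return ExpressionModelFit(
                gene=self.gene, end=self.end, beta_fusion=np.nan,
                beta_covariates=pd.Series(dtype=float), f_stat=np.nan,
                p_value=np.nan, n_fused=n_fused, nobs=nobs,
                conf_int=(np.nan, np.nan), testable=False,
                reason="fusion indicator is constant",
            )
        design = build_design(self.covariates, self.expression.index)
        full, f_stat, p = feature_term_test(self.expression, design, self.fused)
        k = design.shape[1]  # feature coefficient comes last
        beta = float(full.params[k])
        ci = full.conf_int(alpha=0.05)
        return ExpressionModelFit(
            gene=self.gene,
            end=self.end,
            beta_fusion=beta,
            beta_covariates=pd.Series(full.params[:k], index=design.columns),
            f_stat=f_stat,
            p_value=p,
            n_fused=n_fused,
            nobs=nobs,
            conf_int=(float(ci[k][0]), float(ci[k][1])),
        )


def adjust_expression_fdr(
    fits: Sequence[ExpressionModelFit], strata: Sequence[str] | None = None
) -> list[ExpressionModelFit]:
    """BH adjustment within strata (a pan-cancer run is one stratum).

    Mutates and returns the fits; untestable fits keep fdr = NaN.
    """
    strata = list(strata) if strata is not None else ["all"] * len(fits)
    if len(strata) != len(fits):
        raise ValueError("one stratum label per fit required")
    for stratum in set(strata):
        idx = [i for i, s in enumerate(strata) if s == stratum]
        pvals = np.array([fits[i].p_value for i in idx])
        qvals = bh_fdr(pvals)
        for i, q in zip(idx, qvals):
            fits[i].fdr = float(q)
    return list(fits)


@dataclass
class OverexpressionFlag:
    cell_line: str
    gene5: str
    gene3: str
    carrier_expression: float
    percentile_rank: float
    amplified: bool
    flagged: bool
    testable: bool = True


def flag_overexpression(
    events: Sequence[FusionEvent],
    expression_matrix: pd.DataFrame,
    amplified: Iterable[tuple[str, str]] = (),
    percentile: float = 0.95,
) -> list[OverexpressionFlag]:
    """Outlier 3'-gene overexpression screen at the single-event level.

    The carrier's percentile rank is the fraction of *other* cell lines
    with strictly lower expression of the 3' gene; an event is flagged when
    that rank is >= ``percentile`` and the (gene3, carrier) pair is not in
    ``amplified``.  Events whose 3' gene is missing from the matrix are
    marked untestable.
    """
    amplified = set(amplified)
    flags = []
    for e in events:
        if e.gene3 not in expression_matrix.index or e.cell_line not in expression_matrix.columns:
            flags.append(
                OverexpressionFlag(
                    cell_line=e.cell_line, gene5=e.gene5, gene3=e.gene3,
                    carrier_expression=np.nan, percentile_rank=np.nan,
                    amplified=False, flagged=False, testable=False,
                )
            )
            continue
        row = expression_matrix.loc[e.gene3]
        carrier = float(row[e.cell_line])
        others = row.drop(e.cell_line).to_numpy(float)
        rank = float((others < carrier).sum() / others.size) if others.size else np.nan
        amp = (e.gene3, e.cell_line) in amplified
        flags.append(
            OverexpressionFlag(
                cell_line=e.cell_line, gene5=e.gene5, gene3=e.gene3,
                carrier_expression=carrier, percentile_rank=rank,
                amplified=amp,
                flagged=bool(others.size and rank >= percentile and not amp),
            )
        )
    return flags


def run_expression_screen(
    events: Sequence[FusionEvent],
    expression_matrix: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    cna_categories: pd.DataFrame | None = None,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Fit the fusion-expression model for every testable gene end.

    ``covariates`` holds sample-level columns (cancer type, MSI);
    ``cna_categories`` is an optional genes x samples frame of
    loss/neutral/amplified labels supplying the per-gene CNA covariate.
    Returns a tidy table with BH FDR over the (single, pan-cancer) stratum.
    """
    gene_sets = build_fused_gene_sets(events, min_samples=min_samples)
    fits: list[ExpressionModelFit] = []
    for gene in sorted(gene_sets):
        if gene not in expression_matrix.index:
            continue
        for end in ("5p", "3p"):
            if end not in gene_sets[gene]:
                continue
            cov = covariates.copy() if covariates is not None else pd.DataFrame(
                index=expression_matrix.columns
            )
            if cna_categories is not None and gene in cna_categories.index:
                cov = cov.assign(cna=cna_categories.loc[gene])
            try:
                fit = FusionExpressionModel.from_matrix(
                    gene, end, gene_sets[gene][end], expression_matrix, cov
                ).fit()
            except RankDeficientDesignError as exc:
                fit = ExpressionModelFit(
                    gene=gene, end=end, beta_fusion=np.nan,
                    beta_covariates=pd.Series(dtype=float), f_stat=np.nan,
                    p_value=np.nan, n_fused=len(gene_sets[gene][end]),
                    nobs=expression_matrix.shape[1], conf_int=(np.nan, np.nan),
                    testable=False, reason=str(exc),
                )
            fits.append(fit)
    adjust_expression_fdr(fits)
    return pd.DataFrame(
        [
            {
                "gene": f.gene,
                "end": f.end,
                "beta_fusion": f.beta_fusion,
                "f_stat": f.f_stat,
                "p_value": f.p_value,
                "fdr": f.fdr,
                "n_fused": f.n_fused,
                "n_samples": f.nobs,
                "testable": f.testable,
                "reason": f.reason or "",
            }
            for f in fits
        ],
        columns=[
            "gene", "end", "beta_fusion", "f_stat", "p_value", "fdr",
            "n_fused", "n_samples", "testable", "reason",
        ],
    )
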