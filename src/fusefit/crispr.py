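"""Fusion essentiality score (FES) from pooled CRISPR-Cas9 screens.

Gene-level depletion averages cannot tell whether a *fusion* is required
for fitness, because most guides against a fused gene also cut the wild-type
allele region not retained in the chimera.  Individual sgRNAs, however, can
be split by their cut site relative to the fusion breakpoint: a guide is
*mapping* when it targets the portion of the partner gene retained in the
fusion transcript (5' gene on the + strand: cut at or before the
breakpoint; - strand: at or after; mirrored for the 3' gene), and
*non-mapping* otherwise.

Scoring proceeds per screening dataset on fold changes scaled so the median
essential-gene guide sits at -1 and the median non-essential guide at 0:

1. Z-normalize each guide's scaled fold change across all screened lines.
2. Per partner gene: mean Z of mapping guides minus mean Z of non-mapping
   guides (taken from zero when the gene has no non-mapping guides).
3. Average the per-gene differences to give the FES.

Negative FES means fusion-specific depletion.  Significance comes from
randomizing all scaled fold changes *within* each cell line, recomputing
the Z-normalization and every FES per randomization; the plus-one
empirical p counts null FES at or below the observed (depletion-sided).
Significant hits must additionally show a raw mapping-vs-non-mapping mean
scaled fold-change difference of at most -0.45.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._stats import bh_fdr


@dataclass
class ScaledFoldChangeMatrix:
    """Guides x cell lines fold changes after scale-to-essentials."""

    values: pd.DataFrame
    anchors: pd.DataFrame  # per cell line: median_essential, median_nonessential


def scale_to_essentials(
    fold_changes: pd.DataFrame,
    guide_genes: pd.Series,
    essential_genes: Iterable[str],
    nonessential_genes: Iterable[str],
) -> ScaledFoldChangeMatrix:
    """Anchor each cell line's fold changes to the reference gene sets.

    scaled(x) = (x - m_ne) / (m_ne - m_e) per cell line, where m_ne and
    m_e are the medians over guides targeting the non-essential and
    essential reference genes.  After scaling the two anchor medians are
    exactly 0 and -1.  A cell line with m_e >= m_ne failed the screen
    quality contract and raises.
    """
    essential_genes = set(essential_genes)
    nonessential_genes = set(nonessential_genes)
    genes = guide_genes.reindex(fold_changes.index)
    ess_mask = genes.isin(essential_genes).to_numpy()
    ne_mask = genes.isin(nonessential_genes).to_numpy()
    if not ess_mask.any() or not ne_mask.any():
        raise ValueError("need guides targeting both reference lists")
    V = fold_changes.to_numpy(float)
    m_e = np.nanmedian(V[ess_mask], axis=0)
    m_ne = np.nanmedian(V[ne_mask], axis=0)
    bad = m_e >= m_ne
    if bad.any():
        lines = [str(fold_changes.columns[i]) for i in np.nonzero(bad)[0]]
        raise ValueError(
            "essential-guide median not below non-essential median in: "
            + ", ".join(lines)
        )
    scaled = (V - m_ne) / (m_ne - m_e)
    return ScaledFoldChangeMatrix(
        values=pd.DataFrame(scaled, index=fold_changes.index, columns=fold_changes.columns),
        anchors=pd.DataFrame(
            {"median_essential": m_e, "median_nonessential": m_ne},
            index=fold_changes.columns,
        ),
    )


@dataclass
class GuidePartition:
    """Mapping / non-mapping guide ids for one transcript, per partner gene."""

    transcript_id: str
    mapping5: list
    nonmapping5: list
    mapping3: list
    nonmapping3: list
    excluded: list = field(default_factory=list)  # chromosome mismatches

    @property
    def mapping(self) -> list:
        return self.mapping5 + self.mapping3

    @property
    def nonmapping(self) -> list:
        return self.nonmapping5 + self.nonmapping3


def _side_mask(cut: np.ndarray, breakpoint: int, strand: str, end: str) -> np.ndarray:
    # Retained side of the breakpoint, given the gene's genomic strand.
    # Ties (cut == breakpoint) count as mapping on either strand.
    if end == "5p":
        return cut <= breakpoint if strand == "+" else cut >= breakpoint
    return cut >= breakpoint if strand == "+" else cut <= breakpoint


def map_guides_to_transcript(library: pd.DataFrame, transcript) -> GuidePartition:
    """Partition guides on the two partner genes by the strand/side rule.

    ``library`` needs columns gene / chrom / cut_position / strand indexed
    by guide id.  ``transcript`` provides gene5, gene3, chrom5, chrom3,
    breakpoint5, breakpoint3 (attributes or mapping keys).  Guides on the
    wrong chromosome for their gene's breakpoint are excluded with a
    warning.
    """
    get = (
        transcript.get
        if hasattr(transcript, "get")
        else lambda k: getattr(transcript, k)
    )
    tid = str(get("transcript_id") if _has(transcript, "transcript_id") else "")
    part = GuidePartition(tid, [], [], [], [])
    for end, gene_key, chrom_key, bp_key in (
        ("5p", "gene5", "chrom5", "breakpoint5"),
        ("3p", "gene3", "chrom3", "breakpoint3"),
    ):
        gene = get(gene_key)
        chrom = str(get(chrom_key))
        bp = int(get(bp_key))
        sub = library[library["gene"] == gene]
        if sub.empty:
            continue
        wrong = sub[sub["chrom"].astype(str) != chrom]
        if not wrong.empty:
            part.excluded.extend(wrong.index.tolist())
            warnings.warn(
                f"{len(wrong)} guide(s) for {gene} on a different chromosome "
                f"than the {end} breakpoint; excluded",
                RuntimeWarning,
                stacklevel=2,
            )
            sub = sub[sub["chrom"].astype(str) == chrom]
        strands = sub["strand"].unique()
        strand = str(strands[0]) if len(strands) else "+"
        mask = _side_mask(sub["cut_position"].to_numpy(int), bp, strand, end)
        mapping = sub.index[mask].tolist()
        nonmapping = sub.index[~mask].tolist()
        if end == "5p":
            part.mapping5, part.nonmapping5 = mapping, nonmapping
        else:
            part.mapping3, part.nonmapping3 = mapping, nonmapping
    return part


def _has(obj, key) -> bool:
    if hasattr(obj, "get") and not hasattr(obj, key):
        return key in obj
    return hasattr(obj, key)


def _zscore_array(V: np.ndarray) -> np.ndarray:
    """Row-wise z-scores with sample sd; degenerate rows (sd 0, or fewer
    than two finite entries) become all zeros."""
    has_nan = np.isnan(V).any()
    if has_nan:
        cnt = np.sum(~np.isnan(V), axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.where(cnt > 0, np.nanmean(V, axis=1), 0.0)
            sd = np.where(cnt > 1, np.nanstd(V, axis=1, ddof=1), 0.0)
    else:
        mu = V.mean(axis=1)
        sd = V.std(axis=1, ddof=1) if V.shape[1] > 1 else np.zeros(V.shape[0])
    ok = sd > 0
    Z = np.zeros_like(V)
    Z[ok] = (V[ok] - mu[ok, None]) / sd[ok, None]
    if has_nan:
        Z[np.isnan(V)] = np.nan
    return Z


def zscore_per_guide(scaled: pd.DataFrame) -> pd.DataFrame:
    """Z-normalize each guide's scaled fold change across cell lines."""
    return pd.DataFrame(
        _zscore_array(scaled.to_numpy(float)),
        index=scaled.index,
        columns=scaled.columns,
    )


def _nanmean_or(values: np.ndarray, default: float | None = None) -> float:
    finite = values[~np.isnan(values)]
    if finite.size == 0:
        return np.nan if default is None else default
    return float(finite.mean())


def fes_score(
    partition: GuidePartition,
    Z: pd.DataFrame,
    cell_line: str,
    scaled: pd.DataFrame | None = None,
) -> dict:
    """Observed FES for one transcript in one cell line.

    Per gene with >= 1 mapping guide: diff = mean(Z mapping) - mean(Z
    non-mapping), the non-mapping mean taken as 0 when the gene has none.
    FES averages the per-gene diffs.  ``raw_diff`` applies the same
    construction to the *scaled* (not Z) fold changes pooled over both
    genes; it feeds the minimum-difference filter.
    """
    zcol = Z[cell_line]
    per_gene = {}
    diffs = []
    for end, mapping, nonmapping in (
        ("5p", partition.mapping5, partition.nonmapping5),
        ("3p", partition.mapping3, partition.nonmapping3),
    ):
        zm = _nanmean_or(zcol.reindex(mapping).to_numpy(float)) if mapping else np.nan
        znm = (
            _nanmean_or(zcol.reindex(nonmapping).to_numpy(float), default=0.0)
            if nonmapping
            else 0.0
        )
        per_gene[f"z_mapping_mean_{end}"] = zm
        per_gene[f"z_nonmapping_mean_{end}"] = znm if nonmapping else np.nan
        if mapping and np.isfinite(zm):
            diffs.append(zm - (znm if np.isfinite(znm) else 0.0))
    if not diffs:
        raise ValueError("no mapping guides on either gene; transcript untestable")
    fes = float(np.mean(diffs))
    raw_diff = np.nan
    if scaled is not None:
        scol = scaled[cell_line]
        m = _nanmean_or(scol.reindex(partition.mapping).to_numpy(float))
        nm = (
            _nanmean_or(scol.reindex(partition.nonmapping).to_numpy(float), default=0.0)
            if partition.nonmapping
            else 0.0
        )
        raw_diff = m - nm if np.isfinite(m) else np.nan
    return {"fes": fes, "raw_diff": raw_diff, **per_gene}


@dataclass
class FesResults:
    """Transcript x cell-line FES table with permutation significance."""

    frame: pd.DataFrame
    dataset: str
    n_perm: int
    seed: int | None
    fdr_threshold: float
    min_diff: float

    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["significant"]].reset_index(drop=True)

    def summary(self) -> str:
        testable = int(self.frame["testable"].sum())
        return (
            f"FES screen [{self.dataset}]: {len(self.frame)} transcript-line pairs, "
            f"{testable} testable, {int(self.frame['significant'].sum())} significant "
            f"(FDR<{self.fdr_threshold:.0%}, raw diff <= -{self.min_diff:g}; "
            f"{self.n_perm} within-line randomizations, seed={self.seed})"
        )


class FesScreen:
    """Model object for one CRISPR screening dataset.

    Parameters
    ----------
    library
        Guide table indexed by guide id with columns gene / chrom /
        cut_position / strand.
    fold_changes
        Guides x cell lines log fold changes (bias-corrected scale).
    transcripts
        DataFrame with one row per (transcript, carrier cell line):
        columns transcript_id, cell_line, gene5, chrom5, breakpoint5,
        gene3, chrom3, breakpoint3.
    prescaled
        If False, ``essential_genes`` / ``nonessential_genes`` must be
        given and scale-to-essentials is applied first.
    """

    def __init__(
        self,
        library: pd.DataFrame,
        fold_changes: pd.DataFrame,
        transcripts: pd.DataFrame,
        dataset: str = "screen",
        prescaled: bool = True,
        essential_genes: Iterable[str] | None = None,
        nonessential_genes: Iterable[str] | None = None,
    ):
        self.library = library
        self.transcripts = transcripts.reset_index(drop=True)
        self.dataset = dataset
        if prescaled:
            self.scaled = fold_changes.astype(float)
            self.anchors = None
        else:
            if essential_genes is None or nonessential_genes is None:
                raise ValueError("reference gene lists required when not prescaled")
            sm = scale_to_essentials(
                fold_changes, library["gene"], essential_genes, nonessential_genes
            )
            self.scaled = sm.values
            self.anchors = sm.anchors

    def fit(
        self,
        n_perm: int = 10000,
        seed: int | None = None,
        fdr_threshold: float = 0.05,
        min_diff: float = 0.45,
    ) -> FesResults:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        scaled = self.scaled
        Z = zscore_per_guide(scaled)
        guide_pos = {g: i for i, g in enumerate(scaled.index)}
        col_pos = {c: j for j, c in enumerate(scaled.columns)}

        rows = []
        testable = []  # (row_index, per-gene index arrays, column, observed fes)
        for r in self.transcripts.itertuples(index=False):
            rec = {
                "transcript_id": r.transcript_id,
                "cell_line": r.cell_line,
                "dataset": self.dataset,
                "gene5": r.gene5,
                "gene3": r.gene3,
            }
            if r.cell_line not in col_pos:
                rows.append({**rec, "testable": False, "reason": "cell line not screened"})
                continue
            part = map_guides_to_transcript(self.library, r)
            if not part.mapping:
                rows.append({**rec, "testable": False, "reason": "no mapping guides"})
                continue
            obs = fes_score(part, Z, r.cell_line, scaled)
            if not np.isfinite(obs["fes"]):
                rows.append({**rec, "testable": False, "reason": "no finite fold changes"})
                continue
            gene_idx = []
            for mapping, nonmapping in (
                (part.mapping5, part.nonmapping5),
                (part.mapping3, part.nonmapping3),
            ):
                if mapping:
                    gene_idx.append(
                        (
                            np.array([guide_pos[g] for g in mapping], dtype=np.intp),
                            np.array([guide_pos[g] for g in nonmapping], dtype=np.intp),
                        )
                    )
            rows.append(
                {
                    **rec,
                    "n_mapping": len(part.mapping),
                    "n_nonmapping": len(part.nonmapping),
                    **obs,
                    "testable": True,
                    "reason": "",
                }
            )
            testable.append((len(rows) - 1, gene_idx, col_pos[r.cell_line], obs["fes"]))

        exceed = np.zeros(len(testable), dtype=np.int64)
        if testable:
            rng = np.random.default_rng(seed)
            V = scaled.to_numpy(float)
            n_guides, n_lines = V.shape
            col_arange = np.arange(n_lines)
            for _ in range(n_perm):
                # independent permutation of guide values within every cell line
                order = rng.random((n_guides, n_lines)).argsort(axis=0)
                P = V[order, col_arange]
                Zp = _zscore_array(P)
                for t, (_, gene_idx, col, obs_fes) in enumerate(testable):
                    diffs = []
                    for map_idx, nm_idx in gene_idx:
                        zm = _nanmean_or(Zp[map_idx, col])
                        znm = _nanmean_or(Zp[nm_idx, col], default=0.0) if nm_idx.size else 0.0
                        if np.isfinite(zm):
                            diffs.append(zm - (znm if np.isfinite(znm) else 0.0))
                    if diffs and float(np.mean(diffs)) <= obs_fes:
                        exceed[t] += 1

        frame = pd.DataFrame(rows)
        for col in (
            "n_mapping", "n_nonmapping", "fes", "raw_diff",
            "z_mapping_mean_5p", "z_nonmapping_mean_5p",
            "z_mapping_mean_3p", "z_nonmapping_mean_3p",
        ):
            if col not in frame.columns:
                frame[col] = np.nan
        frame["p_value"] = np.nan
        for t, (row_i, _, _, _) in enumerate(testable):
            frame.loc[row_i, "p_value"] = (1.0 + exceed[t]) / (1.0 + n_perm)
        frame["fdr"] = bh_fdr(frame["p_value"])
        frame["passes_min_diff"] = frame["raw_diff"] <= -min_diff
        frame["significant"] = (
            frame["testable"].fillna(False).astype(bool)
            & (frame["fdr"] < fdr_threshold)
            & frame["passes_min_diff"]
        )
        return FesResults(
            frame=frame,
            dataset=self.dataset,
            n_perm=n_perm,
            seed=seed,
            fdr_threshold=fdr_threshold,
            min_diff=min_diff,
        )


def aggregate_events_fes(results: Sequence[FesResults | pd.DataFrame]) -> pd.DataFrame:
    """Event-level significance across datasets.

    A fusion event (ordered gene pair in a cell line) is significant iff
    any of its transcripts is significant in any dataset for that line.
    """
    frames = [r.frame if isinstance(r, FesResults) else r for r in results]
    if not frames:
        return pd.DataFrame(columns=["cell_line", "gene5", "gene3", "n_transcripts", "significant"])
    allf = pd.concat(frames, ignore_index=True)
    grouped = allf.groupby(["cell_line", "gene5", "gene3"], sort=True)
    out = grouped.agg(
        n_transcripts=("transcript_id", "nunique"),
        significant=("significant", "any"),
    ).reset_index()
    return out
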