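"""Permutation test for genes fused more often in a cancer type than expected.

The substrate is a binary gene x sample matrix (1 = the sample carries at
least one fusion involving the gene).  Under the null hypothesis that
fusions distribute homogeneously across cancer types, the matrix is
randomized by degree-preserving *checkerboard switches*: repeatedly pick two
1-cells (g1, s1), (g2, s2) with g1 != g2, s1 != s2 and (g1, s2) = (g2, s1)
= 0, and swap the 2x2 checkerboard.  Every switch preserves the row and
column marginals exactly, and — when failed proposals count as self-loop
steps — the chain's transition kernel is symmetric, so its stationary
distribution is exactly uniform over the margin-compatible matrices.  The
permutation sampler therefore counts proposal *attempts* as its steps;
:func:`rewire` additionally offers an exactly-n-successful-switches
contract for direct matrix randomization.

The test statistic is the per-(gene, cancer type) count of fused samples;
the empirical p-value uses plus-one smoothing, p = (1 + b) / (1 + R), so it
is never zero, and is Benjamini-Hochberg adjusted across all tested pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import bh_fdr, plus_one_pvalue
from .catalog import FusionEvent


@dataclass
class OccurrenceMatrix:
    """Binary gene x sample fusion-status matrix with cancer-type labels."""

    genes: list
    samples: list
    values: np.ndarray  # shape (n_genes, n_samples), dtype int8, entries {0,1}
    cancer_types: list
    rewire_exhausted: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("matrix shape does not match gene/sample lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("occurrence matrix must be binary")
        if len(self.cancer_types) != len(self.samples):
            raise ValueError("one cancer type per sample required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def type_indicator(self) -> tuple[list, np.ndarray]:
        """Unique cancer types and a samples x types 0/1 indicator."""
        types = sorted(set(self.cancer_types))
        ind = np.zeros((len(self.samples), len(types)), dtype=np.int8)
        pos = {t: j for j, t in enumerate(types)}
        for i, t in enumerate(self.cancer_types):
            ind[i, pos[t]] = 1
        return types, ind


def build_occurrence_matrix(
    events: Sequence[FusionEvent],
    cancer_types: Mapping[str, str],
    genes: Sequence[str] | None = None,
) -> OccurrenceMatrix:
    """Entry (G, S) = 1 iff sample S has >= 1 event with G as 5' or 3' partner.

    ``cancer_types`` maps every sample in the cohort to its label and fixes
    the sample order; ``genes`` defaults to all genes seen in the events.
    """
    samples = list(cancer_types)
    if genes is None:
        genes = sorted({g for e in events for g in (e.gene5, e.gene3)})
    gene_pos = {g: i for i, g in enumerate(genes)}
    sample_pos = {s: j for j, s in enumerate(samples)}
    values = np.zeros((len(genes), len(samples)), dtype=np.int8)
    for e in events:
        if e.cell_line not in sample_pos:
            raise ValueError(f"event cell line {e.cell_line!r} not annotated")
        j = sample_pos[e.cell_line]
        for g in (e.gene5, e.gene3):
            if g not in gene_pos:
                raise ValueError(f"event gene {g!r} not in gene list")
            values[gene_pos[g], j] = 1
    return OccurrenceMatrix(
        genes=list(genes),
        samples=samples,
        values=values,
        cancer_types=[cancer_types[s] for s in samples],
    )


def _checkerboard_rewire(
    values: np.ndarray,
    n_switches: int,
    rng: np.random.Generator,
    max_attempts: int | None = None,
) -> tuple[np.ndarray, int]:
    """Perform ``n_switches`` successful checkerboard switches in place.

    Returns ``(matrix, n_done)``; ``n_done < n_switches`` means the retry
    budget was exhausted (e.g. no valid switch exists).  ``values`` is
    modified in place and also returned.
    """
    rows, cols = np.nonzero(values)
    rows = rows.astype(np.int64)
    cols = cols.astype(np.int64)
    n_ones = rows.size
    if n_ones < 2 or n_switches == 0:
        return values, 0
    if max_attempts is None:
        max_attempts = max(100 * n_switches, 1000)
    done = 0
    attempts = 0
    batch = max(256, min(65536, 4 * n_switches))
    while done < n_switches and attempts < max_attempts:
        idx = rng.integers(0, n_ones, size=(batch, 2))
        for i, j in idx:
            attempts += 1
            if done >= n_switches or attempts > max_attempts:
                break
            if i == j:
                continue
            r1, c1 = rows[i], cols[i]
            r2, c2 = rows[j], cols[j]
            if r1 == r2 or c1 == c2:
                continue
            if values[r1, c2] or values[r2, c1]:
                continue
            values[r1, c1] = 0
            values[r2, c2] = 0
            values[r1, c2] = 1
            values[r2, c1] = 1
            cols[i], cols[j] = c2, c1
            done += 1
    return values, done


def _switch_attempts(
    values: np.ndarray, n_steps: int, rng: np.random.Generator
) -> np.ndarray:
    """Run ``n_steps`` proposal attempts in place; failures are self-loops.

    This is the uniform-stationary version of the checkerboard chain: each
    step draws an ordered pair of 1-cells and applies the switch only when
    the 2x2 checkerboard is valid.  Counting failed draws as steps keeps
    the transition kernel symmetric, so a long chain samples uniformly
    from the matrices with the given marginals.
    """
    rows, cols = np.nonzero(values)
    rows = rows.astype(np.int64)
    cols = cols.astype(np.int64)
    n_ones = rows.size
    if n_ones < 2 or n_steps == 0:
        return values
    idx = rng.integers(0, n_ones, size=(n_steps, 2))
    for i, j in idx:
        if i == j:
            continue
        r1, c1 = rows[i], cols[i]
        r2, c2 = rows[j], cols[j]
        if r1 == r2 or c1 == c2 or values[r1, c2] or values[r2, c1]:
            continue
        values[r1, c1] = 0
        values[r2, c2] = 0
        values[r1, c2] = 1
        values[r2, c1] = 1
        cols[i], cols[j] = c2, c1
    return values


def default_n_switches(values: np.ndarray) -> int:
    """Mixing heuristic: 10 x the number of 1-entries."""
    return 10 * int(values.sum())


def rewire(
    matrix: OccurrenceMatrix,
    n_switches: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> OccurrenceMatrix:
    """Degree-preserving randomization of the occurrence matrix.

    Returns a new matrix with row and column sums identical to the input.
    If the retry budget is exhausted before ``n_switches`` successful
    switches (e.g. an all-ones matrix admits none), the partially rewired
    matrix is returned with ``rewire_exhausted`` set and a warning issued.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n_switches is None:
        n_switches = default_n_switches(matrix.values)
    values = matrix.values.copy()
    values, done = _checkerboard_rewire(values, n_switches, rng)
    exhausted = done < n_switches
    if exhausted:
        warnings.warn(
            f"rewire retry budget exhausted after {done}/{n_switches} switches",
            RuntimeWarning,
            stacklevel=2,
        )
    return OccurrenceMatrix(
        genes=matrix.genes,
        samples=matrix.samples,
        values=values,
        cancer_types=matrix.cancer_types,
        rewire_exhausted=exhausted,
    )


def observed_counts(matrix: OccurrenceMatrix) -> pd.DataFrame:
    """Fused-sample counts per (gene, cancer type): genes x types frame."""
    types, ind = matrix.type_indicator()
    counts = matrix.values.astype(np.int64) @ ind.astype(np.int64)
    return pd.DataFrame(counts, index=matrix.genes, columns=types)


def permutation_null(
    matrix: OccurrenceMatrix,
    n_perm: int = 10000,
    n_switches: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Null fused-sample counts, shape (n_perm, n_genes, n_types).

    Each permutation independently runs ``n_switches`` checkerboard
    proposal steps (default 10x the number of ones; failed proposals are
    self-loops, which keeps the chain's stationary distribution uniform
    over the margin class) from the *observed* matrix and records the
    per-gene per-cancer-type counts.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if n_switches is None:
        n_switches = default_n_switches(matrix.values)
    _, ind = matrix.type_indicator()
    ind64 = ind.astype(np.int64)
    out = np.empty((n_perm, len(matrix.genes), ind.shape[1]), dtype=np.int32)
    for k in range(n_perm):
        values = matrix.values.copy()
        values = _switch_attempts(values, n_switches, rng)
        out[k] = values.astype(np.int64) @ ind64
    return out


def empirical_pvalues(
    matrix: OccurrenceMatrix, null_counts: np.ndarray
) -> pd.DataFrame:
    """Plus-one empirical p and BH FDR per tested (gene, cancer type) pair.

    Only pairs with observed count >= 1 are tested; absent pairs carry a
    guaranteed p = 1 and would only inflate the correction burden.
    """
    obs = observed_counts(matrix)
    n_perm = null_counts.shape[0]
    rows = []
    for gi, gene in enumerate(matrix.genes):
        for tj, ctype in enumerate(obs.columns):
            n = int(obs.iat[gi, tj])
            if n < 1:
                continue
            exceed = int((null_counts[:, gi, tj] >= n).sum())
            rows.append(
                {
                    "gene": gene,
                    "cancer_type": ctype,
                    "observed_n": n,
                    "p_value": plus_one_pvalue(exceed, n_perm),
                }
            )
    results = pd.DataFrame(rows, columns=["gene", "cancer_type", "observed_n", "p_value"])
    results["fdr"] = bh_fdr(results["p_value"]) if len(results) else []
    return results


@dataclass
class RecurrenceResults:
    """Fitted recurrence test: per-pair counts, empirical p, FDR."""

    results: pd.DataFrame
    n_perm: int
    n_switches: int
    seed: int | None
    null_counts: np.ndarray | None = field(default=None, repr=False)

    def significant(self, fdr_threshold: float = 0.05) -> pd.DataFrame:
        return self.results[self.results["fdr"] < fdr_threshold].reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            "Fusion recurrence permutation test",
            f"  pairs tested: {len(self.results)}",
            f"  permutations: {self.n_perm} (switches/perm: {self.n_switches}, seed: {self.seed})",
            f"  FDR < 5%:     {int((self.results['fdr'] < 0.05).sum())}",
        ]
        return "\n".join(lines)


class RecurrenceTest:
    """Model object for the per-cancer-type fusion recurrence test.

    Parameters
    ----------
    matrix
        Observed binary occurrence matrix with per-sample cancer types.
    """

    def __init__(self, matrix: OccurrenceMatrix):
        self.matrix = matrix

    @classmethod
    def from_events(
        cls, events: Sequence[FusionEvent], cancer_types: Mapping[str, str]
    ) -> "RecurrenceTest":
        return cls(build_occurrence_matrix(events, cancer_types))

    def fit(
        self,
        n_perm: int = 10000,
        n_switches: int | None = None,
        seed: int | None = None,
        keep_null: bool = False,
    ) -> RecurrenceResults:
        if n_switches is None:
            n_switches = default_n_switches(self.matrix.values)
        null_counts = permutation_null(
            self.matrix, n_perm=n_perm, n_switches=n_switches, seed=seed
        )
        results = empirical_pvalues(self.matrix, null_counts)
        return RecurrenceResults(
            results=results,
            n_perm=n_perm,
            n_switches=n_switches,
            seed=seed,
            null_counts=null_counts if keep_null else None,
        )
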