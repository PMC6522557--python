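import numpy as np
import pandas as pd
import pytest

from fusefit.catalog import FusionTranscript
from fusefit.simulate import SimulationConfig, simulate_bundle


def make_transcript(
    sample="CL001",
    gene5="A",
    gene3="B",
    bp5=1000,
    bp3=5000,
    callers=("defuse", "starfusion"),
    reads=10,
    frame="unknown",
    chrom5="chr1",
    chrom3="chr2",
    strand5="+",
    strand3="+",
):
    return FusionTranscript(
        sample_id=sample, gene5=gene5, gene3=gene3,
        chrom5=chrom5, breakpoint5=bp5, strand5=strand5,
        chrom3=chrom3, breakpoint3=bp3, strand3=strand3,
        supporting_callers=frozenset(callers), max_junction_reads=reads,
        frame=frame,
    )


@pytest.fixture(scope="session")
def bundle():
    """One deterministic synthetic cohort shared across tests."""
    return simulate_bundle(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11,
        n_cell_lines=30,
        n_genes=80,
        n_true_fusions=12,
        n_functional_fusions=2,
        n_expression_fusions=3,
        n_drug_fusions=2,
        n_blacklist_pairs=2,
        n_drugs=8,
        n_cfes=6,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config)


def random_screen(
    rng,
    n_lines=20,
    n_genes=100,
    guides_per_gene=5,
    n_transcripts=10,
    noise_sd=0.25,
    depletion=0.0,
    carrier_col=0,
):
    """Minimal CRISPR screen fixture: library, fold changes, transcripts.

    Genes sit on one chromosome at 10 kb intervals; each transcript fuses
    two distinct genes with mid-gene breakpoints.  ``depletion`` is added
    to mapping guides of the first transcript in the carrier line.
    """
    lines = [f"L{j:02d}" for j in range(n_lines)]
    lib_rows = []
    gene_span = 10_000
    for g in range(n_genes):
        start = 1 + g * gene_span
        for i in range(guides_per_gene):
            lib_rows.append(
                {
                    "guide": f"G{g:03d}_sg{i}",
                    "gene": f"G{g:03d}",
                    "chrom": "chr1",
                    "cut_position": start + (i + 1) * gene_span // (guides_per_gene + 1),
                    "strand": "+",
                }
            )
    library = pd.DataFrame(lib_rows).set_index("guide", drop=False)
    fc = pd.DataFrame(
        rng.normal(0.0, noise_sd, (len(library), n_lines)),
        index=library.index,
        columns=lines,
    )
    tr_rows = []
    for t in range(n_transcripts):
        g5, g3 = 2 * t, 2 * t + 1
        tr_rows.append(
            {
                "transcript_id": f"T{t:02d}",
                "cell_line": lines[(carrier_col + t) % n_lines],
                "gene5": f"G{g5:03d}",
                "chrom5": "chr1",
                "breakpoint5": 1 + g5 * gene_span + gene_span // 2,
                "gene3": f"G{g3:03d}",
                "chrom3": "chr1",
                "breakpoint3": 1 + g3 * gene_span + gene_span // 2,
            }
        )
    transcripts = pd.DataFrame(tr_rows)
    if depletion:
        t0 = transcripts.iloc[0]
        for _, g in library.iterrows():
            if g["gene"] == t0["gene5"] and g["cut_position"] <= t0["breakpoint5"]:
                fc.loc[g["guide"], t0["cell_line"]] += depletion
            if g["gene"] == t0["gene3"] and g["cut_position"] >= t0["breakpoint3"]:
                fc.loc[g["guide"], t0["cell_line"]] += depletion
    return library, fc, transcripts
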