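"""Synthetic inputs with recorded planted truth for every pipeline stage.

The generator emulates the kind of data the triage pipeline consumes —
multi-caller fusion call tables, a log2 RPKM expression matrix with
copy-number confounding, a log IC50 drug-response table with tissue
effects, and pooled CRISPR sgRNA fold-change matrices — with planted
ground truth recorded in a :class:`TruthManifest` so recovery and
calibration are checkable without any external download.

Planted structure:

* true fusions are emitted by at least two callers with >= 4 junction
  reads (minus configured per-caller dropouts) plus breakpoint jitter;
  noise calls are single-caller or low-read and a configured set of gene
  pairs is blacklisted (and still emitted as calls);
* a subset of fusions drives partner-gene expression (3' up, 5' down, on
  top of cancer-type baselines, CNA shifts and Gaussian noise);
* a subset sensitizes carrier lines to one drug, and one *confounded*
  fusion co-occurs with a cancer functional event (CFE) that carries the
  real drug effect;
* functional fusions deplete their mapping sgRNAs in carrier lines only.

Everything is deterministic given ``config.seed``; each generator draws
from its own stream derived from the seed by a fixed offset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

# fixed per-stage offsets into the seed sequence
_STAGE = {
    "annotation": 0,
    "genome": 1,
    "plant": 2,
    "calls": 3,
    "expression": 4,
    "drugs": 5,
    "crispr": 6,
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults describe a desk-scale cohort: 60 cell lines over 4 cancer
    types, 120 genes, 30 true fusions of which 5 are fitness-relevant
    (CRISPR), 8 drive expression and 3 sensitize to a drug.  Effect sizes
    mirror the planted-effect conventions used throughout the test suite:
    log2 expression shifts of +3 (3' oncogene-like) and -2 (5' TSG-like),
    a -3 log IC50 sensitization, and a -1 scaled-fold-change depletion of
    mapping guides against screen noise of sd 0.25.
    """

    seed: int = 0
    # cohort
    n_cell_lines: int = 60
    n_cancer_types: int = 4
    n_replicated_lines: int = 2
    msi_rate: float = 0.15
    # genome
    n_genes: int = 120
    n_chromosomes: int = 4
    gene_min_length: int = 20_000
    gene_max_length: int = 120_000
    intergenic_gap: int = 10_000
    # planted fusions
    n_true_fusions: int = 30
    n_functional_fusions: int = 5
    n_expression_fusions: int = 8
    n_drug_fusions: int = 3
    n_blacklist_pairs: int = 3
    in_frame_rate: float = 0.26
    # caller behaviour
    callers: tuple = ("defuse", "tophatfusion", "starfusion")
    caller_dropout: float = 0.1
    noise_calls_per_sample: float = 3.0
    noise_low_read_fraction: float = 0.8
    true_junction_reads_mean: float = 10.0
    breakpoint_jitter_bp: int = 2
    # expression
    expression_baseline_mean: float = 5.0
    expression_baseline_sd: float = 1.0
    cancer_type_effect_sd: float = 0.5
    residual_sd: float = 1.0
    beta_fusion_5p: float = -2.0
    beta_fusion_3p: float = 3.0
    cna_amp_rate: float = 0.05
    cna_loss_rate: float = 0.05
    cna_effect: float = 1.0
    # drug response
    n_drugs: int = 20
    n_cfes: int = 15
    cfe_rate: float = 0.2
    n_cfe_drug_effects: int = 3
    cfe_effect: float = -2.0
    confounder_effect: float = -3.0
    drug_effect: float = -3.0
    tissue_effect_sd: float = 0.5
    ic50_sd: float = 1.0
    # CRISPR screen
    guides_per_gene_min: int = 5
    guides_per_gene_max: int = 10
    screen_noise_sd: float = 0.25
    depletion_effect: float = -1.0
    essential_mean: float = -1.0
    n_essential_ref: int = 15
    n_nonessential_ref: int = 15
    prescaled: bool = True

    def __post_init__(self):
        for name in ("caller_dropout", "noise_low_read_fraction", "msi_rate",
                     "cna_amp_rate", "cna_loss_rate", "cfe_rate", "in_frame_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        n_special = (
            self.n_functional_fusions + self.n_expression_fusions + self.n_drug_fusions + 1
        )
        if self.n_true_fusions < n_special:
            raise ValueError("n_true_fusions too small for the planted special classes")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "callers" in data:
            data["callers"] = tuple(data["callers"])
        return cls(**data)

    def _rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STAGE[stage]])


@dataclass
class TruthManifest:
    """Planted ground truth, resolvable against the generated files by key."""

    seed: int
    fusions: list = field(default_factory=list)
    cfe_drug_effects: list = field(default_factory=list)
    guide_mapping: dict = field(default_factory=dict)  # fusion_id -> {guide: bool}
    essential_genes: list = field(default_factory=list)
    nonessential_genes: list = field(default_factory=list)

    def fusion(self, fusion_id: str) -> dict:
        for f in self.fusions:
            if f["fusion_id"] == fusion_id:
                return f
        raise KeyError(fusion_id)

    def by_class(self, key: str) -> list:
        return [f for f in self.fusions if f[key]]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# cohort & genome

def cell_line_ids(config: SimulationConfig) -> list[str]:
    return [f"CL{i + 1:03d}" for i in range(config.n_cell_lines)]


def simulate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Sample table: one 'inhouse' sample per line plus replicated 'archive' ones."""
    rng = config._rng("annotation")
    lines = cell_line_ids(config)
    types = [f"CT{(i % config.n_cancer_types) + 1}" for i in range(len(lines))]
    msi = rng.random(len(lines)) < config.msi_rate
    rows = [
        {
            "sample_id": cl,
            "cell_line": cl,
            "source": "inhouse",
            "cancer_type": t,
            "tissue": t,
            "msi": "MSI" if m else "MSS",
        }
        for cl, t, m in zip(lines, types, msi)
    ]
    for cl in lines[: config.n_replicated_lines]:
        base = next(r for r in rows if r["cell_line"] == cl)
        rows.append({**base, "sample_id": f"{cl}-arch", "source": "archive"})
    return pd.DataFrame(rows)


def simulate_genome(config: SimulationConfig) -> pd.DataFrame:
    """Non-overlapping gene intervals with strands, deterministic given seed."""
    if config.n_genes < 2:
        raise ValueError("need at least two genes")
    rng = config._rng("genome")
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    rows = []
    g = 0
    for c in range(config.n_chromosomes):
        pos = 1
        for _ in range(per_chrom):
            if g >= config.n_genes:
                break
            length = int(rng.integers(config.gene_min_length, config.gene_max_length + 1))
            gap = int(rng.integers(1, config.intergenic_gap + 1))
            start = pos + gap
            end = start + length - 1
            rows.append(
                {
                    "gene": f"G{g + 1:04d}",
                    "chrom": f"chr{c + 1}",
                    "start": start,
                    "end": end,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "n_exons": int(rng.integers(3, 25)),
                }
            )
            pos = end + 1
            g += 1
    return pd.DataFrame(rows).set_index("gene", drop=False)


# ---------------------------------------------------------------------------
# planted fusions

def plant_fusions(config: SimulationConfig, genes: pd.DataFrame) -> TruthManifest:
    """Choose fusion gene pairs, breakpoints, carriers and planted classes."""
    rng = config._rng("plant")
    lines = cell_line_ids(config)
    n_pairs = config.n_true_fusions + config.n_blacklist_pairs
    # reserve the tail of the gene list for CRISPR reference sets
    n_reserved = config.n_essential_ref + config.n_nonessential_ref
    eligible = list(genes.index[: len(genes) - n_reserved])
    if len(eligible) < 2 * n_pairs:
        raise ValueError("not enough genes for the requested fusion count")
    chosen = rng.choice(eligible, size=2 * n_pairs, replace=False)
    truth = TruthManifest(seed=config.seed)
    drugs = [f"D{i + 1:03d}" for i in range(config.n_drugs)]

    def _carriers(k: int) -> list[str]:
        return sorted(rng.choice(lines, size=k, replace=False))

    n_func, n_expr, n_drug = (
        config.n_functional_fusions,
        config.n_expression_fusions,
        config.n_drug_fusions,
    )
    for i in range(n_pairs):
        g5, g3 = chosen[2 * i], chosen[2 * i + 1]
        row5, row3 = genes.loc[g5], genes.loc[g3]
        bp5 = int(rng.integers(row5["start"] + 1000, row5["end"] - 1000))
        bp3 = int(rng.integers(row3["start"] + 1000, row3["end"] - 1000))
        blacklisted = i >= config.n_true_fusions
        functional = i < n_func
        drives_expression = n_func <= i < n_func + n_expr
        drugged = n_func + n_expr <= i < n_func + n_expr + n_drug
        confounded = i == n_func + n_expr + n_drug  # exactly one
        if drugged:
            k = int(rng.integers(4, 7))
        elif drives_expression:
            k = int(rng.integers(3, 6))
        elif confounded:
            k = 4
        elif blacklisted:
            k = 2
        elif functional:
            k = int(rng.integers(1, 3))
        else:
            k = 1 if rng.random() < 0.7 else int(rng.integers(2, 4))
        special = functional or drives_expression or drugged or confounded
        truth.fusions.append(
            {
                "fusion_id": f"F{i + 1:03d}",
                "gene5": str(g5),
                "gene3": str(g3),
                "chrom5": str(row5["chrom"]),
                "breakpoint5": bp5,
                "strand5": str(row5["strand"]),
                "chrom3": str(row3["chrom"]),
                "breakpoint3": bp3,
                "strand3": str(row3["strand"]),
                "carriers": _carriers(k),
                "frame": (
                    "in_frame"
                    if special or rng.random() < config.in_frame_rate
                    else "out_of_frame"
                ),
                "functional": bool(functional),
                "drives_expression": bool(drives_expression),
                # the last drug is reserved for the confounded pair and the
                # first n_cfe_drug_effects drugs carry CFE effects
                "drug": drugs[int(rng.integers(config.n_cfe_drug_effects, len(drugs) - 1))]
                if drugged
                else None,
                "confounded": bool(confounded),
                "blacklisted": bool(blacklisted),
                "detectable": not blacklisted,  # refined during call emission
                "detected_in": [],  # carriers with a >=2-caller, >=4-read emission
            }
        )
    return truth


def simulate_fusion_calls(
    config: SimulationConfig,
    truth: TruthManifest,
    annotation: pd.DataFrame,
    genes: pd.DataFrame,
) -> tuple[pd.DataFrame, set]:
    """Per-caller call rows (one combined table) plus the blacklist pairs.

    Updates each planted fusion's ``detectable`` field: emitted by >= 2
    callers with a maximum of >= 4 junction reads in at least one carrier
    sample, and not blacklisted.
    """
    rng = config._rng("calls")
    samples_of_line: dict[str, list[str]] = {}
    for r in annotation.itertuples(index=False):
        samples_of_line.setdefault(r.cell_line, []).append(r.sample_id)
    rows = []

    def _emit(sample, caller, f, reads):
        j5 = int(rng.integers(-config.breakpoint_jitter_bp, config.breakpoint_jitter_bp + 1))
        j3 = int(rng.integers(-config.breakpoint_jitter_bp, config.breakpoint_jitter_bp + 1))
        rows.append(
            {
                "sample_id": sample,
                "caller": caller,
                "gene5": f["gene5"],
                "gene3": f["gene3"],
                "chrom5": f["chrom5"],
                "breakpoint5": max(1, f["breakpoint5"] + j5),
                "strand5": f["strand5"],
                "chrom3": f["chrom3"],
                "breakpoint3": max(1, f["breakpoint3"] + j3),
                "strand3": f["strand3"],
                "junction_reads": int(reads),
                "frame": f["frame"],
            }
        )

    for f in truth.fusions:
        detected_in = []
        for line in f["carriers"]:
            for sample in samples_of_line[line]:
                callers = [c for c in config.callers if rng.random() >= config.caller_dropout]
                reads = [
                    4 + rng.poisson(max(config.true_junction_reads_mean - 4.0, 0.0))
                    for _ in callers
                ]
                for c, r in zip(callers, reads):
                    _emit(sample, c, f, r)
                if sample == line and len(callers) >= 2 and any(r >= 4 for r in reads):
                    detected_in.append(str(line))
        f["detected_in"] = detected_in if not f["blacklisted"] else []
        f["detectable"] = bool(detected_in) and not f["blacklisted"]

    # noise calls: single-caller, or two-caller but low-read
    all_genes = list(genes.index)
    for sample in annotation["sample_id"]:
        for _ in range(rng.poisson(config.noise_calls_per_sample)):
            g5, g3 = rng.choice(all_genes, size=2, replace=False)
            fake = {
                "gene5": str(g5),
                "gene3": str(g3),
                "chrom5": str(genes.loc[g5, "chrom"]),
                "breakpoint5": int(rng.integers(genes.loc[g5, "start"], genes.loc[g5, "end"])),
                "strand5": str(genes.loc[g5, "strand"]),
                "chrom3": str(genes.loc[g3, "chrom"]),
                "breakpoint3": int(rng.integers(genes.loc[g3, "start"], genes.loc[g3, "end"])),
                "strand3": str(genes.loc[g3, "strand"]),
                "frame": "unknown",
            }
            if rng.random() < config.noise_low_read_fraction:
                _emit(sample, str(rng.choice(config.callers)), fake, rng.integers(1, 20))
            else:
                for c in rng.choice(config.callers, size=2, replace=False):
                    _emit(sample, str(c), fake, rng.integers(1, 4))
    calls = pd.DataFrame(rows)
    blacklist = {(f["gene5"], f["gene3"]) for f in truth.fusions if f["blacklisted"]}
    return calls, blacklist


# ---------------------------------------------------------------------------
# expression / CNA

def simulate_expression_cna(
    config: SimulationConfig, truth: TruthManifest, genes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log2 RPKM matrix (genes x lines) and a long CNA category table."""
    rng = config._rng("expression")
    lines = cell_line_ids(config)
    types = [f"CT{(i % config.n_cancer_types) + 1}" for i in range(len(lines))]
    G, S = len(genes), len(lines)
    baseline = rng.normal(config.expression_baseline_mean, config.expression_baseline_sd, G)
    type_names = sorted(set(types))
    type_eff = rng.normal(0.0, config.cancer_type_effect_sd, (G, len(type_names)))
    t_idx = np.array([type_names.index(t) for t in types])
    expr = baseline[:, None] + type_eff[:, t_idx] + rng.normal(0.0, config.residual_sd, (G, S))

    u = rng.random((G, S))
    amp = u < config.cna_amp_rate
    loss = (u >= config.cna_amp_rate) & (u < config.cna_amp_rate + config.cna_loss_rate)
    expr += config.cna_effect * amp - config.cna_effect * loss

    gene_pos = {g: i for i, g in enumerate(genes.index)}
    line_pos = {l: j for j, l in enumerate(lines)}
    for f in truth.fusions:
        if not f["drives_expression"]:
            continue
        for cl in f["carriers"]:
            expr[gene_pos[f["gene3"]], line_pos[cl]] += config.beta_fusion_3p
            expr[gene_pos[f["gene5"]], line_pos[cl]] += config.beta_fusion_5p
    expr_df = pd.DataFrame(expr, index=genes.index, columns=lines)
    gi, si = np.nonzero(amp | loss)
    cna = pd.DataFrame(
        {
            "gene": [genes.index[i] for i in gi],
            "cell_line": [lines[j] for j in si],
            "category": np.where(amp[gi, si], "amplified", "loss"),
        }
    )
    return expr_df, cna


def cna_category_matrix(
    cna: pd.DataFrame, genes, lines
) -> pd.DataFrame:
    """Long CNA table -> genes x lines label matrix (default 'neutral')."""
    mat = pd.DataFrame("neutral", index=list(genes), columns=list(lines))
    for r in cna.itertuples(index=False):
        if r.gene in mat.index and r.cell_line in mat.columns:
            mat.loc[r.gene, r.cell_line] = r.category
    return mat


# ---------------------------------------------------------------------------
# drug response

def simulate_drug_response(
    config: SimulationConfig, truth: TruthManifest, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log IC50 table (drug, cell_line, ic50) and a binary CFE matrix.

    The first ``n_cfe_drug_effects`` CFEs carry a real effect on drugs
    D001..; one extra CFE co-occurs with the planted *confounded* fusion's
    carriers and carries that drug's real effect.
    """
    rng = config._rng("drugs")
    lines = cell_line_ids(config)
    ann = annotation.drop_duplicates("cell_line").set_index("cell_line")
    tissues = ann.loc[lines, "tissue"].tolist()
    drugs = [f"D{i + 1:03d}" for i in range(config.n_drugs)]

    cfes = [f"CFE{i + 1:03d}" for i in range(config.n_cfes)] + ["CFE_CONF"]
    cfe_mat = pd.DataFrame(
        rng.random((config.n_cfes, len(lines))) < config.cfe_rate,
        index=cfes[:-1],
        columns=lines,
    )
    confounded = [f for f in truth.fusions if f["confounded"]]
    conf_drug = drugs[-1]
    conf_lines: list[str] = []
    if confounded:
        conf_lines = list(confounded[0]["carriers"])
        extra = [l for l in lines if l not in conf_lines]
        conf_lines += list(rng.choice(extra, size=min(2, len(extra)), replace=False))
        confounded[0]["drug"] = conf_drug
    cfe_mat.loc["CFE_CONF"] = [l in conf_lines for l in lines]

    truth.cfe_drug_effects = [
        {"cfe": cfes[i], "drug": drugs[i], "effect": config.cfe_effect}
        for i in range(config.n_cfe_drug_effects)
    ] + (
        [{"cfe": "CFE_CONF", "drug": conf_drug, "effect": config.confounder_effect}]
        if confounded
        else []
    )

    tissue_names = sorted(set(tissues))
    tissue_eff = rng.normal(0.0, config.tissue_effect_sd, (len(drugs), len(tissue_names)))
    t_idx = np.array([tissue_names.index(t) for t in tissues])
    ic50 = tissue_eff[:, t_idx] + rng.normal(0.0, config.ic50_sd, (len(drugs), len(lines)))
    for eff in truth.cfe_drug_effects:
        di = drugs.index(eff["drug"])
        ic50[di] += eff["effect"] * cfe_mat.loc[eff["cfe"], lines].to_numpy(float)
    line_pos = {l: j for j, l in enumerate(lines)}
    for f in truth.fusions:
        if f["drug"] is None or f["confounded"]:
            continue  # the confounded fusion has no effect of its own
        di = drugs.index(f["drug"])
        for cl in f["carriers"]:
            ic50[di, line_pos[cl]] += config.drug_effect
    table = pd.DataFrame(
        [
            {"drug": d, "cell_line": l, "ic50": ic50[i, j]}
            for i, d in enumerate(drugs)
            for j, l in enumerate(lines)
        ]
    )
    return table, cfe_mat


# ---------------------------------------------------------------------------
# CRISPR screen

def simulate_crispr_screen(
    config: SimulationConfig, truth: TruthManifest, genes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, list[str], list[str]]:
    """Guide library, fold-change matrix and the two reference gene lists.

    Fold changes are emitted on the already-corrected, scaled convention
    (non-essential background centred at 0, essential reference genes at
    -1) unless ``config.prescaled`` is False, in which case each cell line
    is given its own raw anchors for :func:`fusefit.crispr.scale_to_essentials`
    to undo.
    """
    rng = config._rng("crispr")
    lines = cell_line_ids(config)
    n_res = config.n_essential_ref + config.n_nonessential_ref
    essential = list(map(str, genes.index[-n_res : -config.n_nonessential_ref]))
    noness = list(map(str, genes.index[-config.n_nonessential_ref :]))
    truth.essential_genes = essential
    truth.nonessential_genes = noness

    lib_rows = []
    for g, row in genes.iterrows():
        k = int(rng.integers(config.guides_per_gene_min, config.guides_per_gene_max + 1))
        cuts = np.sort(rng.integers(row["start"], row["end"] + 1, size=k))
        for i, cut in enumerate(cuts):
            lib_rows.append(
                {
                    "guide": f"{g}_sg{i + 1}",
                    "gene": str(g),
                    "chrom": str(row["chrom"]),
                    "cut_position": int(cut),
                    "strand": str(row["strand"]),
                }
            )
    library = pd.DataFrame(lib_rows).set_index("guide", drop=False)

    gene_mean = pd.Series(0.0, index=genes.index)
    gene_mean.loc[essential] = config.essential_mean
    base = gene_mean.loc[library["gene"]].to_numpy(float)
    fc = base[:, None] + rng.normal(0.0, config.screen_noise_sd, (len(library), len(lines)))

    line_pos = {l: j for j, l in enumerate(lines)}
    guide_pos = {g: i for i, g in enumerate(library.index)}
    for f in truth.fusions:
        mapping_status = {}
        for end, gene_key, bp_key in (("5p", "gene5", "breakpoint5"), ("3p", "gene3", "breakpoint3")):
            sub = library[library["gene"] == f[gene_key]]
            bp = f[bp_key]
            strand = f[f"strand{end[0]}"]
            for guide, cut in zip(sub.index, sub["cut_position"]):
                if end == "5p":
                    maps = cut <= bp if strand == "+" else cut >= bp
                else:
                    maps = cut >= bp if strand == "+" else cut <= bp
                mapping_status[str(guide)] = bool(maps)
        truth.guide_mapping[f["fusion_id"]] = mapping_status
        if not f["functional"]:
            continue
        for guide, maps in mapping_status.items():
            if maps:
                for cl in f["carriers"]:
                    fc[guide_pos[guide], line_pos[cl]] += config.depletion_effect

    if not config.prescaled:
        m_e = rng.normal(-2.0, 0.1, len(lines))
        m_ne = rng.normal(0.0, 0.05, len(lines))
        fc = fc * (m_ne - m_e)[None, :] + m_ne[None, :]
    fold_changes = pd.DataFrame(fc, index=library.index, columns=lines)
    return library, fold_changes, essential, noness


# ---------------------------------------------------------------------------
# bundle + file output

@dataclass
class SimulatedBundle:
    """All pipeline inputs in memory, plus the truth manifest."""

    config: SimulationConfig
    truth: TruthManifest
    annotation: pd.DataFrame
    genes: pd.DataFrame
    calls: pd.DataFrame
    blacklist: set
    expression: pd.DataFrame
    cna: pd.DataFrame
    ic50: pd.DataFrame
    cfe_matrix: pd.DataFrame
    library: pd.DataFrame
    fold_changes: pd.DataFrame
    essential_genes: list
    nonessential_genes: list


def simulate_bundle(config: SimulationConfig) -> SimulatedBundle:
    """Run every generator in dependency order; fully in memory."""
    annotation = simulate_annotation(config)
    genes = simulate_genome(config)
    truth = plant_fusions(config, genes)
    calls, blacklist = simulate_fusion_calls(config, truth, annotation, genes)
    expression, cna = simulate_expression_cna(config, truth, genes)
    ic50, cfe_matrix = simulate_drug_response(config, truth, annotation)
    library, fold_changes, ess, noness = simulate_crispr_screen(config, truth, genes)
    return SimulatedBundle(
        config=config, truth=truth, annotation=annotation, genes=genes,
        calls=calls, blacklist=blacklist, expression=expression, cna=cna,
        ic50=ic50, cfe_matrix=cfe_matrix, library=library,
        fold_changes=fold_changes, essential_genes=ess, nonessential_genes=noness,
    )


def simulate_all(config: SimulationConfig, outdir: str | Path) -> SimulatedBundle:
    """Write every pipeline input plus the truth manifest to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    b = simulate_bundle(config)
    ff = "%.6g"
    b.calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
    with open(outdir / "blacklist.tsv", "w") as fh:
        for g5, g3 in sorted(b.blacklist):
            fh.write(f"{g5}\t{g3}\n")
    b.annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    b.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    b.expression.to_csv(outdir / "expression.tsv", sep="\t", float_format=ff,
                        index_label="gene")
    b.cna.to_csv(outdir / "cna.tsv", sep="\t", index=False)
    b.ic50.to_csv(outdir / "ic50.tsv", sep="\t", float_format=ff, index=False)
    b.cfe_matrix.astype(int).to_csv(outdir / "cfe.tsv", sep="\t", index_label="feature")
    b.library.to_csv(outdir / "library.tsv", sep="\t", index=False)
    b.fold_changes.to_csv(outdir / "foldchanges.tsv", sep="\t", float_format=ff,
                          index_label="guide")
    for name, lst in (("essentials.txt", b.essential_genes),
                      ("nonessentials.txt", b.nonessential_genes)):
        with open(outdir / name, "w") as fh:
            fh.write("\n".join(lst) + "\n")
    functional_pairs = sorted(
        f"{f['gene5']}--{f['gene3']}" for f in b.truth.fusions if f["functional"]
    )
    with open(outdir / "sets.gmt", "w") as fh:
        fh.write("functional_truth\tplanted fitness-relevant fusions\t"
                 + "\t".join(functional_pairs) + "\n")
    b.truth.to_json(outdir / "truth.json")
    return b
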