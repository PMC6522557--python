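"""End-to-end orchestration: catalog -> recurrence / expression / drug / FES -> enrichment.

A single :class:`RunConfig` names every input file and stage parameter;
:func:`run_all` executes the stages in dependency order, writes one
tab-separated table per stage and a machine-readable JSON manifest
recording the package version, per-stage seeds, parameter values and
SHA-256 digests of the inputs.  Stage seeds derive from the global seed by
fixed offsets so each stochastic stage is independently reproducible, and
no output embeds a timestamp: re-running with the same config and seed
reproduces every file byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, catalog, crispr, drugs, enrichment, expression, recurrence

logger = logging.getLogger("fusefit")

# fixed offsets from the global seed, one per stochastic stage
SEED_OFFSETS = {"recurrence": 101, "fes": 202, "enrichment": 303}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Input paths and stage parameters for a full pipeline run."""

    # inputs
    calls: str = "calls.tsv"
    blacklist: str = "blacklist.tsv"
    annotation: str = "annotation.tsv"
    expression: str = "expression.tsv"
    cna: str = "cna.tsv"
    ic50: str = "ic50.tsv"
    cfe: str = "cfe.tsv"
    library: str = "library.tsv"
    foldchanges: str = "foldchanges.tsv"
    essentials: str | None = None
    nonessentials: str | None = None
    gmt: str | None = None
    # catalog
    min_junction_reads: int = 4
    min_callers: int = 2
    breakpoint_tolerance_bp: int = 5
    source_precedence: tuple = ("inhouse", "archive")
    # recurrence
    recurrence_n_perm: int = 1000
    # expression
    min_samples: int = 3
    # drugs
    drug_fdr_max: float = 0.25
    drug_p_max: float = 0.001
    drug_delta_min: float = 1.0
    # FES
    fes_n_perm: int = 1000
    fes_fdr: float = 0.05
    fes_min_diff: float = 0.45
    prescaled: bool = True
    # enrichment
    enrich_n_perm: int = 1000
    enrich_weight: float = 1.0
    # global
    seed: int = 0
    input_dir: str = "."

    def resolve(self, name: str) -> Path:
        return Path(self.input_dir) / getattr(self, name)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown run-config fields: {sorted(unknown)}")
        if "source_precedence" in data:
            data["source_precedence"] = tuple(data["source_precedence"])
        cfg = cls(**data)
        if "input_dir" not in data:
            cfg.input_dir = str(Path(path).parent)
        return cfg

    def required_inputs(self) -> list[str]:
        names = ["calls", "blacklist", "annotation", "expression", "cna",
                 "ic50", "cfe", "library", "foldchanges"]
        if not self.prescaled:
            names += ["essentials", "nonessentials"]
        if self.gmt is not None:
            names.append("gmt")
        return names


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class PipelineRun:
    outdir: Path
    manifest: dict = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return pd.read_csv(self.outdir / f"{name}.tsv", sep="\t")


def run_all(config: RunConfig, outdir: str | Path) -> PipelineRun:
    """Execute every stage; any failure halts with the stage name and cause.

    Outputs written up to the failing stage are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    missing = [
        str(config.resolve(n)) for n in config.required_inputs()
        if not config.resolve(n).exists()
    ]
    if missing:
        raise FileNotFoundError("missing input files: " + ", ".join(missing))

    manifest: dict = {
        "package": "fusefit",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {k: config.seed + v for k, v in SEED_OFFSETS.items()},
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "inputs": {
            n: {"path": getattr(config, n), "sha256": _sha256(config.resolve(n))}
            for n in config.required_inputs()
        },
        "outputs": [],
    }

    def _emit(name: str, df: pd.DataFrame) -> None:
        _write(df, outdir / f"{name}.tsv")
        manifest["outputs"].append(f"{name}.tsv")

    annotation = pd.read_csv(config.resolve("annotation"), sep="\t")
    sample_sources = dict(zip(annotation["sample_id"], annotation["source"]))
    sample_cells = dict(zip(annotation["sample_id"], annotation["cell_line"]))
    cancer_types = dict(
        annotation.drop_duplicates("cell_line")[["cell_line", "cancer_type"]].itertuples(
            index=False, name=None
        )
    )

    # --- catalog -----------------------------------------------------------
    stage = "catalog"
    try:
        logger.info("stage %s", stage)
        parsed = catalog.read_fusion_calls(config.resolve("calls"))
        merged = catalog.merge_calls(parsed.calls, config.breakpoint_tolerance_bp)
        removal_log: list = []
        filtered = catalog.filter_transcripts(
            merged,
            min_junction_reads=config.min_junction_reads,
            min_callers=config.min_callers,
            blacklist=catalog.read_blacklist(config.resolve("blacklist")),
            removal_log=removal_log,
        )
        deduped = catalog.deduplicate_samples(
            filtered, sample_sources, list(config.source_precedence), sample_cells
        )
        events = catalog.aggregate_events(deduped, sample_cells)
        summary = catalog.summarize_catalog(events, cancer_types, n_transcripts=len(deduped))
        _emit("transcripts", catalog.transcripts_to_frame(deduped))
        _emit("events", catalog.events_to_frame(events))
        _emit("catalog_summary", summary.to_frame())
        _emit(
            "removals",
            pd.DataFrame(
                [{"transcript_id": t.transcript_id, "sample_id": t.sample_id, "reason": r}
                 for t, r in removal_log]
            ),
        )
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc

    # --- recurrence --------------------------------------------------------
    stage = "recurrence"
    try:
        logger.info("stage %s", stage)
        rec = recurrence.RecurrenceTest.from_events(events, cancer_types).fit(
            n_perm=config.recurrence_n_perm,
            seed=config.seed + SEED_OFFSETS["recurrence"],
        )
        _emit("recurrence", rec.results)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- expression --------------------------------------------------------
    stage = "expression"
    try:
        logger.info("stage %s", stage)
        expr = pd.read_csv(config.resolve("expression"), sep="\t", index_col=0)
        cna_long = pd.read_csv(config.resolve("cna"), sep="\t")
        covars = (
            annotation.drop_duplicates("cell_line")
            .set_index("cell_line")[["cancer_type", "msi"]]
            .reindex(expr.columns)
        )
        from .simulate import cna_category_matrix

        cna_mat = cna_category_matrix(cna_long, expr.index, expr.columns)
        assoc = expression.run_expression_screen(
            events, expr, covariates=covars, cna_categories=cna_mat,
            min_samples=config.min_samples,
        )
        amplified = {
            (r.gene, r.cell_line)
            for r in cna_long.itertuples(index=False)
            if r.category == "amplified"
        }
        flags = expression.flag_overexpression(events, expr, amplified)
        _emit("expression_assoc", assoc)
        _emit(
            "overexpression",
            pd.DataFrame(
                [
                    {
                        "cell_line": f.cell_line, "gene5": f.gene5, "gene3": f.gene3,
                        "carrier_expression": f.carrier_expression,
                        "percentile_rank": f.percentile_rank,
                        "amplified": f.amplified, "flagged": f.flagged,
                        "testable": f.testable,
                    }
                    for f in flags
                ]
            ),
        )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- drugs -------------------------------------------------------------
    stage = "drugs"
    try:
        logger.info("stage %s", stage)
        ic50 = pd.read_csv(config.resolve("ic50"), sep="\t")
        cfe_mat = pd.read_csv(config.resolve("cfe"), sep="\t", index_col=0).astype(bool)
        covars_d = (
            annotation.drop_duplicates("cell_line")
            .set_index("cell_line")[["tissue", "msi"]]
        )
        stage1 = drugs.run_cfe_drug_screen(
            cfe_mat, ic50, covars_d,
            fdr_max=config.drug_fdr_max, delta_min=config.drug_delta_min,
        )
        selected = drugs.select_cfe_covariates(
            stage1, fdr_max=config.drug_fdr_max, p_max=config.drug_p_max,
            delta_min=config.drug_delta_min,
        )
        ev_df = catalog.events_to_frame(events)
        pair_counts = ev_df.groupby(["gene5", "gene3"])["cell_line"].nunique()
        recurrent = pair_counts[pair_counts >= 2].index
        lines = sorted(set(ic50["cell_line"]) | set(ev_df["cell_line"]))
        fusion_features = pd.DataFrame(False, index=[f"{a}--{b}" for a, b in recurrent], columns=lines)
        for (a, b) in recurrent:
            carriers = ev_df[(ev_df["gene5"] == a) & (ev_df["gene3"] == b)]["cell_line"]
            fusion_features.loc[f"{a}--{b}", [c for c in carriers if c in lines]] = True
        stage2 = drugs.run_fusion_drug_screen(
            fusion_features, ic50, covars_d, selected, cfe_mat,
            fdr_max=config.drug_fdr_max, delta_min=config.drug_delta_min,
        )
        _emit("drug_stage1", stage1.frame)
        _emit("drug_stage2", stage2.frame)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- FES ---------------------------------------------------------------
    stage = "fes"
    try:
        logger.info("stage %s", stage)
        library = pd.read_csv(config.resolve("library"), sep="\t").set_index("guide", drop=False)
        fc = pd.read_csv(config.resolve("foldchanges"), sep="\t", index_col=0)
        tr_frame = catalog.transcripts_to_frame(deduped)
        tr_frame["cell_line"] = tr_frame["sample_id"].map(lambda s: sample_cells.get(s, s))
        fes_input = tr_frame[
            ["transcript_id", "cell_line", "gene5", "chrom5", "breakpoint5",
             "gene3", "chrom3", "breakpoint3"]
        ]
        kwargs: dict = {"prescaled": config.prescaled}
        if not config.prescaled:
            kwargs["essential_genes"] = [
                l.strip() for l in open(config.resolve("essentials")) if l.strip()
            ]
            kwargs["nonessential_genes"] = [
                l.strip() for l in open(config.resolve("nonessentials")) if l.strip()
            ]
        screen = crispr.FesScreen(library, fc, fes_input, dataset="screen", **kwargs)
        fes_res = screen.fit(
            n_perm=config.fes_n_perm,
            seed=config.seed + SEED_OFFSETS["fes"],
            fdr_threshold=config.fes_fdr,
            min_diff=config.fes_min_diff,
        )
        fes_events = crispr.aggregate_events_fes([fes_res])
        _emit("fes", fes_res.frame)
        _emit("fes_events", fes_events)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- enrichment --------------------------------------------------------
    stage = "enrichment"
    try:
        logger.info("stage %s", stage)
        testable = fes_res.frame[fes_res.frame["testable"].astype(bool)]
        if len(testable) and config.gmt is not None:
            pair_scores = (
                testable.assign(pair=testable["gene5"] + "--" + testable["gene3"])
                .groupby("pair")["fes"]
                .min()
            )
            # most depleted first
            ranked = enrichment.rank_scores(-pair_scores)
            sets = enrichment.read_gmt(config.resolve("gmt"))
            rows = []
            for name, members in sorted(sets.items()):
                hit = set(members) & set(ranked.index)
                if not hit or len(hit) == len(ranked):
                    continue
                res = enrichment.enrichment_pvalue(
                    ranked, hit, n_perm=config.enrich_n_perm,
                    weight_exponent=config.enrich_weight,
                    seed=config.seed + SEED_OFFSETS["enrichment"], set_name=name,
                )
                rows.append(
                    {"set": res.set_name, "es": res.es, "p_value": res.p_value,
                     "n_set": res.n_set, "n_total": res.n_total}
                )
            _emit("enrichment", pd.DataFrame(rows, columns=["set", "es", "p_value", "n_set", "n_total"]))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return PipelineRun(outdir=outdir, manifest=manifest)
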