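"""Consensus fusion-transcript catalog.

Fusion callers applied to bulk RNA-seq are noisy, so calls from several
algorithms are merged per sample into breakpoint-level *fusion transcripts*
and filtered: a transcript is kept only if it is supported by at least two
callers, at least one caller reports four or more reads spanning the
junction, and the gene pair is not on a normal-tissue blacklist.  Filtered
transcripts are then collapsed into *fusion events* — the presence of any
fusion between an ordered (5', 3') gene pair in one cell line — and
summarized cohort-wide (unique fusions, recurrent fusions, per-cancer-type
event counts).

Coordinates are 1-based and inclusive throughout: ``breakpoint5`` is the
last base of the 5' segment retained in the chimera, ``breakpoint3`` the
first retained base of the 3' segment.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._stats import percent

VALID_STRANDS = frozenset({"+", "-"})
VALID_FRAMES = frozenset({"in_frame", "out_of_frame", "unknown"})

#: Default column names expected in a tab-separated calls table.
CALL_COLUMNS = (
    "sample_id",
    "caller",
    "gene5",
    "gene3",
    "chrom5",
    "breakpoint5",
    "strand5",
    "chrom3",
    "breakpoint3",
    "strand3",
    "junction_reads",
    "frame",
)


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


@dataclass(frozen=True)
class RawFusionCall:
    """One caller-specific fusion call in one sample."""

    sample_id: str
    caller: str
    gene5: str
    gene3: str
    chrom5: str
    breakpoint5: int
    strand5: str
    chrom3: str
    breakpoint3: int
    strand3: str
    junction_reads: int
    frame: str = "unknown"

    def __post_init__(self):
        if self.junction_reads < 0:
            raise ValueError("junction_reads must be non-negative")
        if self.strand5 not in VALID_STRANDS or self.strand3 not in VALID_STRANDS:
            raise ValueError(f"invalid strand: {self.strand5!r}/{self.strand3!r}")
        if self.breakpoint5 < 1 or self.breakpoint3 < 1:
            raise ValueError("breakpoints are 1-based; must be >= 1")
        if self.frame not in VALID_FRAMES:
            raise ValueError(f"invalid frame label: {self.frame!r}")


@dataclass
class FusionTranscript:
    """A merged breakpoint-level fusion call in one sample.

    The representative breakpoints come from the supporting call with the
    most junction reads; ``supporting_callers`` is the union across the
    merged calls and ``max_junction_reads`` their maximum.
    """

    sample_id: str
    gene5: str
    gene3: str
    chrom5: str
    breakpoint5: int
    strand5: str
    chrom3: str
    breakpoint3: int
    strand3: str
    supporting_callers: frozenset
    max_junction_reads: int
    frame: str = "unknown"
    source: str | None = None

    @property
    def transcript_key(self) -> tuple:
        return (self.gene5, self.gene3, self.breakpoint5, self.breakpoint3)

    @property
    def transcript_id(self) -> str:
        return f"{self.gene5}--{self.gene3}@{self.breakpoint5}:{self.breakpoint3}"

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)


@dataclass(frozen=True)
class FusionEvent:
    """Presence of any fusion between an ordered gene pair in one cell line."""

    cell_line: str
    gene5: str
    gene3: str
    transcript_count: int
    any_in_frame: bool

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)


@dataclass
class CatalogSummary:
    n_transcripts: int
    n_events: int
    n_unique_fusions: int
    n_recurrent_fusions: int
    recurrent_percent: float
    fraction_in_frame: float
    events_per_type: dict = field(default_factory=dict)
    median_events_per_type: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_transcripts", self.n_transcripts),
            ("n_events", self.n_events),
            ("n_unique_fusions", self.n_unique_fusions),
            ("n_recurrent_fusions", self.n_recurrent_fusions),
            ("recurrent_percent", self.recurrent_percent),
            ("fraction_in_frame", round(self.fraction_in_frame, 6)),
        ]
        for t in sorted(self.events_per_type):
            rows.append((f"events[{t}]", self.events_per_type[t]))
        for t in sorted(self.median_events_per_type):
            rows.append((f"median_events_per_line[{t}]", self.median_events_per_type[t]))
        return pd.DataFrame(rows, columns=["statistic", "value"])


@dataclass
class ParseResult:
    """Parsed calls plus row-level diagnostics for rejected rows."""

    calls: list
    rejected: list  # (line_number, reason)


def read_fusion_calls(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> ParseResult:
    """Read a tab-separated calls table, validating each row.

    ``schema`` maps the canonical field names (:data:`CALL_COLUMNS`) to the
    actual column headers in the file; identity by default.  Malformed rows
    are rejected individually with their 1-based line number, never
    aborting the parse.
    """
    schema = dict(schema or {})
    colmap = {name: schema.get(name, name) for name in CALL_COLUMNS}
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {', '.join(missing)}")
    calls: list[RawFusionCall] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        rec = {name: getattr(row, colmap[name]) for name in CALL_COLUMNS}
        try:
            call = RawFusionCall(
                sample_id=str(rec["sample_id"]),
                caller=str(rec["caller"]),
                gene5=str(rec["gene5"]),
                gene3=str(rec["gene3"]),
                chrom5=str(rec["chrom5"]),
                breakpoint5=int(rec["breakpoint5"]),
                strand5=str(rec["strand5"]),
                chrom3=str(rec["chrom3"]),
                breakpoint3=int(rec["breakpoint3"]),
                strand3=str(rec["strand3"]),
                junction_reads=int(rec["junction_reads"]),
                frame=str(rec["frame"]),
            )
        except (ValueError, TypeError) as exc:
            rejected.append((line_no, str(exc)))
            continue
        calls.append(call)
    return ParseResult(calls=calls, rejected=rejected)


def _consensus_frame(frames: Iterable[str]) -> str:
    frames = set(frames)
    if "in_frame" in frames:
        return "in_frame"
    if "out_of_frame" in frames:
        return "out_of_frame"
    return "unknown"


def merge_calls(
    calls: Sequence[RawFusionCall], breakpoint_tolerance_bp: int = 5
) -> list[FusionTranscript]:
    """Merge per-caller calls into fusion transcripts (pre-filter).

    Calls in the same sample with the same ordered gene pair and both
    breakpoints within ``breakpoint_tolerance_bp`` of a cluster's
    representative are one transcript.  Clustering is greedy by descending
    junction reads so the representative breakpoints always come from the
    best-supported call.
    """
    if breakpoint_tolerance_bp < 0:
        raise ValueError("tolerance must be >= 0")
    groups: dict[tuple, list[RawFusionCall]] = {}
    for c in calls:
        groups.setdefault((c.sample_id, c.gene5, c.gene3), []).append(c)
    transcripts: list[FusionTranscript] = []
    for members in groups.values():
        members = sorted(
            members, key=lambda c: (-c.junction_reads, c.caller, c.breakpoint5)
        )
        clusters: list[list[RawFusionCall]] = []
        for c in members:
            for cluster in clusters:
                rep = cluster[0]
                if (
                    rep.chrom5 == c.chrom5
                    and rep.chrom3 == c.chrom3
                    and abs(rep.breakpoint5 - c.breakpoint5) <= breakpoint_tolerance_bp
                    and abs(rep.breakpoint3 - c.breakpoint3) <= breakpoint_tolerance_bp
                ):
                    cluster.append(c)
                    break
            else:
                clusters.append([c])
        for cluster in clusters:
            rep = cluster[0]
            transcripts.append(
                FusionTranscript(
                    sample_id=rep.sample_id,
                    gene5=rep.gene5,
                    gene3=rep.gene3,
                    chrom5=rep.chrom5,
                    breakpoint5=rep.breakpoint5,
                    strand5=rep.strand5,
                    chrom3=rep.chrom3,
                    breakpoint3=rep.breakpoint3,
                    strand3=rep.strand3,
                    supporting_callers=frozenset(c.caller for c in cluster),
                    max_junction_reads=max(c.junction_reads for c in cluster),
                    frame=_consensus_frame(c.frame for c in cluster),
                )
            )
    transcripts.sort(key=lambda t: (t.sample_id, t.gene5, t.gene3, t.breakpoint5))
    return transcripts


def filter_transcripts(
    transcripts: Sequence[FusionTranscript],
    min_junction_reads: int = 4,
    min_callers: int = 2,
    blacklist: Iterable[tuple[str, str]] = (),
    removal_log: list | None = None,
) -> list[FusionTranscript]:
    """Apply the consensus filtering criteria.

    Retains transcripts supported by >= ``min_callers`` algorithms with a
    maximum junction-read count >= ``min_junction_reads`` whose ordered gene
    pair is not blacklisted.  Self-pairs (gene5 == gene3, read-through
    artifacts) are also removed.  Removal reasons are appended to
    ``removal_log`` as ``(transcript, reason)`` when a list is supplied.
    """
    if min_junction_reads < 1 or min_callers < 1:
        raise ValueError("thresholds must be >= 1")
    blacklist = set(blacklist)
    kept = []
    for t in transcripts:
        reasons = []
        if len(t.supporting_callers) < min_callers:
            reasons.append("too_few_callers")
        if t.max_junction_reads < min_junction_reads:
            reasons.append("too_few_junction_reads")
        if t.gene_pair in blacklist:
            reasons.append("blacklisted")
        if t.gene5 == t.gene3:
            reasons.append("self_pair")
        if reasons:
            if removal_log is not None:
                removal_log.append((t, ";".join(reasons)))
        else:
            kept.append(t)
    return kept


def deduplicate_samples(
    transcripts: Sequence[FusionTranscript],
    sample_sources: Mapping[str, str],
    source_precedence: Sequence[str],
    sample_cell_lines: Mapping[str, str] | None = None,
) -> list[FusionTranscript]:
    """Resolve replicated cell lines to a single data source.

    For cell lines sequenced under more than one source, only transcripts
    from the highest-precedence source (first match in
    ``source_precedence``) are taken forward.  ``sample_cell_lines`` maps
    sample ids to cell-line ids; identity when omitted.
    """
    if not source_precedence:
        raise ValueError("source precedence list is empty")
    rank = {s: i for i, s in enumerate(source_precedence)}
    cell_of = dict(sample_cell_lines or {})

    def _cell(sample_id: str) -> str:
        return cell_of.get(sample_id, sample_id)

    best: dict[str, int] = {}
    for t in transcripts:
        if t.sample_id not in sample_sources:
            raise ValueError(f"sample {t.sample_id!r} has no source annotation")
        src = sample_sources[t.sample_id]
        r = rank.get(src, len(rank) + 1)
        cl = _cell(t.sample_id)
        best[cl] = min(best.get(cl, r), r)
    out = []
    for t in transcripts:
        src = sample_sources[t.sample_id]
        r = rank.get(src, len(rank) + 1)
        if r == best[_cell(t.sample_id)]:
            out.append(replace(t, source=src))
    return out


def aggregate_events(
    transcripts: Sequence[FusionTranscript],
    sample_cell_lines: Mapping[str, str] | None = None,
) -> list[FusionEvent]:
    """Collapse transcripts into one event per (cell line, ordered gene pair)."""
    cell_of = dict(sample_cell_lines or {})
    buckets: dict[tuple, list[FusionTranscript]] = {}
    for t in transcripts:
        cl = cell_of.get(t.sample_id, t.sample_id)
        buckets.setdefault((cl, t.gene5, t.gene3), []).append(t)
    events = [
        FusionEvent(
            cell_line=cl,
            gene5=g5,
            gene3=g3,
            transcript_count=len(ts),
            any_in_frame=any(t.frame == "in_frame" for t in ts),
        )
        for (cl, g5, g3), ts in buckets.items()
    ]
    events.sort(key=lambda e: (e.cell_line, e.gene5, e.gene3))
    return events


def summarize_catalog(
    events: Sequence[FusionEvent],
    cancer_types: Mapping[str, str],
    n_transcripts: int | None = None,
) -> CatalogSummary:
    """Cohort-level catalog summary.

    ``cancer_types`` maps every cell line in the cohort (including lines
    with zero events) to its cancer type; an event whose line is missing
    from the map is an error.  A unique fusion is a distinct ordered gene
    pair; it is recurrent when seen as an event in >= 2 cell lines.  The
    recurrent percentage is half-away rounded to the nearest integer.
    """
    for e in events:
        if e.cell_line not in cancer_types:
            raise ValueError(f"cell line {e.cell_line!r} has no cancer-type annotation")
    pair_lines: dict[tuple, set] = {}
    per_line: dict[str, int] = {cl: 0 for cl in cancer_types}
    for e in events:
        pair_lines.setdefault(e.gene_pair, set()).add(e.cell_line)
        per_line[e.cell_line] += 1
    n_unique = len(pair_lines)
    n_recurrent = sum(1 for lines in pair_lines.values() if len(lines) >= 2)
    by_type: dict[str, list[int]] = {}
    for cl, t in cancer_types.items():
        by_type.setdefault(t, []).append(per_line[cl])
    return CatalogSummary(
        n_transcripts=(
            n_transcripts
            if n_transcripts is not None
            else sum(e.transcript_count for e in events)
        ),
        n_events=len(events),
        n_unique_fusions=n_unique,
        n_recurrent_fusions=n_recurrent,
        recurrent_percent=percent(n_recurrent, n_unique) if n_unique else 0.0,
        fraction_in_frame=(
            sum(e.any_in_frame for e in events) / len(events) if events else 0.0
        ),
        events_per_type={t: sum(v) for t, v in by_type.items()},
        median_events_per_type={t: statistics.median(v) for t, v in by_type.items()},
    )


# ---------------------------------------------------------------------------
# tabular I/O

def read_blacklist(path: str | Path) -> set[tuple[str, str]]:
    """Two-column tab-separated (gene5, gene3) pairs; '#' comments allowed."""
    pairs = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"blacklist line has fewer than two columns: {line!r}")
            pairs.add((fields[0], fields[1]))
    return pairs


def transcripts_to_frame(transcripts: Sequence[FusionTranscript]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": t.transcript_id,
                "sample_id": t.sample_id,
                "gene5": t.gene5,
                "gene3": t.gene3,
                "chrom5": t.chrom5,
                "breakpoint5": t.breakpoint5,
                "strand5": t.strand5,
                "chrom3": t.chrom3,
                "breakpoint3": t.breakpoint3,
                "strand3": t.strand3,
                "n_callers": len(t.supporting_callers),
                "callers": ",".join(sorted(t.supporting_callers)),
                "max_junction_reads": t.max_junction_reads,
                "frame": t.frame,
                "source": t.source if t.source is not None else "",
            }
            for t in transcripts
        ],
        columns=[
            "transcript_id", "sample_id", "gene5", "gene3", "chrom5",
            "breakpoint5", "strand5", "chrom3", "breakpoint3", "strand3",
            "n_callers", "callers", "max_junction_reads", "frame", "source",
        ],
    )


def events_to_frame(events: Sequence[FusionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_line": e.cell_line,
                "gene5": e.gene5,
                "gene3": e.gene3,
                "transcript_count": e.transcript_count,
                "any_in_frame": e.any_in_frame,
            }
            for e in events
        ],
        columns=["cell_line", "gene5", "gene3", "transcript_count", "any_in_frame"],
    )


def events_from_frame(df: pd.DataFrame) -> list[FusionEvent]:
    return [
        FusionEvent(
            cell_line=str(r.cell_line),
            gene5=str(r.gene5),
            gene3=str(r.gene3),
            transcript_count=int(r.transcript_count),
            any_in_frame=bool(r.any_in_frame),
        )
        for r in df.itertuples(index=False)
    ]
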