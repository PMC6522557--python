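
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusefit import catalog
from fusefit.catalog import (
    RawFusionCall,
    SchemaError,
    aggregate_events,
    deduplicate_samples,
    filter_transcripts,
    merge_calls,
    read_fusion_calls,
    summarize_catalog,
)

from .conftest import make_transcript

HEADER = "\t".join(catalog.CALL_COLUMNS)


def _row(sample="S1", caller="defuse", g5="A", g3="B", bp5=1000, bp3=5000,
         strand5="+", strand3="+", reads=10, frame="unknown"):
    return "\t".join(map(str, [sample, caller, g5, g3, "chr1", bp5, strand5,
                               "chr2", bp3, strand3, reads, frame]))


def _call(**kw):
    defaults = dict(sample_id="S1", caller="defuse", gene5="A", gene3="B",
                    chrom5="chr1", breakpoint5=1000, strand5="+",
                    chrom3="chr2", breakpoint3=5000, strand3="+",
                    junction_reads=10, frame="unknown")
    defaults.update(kw)
    return RawFusionCall(**defaults)


class TestReadFusionCalls:
    def test_well_formed_rows_parse(self, tmp_path):
        p = tmp_path / "calls.tsv"
        p.write_text(HEADER + "\n" + "\n".join(
            [_row(), _row(caller="starfusion"), _row(g5="C", g3="D")]) + "\n")
        res = read_fusion_calls(p)
        assert len(res.calls) == 3 and not res.rejected

    def test_invalid_strand_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "calls.tsv"
        p.write_text(HEADER + "\n" + _row() + "\n" + _row(strand5=".") + "\n")
        res = read_fusion_calls(p)
        assert len(res.calls) == 1
        assert res.rejected[0][0] == 3 and "strand" in res.rejected[0][1]

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "calls.tsv"
        p.write_text(HEADER + "\n")
        assert read_fusion_calls(p).calls == []

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "calls.tsv"
        p.write_text("sample_id\tcaller\nS1\tdefuse\n")
        with pytest.raises(SchemaError, match="gene5"):
            read_fusion_calls(p)

    def test_schema_remaps_column_names(self, tmp_path):
        header = HEADER.replace("sample_id", "cell")
        p = tmp_path / "calls.tsv"
        p.write_text(header + "\n" + _row() + "\n")
        res = read_fusion_calls(p, schema={"sample_id": "cell"})
        assert res.calls[0].sample_id == "S1"


class TestMergeCalls:
    def test_within_tolerance_is_one_transcript(self):
        calls = [_call(caller="defuse", breakpoint5=1000, junction_reads=8),
                 _call(caller="tophatfusion", breakpoint5=1003, junction_reads=5)]
        merged = merge_calls(calls, breakpoint_tolerance_bp=5)
        assert len(merged) == 1
        t = merged[0]
        assert t.supporting_callers == {"defuse", "tophatfusion"}
        # representative breakpoints come from the best-supported call
        assert t.breakpoint5 == 1000 and t.max_junction_reads == 8

    def test_beyond_tolerance_splits(self):
        calls = [_call(breakpoint5=1000), _call(caller="x", breakpoint5=1050)]
        assert len(merge_calls(calls, breakpoint_tolerance_bp=5)) == 2

    def test_single_call_single_transcript(self):
        merged = merge_calls([_call()])
        assert len(merged) == 1 and len(merged[0].supporting_callers) == 1

    def test_samples_never_merge(self):
        calls = [_call(sample_id="S1"), _call(sample_id="S2")]
        assert len(merge_calls(calls)) == 2

    def test_frame_consensus_prefers_in_frame(self):
        calls = [_call(frame="in_frame"), _call(caller="x", frame="unknown")]
        assert merge_calls(calls)[0].frame == "in_frame"


class TestFilterTranscripts:
    @pytest.mark.parametrize(
        "callers, reads, pair, kept, reason",
        [
            (("a", "b"), 5, ("A", "B"), True, None),
            (("a",), 10, ("A", "B"), False, "too_few_callers"),
            (("a", "b"), 3, ("A", "B"), False, "too_few_junction_reads"),
            (("a", "b"), 5, ("X", "Y"), False, "blacklisted"),
        ],
    )
    def test_criteria(self, callers, reads, pair, kept, reason):
        t = make_transcript(gene5=pair[0], gene3=pair[1], callers=callers, reads=reads)
        log = []
        out = filter_transcripts([t], blacklist={("X", "Y")}, removal_log=log)
        assert (len(out) == 1) is kept
        if reason:
            assert reason in log[0][1]

    def test_self_pair_removed(self):
        t = make_transcript(gene5="A", gene3="A")
        assert filter_transcripts([t]) == []

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            filter_transcripts([], min_junction_reads=0)


class TestDeduplicateSamples:
    def test_lower_precedence_source_dropped(self):
        t1 = make_transcript(sample="S1")
        t2 = make_transcript(sample="S1b", gene5="C", gene3="D")
        sources = {"S1": "inhouse", "S1b": "archive"}
        cells = {"S1": "CL1", "S1b": "CL1"}
        out = deduplicate_samples([t1, t2], sources, ["inhouse", "archive"], cells)
        assert [t.sample_id for t in out] == ["S1"]
        assert out[0].source == "inhouse"

    def test_single_source_unchanged(self):
        t = make_transcript(sample="S1")
        out = deduplicate_samples([t], {"S1": "archive"}, ["inhouse", "archive"])
        assert len(out) == 1

    def test_empty_precedence_errors(self):
        with pytest.raises(ValueError):
            deduplicate_samples([make_transcript()], {"CL001": "x"}, [])

    def test_missing_source_annotation_errors(self):
        with pytest.raises(ValueError, match="source"):
            deduplicate_samples([make_transcript(sample="S9")], {}, ["inhouse"])


class TestAggregateEvents:
    def test_multiple_transcripts_collapse_to_one_event(self):
        ts = [make_transcript(bp5=1000), make_transcript(bp5=9000, frame="in_frame")]
        events = aggregate_events(ts)
        assert len(events) == 1
        assert events[0].transcript_count == 2 and events[0].any_in_frame

    def test_same_pair_in_two_lines_two_events(self):
        ts = [make_transcript(sample="CL1"), make_transcript(sample="CL2")]
        events = aggregate_events(ts)
        assert len(events) == 2
        assert len({e.gene_pair for e in events}) == 1

    def test_empty_input(self):
        assert aggregate_events([]) == []

    def test_idempotent_under_reapplication(self):
        ts = [make_transcript(bp5=1000), make_transcript(bp5=9000),
              make_transcript(sample="CL2")]
        filtered = filter_transcripts(ts)
        once = aggregate_events(filtered)
        again = aggregate_events(filter_transcripts(filtered))
        assert once == again


class TestSummarizeCatalog:
    def test_forced_arithmetic(self):
        ts = [make_transcript(sample="L1"), make_transcript(sample="L2"),
              make_transcript(sample="L1", gene5="C", gene3="D")]
        events = aggregate_events(ts)
        s = summarize_catalog(events, {"L1": "T", "L2": "T"})
        assert s.n_unique_fusions == 2 and s.n_recurrent_fusions == 1
        assert s.recurrent_percent == 50.0

    def test_zero_event_line_has_median_zero(self):
        s = summarize_catalog([], {"L1": "T"})
        assert s.median_events_per_type == {"T": 0}

    def test_unknown_cell_line_errors(self):
        events = aggregate_events([make_transcript(sample="L9")])
        with pytest.raises(ValueError, match="L9"):
            summarize_catalog(events, {"L1": "T"})


# ---------------------------------------------------------------------------
# properties

transcript_strategy = st.builds(
    make_transcript,
    sample=st.sampled_from(["L1", "L2", "L3"]),
    gene5=st.sampled_from(list("ABCD")),
    gene3=st.sampled_from(list("EFGH")),
    callers=st.sets(st.sampled_from(["c1", "c2", "c3"]), min_size=1).map(tuple),
    reads=st.integers(min_value=0, max_value=12),
)


@settings(max_examples=60, deadline=None)
@given(
    ts=st.lists(transcript_strategy, max_size=30),
    reads1=st.integers(1, 6),
    reads2=st.integers(1, 6),
    callers1=st.integers(1, 3),
    callers2=st.integers(1, 3),
)
def test_filtering_is_monotone_in_both_thresholds(ts, reads1, reads2, callers1, callers2):
    """Raising either threshold never enlarges the retained set."""
    lo_r, hi_r = sorted((reads1, reads2))
    lo_c, hi_c = sorted((callers1, callers2))
    strict = {t.transcript_key + (t.sample_id,)
              for t in filter_transcripts(ts, hi_r, hi_c)}
    loose = {t.transcript_key + (t.sample_id,)
             for t in filter_transcripts(ts, lo_r, lo_c)}
    assert strict <= loose


@settings(max_examples=60, deadline=None)
@given(ts=st.lists(transcript_strategy, max_size=30))
def test_filter_matches_rowwise_rescan(ts):
    """Retained set equals a brute-force row-by-row application of the criteria."""
    blacklist = {("A", "E")}
    kept = filter_transcripts(ts, 4, 2, blacklist)
    brute = [
        t for t in ts
        if len(t.supporting_callers) >= 2
        and t.max_junction_reads >= 4
        and (t.gene5, t.gene3) not in blacklist
        and t.gene5 != t.gene3
    ]
    assert kept == brute


@settings(max_examples=60, deadline=None)
@given(ts=st.lists(transcript_strategy, max_size=40))
def test_count_hierarchy(ts):
    """transcripts >= events >= unique fusions >= recurrent fusions."""
    filtered = filter_transcripts(ts)
    events = aggregate_events(filtered)
    types = {t.sample_id: "T" for t in ts} or {"L1": "T"}
    s = summarize_catalog(events, types, n_transcripts=len(filtered))
    assert s.n_transcripts >= s.n_events >= s.n_unique_fusions >= s.n_recurrent_fusions
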