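import numpy as np
import pandas as pd
import pytest

from fusefit.crispr import (
    FesScreen,
    GuidePartition,
    aggregate_events_fes,
    fes_score,
    map_guides_to_transcript,
    scale_to_essentials,
    zscore_per_guide,
)

from .conftest import random_screen


def _library(rows):
    df = pd.DataFrame(rows, columns=["guide", "gene", "chrom", "cut_position", "strand"])
    return df.set_index("guide", drop=False)


class TestScaleToEssentials:
    def _fixture(self):
        lib = _library([
            ("e1", "ESS", "chr1", 100, "+"),
            ("n1", "NE", "chr1", 200, "+"),
            ("g1", "G", "chr1", 300, "+"),
        ])
        fc = pd.DataFrame({"L1": [-2.0, 0.0, -1.0]}, index=lib.index)
        return lib, fc

    def test_closed_form(self):
        lib, fc = self._fixture()
        scaled = scale_to_essentials(fc, lib["gene"], {"ESS"}, {"NE"})
        assert scaled.values["L1"].tolist() == pytest.approx([-1.0, 0.0, -0.5])

    def test_idempotent_at_anchors(self):
        lib, fc = self._fixture()
        once = scale_to_essentials(fc, lib["gene"], {"ESS"}, {"NE"}).values
        twice = scale_to_essentials(once, lib["gene"], {"ESS"}, {"NE"}).values
        assert np.allclose(once, twice, atol=1e-12)

    def test_inverted_anchors_error(self):
        lib, fc = self._fixture()
        fc.loc["e1", "L1"] = 1.0  # essential guide above non-essential
        with pytest.raises(ValueError, match="L1"):
            scale_to_essentials(fc, lib["gene"], {"ESS"}, {"NE"})

    def test_missing_reference_guides_error(self):
        lib, fc = self._fixture()
        with pytest.raises(ValueError, match="reference"):
            scale_to_essentials(fc, lib["gene"], {"ABSENT"}, {"NE"})


def _transcript(bp5=2000, bp3=2000, chrom="chr1"):
    return {
        "transcript_id": "T1", "gene5": "A", "chrom5": chrom, "breakpoint5": bp5,
        "gene3": "B", "chrom3": chrom, "breakpoint3": bp3,
    }


class TestGuideMapping:
    @pytest.mark.parametrize(
        "gene, strand, cut, expect_mapping",
        [
            ("A", "+", 1000, True),    # 5' gene, + strand, before breakpoint
            ("A", "-", 3000, True),    # 5' gene, - strand, after breakpoint
            ("A", "+", 2500, False),
            ("A", "-", 1500, False),
            ("B", "+", 2500, True),    # 3' gene, + strand, after breakpoint
            ("B", "-", 1500, True),
            ("B", "+", 1000, False),
            ("A", "+", 2000, True),    # tie rule: cut == breakpoint maps
            ("B", "-", 2000, True),
        ],
    )
    def test_strand_side_rules(self, gene, strand, cut, expect_mapping):
        lib = _library([("g", gene, "chr1", cut, strand)])
        part = map_guides_to_transcript(lib, _transcript())
        mapping = part.mapping5 if gene == "A" else part.mapping3
        assert (("g" in mapping) is expect_mapping)

    def test_chromosome_mismatch_excluded_with_warning(self):
        lib = _library([("g", "A", "chr9", 1000, "+")])
        with pytest.warns(RuntimeWarning, match="different chromosome"):
            part = map_guides_to_transcript(lib, _transcript())
        assert part.excluded == ["g"] and not part.mapping

    def test_partition_matches_bruteforce_on_random_fixtures(self):
        """Re-derive mapping guide-by-guide from the four strand/side rules."""
        rng = np.random.default_rng(5)
        for _ in range(300):
            strand5, strand3 = rng.choice(["+", "-"], 2)
            bp5, bp3 = rng.integers(100, 10_000, 2)
            rows = []
            for i in range(rng.integers(2, 12)):
                gene = rng.choice(["A", "B"])
                rows.append((f"g{i}", gene, "chr1", int(rng.integers(1, 11_000)),
                             strand5 if gene == "A" else strand3))
            lib = _library(rows)
            t = _transcript(bp5=int(bp5), bp3=int(bp3))
            part = map_guides_to_transcript(lib, t)
            for g, gene, _, cut, strand in rows:
                if gene == "A":
                    expect = bool(cut <= bp5 if strand == "+" else cut >= bp5)
                    assert (g in part.mapping5) is expect
                else:
                    expect = bool(cut >= bp3 if strand == "+" else cut <= bp3)
                    assert (g in part.mapping3) is expect


class TestZscore:
    def test_unit_row(self):
        df = pd.DataFrame([[-1.0, 0.0, 1.0]], index=["g"], columns=list("abc"))
        assert zscore_per_guide(df).loc["g"].tolist() == pytest.approx([-1, 0, 1])

    def test_constant_row_is_zero(self):
        df = pd.DataFrame([[2.0, 2.0, 2.0]], index=["g"], columns=list("abc"))
        assert (zscore_per_guide(df).loc["g"] == 0).all()

    def test_single_finite_entry_is_zero(self):
        df = pd.DataFrame([[1.5, np.nan, np.nan]], index=["g"], columns=list("abc"))
        out = zscore_per_guide(df)
        assert out.loc["g", "a"] == 0.0


class TestFesScore:
    def _zmatrix(self, values, guides):
        return pd.DataFrame({"L1": values}, index=guides)

    def test_forced_arithmetic(self):
        # gene5: mapping mean -2, non-mapping -0.5 -> diff -1.5
        # gene3: mapping only, mean -1 -> diff -1; FES = -1.25
        part = GuidePartition("T", ["a"], ["b"], ["c"], [])
        Z = self._zmatrix([-2.0, -0.5, -1.0], ["a", "b", "c"])
        out = fes_score(part, Z, "L1")
        assert out["fes"] == pytest.approx(-1.25)

    def test_all_equal_z_gives_zero(self):
        part = GuidePartition("T", ["a"], ["b"], [], ["c"])
        Z = self._zmatrix([0.7, 0.7, 0.7], ["a", "b", "c"])
        assert fes_score(part, Z, "L1")["fes"] == pytest.approx(0.0)

    def test_only_gene3_mapping_no_nonmapping(self):
        part = GuidePartition("T", [], [], ["c"], [])
        Z = self._zmatrix([0.0, 0.0, -1.0], ["a", "b", "c"])
        assert fes_score(part, Z, "L1")["fes"] == pytest.approx(-1.0)

    def test_no_mapping_guides_raises(self):
        part = GuidePartition("T", [], ["b"], [], [])
        Z = self._zmatrix([0.0], ["b"])
        with pytest.raises(ValueError, match="untestable"):
            fes_score(part, Z, "L1")

    def test_raw_diff_pools_both_genes(self):
        part = GuidePartition("T", ["a"], ["b"], ["c"], [])
        Z = self._zmatrix([0.0, 0.0, 0.0], ["a", "b", "c"])
        scaled = self._zmatrix([-1.0, -0.2, -0.8], ["a", "b", "c"])
        out = fes_score(part, Z, "L1", scaled)
        assert out["raw_diff"] == pytest.approx((-1.0 - 0.8) / 2 - (-0.2))


class TestFesScreen:
    def test_planted_depletion_detected(self):
        rng = np.random.default_rng(2)
        lib, fc, tr = random_screen(rng, n_lines=30, n_genes=40, n_transcripts=5,
                                    depletion=-1.0)
        res = FesScreen(lib, fc, tr).fit(n_perm=300, seed=3)
        df = res.frame.set_index("transcript_id")
        assert df.loc["T00", "significant"]
        assert df.loc["T00", "raw_diff"] <= -0.45
        others = df.drop("T00")
        assert not others["significant"].any()

    def test_min_diff_filter_removes_shallow_hits(self):
        rng = np.random.default_rng(4)
        lib, fc, tr = random_screen(rng, n_lines=30, n_genes=40, n_transcripts=5,
                                    noise_sd=0.05, depletion=-0.3)
        res = FesScreen(lib, fc, tr).fit(n_perm=300, seed=5)
        row = res.frame.set_index("transcript_id").loc["T00"]
        # strong z-shift but shallow raw difference: filtered out
        assert row["raw_diff"] > -0.45 and not row["significant"]

    def test_pvalues_in_unit_interval_and_reproducible(self):
        rng = np.random.default_rng(6)
        lib, fc, tr = random_screen(rng, n_lines=10, n_genes=20, n_transcripts=4)
        a = FesScreen(lib, fc, tr).fit(n_perm=100, seed=8)
        b = FesScreen(lib, fc, tr).fit(n_perm=100, seed=8)
        p = a.frame.loc[a.frame["testable"], "p_value"]
        assert ((p > 0) & (p <= 1)).all()
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_invariance_to_guide_relabeling_and_line_order(self):
        rng = np.random.default_rng(9)
        lib, fc, tr = random_screen(rng, n_lines=12, n_genes=20, n_transcripts=3,
                                    depletion=-1.0)
        base = FesScreen(lib, fc, tr).fit(n_perm=50, seed=1)
        relabel = {g: f"x_{g}" for g in lib.index}
        lib2 = lib.rename(index=relabel)
        lib2["guide"] = lib2.index
        fc2 = fc.rename(index=relabel)[list(fc.columns[::-1])]
        out2 = FesScreen(lib2, fc2, tr).fit(n_perm=50, seed=1)
        assert np.allclose(base.frame["fes"], out2.frame["fes"], equal_nan=True)

    def test_unscreened_line_untestable(self):
        rng = np.random.default_rng(10)
        lib, fc, tr = random_screen(rng, n_lines=5, n_genes=10, n_transcripts=2)
        tr.loc[0, "cell_line"] = "NOT_SCREENED"
        res = FesScreen(lib, fc, tr).fit(n_perm=20, seed=0)
        row = res.frame.iloc[0]
        assert not row["testable"] and "not screened" in row["reason"]

    def test_plus_one_bound_on_extreme_depletion(self):
        rng = np.random.default_rng(12)
        lib, fc, tr = random_screen(rng, n_lines=20, n_genes=20, n_transcripts=1,
                                    noise_sd=0.1, depletion=-3.0)
        res = FesScreen(lib, fc, tr).fit(n_perm=200, seed=2)
        assert res.frame.iloc[0]["p_value"] == pytest.approx(1 / 201)


class TestAggregateEventsFes:
    def _frame(self, tid, line, sig, dataset="d1"):
        return pd.DataFrame([
            {"transcript_id": tid, "cell_line": line, "gene5": "A", "gene3": "B",
             "dataset": dataset, "significant": sig}
        ])

    def test_significant_transcript_in_two_lines_two_events(self):
        f = pd.concat([self._frame("T1", "L1", True), self._frame("T1", "L2", True)])
        out = aggregate_events_fes([f])
        assert len(out) == 2 and out["significant"].all()

    def test_any_dataset_rule(self):
        f1 = self._frame("T1", "L1", False, "d1")
        f2 = self._frame("T1", "L1", True, "d2")
        out = aggregate_events_fes([f1, f2])
        assert len(out) == 1 and out.iloc[0]["significant"]

    def test_no_significant_transcripts(self):
        out = aggregate_events_fes([self._frame("T1", "L1", False)])
        assert not out["significant"].any()
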