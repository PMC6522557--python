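import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from fusefit.drugs import (
    fit_feature_drug_anova,
    glass_deltas,
    run_cfe_drug_screen,
    run_fusion_drug_screen,
    select_cfe_covariates,
)

from .test_expression import anova_type2_oracle


class TestGlassDeltas:
    def test_closed_form(self):
        d_pos, d_neg = glass_deltas([-1, 1], [3, 5])
        assert d_pos == pytest.approx(4 / np.sqrt(2))
        assert d_neg == pytest.approx(4 / np.sqrt(2))

    def test_equal_means_give_zero(self):
        assert glass_deltas([1, 3], [0, 4]) == (0.0, 0.0)

    def test_zero_sd_is_undefined(self):
        d_pos, d_neg = glass_deltas([2, 2], [0, 1])
        assert np.isnan(d_pos) and np.isfinite(d_neg)

    def test_singleton_group_is_undefined(self):
        d_pos, _ = glass_deltas([2], [0, 1])
        assert np.isnan(d_pos)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            glass_deltas([], [1, 2])

    @settings(max_examples=50, deadline=None)
    @given(
        shift=st.floats(-5, 5),
        scale=st.floats(0.1, 10),
        seed=st.integers(0, 1000),
    )
    def test_location_invariance_and_inverse_scaling(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        pos, neg = rng.normal(0, 1, 5), rng.normal(2, 1, 7)
        base = glass_deltas(pos, neg)
        shifted = glass_deltas(pos + shift, neg + shift)
        scaled = glass_deltas(pos * scale, neg * scale)
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled[0] == pytest.approx(base[0], rel=1e-9)
        assert scaled[1] == pytest.approx(base[1], rel=1e-9)


def _series(values, prefix="L"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))],
                     dtype=float)


class TestFeatureDrugAnova:
    def test_degenerate_groups_fail_effect_gate(self):
        y = _series([0, 0, 0, 2, 2, 2, 2])
        feat = pd.Series([True] * 3 + [False] * 4, index=y.index)
        res = fit_feature_drug_anova(feat, y)
        assert res.effect_size == pytest.approx(-2.0)
        assert np.isnan(res.glass_delta_pos) and not res.passes_effect_gate()

    def test_constant_feature_not_testable(self):
        y = _series(np.arange(6))
        res = fit_feature_drug_anova(pd.Series(False, index=y.index), y)
        assert not res.testable and "group size" in res.reason

    @pytest.mark.parametrize("seed", range(10))
    def test_p_matches_type2_oracle_with_tissue_covariate(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 60
        idx = [f"L{i}" for i in range(n)]
        y = pd.Series(rng.normal(size=n), index=idx)
        feat = pd.Series(rng.random(n) < 0.25, index=idx)
        if feat.sum() < 2 or (~feat).sum() < 2:
            pytest.skip("degenerate draw")
        cov = pd.DataFrame({"tissue": rng.choice(["lung", "colon", "skin"], n)},
                           index=idx)
        res = fit_feature_drug_anova(feat, y, cov)
        assert res.p_value == pytest.approx(
            anova_type2_oracle(y, feat, cov), abs=1e-10
        )

    def test_feature_collinear_with_covariate_not_testable(self):
        y = _series(np.arange(8))
        feat = pd.Series([True] * 4 + [False] * 4, index=y.index)
        cov = pd.DataFrame({"cfe": feat.astype(bool)}, index=y.index)
        res = fit_feature_drug_anova(feat, y, cov)
        assert not res.testable and "collinear" in res.reason

    def test_single_tissue_drops_covariate(self):
        rng = np.random.default_rng(0)
        y = _series(rng.normal(size=10))
        feat = pd.Series([True] * 3 + [False] * 7, index=y.index)
        cov = pd.DataFrame({"tissue": ["lung"] * 10}, index=y.index)
        res = fit_feature_drug_anova(feat, y, cov)
        assert res.testable and res.covariates_used == ()


class TestSelectCovariates:
    def _frame(self, **overrides):
        base = dict(feature="CFE1", drug="D1", effect_size=-2.0, f_stat=30.0,
                    p_value=1e-5, fdr=0.1, glass_delta_pos=1.5,
                    glass_delta_neg=2.0, n_pos=5, n_neg=20,
                    covariates_used="", testable=True, reason="")
        base.update(overrides)
        return pd.DataFrame([base])

    def test_passing_association_selected(self):
        assert select_cfe_covariates(self._frame()) == {"D1": ["CFE1"]}

    def test_small_delta_rejected(self):
        assert select_cfe_covariates(self._frame(glass_delta_pos=0.8)) == {}

    def test_large_p_rejected(self):
        assert select_cfe_covariates(self._frame(p_value=0.01)) == {}

    def test_empty_stage1(self):
        assert select_cfe_covariates(pd.DataFrame()) == {}


def _confounded_fixture(seed=0, n=40):
    """Fusion carried by 2 lines that also carry a truly causal CFE."""
    rng = np.random.default_rng(seed)
    lines = [f"L{i}" for i in range(n)]
    cfe_lines = lines[:6]
    fusion_lines = lines[:2]  # subset of CFE carriers
    cfe = pd.DataFrame([[l in cfe_lines for l in lines]], index=["DRIVER_MUT"],
                       columns=lines)
    fusion = pd.DataFrame([[l in fusion_lines for l in lines]], index=["FUSX"],
                          columns=lines)
    ic50 = rng.normal(0, 0.5, n) - 4.0 * np.array([l in cfe_lines for l in lines])
    table = pd.DataFrame({"drug": "drug1", "cell_line": lines, "ic50": ic50})
    return fusion, cfe, table


class TestTwoStageScreen:
    def test_planted_sensitizing_fusion_recovered(self):
        rng = np.random.default_rng(1)
        n = 50
        lines = [f"L{i}" for i in range(n)]
        carriers = set(lines[:4])
        ic50 = rng.normal(0, 1, n) - 3.0 * np.array([l in carriers for l in lines])
        table = pd.DataFrame({"drug": "D1", "cell_line": lines, "ic50": ic50})
        features = pd.DataFrame([[l in carriers for l in lines]], index=["F1"],
                                columns=lines)
        res = run_fusion_drug_screen(features, table)
        assert res.frame.iloc[0]["significant"]
        assert res.frame.iloc[0]["effect_size"] < 0  # sensitizing

    def test_confounded_fusion_explained_by_cfe_covariate(self):
        fusion, cfe, table = _confounded_fixture()
        naked = run_fusion_drug_screen(fusion, table)
        assert naked.frame.iloc[0]["significant"]
        stage1 = run_cfe_drug_screen(cfe, table)
        selected = select_cfe_covariates(stage1)
        assert selected == {"drug1": ["DRIVER_MUT"]}
        adjusted = run_fusion_drug_screen(fusion, table, cfe_covariates=selected,
                                          cfe_matrix=cfe)
        assert not adjusted.frame.iloc[0]["significant"]

    def test_perfectly_cooccurring_fusion_is_collinear(self):
        fusion, cfe, table = _confounded_fixture()
        fusion_full = cfe.rename(index={"DRIVER_MUT": "F1"})
        res = run_fusion_drug_screen(fusion_full, table,
                                     cfe_covariates={"drug1": ["DRIVER_MUT"]},
                                     cfe_matrix=cfe)
        row = res.frame.iloc[0]
        assert not row["testable"] and "collinear" in row["reason"]

    def test_null_pvalues_uniform_by_ks(self):
        """Stage-2 p-values under no planted effect but real tissue effects."""
        rng = np.random.default_rng(7)
        n = 40
        lines = [f"L{i}" for i in range(n)]
        tissue = rng.choice(["a", "b"], n)
        cov = pd.DataFrame({"tissue": tissue}, index=lines)
        pvals = []
        for d in range(8):
            ic50 = rng.normal(0, 1, n) + 0.8 * (tissue == "a")
            table = pd.DataFrame({"drug": f"D{d}", "cell_line": lines, "ic50": ic50})
            feats = pd.DataFrame(
                rng.random((25, n)) < 0.2, columns=lines,
                index=[f"F{d}_{k}" for k in range(25)],
            )
            res = run_fusion_drug_screen(feats, table, cov)
            pvals.extend(res.frame.loc[res.frame["testable"], "p_value"])
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_effect_screen_rarely_gates(self):
        rng = np.random.default_rng(11)
        n = 40
        lines = [f"L{i}" for i in range(n)]
        ic50 = rng.normal(0, 1, n)
        table = pd.DataFrame({"drug": "D1", "cell_line": lines, "ic50": ic50})
        feats = pd.DataFrame(rng.random((200, n)) < 0.15, columns=lines,
                             index=[f"F{k}" for k in range(200)])
        res = run_fusion_drug_screen(feats, table)
        # the FDR + dual-delta gate keeps false positives to a handful
        assert int(res.frame["significant"].sum()) <= 5
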