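import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sevmir import (
    CytokineTable,
    ValidationError,
    analyze_cytokine_panel,
    bh_adjust,
    hindpaw_weight_ratio,
    impute_lloq,
    protein_normalize,
    students_t,
    welch_from_samples,
    welch_from_summary,
)
from sevmir.datasets import load_cytokine_summary

from conftest import make_sheet


def cytokine_table(values: dict, lloq: dict, censored: dict | None = None):
    df = pd.DataFrame(values).T
    df.columns = [f"m{i+1}" for i in range(df.shape[1])]
    cens = pd.DataFrame(False, index=df.index, columns=df.columns)
    for analyte, cols in (censored or {}).items():
        for c in cols:
            cens.at[analyte, c] = True
            df.at[analyte, c] = np.nan
    return CytokineTable(df.astype(float), cens, pd.Series(lloq))


class TestImputeLLOQ:
    def test_censored_replaced_by_lloq(self):
        t = cytokine_table({"IL-6": [5.0, 7.0]}, {"IL-6": 3.2}, censored={"IL-6": ["m2"]})
        out = impute_lloq(t)
        assert out.values.at["IL-6", "m2"] == 3.2
        assert out.n_imputed.at["IL-6"] == 1

    def test_no_censoring_identity(self):
        t = cytokine_table({"IL-6": [5.0, 7.0]}, {"IL-6": 3.2})
        out = impute_lloq(t)
        pd.testing.assert_frame_equal(out.values, t.values)

    def test_fully_censored_analyte_has_zero_sd(self):
        t = cytokine_table({"IL-6": [1.0, 1.0]}, {"IL-6": 3.2}, censored={"IL-6": ["m1", "m2"]})
        out = impute_lloq(t)
        assert out.values.loc["IL-6"].std(ddof=1) == 0.0
        assert (out.values.loc["IL-6"] == 3.2).all()

    def test_never_decreases_never_touches_uncensored(self):
        rng = np.random.default_rng(0)
        vals = {f"a{i}": rng.uniform(1, 100, size=5).tolist() for i in range(4)}
        t = cytokine_table(vals, {f"a{i}": 50.0 for i in range(4)},
                           censored={"a0": ["m1", "m3"], "a2": ["m5"]})
        out = impute_lloq(t)
        before = t.values.fillna(-np.inf)
        assert (out.values >= before).all().all()
        untouched = ~t.censored
        pd.testing.assert_frame_equal(out.values[untouched], t.values[untouched])


class TestProteinNormalize:
    def test_division(self):
        t = cytokine_table({"IL-6": [500.0]}, {"IL-6": 1.0})
        sheet = make_sheet({"m1": "control"}, protein={"m1": 2.0})
        out = protein_normalize(t, sheet)
        assert out.values.at["IL-6", "m1"] == 250.0
        assert out.unit == "pg/mg"

    def test_unit_protein_is_identity(self):
        t = cytokine_table({"IL-6": [500.0, 30.0]}, {"IL-6": 1.0})
        sheet = make_sheet({"m1": "control", "m2": "case"}, protein={"m1": 1.0, "m2": 1.0})
        out = protein_normalize(t, sheet)
        pd.testing.assert_frame_equal(out.values, t.values)

    def test_missing_protein_is_error(self):
        t = cytokine_table({"IL-6": [500.0]}, {"IL-6": 1.0})
        sheet = make_sheet({"m1": "control"})  # protein NaN
        with pytest.raises(ValidationError, match="m1"):
            protein_normalize(t, sheet)


class TestWelch:
    # published panel rows: (control mean, sd, n), (case mean, sd, n) -> printed p
    @pytest.mark.parametrize(
        "analyte,expected_p",
        [("RANTES", 0.65), ("IL-6", 0.57), ("IL-10", 0.40)],
    )
    def test_reproduces_published_panel_p(self, analyte, expected_p):
        row = load_cytokine_summary().loc[analyte]
        t, df, p = welch_from_summary(
            row.control_mean, row.control_sd, int(row.control_n),
            row.tfm_mean, row.tfm_sd, int(row.tfm_n),
        )
        assert p == pytest.approx(expected_p, abs=0.01)

    def test_equal_means_p_one(self):
        t, df, p = welch_from_summary(5.0, 1.0, 4, 5.0, 2.0, 4)
        assert t == 0.0 and p == 1.0

    def test_zero_variance_equal_means_convention(self):
        t, df, p = welch_from_summary(5.0, 0.0, 4, 5.0, 0.0, 4)
        assert (t, p) == (0.0, 1.0)

    def test_matches_scipy_on_raw_data(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        g1, g2 = rng.normal(size=6), rng.normal(loc=1, size=8)
        t, df, p = welch_from_samples(g1, g2)
        ref = stats.ttest_ind(g2, g1, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(
        g1=st.lists(st.floats(-50, 50), min_size=3, max_size=8),
        g2=st.lists(st.floats(-50, 50), min_size=3, max_size=8),
    )
    def test_summary_path_equals_raw_path(self, g1, g2):
        """Welch from (m, s, n) summaries equals Welch from the raw samples."""
        g1, g2 = np.asarray(g1), np.asarray(g2)
        if g1.std(ddof=1) == 0 and g2.std(ddof=1) == 0:
            return
        raw = welch_from_samples(g1, g2)
        summ = welch_from_summary(
            g1.mean(), g1.std(ddof=1), len(g1), g2.mean(), g2.std(ddof=1), len(g2)
        )
        np.testing.assert_allclose(raw, summ, rtol=1e-9, atol=1e-12)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == [0.3]

    def test_published_panel_adjustment(self):
        """BH over the 23 published raw p-values reproduces the printed IL-6 value."""
        summary = load_cytokine_summary()
        adj = pd.Series(bh_adjust(summary["p"].tolist()), index=summary.index)
        assert adj["IL-6"] == pytest.approx(0.60, abs=0.01)
        assert adj["RANTES"] == pytest.approx(0.65, abs=0.01)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.uniform(1e-6, 1, size=40)
        ours = bh_adjust(p.tolist())
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, rtol=1e-12)

    def test_out_of_range_rejected(self):
        for bad in ([0.0], [1.5], [np.nan]):
            with pytest.raises(ValidationError):
                bh_adjust(bad)

    @settings(max_examples=30, deadline=None)
    @given(p=st.lists(st.floats(1e-9, 1.0, exclude_min=False), min_size=1, max_size=30))
    def test_properties(self, p):
        """Adjusted >= raw and monotone non-decreasing along sorted raw p."""
        adj = np.array(bh_adjust(p))
        assert (adj >= np.array(p) - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj <= 1.0).all()

    def test_m_override(self):
        # one reported p from a family of 10 tests
        assert bh_adjust([0.01], m=10) == [0.1]


class TestPanelPipeline:
    def test_identical_groups_all_p_one(self):
        values = {f"a{i}": [5.0, 7.0, 5.0, 7.0] for i in range(3)}
        t = cytokine_table(values, {f"a{i}": 1.0 for i in range(3)})
        sheet = make_sheet(
            {"m1": "control", "m2": "control", "m3": "case", "m4": "case"},
            protein={f"m{i}": 1.0 for i in range(1, 5)},
        )
        res = analyze_cytokine_panel(t, sheet)
        assert (res["p"] == 1.0).all()
        assert not res["significant"].any()

    def test_planted_shift_has_minimal_p(self):
        rng = np.random.default_rng(6)
        samples = {f"m{i}": ("control" if i <= 6 else "case") for i in range(1, 15)}
        values = {f"a{i}": rng.lognormal(3, 0.1, size=14).tolist() for i in range(8)}
        values["shifted"] = (
            rng.lognormal(3, 0.1, size=6).tolist() + rng.lognormal(3 + np.log(5), 0.1, size=8).tolist()
        )
        t = cytokine_table(values, {a: 0.1 for a in values})
        sheet = make_sheet(samples, protein={s: 1.0 for s in samples})
        res = analyze_cytokine_panel(t, sheet)
        assert res["p"].idxmin() == "shifted"
        assert res.at["shifted", "significant"]

    def test_type_one_error_calibrated_under_null(self):
        """With no group shift, ~5% of Welch tests reject at 0.05."""
        from sevmir.synthetic import SyntheticConfig, simulate_cytokines

        rejections, total = 0, 0
        for seed in range(200):
            config = SyntheticConfig(
                seed=seed, cytokine_shift_sev_plus=1.0,
                n_cytokine_control=6, n_cytokine_case=8,
            )
            sev_plus, _, sheet, _ = simulate_cytokines(config)
            res = analyze_cytokine_panel(sev_plus, sheet, normalize_protein=False)
            rejections += int((res["p"] < 0.05).sum())
            total += len(res)
        rate = rejections / total
        se = np.sqrt(0.05 * 0.95 / total)
        # lognormal noise at n=6/8 makes the t test only approximately exact
        assert abs(rate - 0.05) < max(4 * se, 0.02)


class TestSmallFormulas:
    @pytest.mark.parametrize("r,l,expected", [(1.0, 1.0, 100.0), (1.0, 3.0, 50.0), (1.0, 0.0, 200.0)])
    def test_weight_ratio(self, r, l, expected):
        assert hindpaw_weight_ratio(r, l) == pytest.approx(expected)

    def test_weight_ratio_zero_total_is_error(self):
        with pytest.raises(ValidationError):
            hindpaw_weight_ratio(0.0, 0.0)

    def test_students_t_identical_groups(self):
        t, df, p = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_students_t_hand_computed(self):
        # pooled sd 1, se = sqrt(2/3), t = -3/0.8165 = -3.674, df = 4
        t, df, p = students_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(0.0214, abs=5e-4)

    def test_students_t_scale_invariance(self):
        a = students_t([1, 2, 3], [4, 5, 6])
        b = students_t([10, 20, 30], [40, 50, 60])
        assert a[0] == pytest.approx(b[0]) and a[2] == pytest.approx(b[2])
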