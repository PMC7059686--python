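"""Sequential-SS ANOVA/ANCOVA and multiple-testing adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lcmsvar.datamodel import AnalysisConfig
from lcmsvar.model import (
    RESIDUAL,
    DesignSpec,
    ModelError,
    adjust_pvalues,
    fit_feature,
    run_model_stage,
)

from conftest import make_matrix, make_metadata
from oracles import adjust_oracle, random_small_design, sequential_ss_oracle


# ---------------------------------------------------------------------------
# single-feature fits
# ---------------------------------------------------------------------------

def test_two_group_worked_example():
    # groups {1,3} vs {5,7}: group means 2 and 6, grand mean 4
    meta = make_metadata(["S0", "S1", "S2", "S3"], categorical={"G": ["a", "a", "b", "b"]})
    res = fit_feature([1.0, 3.0, 5.0, 7.0], DesignSpec(categorical_vars=["G"]), meta)
    assert res.ss["G"] == pytest.approx(16.0)
    assert res.ss[RESIDUAL] == pytest.approx(4.0)
    assert res.pct_ss["G"] == pytest.approx(80.0)
    assert res.f_stat["G"] == pytest.approx(8.0)
    assert res.df["G"] == 1 and res.df[RESIDUAL] == 2


def test_constant_response_degenerates_gracefully():
    meta = make_metadata(["S0", "S1", "S2", "S3"], categorical={"G": ["a", "a", "b", "b"]})
    res = fit_feature([5.0, 5.0, 5.0, 5.0], DesignSpec(categorical_vars=["G"]), meta)
    assert res.ss["G"] == 0.0
    assert res.pct_ss["G"] == 0.0 and res.pct_ss[RESIDUAL] == 0.0
    assert np.isnan(res.p_value["G"])


def test_two_group_f_equals_squared_t():
    rng = np.random.default_rng(0)
    y = rng.normal(size=10)
    labels = ["a"] * 5 + ["b"] * 5
    meta = make_metadata([f"S{i}" for i in range(10)], categorical={"G": labels})
    res = fit_feature(y, DesignSpec(categorical_vars=["G"]), meta)
    from scipy.stats import ttest_ind

    t, p = ttest_ind(y[:5], y[5:], equal_var=True)
    assert res.f_stat["G"] == pytest.approx(t**2, abs=1e-10)
    assert res.p_value["G"] == pytest.approx(p, abs=1e-12)


def test_sequential_ss_matches_projection_oracle():
    rng = np.random.default_rng(42)
    for _ in range(100):
        y, continuous, categorical = random_small_design(rng)
        n = len(y)
        meta = make_metadata(
            [f"S{i}" for i in range(n)],
            categorical=categorical, continuous=continuous,
        )
        design = DesignSpec(
            categorical_vars=list(categorical), continuous_vars=list(continuous)
        )
        res = fit_feature(y, design, meta)
        ss_oracle, resid_oracle, total_oracle = sequential_ss_oracle(
            y, continuous, categorical
        )
        for term, val in ss_oracle.items():
            assert res.ss[term] == pytest.approx(val, abs=1e-8)
        assert res.ss[RESIDUAL] == pytest.approx(resid_oracle, abs=1e-8)
        assert sum(res.ss.values()) == pytest.approx(total_oracle, abs=1e-8)


def test_matches_statsmodels_type_i_anova():
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(5)
    n = 24
    frame = pd.DataFrame({
        "A": rng.choice(["a1", "a2"], size=n),
        "B": rng.choice(["b1", "b2", "b3"], size=n),
        "X": rng.normal(size=n),
    })
    frame["y"] = rng.normal(size=n)
    meta = make_metadata([f"S{i}" for i in range(n)],
                         categorical={"A": frame["A"].tolist(), "B": frame["B"].tolist()},
                         continuous={"X": frame["X"].tolist()})
    res = fit_feature(frame["y"].to_numpy(),
                      DesignSpec(categorical_vars=["A", "B"], continuous_vars=["X"]),
                      meta)
    # patsy reorders categorical terms ahead of numeric ones, so encode the
    # factors as explicit dummy columns to pin the sequential order X, A, B
    frame["dA"] = (frame["A"] == "a2").astype(float)
    frame["dB2"] = (frame["B"] == "b2").astype(float)
    frame["dB3"] = (frame["B"] == "b3").astype(float)
    fit = smf.ols("y ~ X + dA + dB2 + dB3", data=frame).fit()
    tab = sm.stats.anova_lm(fit, typ=1)
    assert res.ss["X"] == pytest.approx(tab.loc["X", "sum_sq"], rel=1e-8)
    assert res.ss["A"] == pytest.approx(tab.loc["dA", "sum_sq"], rel=1e-8)
    assert res.ss["B"] == pytest.approx(
        tab.loc["dB2", "sum_sq"] + tab.loc["dB3", "sum_sq"], rel=1e-8
    )
    assert res.ss["Residual"] == pytest.approx(tab.loc["Residual", "sum_sq"], rel=1e-8)


def test_balanced_design_order_invariance(demo_data):
    meta = demo_data.metadata
    rng = np.random.default_rng(9)
    y = rng.normal(size=len(meta.sample_ids))
    orders = [["M1", "M2", "Run"], ["Run", "M2", "M1"], ["M2", "M1", "Run"]]
    results = [
        fit_feature(y, DesignSpec(categorical_vars=order), meta) for order in orders
    ]
    for term in ["M1", "M2", "Run"]:
        vals = [r.ss[term] for r in results]
        assert max(vals) - min(vals) < 1e-8


def test_rank_deficient_design_names_aliased_term():
    meta = make_metadata(
        [f"S{i}" for i in range(6)],
        categorical={"G": list("aaabbb"), "H": list("cccddd")},  # H aliases G
    )
    with pytest.raises(ModelError, match="H"):
        fit_feature(np.arange(6.0), DesignSpec(categorical_vars=["G", "H"]), meta)


def test_missing_response_rejected():
    meta = make_metadata(["S0", "S1", "S2", "S3"], categorical={"G": ["a", "a", "b", "b"]})
    with pytest.raises(ModelError, match="missing"):
        fit_feature([1.0, np.nan, 2.0, 3.0], DesignSpec(categorical_vars=["G"]), meta)


# ---------------------------------------------------------------------------
# p-value adjustment
# ---------------------------------------------------------------------------

def test_bh_and_holm_worked_examples():
    np.testing.assert_allclose(adjust_pvalues([0.01, 0.02, 0.03], "BH"),
                               [0.03, 0.03, 0.03])
    np.testing.assert_allclose(adjust_pvalues([0.01, 0.02, 0.03], "holm"),
                               [0.03, 0.04, 0.04])


def test_single_pvalue_is_unchanged():
    for method in ("BH", "bonferroni", "holm", "hochberg", "hommel", "BY"):
        np.testing.assert_allclose(adjust_pvalues([0.2], method), [0.2])


@pytest.mark.parametrize("method", ["BH", "bonferroni", "holm", "hochberg", "hommel", "BY"])
def test_adjustments_match_literal_oracles(method):
    rng = np.random.default_rng(hash(method) % 2**31)
    for _ in range(50):
        n = int(rng.integers(1, 11))
        p = rng.uniform(size=n)
        np.testing.assert_allclose(
            adjust_pvalues(p, method), adjust_oracle(p, method), atol=1e-12
        )


def test_adjustments_match_statsmodels():
    from statsmodels.stats.multitest import multipletests

    sm_name = {"BH": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm",
               "hochberg": "simes-hochberg", "hommel": "hommel", "BY": "fdr_by"}
    rng = np.random.default_rng(17)
    for _ in range(20):
        p = rng.uniform(size=int(rng.integers(1, 40)))
        for ours, theirs in sm_name.items():
            np.testing.assert_allclose(
                adjust_pvalues(p, ours), multipletests(p, method=theirs)[1],
                atol=1e-12,
            )


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_adjusted_never_below_raw_and_capped(p):
    for method in ("BH", "bonferroni", "holm", "hochberg", "hommel", "BY"):
        adj = adjust_pvalues(p, method)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()


def test_invalid_pvalues_rejected():
    with pytest.raises(ModelError, match=r"\[0, 1\]"):
        adjust_pvalues([0.5, 1.5], "BH")


def test_nan_pvalues_passed_through():
    adj = adjust_pvalues([0.01, np.nan, 0.02], "bonferroni")
    assert np.isnan(adj[1])
    np.testing.assert_allclose(adj[[0, 2]], [0.02, 0.04])  # n counts non-NaN only


# ---------------------------------------------------------------------------
# stage driver
# ---------------------------------------------------------------------------

def _stage_inputs(seed=0, n_feat=50):
    rng = np.random.default_rng(seed)
    n = 12
    meta = make_metadata(
        [f"S{i}" for i in range(n)],
        categorical={"G": list("aaaabbbbcccc")},
        continuous={"X": rng.normal(size=n)},
    )
    shift = np.array([0.0] * 4 + [1.0] * 4 + [0.5] * 4)
    vals = 16 + shift[None, :] + rng.normal(0, 0.5, size=(n_feat, n))
    expr = make_matrix(vals, scale_tag="log2")
    return expr, meta


def test_stage_conservation_and_counts():
    expr, meta = _stage_inputs()
    design = DesignSpec(categorical_vars=["G"], continuous_vars=["X"])
    res = run_model_stage(expr, design, AnalysisConfig(), meta)
    tab = res.table
    total = tab["SS_X"] + tab["SS_G"] + tab["SS_Residual"]
    pct_sum = tab["pctSS_X"] + tab["pctSS_G"] + tab["pctSS_Residual"]
    np.testing.assert_allclose(pct_sum, 100.0, atol=1e-6)
    # SS conservation against the direct total about the mean
    y = expr.values.to_numpy()
    direct_total = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    np.testing.assert_allclose(total, direct_total, rtol=1e-8)
    counts = res.counts
    assert (counts["n_significant_adjusted"] <= counts["n_significant_raw"]).all()
    assert (counts <= expr.n_features).all().all()
    assert list(res.summary.index) == ["X", "G", RESIDUAL]


def test_stage_excludes_constant_features_from_counts():
    expr, meta = _stage_inputs(n_feat=10)
    vals = expr.values.copy()
    vals.iloc[0] = 7.0  # constant feature
    expr = make_matrix(vals.to_numpy(), scale_tag="log2")
    design = DesignSpec(categorical_vars=["G"])
    res = run_model_stage(expr, design, AnalysisConfig(), meta)
    assert np.isnan(res.table["p_G"].iloc[0])
    assert res.table["pctSS_G"].iloc[0] == 0.0
    assert res.counts.loc["G", "n_significant_raw"] <= 9


def test_stage_adjustment_is_per_variable_across_features():
    expr, meta = _stage_inputs()
    design = DesignSpec(categorical_vars=["G"], continuous_vars=["X"])
    res = run_model_stage(expr, design, AnalysisConfig(adjust_method="bonferroni"), meta)
    np.testing.assert_allclose(
        res.table["padj_G"],
        np.minimum(1.0, res.table["p_G"] * expr.n_features),
        atol=1e-12,
    )
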