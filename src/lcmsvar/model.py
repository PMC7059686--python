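"""Per-feature fixed-effects ANOVA/ANCOVA with sequential sum-of-squares.

Each feature's preprocessed intensities are regressed on the selected
design variables (main effects only) and the total sum of squares about
the mean is decomposed sequentially (Type-I): continuous covariates
enter first, then the categorical factors in user order.  On balanced
complete designs the factor columns are orthogonal, so sequential SS for
the categorical terms is order-invariant and equals partial SS.

Per term the module reports SS, df, %SS (share of the total, residual
included so shares sum to 100), the F statistic against the residual
mean square and its p-value, plus p-values adjusted across features
within each term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    ADJUST_METHODS,
    AnalysisConfig,
    ExpressionMatrix,
    SampleMetadata,
)

RESIDUAL = "Residual"


class ModelError(ValueError):
    pass


@dataclass
class DesignSpec:
    """Ordered analysis variables: covariates enter the model first."""

    categorical_vars: list[str] = field(default_factory=list)
    continuous_vars: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.categorical_vars and not self.continuous_vars:
            raise ModelError("design needs at least one variable")
        overlap = set(self.categorical_vars) & set(self.continuous_vars)
        if overlap:
            raise ModelError(f"variable(s) listed as both types: {sorted(overlap)}")

    @property
    def terms(self) -> list[str]:
        return list(self.continuous_vars) + list(self.categorical_vars)


@dataclass
class FeatureModelResult:
    """Decomposition for one feature: SS/df/%SS/F/p per term + residual."""

    feature_id: object
    ss: dict
    df: dict
    pct_ss: dict
    f_stat: dict
    p_value: dict
    p_adjusted: dict = field(default_factory=dict)


def build_design(design: DesignSpec, meta: SampleMetadata):
    """Assemble the design matrix as ordered term blocks.

    Returns (X, blocks) where blocks is a list of (term, column_slice, df).
    Categorical factors are coded as treatment dummies against their
    first-appearance level; the intercept is the leading block.
    """
    n = len(meta.sample_ids)
    cols = [np.ones((n, 1))]
    blocks = [("Intercept", slice(0, 1), 1)]
    start = 1
    for var in design.continuous_vars:
        x = meta.continuous(var).to_numpy(dtype=float)[:, None]
        cols.append(x)
        blocks.append((var, slice(start, start + 1), 1))
        start += 1
    for var in design.categorical_vars:
        levels = meta.levels(var)
        if len(levels) < 2:
            raise ModelError(f"categorical variable {var!r} has fewer than 2 levels")
        lab = meta.table[var].astype(str).to_numpy()
        dummies = np.column_stack([(lab == lev).astype(float) for lev in levels[1:]])
        cols.append(dummies)
        k = dummies.shape[1]
        blocks.append((var, slice(start, start + k), k))
        start += k
    X = np.hstack(cols)
    if X.shape[1] >= n:
        raise ModelError(
            f"model degrees of freedom ({X.shape[1]}) must be below the "
            f"number of samples ({n})"
        )
    return X, blocks


def _qr_with_rank_check(X: np.ndarray, blocks) -> np.ndarray:
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    col_norms = np.linalg.norm(X, axis=0)
    tol = X.shape[0] * np.finfo(float).eps
    deficient = diag <= tol * np.maximum(col_norms, 1.0)
    if deficient.any():
        bad_cols = np.where(deficient)[0]
        aliased = sorted(
            {term for term, sl, _ in blocks if any(sl.start <= c < sl.stop for c in bad_cols)}
        )
        raise ModelError(
            f"rank-deficient design: term(s) {aliased} are confounded with earlier terms"
        )
    return Q


def decompose(Y: np.ndarray, design: DesignSpec, meta: SampleMetadata):
    """Sequential SS decomposition for a stack of responses.

    Parameters
    ----------
    Y
        Array of shape (n_features, n_samples), complete (no NaN).

    Returns
    -------
    dict with per-term SS arrays, residual SS, dfs, F and p arrays, and a
    boolean mask of degenerate (constant-response) features.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if np.isnan(Y).any():
        raise ModelError("responses contain missing values; exclude or impute first")
    X, blocks = build_design(design, meta)
    n = X.shape[0]
    if Y.shape[1] != n:
        raise ModelError(f"response length {Y.shape[1]} does not match design rows {n}")
    Q = _qr_with_rank_check(X, blocks)
    effects = Q.T @ Y.T                              # (p, n_features)
    total = (Y * Y).sum(axis=1) - effects[0] ** 2    # SS about the mean
    terms = [(t, sl, df) for t, sl, df in blocks if t != "Intercept"]
    ss = {t: (effects[sl] ** 2).sum(axis=0) for t, sl, _ in terms}
    dfs = {t: df for t, _, df in terms}
    model_ss = sum(ss.values())
    resid = np.maximum(total - model_ss, 0.0)
    df_resid = n - X.shape[1]
    if df_resid <= 0:
        raise ModelError("zero residual degrees of freedom")

    degenerate = total <= 1e-10 * max(1.0, float(np.nanmax(np.abs(Y), initial=1.0)) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_resid = resid / df_resid
        f_stat = {t: (ss[t] / dfs[t]) / ms_resid for t, _, _ in terms}
        p_value = {t: stats.f.sf(f_stat[t], dfs[t], df_resid) for t, _, _ in terms}
        pct = {t: 100.0 * ss[t] / total for t, _, _ in terms}
        pct[RESIDUAL] = 100.0 * resid / total
    for t in list(f_stat):
        f_stat[t] = np.where(degenerate | (ms_resid == 0.0), np.nan, f_stat[t])
        p_value[t] = np.where(degenerate | (ms_resid == 0.0), np.nan, p_value[t])
    for t in list(pct):
        pct[t] = np.where(degenerate, 0.0, pct[t])
    for t in list(ss):
        ss[t] = np.where(degenerate, 0.0, ss[t])
    return {
        "terms": [t for t, _, _ in terms],
        "ss": ss,
        "df": dfs,
        "residual_ss": np.where(degenerate, 0.0, resid),
        "df_resid": df_resid,
        "total_ss": total,
        "pct_ss": pct,
        "f": f_stat,
        "p": p_value,
        "degenerate": degenerate,
    }


def fit_feature(y, design: DesignSpec, meta: SampleMetadata) -> FeatureModelResult:
    """Fit the fixed-effects model for a single feature's responses."""
    y = np.asarray(y, dtype=float)
    out = decompose(y[None, :], design, meta)
    i = 0
    ss = {t: float(out["ss"][t][i]) for t in out["terms"]}
    ss[RESIDUAL] = float(out["residual_ss"][i])
    df = dict(out["df"])
    df[RESIDUAL] = out["df_resid"]
    return FeatureModelResult(
        feature_id=None,
        ss=ss,
        df=df,
        pct_ss={t: float(out["pct_ss"][t][i]) for t in out["terms"] + [RESIDUAL]},
        f_stat={t: float(out["f"][t][i]) for t in out["terms"]},
        p_value={t: float(out["p"][t][i]) for t in out["terms"]},
    )


# ---------------------------------------------------------------------------
# multiple-testing adjustment
# ---------------------------------------------------------------------------

def _adjust_sorted(p: np.ndarray, method: str) -> np.ndarray:
    """Adjust a complete (no-NaN) vector; classic step-up/step-down forms."""
    n = p.size
    if method == "bonferroni":
        return np.minimum(1.0, n * p)
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    i = np.arange(1, n + 1)
    if method == "holm":
        adj = np.maximum.accumulate((n - i + 1) * ps)           # step-down
    elif method == "hochberg":
        adj = np.minimum.accumulate(((n - i + 1) * ps)[::-1])[::-1]  # step-up
    elif method == "BH":
        adj = np.minimum.accumulate((n / i * ps)[::-1])[::-1]
    elif method == "BY":
        c = float(np.sum(1.0 / i))
        adj = np.minimum.accumulate((c * n / i * ps)[::-1])[::-1]
    elif method == "hommel":
        return _hommel(p)
    else:  # pragma: no cover - guarded by adjust_pvalues
        raise ModelError(f"unknown adjustment {method!r}")
    out = np.empty(n)
    out[order] = np.minimum(1.0, adj)
    return out


def _hommel(p: np.ndarray) -> np.ndarray:
    """Hommel adjusted p-values, O(n^2) step-wise form of closed testing."""
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    i = np.arange(1, n + 1)
    q = np.full(n, min(1.0, float(np.min(n * ps / i))))
    pa = q.copy()
    for m in range(n - 1, 1, -1):
        upper = np.arange(n - m + 1, n)            # the m-1 largest p-values
        q1 = np.min(m * ps[upper] / np.arange(2, m + 1))
        lower = np.arange(0, n - m + 1)
        q[lower] = np.minimum(m * ps[lower], q1)
        q[upper] = q[n - m]
        pa = np.maximum(pa, q)
    out = np.empty(n)
    out[order] = np.minimum(1.0, np.maximum(pa, ps))
    return out


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Adjust a vector of p-values by one of the six classic procedures.

    NaN entries (degenerate features) are passed through and do not count
    toward the number of tests.
    """
    if method not in ADJUST_METHODS:
        raise ModelError(f"adjust method must be one of {ADJUST_METHODS}, got {method!r}")
    p = np.asarray(p, dtype=float)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ModelError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if mask.any():
        out[mask] = _adjust_sorted(p[mask], method)
    return out


# ---------------------------------------------------------------------------
# stage driver
# ---------------------------------------------------------------------------

@dataclass
class ModelStageResult:
    """All model-stage outputs: per-feature table, %SS summary, counts."""

    table: pd.DataFrame        # one row per feature, SS/%SS/F/p/padj per term
    summary: pd.DataFrame      # %SS distribution summary per term + residual
    counts: pd.DataFrame       # significant-feature counts per variable
    terms: list[str]
    df: dict


def _distribution_summary(frame: pd.DataFrame) -> pd.DataFrame:
    """min/Q1/median/mean/Q3/max per column, missing values skipped."""
    return pd.DataFrame(
        {
            "min": frame.min(),
            "Q1": frame.quantile(0.25),
            "median": frame.median(),
            "mean": frame.mean(),
            "Q3": frame.quantile(0.75),
            "max": frame.max(),
        }
    )


def run_model_stage(
    expr: ExpressionMatrix,
    design: DesignSpec,
    config: AnalysisConfig,
    meta: SampleMetadata,
) -> ModelStageResult:
    """Fit every feature, adjust p-values within each term, summarize.

    Adjustment runs across features separately for each model term, with
    the configured method; significant-feature counts use ``config.alpha``
    and skip degenerate (constant) features.
    """
    sub = meta.subset(expr.sample_ids)
    Y = expr.values.to_numpy()
    out = decompose(Y, design, sub)
    terms = out["terms"]

    cols: dict[str, np.ndarray] = {}
    counts_raw = {}
    counts_adj = {}
    for t in terms:
        padj = adjust_pvalues(out["p"][t], config.adjust_method)
        cols[f"SS_{t}"] = out["ss"][t]
        cols[f"pctSS_{t}"] = out["pct_ss"][t]
        cols[f"F_{t}"] = out["f"][t]
        cols[f"p_{t}"] = out["p"][t]
        cols[f"padj_{t}"] = padj
        with np.errstate(invalid="ignore"):
            counts_raw[t] = int(np.nansum(out["p"][t] < config.alpha))
            counts_adj[t] = int(np.nansum(padj < config.alpha))
    cols[f"SS_{RESIDUAL}"] = out["residual_ss"]
    cols[f"pctSS_{RESIDUAL}"] = out["pct_ss"][RESIDUAL]
    table = pd.DataFrame(cols, index=expr.values.index)

    pct_frame = pd.DataFrame(
        {t: out["pct_ss"][t] for t in terms + [RESIDUAL]}, index=expr.values.index
    )
    if out["degenerate"].any():
        pct_frame = pct_frame.loc[~out["degenerate"]]
    summary = _distribution_summary(pct_frame)

    counts = pd.DataFrame(
        {
            "n_significant_raw": pd.Series(counts_raw),
            "n_significant_adjusted": pd.Series(counts_adj),
        }
    )
    counts.index.name = "variable"
    df = dict(out["df"])
    df[RESIDUAL] = out["df_resid"]
    return ModelStageResult(table=table, summary=summary, counts=counts, terms=terms, df=df)
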