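"""Transformation and normalization of intensity matrices.

Four options are offered, mirroring common LC-MS preprocessing practice:

``log2``
    Plain log base-2 transform of the raw intensities.
``QN``
    Quantile normalization of the log2 data: every sample is forced onto
    the reference distribution formed by averaging order statistics
    across samples.
``VSN``
    Variance-stabilizing normalization of the raw intensities: a
    per-sample affine calibration followed by a generalized logarithm
    (arsinh), fitted by profile maximum likelihood under a
    constant-variance model and scaled to agree with log2 at high
    intensities.
``none``
    Pass-through, for data the user has already normalized.

QN and VSN can be applied group-wise on the ``Norm_Imp_Group`` sample
partition, each group being normalized fully independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import rankdata

from .datamodel import (
    AnalysisConfig,
    DataModelError,
    ExpressionMatrix,
    SampleMetadata,
)

LN2 = float(np.log(2.0))


class NormalizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# log2
# ---------------------------------------------------------------------------

def log2_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2 of every non-missing value; non-positive values become missing.

    Zeros (and any negative values on a mislabelled scale) cannot be
    log-transformed; they are converted to missing and reported through a
    warning rather than silently offset.
    """
    if expr.scale_tag != "raw":
        raise NormalizationError(f"log2_transform expects raw data, got {expr.scale_tag!r}")
    vals = expr.values.to_numpy(copy=True)
    with np.errstate(invalid="ignore"):
        nonpos = (vals <= 0) & ~np.isnan(vals)
    n_nonpos = int(nonpos.sum())
    if n_nonpos:
        warnings.warn(
            f"log2_transform: {n_nonpos} non-positive value(s) set to missing",
            UserWarning,
            stacklevel=2,
        )
        vals[nonpos] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(vals)
    frame = pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns)
    return expr.with_values(frame, scale_tag="log2")


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Mean-of-order-statistics quantile normalization on log2 data.

    The reference distribution is the across-sample mean of order
    statistics, built from each column's observed values only (columns
    with missing entries contribute through quantile interpolation onto a
    common grid).  Each column's observed values are then mapped to the
    reference by rank; tied values receive the average of the reference
    values at their tied ranks.  Missingness is preserved exactly.
    """
    if expr.scale_tag != "log2":
        raise NormalizationError(f"quantile_normalize expects log2 data, got {expr.scale_tag!r}")
    if expr.n_samples < 2:
        warnings.warn("quantile_normalize: single sample, returning input unchanged", UserWarning)
        return expr.copy()
    X = expr.values.to_numpy(copy=True)
    n_feat, n_samp = X.shape
    grid = np.linspace(0.0, 1.0, n_feat) if n_feat > 1 else np.array([0.0])

    # reference: mean over samples of each column's observed order statistics,
    # interpolated onto the common quantile grid
    ref = np.zeros(n_feat)
    for j in range(n_samp):
        col = X[:, j]
        obs = np.sort(col[~np.isnan(col)])
        m = obs.size
        if m == 0:
            raise NormalizationError(f"sample {expr.values.columns[j]!r} is entirely missing")
        probs = np.linspace(0.0, 1.0, m) if m > 1 else np.array([0.5])
        ref += np.interp(grid, probs, obs)
    ref /= n_samp

    out = np.full_like(X, np.nan)
    for j in range(n_samp):
        col = X[:, j]
        mask = ~np.isnan(col)
        obs = col[mask]
        m = obs.size
        # values at ordinal ranks, then averaged within tie groups
        order = np.argsort(obs, kind="mergesort")
        probs = np.linspace(0.0, 1.0, m) if m > 1 else np.array([0.5])
        at_ordinal = np.empty(m)
        at_ordinal[order] = np.interp(probs, grid, ref)
        ranks = rankdata(obs, method="average")
        normalized = pd.Series(at_ordinal).groupby(ranks).transform("mean").to_numpy()
        out[mask, j] = normalized
    frame = pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns)
    return expr.with_values(frame, scale_tag="log2")


# ---------------------------------------------------------------------------
# variance-stabilizing normalization
# ---------------------------------------------------------------------------

@dataclass
class VSNFit:
    """Fitted per-sample calibration of the glog transform.

    The transform for sample ``s`` is ``h_s(x) = arsinh(a_s + b_s x) / ln 2``,
    strictly increasing in ``x`` for ``b_s > 0`` and asymptotically equal to
    ``log2(x) + log2(2 b_s)`` at high intensities.
    """

    offsets: pd.Series          # a_s
    scales: pd.Series           # b_s, positive
    converged: bool
    n_iter: int
    objective: float

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        a = self.offsets[values.columns].to_numpy()
        b = self.scales[values.columns].to_numpy()
        z = a[None, :] + b[None, :] * values.to_numpy()
        return pd.DataFrame(
            np.arcsinh(z) / LN2, index=values.index, columns=values.columns
        )


MIN_COMPLETE_FEATURES = 10
# Floor on the per-entry mean squared residual inside the log-likelihood.
# It only matters for exactly-collinear samples, where the ML optimum has
# zero residual; the floor keeps the objective finite there.
_MSE_FLOOR = 1e-18


def _vsn_objective(theta: np.ndarray, X: np.ndarray, mask: np.ndarray):
    """Profile negative log-likelihood and its gradient.

    Model: h(x_is) = arsinh(a_s + b_s x_is) = mu_i + eps, eps ~ N(0, s^2),
    with the row means mu_i and the variance s^2 profiled out.  The
    Jacobian term sum log h'(x_is) makes the likelihood invariant to the
    measurement scale and prevents the transform from collapsing.
    """
    n_samp = X.shape[1]
    a = theta[:n_samp]
    logb = theta[n_samp:]
    b = np.exp(logb)
    z = a[None, :] + b[None, :] * X
    h = np.arcsinh(z)
    hyp = np.hypot(1.0, z)  # sqrt(1 + z^2), overflow-safe

    w = mask.astype(float)
    n_obs_row = w.sum(axis=1)
    h0 = np.where(mask, h, 0.0)
    mu = h0.sum(axis=1) / np.maximum(n_obs_row, 1.0)
    r = np.where(mask, h - mu[:, None], 0.0)
    N = w.sum()
    rss = float((r * r).sum())
    mse = rss / N

    # - sum log h' = - sum [log b_s - log hyp]
    log_jac = np.where(mask, logb[None, :] - np.log(hyp), 0.0)
    obj = 0.5 * N * np.log(mse + _MSE_FLOOR) - log_jac.sum()

    # gradient (envelope theorem: mu, s^2 at their optima)
    dL_dh = (N / (rss + _MSE_FLOOR * N)) * r          # = r / (mse + floor) / 1 ... per entry
    inv_hyp = 1.0 / hyp
    zr = z * inv_hyp * inv_hyp                         # z / (1 + z^2)
    grad_a = np.where(mask, dL_dh * inv_hyp + zr, 0.0).sum(axis=0)
    bx = b[None, :] * X
    grad_logb = np.where(mask, (dL_dh * inv_hyp + zr) * bx - 1.0, 0.0).sum(axis=0)
    return obj, np.concatenate([grad_a, grad_logb])


def vsn_normalize(expr: ExpressionMatrix, max_iter: int = 2000) -> tuple[ExpressionMatrix, VSNFit]:
    """Fit and apply the variance-stabilizing glog transform.

    Initialization is deterministic (column medians/MADs); the fit runs
    L-BFGS-B on the profile likelihood to tight tolerances so that exact
    between-sample scale factors are absorbed to high precision.
    """
    if expr.scale_tag != "raw":
        raise NormalizationError(f"vsn_normalize expects raw data, got {expr.scale_tag!r}")
    if expr.n_samples < 2:
        raise NormalizationError("vsn_normalize requires at least 2 samples")
    X = expr.values.to_numpy()
    mask = ~np.isnan(X)
    complete = mask.all(axis=1)
    if int(complete.sum()) < MIN_COMPLETE_FEATURES:
        raise NormalizationError(
            f"VSN needs at least {MIN_COMPLETE_FEATURES} complete features to fit "
            f"({int(complete.sum())} found); consider log2 + quantile normalization"
        )
    usable = mask.sum(axis=1) >= 2
    maskf = mask[usable]
    Xfit = np.where(maskf, X[usable], 0.0)

    a0 = np.empty(expr.n_samples)
    b0 = np.empty(expr.n_samples)
    for j in range(expr.n_samples):
        col = X[:, j][mask[:, j]]
        med = float(np.median(col))
        mad = float(np.median(np.abs(col - med)))
        if mad <= 0:
            mad = max(abs(med), 1.0)
        b0[j] = 1.0 / mad
        a0[j] = -med / mad
    theta0 = np.concatenate([a0, np.log(b0)])

    res = minimize(
        _vsn_objective,
        theta0,
        args=(Xfit, maskf),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-10, "maxcor": 25},
    )
    n_samp = expr.n_samples
    a = res.x[:n_samp]
    b = np.exp(res.x[n_samp:])
    fit = VSNFit(
        offsets=pd.Series(a, index=expr.values.columns),
        scales=pd.Series(b, index=expr.values.columns),
        converged=bool(res.success),
        n_iter=int(res.nit),
        objective=float(res.fun),
    )
    transformed = fit.transform(expr.values)
    return expr.with_values(transformed, scale_tag="glog"), fit


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def _normalize_block(expr: ExpressionMatrix, method: str) -> ExpressionMatrix:
    if method == "log2":
        return log2_transform(expr)
    if method == "QN":
        return quantile_normalize(log2_transform(expr))
    if method == "VSN":
        out, _ = vsn_normalize(expr)
        return out
    if method == "none":
        return expr.copy()
    raise NormalizationError(f"unknown normalization {method!r}")


def apply_normalization(
    expr: ExpressionMatrix, config: AnalysisConfig, meta: SampleMetadata
) -> ExpressionMatrix:
    """Dispatch the configured normalization, globally or group-wise.

    Group-wise QN/VSN runs fully independently on each ``Norm_Imp_Group``
    subset of samples and reassembles the columns in their original order.
    The log2 transform is elementwise, so group-wise and global log2
    coincide; ``none`` is always a pass-through.
    """
    method = config.normalization
    if method == "none":
        return expr.copy()
    if not config.groupwise or method == "log2":
        return _normalize_block(expr, method)
    if meta.norm_imp_group is None:
        raise DataModelError(
            "group-wise normalization requested but metadata has no Norm_Imp_Group column"
        )
    groups = meta.norm_imp_group[expr.values.columns]
    pieces = []
    for g in dict.fromkeys(groups):
        cols = [s for s in expr.sample_ids if groups[s] == g]
        sub = expr.with_values(expr.values[cols])
        pieces.append(_normalize_block(sub, method))
    tags = {p.scale_tag for p in pieces}
    merged = pd.concat([p.values for p in pieces], axis=1)[expr.sample_ids]
    return ExpressionMatrix(values=merged, scale_tag=tags.pop(), protein_ids=expr.protein_ids)
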