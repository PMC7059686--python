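"""Missing-value imputation under MAR/MCAR: feature-wise KNN and iterative SVD.

Both methods run on normalized (log2/glog) data, leave observed cells
untouched, and return a matrix with no missing entries.  They can be
applied globally or independently per ``Norm_Imp_Group`` sample subset.
MNAR-aware (left-censored) imputation is deliberately not offered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    AnalysisConfig,
    DataModelError,
    ExpressionMatrix,
    SampleMetadata,
)


class ImputationError(ValueError):
    pass


@dataclass
class ImputationSpec:
    """Tuning parameters for the two imputers.

    ``k_neighbors`` (KNN) and ``rank`` (SVD) follow the conventional
    defaults of their method families; ``max_missing_row_frac`` is the
    row-missingness fraction beyond which KNN falls back to per-sample
    column means.
    """

    method: str = "SVD"
    k_neighbors: int = 10
    rank: int = 2
    max_missing_row_frac: float = 0.5
    tol: float = 1e-6
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.method not in ("SVD", "KNN"):
            raise DataModelError(f"imputation method must be SVD or KNN, got {self.method!r}")
        if self.k_neighbors < 1 or self.rank < 1 or self.max_iter < 1:
            raise DataModelError("k_neighbors, rank and max_iter must be positive")
        if not (0.0 <= self.max_missing_row_frac <= 1.0):
            raise DataModelError("max_missing_row_frac must lie in [0, 1]")
        if self.tol <= 0:
            raise DataModelError("tol must be positive")


def _check_scale(expr: ExpressionMatrix) -> None:
    # raw-tagged input is allowed (the "none" normalization option hands
    # pre-normalized user data through with its tag unchanged) but both
    # imputers are designed for log-like scales, so flag it
    if expr.scale_tag not in ("log2", "glog"):
        warnings.warn(
            f"imputing data tagged {expr.scale_tag!r}; imputation is intended "
            "for normalized (log2/glog) intensities",
            UserWarning,
        )


def _check_columns(X: np.ndarray, columns) -> None:
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        bad = [str(columns[j]) for j in np.where(all_missing)[0]]
        raise ImputationError(f"column(s) entirely missing, cannot impute: {bad}")


# ---------------------------------------------------------------------------
# KNN
# ---------------------------------------------------------------------------

def impute_knn(expr: ExpressionMatrix, spec: ImputationSpec | None = None) -> ExpressionMatrix:
    """Feature-wise k-nearest-neighbour imputation.

    For each incomplete feature the k nearest donor features are found by
    Euclidean distance over coordinates observed in both rows, rescaled
    by the number of shared coordinates (an RMS distance, so rows with
    different overlap sizes are comparable).  Each missing cell is the
    1/distance-weighted average of donor values at that cell, skipping
    donors that are also missing there; zero-distance donors (exact
    duplicates) are averaged unweighted.  Features missing more than
    ``max_missing_row_frac`` of their samples — and cells no donor can
    supply — fall back to the per-sample column mean.  Ties in distance
    are broken by feature input order.
    """
    spec = spec or ImputationSpec(method="KNN")
    _check_scale(expr)
    X = expr.values.to_numpy(copy=True)
    n_feat, n_samp = X.shape
    _check_columns(X, expr.values.columns)
    mask = ~np.isnan(X)
    col_means = np.nanmean(X, axis=0)

    too_missing = mask.sum(axis=1) < (1.0 - spec.max_missing_row_frac) * n_samp
    incomplete = np.where(~mask.all(axis=1))[0]
    Xobs = np.where(mask, X, 0.0)
    for i in incomplete:
        if too_missing[i]:
            X[i, ~mask[i]] = col_means[~mask[i]]
            continue
        shared = mask & mask[i]            # (n_feat, n_samp)
        n_shared = shared.sum(axis=1)
        diff = np.where(shared, Xobs - Xobs[i], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            d2 = (diff * diff).sum(axis=1) / n_shared
        d = np.sqrt(d2)
        d[i] = np.inf                       # not its own donor
        d[n_shared == 0] = np.inf
        order = np.argsort(d, kind="stable")
        k = min(spec.k_neighbors, int(np.isfinite(d[order]).sum()))
        if k == 0:
            X[i, ~mask[i]] = col_means[~mask[i]]
            continue
        donors = order[:k]
        for j in np.where(~mask[i])[0]:
            have = donors[mask[donors, j]]
            if have.size == 0:
                X[i, j] = col_means[j]
                continue
            dh = d[have]
            if np.any(dh == 0.0):
                X[i, j] = X[have[dh == 0.0], j].mean()
            else:
                w = 1.0 / dh
                X[i, j] = float(np.dot(w, X[have, j]) / w.sum())
    frame = pd.DataFrame(X, index=expr.values.index, columns=expr.values.columns)
    return expr.with_values(frame)


# ---------------------------------------------------------------------------
# iterative SVD
# ---------------------------------------------------------------------------

def impute_svd(
    expr: ExpressionMatrix,
    spec: ImputationSpec | None = None,
    _trace: list | None = None,
) -> ExpressionMatrix:
    """Iterative low-rank (truncated SVD) matrix completion.

    Missing cells are initialized with feature (row) means, then
    repeatedly replaced by their rank-``r`` reconstruction until the
    relative change of the imputed cells drops below ``tol`` or
    ``max_iter`` is reached.  Observed cells are never modified; the
    Frobenius distance between successive fills is non-increasing.
    """
    spec = spec or ImputationSpec(method="SVD")
    _check_scale(expr)
    X = expr.values.to_numpy(copy=True)
    _check_columns(X, expr.values.columns)
    mask = ~np.isnan(X)
    if mask.all():
        return expr.copy()
    rank = min(spec.rank, min(X.shape) - 1) if min(X.shape) > 1 else 1

    row_means = np.nanmean(np.where(mask, X, np.nan), axis=1)
    col_means = np.nanmean(np.where(mask, X, np.nan), axis=0)
    fill = np.where(np.isnan(row_means)[:, None], col_means[None, :], row_means[:, None])
    X[~mask] = fill[~mask]

    converged = False
    for _ in range(spec.max_iter):
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        recon = (U[:, :rank] * s[:rank]) @ Vt[:rank]
        new_vals = recon[~mask]
        old_vals = X[~mask]
        denom = max(float(np.linalg.norm(old_vals)), 1e-12)
        delta = float(np.linalg.norm(new_vals - old_vals)) / denom
        if _trace is not None:
            # alternating-minimization objective ||X_fill - rank-r recon||_F;
            # non-increasing by construction (each half-step minimizes it)
            _trace.append(float(np.linalg.norm(X - recon)))
        X[~mask] = new_vals
        if delta < spec.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"SVD imputation did not converge within {spec.max_iter} iterations",
            UserWarning,
        )
    frame = pd.DataFrame(X, index=expr.values.index, columns=expr.values.columns)
    return expr.with_values(frame)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def apply_imputation(
    expr: ExpressionMatrix,
    config: AnalysisConfig,
    meta: SampleMetadata,
    spec: ImputationSpec | None = None,
) -> ExpressionMatrix:
    """Dispatch SVD/KNN imputation, globally or per Norm_Imp_Group subset.

    Imputation happens at the level the data was provided; for peptide
    data analyzed at protein level the pipeline imputes peptides first
    and aggregates afterwards.
    """
    if config.analysis_method != "impute_mv":
        raise ImputationError("apply_imputation called but analysis_method is not impute_mv")
    spec = spec or ImputationSpec(method=config.imputation)
    func = impute_svd if spec.method == "SVD" else impute_knn
    if not config.groupwise:
        return func(expr, spec)
    if meta.norm_imp_group is None:
        raise DataModelError(
            "group-wise imputation requested but metadata has no Norm_Imp_Group column"
        )
    groups = meta.norm_imp_group[expr.values.columns]
    pieces = []
    for g in dict.fromkeys(groups):
        cols = [s for s in expr.sample_ids if groups[s] == g]
        sub = expr.with_values(expr.values[cols])
        pieces.append(func(sub, spec))
    merged = pd.concat([p.values for p in pieces], axis=1)[expr.sample_ids]
    return ExpressionMatrix(values=merged, scale_tag=expr.scale_tag, protein_ids=expr.protein_ids)
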