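"""Coefficient-of-variation analysis per group within categorical variables.

For every feature and every level of each selected categorical variable,
CV = 100 * sample SD / sample mean over the samples at that level
(computed on the same preprocessed matrix that enters the model stage).
A smaller CV marks a less variable workflow option.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, SampleMetadata

#: Means at or below this magnitude make the CV numerically meaningless.
MEAN_EPS = 1e-12


def group_columns(meta: SampleMetadata, variables: list[str]) -> dict[str, list]:
    """Map ``"var=level"`` labels to the sample ids at that level."""
    out: dict[str, list] = {}
    for var in variables:
        lab = meta.table[var].astype(str)
        for level in meta.levels(var):
            out[f"{var}={level}"] = list(lab.index[lab == level])
    return out


def compute_cv(
    expr: ExpressionMatrix, meta: SampleMetadata, variables: list[str]
) -> pd.DataFrame:
    """Per-feature CV (percent) for each (variable, level) group.

    Uses the sample (n-1) standard deviation.  Cells with fewer than two
    observed values or with mean <= ``MEAN_EPS`` are missing rather than
    infinite; a level with fewer than two samples yields an all-missing
    column and a warning.
    """
    sub = meta.subset(expr.sample_ids)
    groups = group_columns(sub, variables)
    out = {}
    for label, samples in groups.items():
        if len(samples) < 2:
            warnings.warn(
                f"group {label!r} has fewer than 2 samples; its CV column is all missing",
                UserWarning,
            )
            out[label] = pd.Series(np.nan, index=expr.values.index)
            continue
        block = expr.values[samples]
        n_obs = block.notna().sum(axis=1)
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        cv = 100.0 * sd / mean
        cv[(n_obs < 2) | (mean <= MEAN_EPS)] = np.nan
        out[label] = cv
    table = pd.DataFrame(out, index=expr.values.index)
    table.index.name = "feature"
    return table


def summarize_cv(table: pd.DataFrame) -> pd.DataFrame:
    """min/Q1/median/mean/Q3/max of CV across features, per group."""
    if table.empty:
        raise ValueError("CV table is empty")
    return pd.DataFrame(
        {
            "min": table.min(),
            "Q1": table.quantile(0.25),
            "median": table.median(),
            "mean": table.mean(),
            "Q3": table.quantile(0.75),
            "max": table.max(),
        }
    )
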