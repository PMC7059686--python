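"""Peptide-to-protein rollup (and merging of redundant feature ids).

Aggregation collapses each group of rows sharing a protein id to a single
row using one of four summaries: mean, median, sum or maximum.  Missing
values are skipped when at least one contributing value is observed; a
cell is missing only when every contributing value is missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datamodel import AGGREGATION_METHODS, DataModelError, ExpressionMatrix


@dataclass
class AggregationSpec:
    """How to collapse features: a summary method plus feature -> group map."""

    method: str
    group_key: pd.Series  # feature_id -> protein_id, parallel to the matrix rows

    def __post_init__(self) -> None:
        if self.method not in AGGREGATION_METHODS:
            raise DataModelError(
                f"aggregation method must be one of {AGGREGATION_METHODS}, got {self.method!r}"
            )


_AGG_FUNCS = {"mean": "mean", "median": "median", "maximum": "max"}


def aggregate(expr: ExpressionMatrix, spec: AggregationSpec) -> ExpressionMatrix:
    """Collapse rows of ``expr`` by protein id.

    Output rows follow first-appearance order of the protein ids; the
    scale tag is preserved.  ``sum`` uses ``min_count=1`` so that a group
    with no observed values yields a missing cell rather than 0.
    """
    if expr.n_features == 0:
        raise DataModelError("cannot aggregate an empty matrix")
    if len(spec.group_key) != expr.n_features or not (
        pd.Index(spec.group_key.index) == expr.values.index
    ).all():
        missing = set(expr.values.index) - set(spec.group_key.index)
        raise DataModelError(f"group_key does not cover all features; missing {sorted(missing)[:5]}")
    groups = pd.Series(spec.group_key.to_numpy(), index=expr.values.index)
    gb = expr.values.groupby(groups.to_numpy(), sort=False)
    if spec.method == "sum":
        out = gb.sum(min_count=1)
    else:
        out = gb.agg(_AGG_FUNCS[spec.method])
    out.index.name = "feature"
    return ExpressionMatrix(values=out, scale_tag=expr.scale_tag, protein_ids=None)


def spec_from_matrix(expr: ExpressionMatrix, method: str) -> AggregationSpec:
    """Build an AggregationSpec from the matrix's own protein mapping.

    Falls back to the feature ids themselves (merging redundant duplicate
    ids) when no protein mapping is attached.
    """
    if expr.protein_ids is not None:
        key = expr.protein_ids
    else:
        key = pd.Series(expr.values.index.to_numpy(), index=expr.values.index)
    return AggregationSpec(method=method, group_key=key)
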