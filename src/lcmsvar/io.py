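"""Reading and writing expression matrices, sample metadata and result tables.

File dialect
------------
Both inputs are delimited text (tab or comma, sniffed from the header
line).  The expression file carries one row per feature:

* protein level:  ``Protein, <sample 1>, <sample 2>, ...``
* peptide level:  ``Protein, Peptide, <sample 1>, ...``

Empty cells, ``NA`` and ``NaN`` (case-insensitive) are missing values.
The metadata file carries one row per sample: ``Sample, <var 1>, ...``;
a column literally named ``Norm_Imp_Group`` defines the group-wise
normalization/imputation partition and is not offered as an analysis
variable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    NORM_IMP_GROUP,
    DataModelError,
    ExpressionMatrix,
    SampleMetadata,
)

MISSING_TOKENS = {"", "na", "nan"}


class InputFormatError(ValueError):
    """Raised when an input file cannot be interpreted."""


def _sniff_sep(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _parse_numeric(raw: pd.DataFrame) -> pd.DataFrame:
    """Parse a table of strings into floats, NaN for missing tokens.

    Raises with the (feature, sample) coordinate of the first cell that is
    neither numeric nor a recognized missing token.
    """
    cleaned = raw.apply(lambda c: c.str.strip(), axis=0)
    is_missing = cleaned.apply(lambda c: c.str.lower().isin(MISSING_TOKENS))
    numeric = cleaned.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    bad = numeric.isna() & ~is_missing
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise InputFormatError(
            f"non-numeric intensity {raw.iat[i, j]!r} at feature "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    return numeric.mask(is_missing)


def read_expression(path, feature_type: str) -> ExpressionMatrix:
    """Read an expression matrix on the raw intensity scale.

    Parameters
    ----------
    path
        Delimited text file in the dialect above.
    feature_type
        Level of the *file*: ``"protein"`` (one id column) or
        ``"peptide"`` (protein id column followed by peptide id column).
    """
    path = Path(path)
    if feature_type not in ("protein", "peptide"):
        raise InputFormatError(f"feature_type must be protein or peptide, got {feature_type!r}")
    if not path.exists():
        raise InputFormatError(f"expression file not found: {path}")
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    n_id_cols = 2 if feature_type == "peptide" else 1
    if raw.shape[1] <= n_id_cols:
        raise InputFormatError(f"expression file {path} has zero sample columns")
    if raw.shape[0] == 0:
        raise InputFormatError(f"expression file {path} has no feature rows")
    protein_ids = None
    if feature_type == "peptide":
        protein_col = raw.iloc[:, 0].str.strip()
        feature_col = raw.iloc[:, 1].str.strip()
    else:
        feature_col = raw.iloc[:, 0].str.strip()
    body = raw.iloc[:, n_id_cols:]
    body.index = pd.Index(feature_col, name="feature")
    values = _parse_numeric(body)
    neg = values < 0
    if neg.to_numpy().any():
        i, j = np.argwhere(neg.to_numpy())[0]
        raise InputFormatError(
            f"negative intensity at feature {values.index[i]!r}, "
            f"sample {values.columns[j]!r}"
        )
    if feature_type == "peptide":
        protein_ids = pd.Series(np.asarray(protein_col), index=values.index)
    return ExpressionMatrix(values=values, scale_tag="raw", protein_ids=protein_ids)


def read_metadata(path) -> SampleMetadata:
    """Read the sample-information table and type its variables.

    A variable whose non-missing entries all parse as numbers becomes a
    continuous candidate; every other variable is a categorical candidate.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"metadata file not found: {path}")
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise InputFormatError("metadata file must have a sample id column plus >=1 variable")
    sample_ids = raw.iloc[:, 0].str.strip()
    if sample_ids.duplicated().any():
        dups = sample_ids[sample_ids.duplicated()].tolist()
        raise InputFormatError(f"duplicate sample ids in metadata: {dups}")
    table = raw.iloc[:, 1:].copy()
    table.index = pd.Index(sample_ids, name="sample")

    norm_imp_group = None
    if NORM_IMP_GROUP in table.columns:
        norm_imp_group = table[NORM_IMP_GROUP].astype(str)
        table = table.drop(columns=[NORM_IMP_GROUP])

    categorical: list[str] = []
    continuous: list[str] = []
    parsed = {}
    for col in table.columns:
        stripped = table[col].str.strip()
        numeric = pd.to_numeric(stripped, errors="coerce")
        if not numeric.isna().any():
            continuous.append(col)
            parsed[col] = numeric
        else:
            categorical.append(col)
            parsed[col] = stripped
    typed = pd.DataFrame(parsed, index=table.index)[list(table.columns)]
    return SampleMetadata(
        table=typed,
        categorical_vars=categorical,
        continuous_vars=continuous,
        norm_imp_group=norm_imp_group,
    )


def align(expr: ExpressionMatrix, meta: SampleMetadata) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Reorder expression columns to the metadata row order (id-based).

    The two sample id sets must be equal; values always follow their ids.
    """
    expr_ids = set(expr.sample_ids)
    meta_ids = set(meta.sample_ids)
    if expr_ids != meta_ids:
        only_expr = sorted(expr_ids - meta_ids)
        only_meta = sorted(meta_ids - expr_ids)
        raise DataModelError(
            "sample id mismatch between expression and metadata; "
            f"only in expression: {only_expr}; only in metadata: {only_meta}"
        )
    reordered = expr.values[meta.sample_ids]
    return expr.with_values(reordered), meta


def write_table(result: pd.DataFrame, path) -> None:
    """Write any result table as CSV with ``NA`` for missing entries."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    result.to_csv(path, na_rep="NA")


def read_table(path, index_col: int = 0) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, index_col=index_col, na_values=["NA"])
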