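"""Core data containers for the variability-analysis pipeline.

The pipeline moves a single object — an :class:`ExpressionMatrix` — through
aggregation, normalization, imputation and modelling.  Sample annotations
travel alongside it in a :class:`SampleMetadata`, and every user-facing
choice is collected in an :class:`AnalysisConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

SCALE_TAGS = ("raw", "log2", "glog")

AGGREGATION_METHODS = ("mean", "median", "sum", "maximum")
ANALYSIS_METHODS = ("exclude_mv", "impute_mv")
IMPUTATION_METHODS = ("SVD", "KNN")
NORMALIZATION_METHODS = ("log2", "QN", "VSN", "none")
ADJUST_METHODS = ("BH", "bonferroni", "holm", "hochberg", "hommel", "BY")
FEATURE_TYPES = ("protein", "peptide")

#: Name of the optional metadata column that partitions samples for
#: group-wise normalization/imputation.
NORM_IMP_GROUP = "Norm_Imp_Group"


class DataModelError(ValueError):
    """Raised when a container invariant is violated."""


@dataclass
class ExpressionMatrix:
    """A features x samples intensity table.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample.
        ``NaN`` encodes a missing measurement.  Duplicate feature ids are
        tolerated (they are merged by :func:`lcmsvar.aggregate.aggregate`);
        sample ids must be unique.
    scale_tag
        Records the transform state of the values: ``raw`` (non-negative
        intensities), ``log2`` or ``glog`` (generalized log from VSN).
    protein_ids
        For peptide-level data, a Series parallel to ``values.index``
        mapping each peptide to its protein.
    """

    values: pd.DataFrame
    scale_tag: str = "raw"
    protein_ids: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise DataModelError(
                f"unknown scale_tag {self.scale_tag!r}; expected one of {SCALE_TAGS}"
            )
        if not isinstance(self.values, pd.DataFrame):
            raise DataModelError("values must be a pandas DataFrame")
        self.values = self.values.astype(float)
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise DataModelError(f"duplicate sample ids: {dups}")
        if self.scale_tag == "raw":
            arr = self.values.to_numpy()
            with np.errstate(invalid="ignore"):
                bad = np.asarray(arr < 0)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise DataModelError(
                    "negative intensity on raw scale at feature "
                    f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
                )
        if self.protein_ids is not None:
            self.protein_ids = pd.Series(
                np.asarray(self.protein_ids), index=self.values.index
            )

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def with_values(self, values: pd.DataFrame, scale_tag: str | None = None) -> "ExpressionMatrix":
        """Return a copy carrying new values (and optionally a new scale)."""
        keep_proteins = self.protein_ids
        if keep_proteins is not None and not values.index.equals(self.values.index):
            keep_proteins = None
        return ExpressionMatrix(
            values=values.copy(),
            scale_tag=self.scale_tag if scale_tag is None else scale_tag,
            protein_ids=None if keep_proteins is None else keep_proteins.copy(),
        )

    def copy(self) -> "ExpressionMatrix":
        return self.with_values(self.values)


@dataclass
class SampleMetadata:
    """Per-sample design variables.

    ``table`` is indexed by sample id.  ``categorical_vars`` and
    ``continuous_vars`` list the candidate analysis variables by type;
    a column literally named ``Norm_Imp_Group`` is routed to
    ``norm_imp_group`` and never offered as an analysis variable.
    """

    table: pd.DataFrame
    categorical_vars: list[str] = field(default_factory=list)
    continuous_vars: list[str] = field(default_factory=list)
    norm_imp_group: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise DataModelError(f"duplicate sample ids in metadata: {dups}")
        for var in self.continuous_vars:
            col = pd.to_numeric(self.table[var], errors="coerce")
            if col.isna().any():
                raise DataModelError(
                    f"continuous variable {var!r} contains missing/non-numeric values"
                )
        if self.norm_imp_group is not None:
            self.norm_imp_group = pd.Series(
                np.asarray(self.norm_imp_group).astype(str), index=self.table.index
            )

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    def levels(self, var: str) -> list:
        """Distinct levels of a categorical variable, in order of appearance."""
        if var not in self.categorical_vars:
            raise DataModelError(f"{var!r} is not a categorical variable")
        seen = self.table[var].astype(str)
        return list(dict.fromkeys(seen))

    def continuous(self, var: str) -> pd.Series:
        if var not in self.continuous_vars:
            raise DataModelError(f"{var!r} is not a continuous variable")
        return pd.to_numeric(self.table[var])

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(
            table=self.table.loc[list(sample_ids)].copy(),
            categorical_vars=list(self.categorical_vars),
            continuous_vars=list(self.continuous_vars),
            norm_imp_group=None
            if self.norm_imp_group is None
            else self.norm_imp_group.loc[list(sample_ids)].copy(),
        )


def _check_choice(name: str, value, options) -> None:
    if value not in options:
        raise DataModelError(f"{name} must be one of {options}, got {value!r}")


@dataclass
class AnalysisConfig:
    """Every user choice of the analysis workflow.

    ``feature_type`` is the level at which variability is analyzed; when
    peptide data is analyzed at protein level the aggregation method is
    used to roll peptides up.  ``analysis_method`` selects between
    discarding features with missing values and imputing them
    (``imputation`` only matters in the latter case).
    """

    feature_type: str = "protein"
    aggregation: str = "mean"
    analysis_method: str = "exclude_mv"
    imputation: str = "SVD"
    normalization: str = "log2"
    groupwise: bool = False
    alpha: float = 0.05
    adjust_method: str = "BH"
    seed: int = 0

    def __post_init__(self) -> None:
        _check_choice("feature_type", self.feature_type, FEATURE_TYPES)
        _check_choice("aggregation", self.aggregation, AGGREGATION_METHODS)
        _check_choice("analysis_method", self.analysis_method, ANALYSIS_METHODS)
        _check_choice("imputation", self.imputation, IMPUTATION_METHODS)
        _check_choice("normalization", self.normalization, NORMALIZATION_METHODS)
        _check_choice("adjust_method", self.adjust_method, ADJUST_METHODS)
        if not (0.0 < self.alpha < 1.0):
            raise DataModelError(f"alpha must lie in (0, 1), got {self.alpha}")
        self.seed = int(self.seed)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "feature_type": self.feature_type,
            "aggregation": self.aggregation,
            "analysis_method": self.analysis_method,
            "imputation": self.imputation,
            "normalization": self.normalization,
            "groupwise": self.groupwise,
            "alpha": self.alpha,
            "adjust_method": self.adjust_method,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = cls().to_dict().keys()
        unknown = set(d) - set(known)
        if unknown:
            raise DataModelError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "groupwise" in kwargs and isinstance(kwargs["groupwise"], str):
            kwargs["groupwise"] = kwargs["groupwise"].strip().lower() in ("true", "1", "yes")
        if "alpha" in kwargs:
            kwargs["alpha"] = float(kwargs["alpha"])
        if "seed" in kwargs:
            kwargs["seed"] = int(kwargs["seed"])
        return cls(**kwargs)
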