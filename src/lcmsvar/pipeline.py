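"""End-to-end orchestration: read -> preprocess -> model -> CV -> report.

Stage order
-----------
* exclude mode: read & align -> drop features with any missing value ->
  normalize -> aggregate (if analyzing peptide data at protein level) ->
  model/CV/plots.
* impute mode: read & align -> normalize -> impute at the provided level
  -> aggregate -> model/CV/plots.

Every stage appends a structured record (name, features/samples in and
out) to the run's stage log for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from . import report
from .aggregate import aggregate as _aggregate, spec_from_matrix
from . import cv as cvmod
from . import impute as impmod
from . import model as modelmod
from . import normalize as normmod
from .datamodel import AnalysisConfig, ExpressionMatrix


class PipelineError(RuntimeError):
    pass


@dataclass
class RunResult:
    """Everything a pipeline run produced."""

    config: AnalysisConfig
    expr: ExpressionMatrix              # matrix that entered the model stage
    model: modelmod.ModelStageResult
    cv_table: pd.DataFrame
    cv_summary: pd.DataFrame
    stage_log: list = field(default_factory=list)
    paths: dict = field(default_factory=dict)


def load_config(path) -> AnalysisConfig:
    """Load an AnalysisConfig from a YAML (or flat key: value) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise PipelineError(f"config file {path} must contain a mapping")
    return AnalysisConfig.from_dict(data)


def detect_level(path) -> str:
    """Guess whether an expression file is peptide- or protein-level.

    Peptide files carry a second, non-numeric id column before the sample
    columns; if every value of column 2 parses as a number the file is
    taken as protein-level.
    """
    head = pd.read_csv(path, sep=io._sniff_sep(Path(path)), dtype=str, nrows=50,
                       keep_default_na=False)
    if head.shape[1] < 2:
        return "protein"
    second = pd.to_numeric(head.iloc[:, 1].str.strip(), errors="coerce")
    return "protein" if not second.isna().any() else "peptide"


def _needs_aggregation(expr: ExpressionMatrix, config: AnalysisConfig, data_level: str) -> bool:
    if data_level == "peptide" and config.feature_type == "protein":
        return True
    return bool(expr.values.index.duplicated().any())


def run_pipeline(
    config: AnalysisConfig,
    expr_path,
    meta_path,
    outdir,
    categorical_vars: list[str] | None = None,
    continuous_vars: list[str] | None = None,
    data_level: str | None = None,
    imputation_spec: impmod.ImputationSpec | None = None,
    write_plots: bool = True,
) -> RunResult:
    """Execute the full analysis and write all result tables and plots.

    ``categorical_vars`` / ``continuous_vars`` default to every candidate
    the metadata offers.  ``data_level`` (the level of the uploaded file)
    is sniffed from the file when not given.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list = []

    def record(stage: str, expr: ExpressionMatrix) -> None:
        log.append(
            {
                "stage": stage,
                "n_features": expr.n_features,
                "n_samples": expr.n_samples,
                "n_missing": expr.n_missing,
                "scale": expr.scale_tag,
            }
        )

    try:
        level = data_level or detect_level(expr_path)
        expr = io.read_expression(expr_path, feature_type=level)
        meta = io.read_metadata(meta_path)
        expr, meta = io.align(expr, meta)
    except Exception as exc:  # stage-named failure
        raise PipelineError(f"input stage: {exc}") from exc
    record("read_align", expr)

    cat = categorical_vars if categorical_vars is not None else list(meta.categorical_vars)
    cont = continuous_vars if continuous_vars is not None else list(meta.continuous_vars)
    design = modelmod.DesignSpec(categorical_vars=cat, continuous_vars=cont)

    if config.analysis_method == "exclude_mv":
        complete = expr.values.notna().all(axis=1)
        kept = expr.values.loc[complete]
        if kept.shape[0] == 0:
            raise PipelineError(
                "exclusion stage: no features remain after discarding features "
                "with missing values; consider analysis_method=impute_mv"
            )
        prot = None if expr.protein_ids is None else expr.protein_ids.loc[complete]
        expr = ExpressionMatrix(values=kept, scale_tag=expr.scale_tag, protein_ids=prot)
        record("exclude_missing", expr)
        try:
            expr = normmod.apply_normalization(expr, config, meta)
        except Exception as exc:
            raise PipelineError(f"normalization stage: {exc}") from exc
        record("normalize", expr)
    else:
        try:
            expr = normmod.apply_normalization(expr, config, meta)
        except Exception as exc:
            raise PipelineError(f"normalization stage: {exc}") from exc
        record("normalize", expr)
        try:
            expr = impmod.apply_imputation(expr, config, meta, imputation_spec)
        except Exception as exc:
            raise PipelineError(f"imputation stage: {exc}") from exc
        record("impute", expr)

    if _needs_aggregation(expr, config, level):
        try:
            expr = _aggregate(expr, spec_from_matrix(expr, config.aggregation))
        except Exception as exc:
            raise PipelineError(f"aggregation stage: {exc}") from exc
        record("aggregate", expr)

    # exclude mode can still hold missing cells created by log2 of zeros
    if config.analysis_method == "exclude_mv" and expr.n_missing:
        complete = expr.values.notna().all(axis=1)
        expr = expr.with_values(expr.values.loc[complete])
        record("exclude_missing_post_transform", expr)

    try:
        model_res = modelmod.run_model_stage(expr, design, config, meta)
    except Exception as exc:
        raise PipelineError(f"model stage: {exc}") from exc
    record("model", expr)

    try:
        cv_table = cvmod.compute_cv(expr, meta, cat)
        cv_summary = cvmod.summarize_cv(cv_table)
    except Exception as exc:
        raise PipelineError(f"cv stage: {exc}") from exc
    record("cv", expr)

    paths = {}
    tables = {
        "ss_table.csv": model_res.table,
        "ss_summary.csv": model_res.summary,
        "significance_counts.csv": model_res.counts,
        "cv_table.csv": cv_table,
        "cv_summary.csv": cv_summary,
        "inputs.csv": report.echo_inputs(config),
    }
    for name, tab in tables.items():
        io.write_table(tab, outdir / name)
        paths[name] = outdir / name
    if write_plots:
        for p in report.plot_preprocessed(expr, outdir):
            paths[p.name] = p
        for p in report.plot_results(model_res.table, cv_table, outdir):
            paths[p.name] = p
    log_frame = pd.DataFrame(log).set_index("stage")
    io.write_table(log_frame, outdir / "stage_log.csv")
    paths["stage_log.csv"] = outdir / "stage_log.csv"

    return RunResult(
        config=config,
        expr=expr,
        model=model_res,
        cv_table=cv_table,
        cv_summary=cv_summary,
        stage_log=log,
        paths=paths,
    )
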