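"""Static exploratory and result plots, plus the input-echo table.

All figures are written as both PNG and SVG with deterministic content:
a fixed SVG hash salt and no embedded timestamps, so identical inputs
regenerate byte-identical files.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .datamodel import AnalysisConfig, ExpressionMatrix

matplotlib.rcParams["svg.hashsalt"] = "lcmsvar"


def _save(fig, outdir: Path, stem: str) -> list[Path]:
    paths = []
    for ext in ("png", "svg"):
        p = outdir / f"{stem}.{ext}"
        fig.savefig(p, metadata={"Date": None} if ext == "svg" else {"Software": "lcmsvar"})
        paths.append(p)
    plt.close(fig)
    return paths


def plot_preprocessed(expr: ExpressionMatrix, outdir) -> list[Path]:
    """Per-sample box plot, density overlay and sample-correlation heatmap.

    The heatmap uses pairwise-complete Pearson correlations so it can be
    drawn on data that still contains missing values.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vals = expr.values
    written: list[Path] = []

    fig, ax = plt.subplots(figsize=(max(6, 0.25 * expr.n_samples), 4))
    data = [vals[c].dropna().to_numpy() for c in vals.columns]
    ax.boxplot(data, tick_labels=[str(c) for c in vals.columns])
    ax.set_ylabel(f"intensity ({expr.scale_tag})")
    ax.set_title("Per-sample intensity distribution")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    written += _save(fig, outdir, "boxplot_samples")

    fig, ax = plt.subplots(figsize=(6, 4))
    for c in vals.columns:
        x = vals[c].dropna().to_numpy()
        if x.size < 2 or np.ptp(x) == 0:
            continue
        grid = np.linspace(x.min(), x.max(), 200)
        ax.plot(grid, gaussian_kde(x)(grid), linewidth=0.8)
    ax.set_xlabel(f"intensity ({expr.scale_tag})")
    ax.set_ylabel("density")
    ax.set_title("Per-sample intensity density")
    fig.tight_layout()
    written += _save(fig, outdir, "density_samples")

    corr = vals.corr(method="pearson")  # pairwise-complete by construction
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), [str(c) for c in corr.columns], rotation=90, fontsize=5)
    ax.set_yticks(range(len(corr)), [str(c) for c in corr.index], fontsize=5)
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title("Sample-sample correlation")
    fig.tight_layout()
    written += _save(fig, outdir, "corr_heatmap")
    return written


def plot_results(ss_table: pd.DataFrame, cv_table: pd.DataFrame, outdir) -> list[Path]:
    """Box plots of %SS per model term and of CV per variable level."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    pct_cols = [c for c in ss_table.columns if c.startswith("pctSS_")]
    if pct_cols:
        fig, ax = plt.subplots(figsize=(max(5, 1.0 * len(pct_cols)), 4))
        data = [ss_table[c].dropna().to_numpy() for c in pct_cols]
        ax.boxplot(data, tick_labels=[c.removeprefix("pctSS_") for c in pct_cols])
        ax.set_ylabel("% of total SS")
        ax.set_title("Sum-of-squares contribution per variable")
        fig.tight_layout()
        written += _save(fig, outdir, "ss_boxplot")

    if cv_table is None or cv_table.empty or cv_table.notna().sum().sum() == 0:
        warnings.warn("CV table empty; skipping CV box plot", UserWarning)
        return written
    fig, ax = plt.subplots(figsize=(max(5, 0.8 * cv_table.shape[1]), 4))
    data = [cv_table[c].dropna().to_numpy() for c in cv_table.columns]
    ax.boxplot(data, tick_labels=[str(c) for c in cv_table.columns])
    ax.set_ylabel("CV (%)")
    ax.set_title("Coefficient of variation per group")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    written += _save(fig, outdir, "cv_boxplot")
    return written


def echo_inputs(config: AnalysisConfig) -> pd.DataFrame:
    """Flat key/value table of every configuration choice."""
    d = config.to_dict()
    table = pd.DataFrame({"value": [str(v) for v in d.values()]}, index=list(d.keys()))
    table.index.name = "setting"
    return table


def config_from_echo(table: pd.DataFrame) -> AnalysisConfig:
    """Rebuild an AnalysisConfig from its echo table (round-trip)."""
    return AnalysisConfig.from_dict(dict(zip(table.index, table["value"])))
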