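"""Synthetic LC-MS expression data with a known variance structure.

The default design emulates a two-step workflow comparison: 200 proteins
quantified through 1000 peptides over a three-factor balanced layout —
storage method M1 (levels A1, A2), extraction method M2 (levels B1, B2,
B3), three biological replicates per cell and two MS runs, i.e.
2 x 3 x 3 x 2 = 36 samples — with subject Age as a continuous covariate.

Log2-scale intensities follow

    y = baseline(protein) + offset(peptide) + e_M1(protein, level)
        + e_M2(protein, level) + e_run(protein, run)
        + beta(protein) * age + N(0, sigma(levels)^2)

and are exported on the raw scale (2^y).  Each effect is drawn per
protein around a level mean (e.g. e_M1 ~ N(delta_M1(level),
effect_sd_m1^2)): different proteins respond differently to a workflow
choice.  This heterogeneity matters — an effect that is identical for
every feature is a per-sample calibration shift, which quantile/VSN
normalization absorbs by construction; only the protein-specific
component remains measurable downstream.  The default spreads make the
extraction step (M2) the dominant source of variation, storage (M1)
second and Age least, and the residual-noise defaults give A2 a smaller
spread than A1 and B2 the smallest within M2 — so every downstream
ranking has a known ground truth.  Missingness is MCAR by default, with
an optional intensity-dependent (MNAR) logistic mechanism for
robustness studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, SampleMetadata


@dataclass
class SimulationDesign:
    """Parameters of the synthetic dataset (log2-scale units throughout)."""

    n_proteins: int = 200
    n_peptides: int = 1000
    m1_levels: tuple = ("A1", "A2")
    m2_levels: tuple = ("B1", "B2", "B3")
    n_replicates: int = 3
    n_runs: int = 2
    age_range: tuple = (25.0, 65.0)
    # mean effects (log2 units); constant across features, hence largely
    # absorbed by sample-level normalization
    delta_m1: dict = field(default_factory=lambda: {"A1": 0.0, "A2": 0.3})
    delta_m2: dict = field(default_factory=lambda: {"B1": 0.0, "B2": 0.6, "B3": -0.6})
    delta_run: dict = field(default_factory=lambda: {"R1": 0.0, "R2": 0.15})
    age_slope: float = 0.01
    # protein-specific response spreads around the mean effects: different
    # proteins react differently to storage/extraction/run, and it is this
    # feature-level heterogeneity that survives normalization and drives
    # the SS decomposition (spread of M2 > M1 > age by default)
    effect_sd_m1: float = 0.3
    effect_sd_m2: float = 0.5
    effect_sd_run: float = 0.25
    age_slope_sd: float = 0.005
    # residual noise per level; combined per sample as sqrt(s_m1^2 + s_m2^2)
    sigma_m1: dict = field(default_factory=lambda: {"A1": 0.45, "A2": 0.30})
    sigma_m2: dict = field(default_factory=lambda: {"B1": 0.45, "B2": 0.30, "B3": 0.50})
    baseline_mean: float = 20.0
    baseline_sd: float = 1.5
    peptide_offset_sd: float = 0.4
    mcar_rate: float = 0.05
    mnar_intercept: float | None = None   # logistic on log2 intensity; None = off
    mnar_slope: float = 0.0
    norm_imp_groups: int = 0              # 0 = no Norm_Imp_Group column
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_peptides < self.n_proteins:
            raise ValueError("need n_peptides >= n_proteins >= 1")
        if self.n_replicates < 1 or self.n_runs < 1:
            raise ValueError("replicates and runs must be positive")
        if not (0.0 <= self.mcar_rate < 1.0):
            raise ValueError("mcar_rate must lie in [0, 1)")
        for d in (self.sigma_m1, self.sigma_m2):
            if any(s <= 0 for s in d.values()):
                raise ValueError("all residual SDs must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.m1_levels) * len(self.m2_levels) * self.n_replicates * self.n_runs


@dataclass
class SimulatedData:
    """Generator output: raw peptide matrix, metadata and the ground truth."""

    expression: ExpressionMatrix           # raw scale, with missingness applied
    metadata: SampleMetadata
    truth: dict                            # parameters + complete log2 matrix


def generate(design: SimulationDesign | None = None) -> SimulatedData:
    """Draw one dataset from the design's generative model."""
    design = design or SimulationDesign()
    rng = np.random.default_rng(design.seed)

    # peptide -> protein assignment: each protein gets >=1 peptide,
    # the remainder are spread uniformly at random
    proteins = [f"Prot{i + 1:04d}" for i in range(design.n_proteins)]
    assignment = np.concatenate(
        [
            np.arange(design.n_proteins),
            rng.integers(0, design.n_proteins, size=design.n_peptides - design.n_proteins),
        ]
    )
    assignment = np.sort(assignment)  # group peptides of a protein together
    peptides = [f"Pep{i + 1:05d}" for i in range(design.n_peptides)]
    protein_of_peptide = [proteins[a] for a in assignment]

    # sample layout: subjects are (m1, m2, replicate); each runs twice
    rows = []
    ages: dict[tuple, float] = {}
    runs = [f"R{r + 1}" for r in range(design.n_runs)]
    for m1 in design.m1_levels:
        for m2 in design.m2_levels:
            for rep in range(1, design.n_replicates + 1):
                subject = (m1, m2, rep)
                ages[subject] = float(
                    rng.uniform(design.age_range[0], design.age_range[1])
                )
                for run in runs:
                    rows.append(
                        {
                            "Sample": f"{m1}_{m2}_S{rep}_{run}",
                            "M1": m1,
                            "M2": m2,
                            "Run": run,
                            "Age": round(ages[subject], 1),
                        }
                    )
    meta_table = pd.DataFrame(rows).set_index("Sample")

    baseline = rng.normal(design.baseline_mean, design.baseline_sd, size=design.n_proteins)
    pep_offset = rng.normal(0.0, design.peptide_offset_sd, size=design.n_peptides)

    # per-protein responses to each workflow choice, shared by the
    # protein's peptides
    P = design.n_proteins
    eff_m1 = {
        lev: design.delta_m1[lev] + rng.normal(0.0, design.effect_sd_m1, size=P)
        for lev in design.m1_levels
    }
    eff_m2 = {
        lev: design.delta_m2[lev] + rng.normal(0.0, design.effect_sd_m2, size=P)
        for lev in design.m2_levels
    }
    eff_run = {
        run: design.delta_run[run] + rng.normal(0.0, design.effect_sd_run, size=P)
        for run in runs
    }
    slope = design.age_slope + rng.normal(0.0, design.age_slope_sd, size=P)

    n_samp = len(meta_table)
    base_per_pep = baseline[assignment] + pep_offset
    sample_sigma = np.empty(n_samp)
    signal = np.empty((design.n_peptides, n_samp))
    for j, (sid, row) in enumerate(meta_table.iterrows()):
        eff = (
            eff_m1[row["M1"]][assignment]
            + eff_m2[row["M2"]][assignment]
            + eff_run[row["Run"]][assignment]
            + slope[assignment] * row["Age"]
        )
        signal[:, j] = base_per_pep + eff
        sample_sigma[j] = np.sqrt(
            design.sigma_m1[row["M1"]] ** 2 + design.sigma_m2[row["M2"]] ** 2
        )
    noise = rng.normal(0.0, 1.0, size=(design.n_peptides, n_samp)) * sample_sigma[None, :]
    log2_vals = signal + noise

    missing = rng.uniform(size=log2_vals.shape) < design.mcar_rate
    if design.mnar_intercept is not None:
        p_mnar = 1.0 / (1.0 + np.exp(-(design.mnar_intercept + design.mnar_slope * log2_vals)))
        missing |= rng.uniform(size=log2_vals.shape) < p_mnar

    raw = np.power(2.0, log2_vals)
    raw_masked = raw.copy()
    raw_masked[missing] = np.nan

    values = pd.DataFrame(raw_masked, index=pd.Index(peptides, name="feature"),
                          columns=meta_table.index)
    expr = ExpressionMatrix(
        values=values,
        scale_tag="raw",
        protein_ids=pd.Series(protein_of_peptide, index=values.index),
    )

    if design.norm_imp_groups > 1:
        group = pd.Series(
            (np.arange(n_samp) % design.norm_imp_groups + 1).astype(str),
            index=meta_table.index,
        )
    else:
        group = None
    meta = SampleMetadata(
        table=meta_table,
        categorical_vars=["M1", "M2", "Run"],
        continuous_vars=["Age"],
        norm_imp_group=group,
    )

    truth = {
        "design": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in design.__dict__.items()
        },
        "protein_of_peptide": dict(zip(peptides, protein_of_peptide)),
        "protein_effects": {
            "M1": {lev: eff_m1[lev].tolist() for lev in design.m1_levels},
            "M2": {lev: eff_m2[lev].tolist() for lev in design.m2_levels},
            "Run": {run: eff_run[run].tolist() for run in runs},
            "age_slope": slope.tolist(),
        },
        "complete_log2": pd.DataFrame(
            log2_vals, index=values.index, columns=values.columns
        ),
        "n_missing": int(missing.sum()),
    }
    return SimulatedData(expression=expr, metadata=meta, truth=truth)


def write_fixture(data: SimulatedData, outdir) -> dict[str, Path]:
    """Write expression.csv / metadata.csv / truth.json in the I/O dialect.

    Output is deterministic: a fixed seed reproduces byte-identical files.
    The complete (pre-masking) log2 matrix goes to its own CSV so the
    JSON stays small.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = data.expression

    table = expr.values.copy()
    table.insert(0, "Peptide", table.index)
    table.insert(0, "Protein", expr.protein_ids.to_numpy())
    expr_path = outdir / "expression.csv"
    table.to_csv(expr_path, index=False, na_rep="NA", float_format="%.10g")

    meta_out = data.metadata.table.copy()
    if data.metadata.norm_imp_group is not None:
        meta_out["Norm_Imp_Group"] = data.metadata.norm_imp_group
    meta_path = outdir / "metadata.csv"
    meta_out.to_csv(meta_path, na_rep="NA")

    truth_path = outdir / "truth.json"
    truth = {k: v for k, v in data.truth.items() if k != "complete_log2"}
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    complete_path = outdir / "truth_complete_log2.csv"
    data.truth["complete_log2"].to_csv(complete_path, float_format="%.10g")
    return {
        "expression": expr_path,
        "metadata": meta_path,
        "truth": truth_path,
        "complete_log2": complete_path,
    }
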