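"""Synthetic DIA experiments with known ground truth.

The generator emulates the statistical structure the downstream pipeline
assumes: a cohort of MS runs split into treatment conditions (default
B:5, BTH:5, DEX:4, TH:4, V:4, mirroring a bleomycin lung-fibrosis study
design), several precursors per protein group, per-run scale offsets,
Gaussian residual noise on the log2 scale, and two-component missingness —
intensity-dependent left censoring (MNAR, logistic detection curve on log2
intensity) followed by uniform random dropout (MCAR).

The additive model on the log2 scale is::

    log2 intensity = base(precursor) + run_offset(run)
                     + condition_effect(protein, condition) + N(0, noise_sd)

and the emitted report carries ``2**log2`` on the linear scale.  A regulated
protein receives an independent signed effect of fixed magnitude in every
non-reference condition, so its true log2 fold change versus the reference
equals that condition's effect; unregulated proteins have true log2FC
exactly 0 everywhere.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError, IntegrityError
from .io_formats import DesignTable

DEFAULT_COHORTS = {"B": 5, "BTH": 5, "DEX": 4, "TH": 4, "V": 4}


@dataclass
class SimConfig:
    """Generator parameters.

    Parameters
    ----------
    n_proteins
        Number of simulated protein groups.
    precursor_mean, precursor_max
        Precursors per protein ~ geometric with this mean, truncated to
        [1, precursor_max].
    cohort_sizes
        Condition -> number of runs (each >= 2).
    frac_regulated
        Fraction of proteins given a nonzero effect.
    effect_log2fc
        Magnitude of the condition effect; sign drawn +/- with equal
        probability, independently per non-reference condition.
    base_mean, base_sd
        Per-precursor baseline log2 intensity ~ Normal(base_mean, base_sd).
    run_effect_sd
        SD of the additive per-run log2 offset.
    noise_sd
        SD of the residual log2 noise per entry.
    mnar_midpoint, mnar_slope
        Logistic detection curve on log2 intensity: detection probability
        ``1/(1+exp(-slope*(x-midpoint)))``; ``mnar_midpoint=None`` disables
        left censoring.
    mcar_rate
        Uniform dropout probability applied after detection.
    reference_condition
        Condition with zero effect; truth log2FC is test - reference.
    compartment
        Compartment label written into the design table.
    seed
        RNG seed; identical configs give byte-identical reports.
    """

    n_proteins: int = 1000
    precursor_mean: float = 5.0
    precursor_max: int = 30
    cohort_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COHORTS))
    frac_regulated: float = 0.1
    effect_log2fc: float = 2.0
    base_mean: float = 14.0
    base_sd: float = 2.5
    run_effect_sd: float = 0.3
    noise_sd: float = 0.25
    mnar_midpoint: float | None = 9.0
    mnar_slope: float = 1.5
    mcar_rate: float = 0.02
    reference_condition: str = "B"
    compartment: str = "lung"
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if self.precursor_mean < 1 or self.precursor_max < 1:
            raise ConfigError("precursor distribution must have mean, max >= 1")
        for cond, n in self.cohort_sizes.items():
            if n < 2:
                raise ConfigError(f"cohort {cond!r} has {n} runs; need >= 2")
        if self.reference_condition not in self.cohort_sizes:
            raise ConfigError(
                f"reference condition {self.reference_condition!r} "
                f"not in cohort_sizes")
        for name in ("base_sd", "run_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("frac_regulated", "mcar_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")

    def comparisons(self) -> list[str]:
        """Display names of the truth comparisons (each condition vs reference)."""
        ref = self.reference_condition
        return [f"{c}_vs_{ref}" for c in sorted(self.cohort_sizes) if c != ref]


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment.

    ``protein_effects``: protein_group x comparison true log2FC (test minus
    reference).  ``precursors``: per precursor its parent protein and
    baseline log2 intensity.  ``missing_log2`` / ``observed_log2``: the
    pre-censoring log2 intensities of entries that were dropped / kept,
    for checking that missingness is left-censored.
    """

    protein_effects: pd.DataFrame
    precursors: pd.DataFrame
    observed_log2: np.ndarray
    missing_log2: np.ndarray


def simulate_experiment(
    config: SimConfig,
) -> tuple[pd.DataFrame, DesignTable, SimTruth]:
    """Generate one experiment: precursor records, design, and ground truth.

    Returns records in the same long format :func:`~diaquant.io_formats.
    read_precursor_report` produces (run_id, protein_group, precursor_id,
    linear intensity), sorted by (run_id, precursor_id).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    conditions = sorted(config.cohort_sizes)
    ref = config.reference_condition

    run_rows = []
    for cond in conditions:
        for i in range(config.cohort_sizes[cond]):
            run_rows.append({
                "run_id": f"{cond}_{i + 1:02d}",
                "condition": cond,
                "compartment": config.compartment,
            })
    design = DesignTable(pd.DataFrame(run_rows))
    run_ids = design.run_ids
    run_cond = design.table.set_index("run_id")["condition"]
    n_runs = len(run_ids)

    proteins = np.array([f"P{i + 1:05d}" for i in range(config.n_proteins)])

    # condition effects: regulated proteins get +/- magnitude per non-ref cond
    n_reg = int(round(config.frac_regulated * config.n_proteins))
    reg_idx = rng.choice(config.n_proteins, size=n_reg, replace=False)
    non_ref = [c for c in conditions if c != ref]
    effects = pd.DataFrame(
        0.0, index=proteins, columns=[f"{c}_vs_{ref}" for c in non_ref])
    for c in non_ref:
        signs = rng.choice([-1.0, 1.0], size=n_reg)
        effects.iloc[reg_idx, effects.columns.get_loc(f"{c}_vs_{ref}")] = (
            signs * config.effect_log2fc)
    cond_effect = {ref: pd.Series(0.0, index=proteins)}
    for c in non_ref:
        cond_effect[c] = effects[f"{c}_vs_{ref}"]

    # precursors per protein: truncated geometric
    p_geom = min(1.0, 1.0 / config.precursor_mean)
    n_prec = np.minimum(rng.geometric(p_geom, size=config.n_proteins),
                        config.precursor_max)
    parent = np.repeat(np.arange(config.n_proteins), n_prec)
    total_prec = int(n_prec.sum())
    prec_ids = np.array([
        f"{proteins[pi]}_pre{j + 1:02d}"
        for pi, j in zip(parent, _within_group_index(n_prec))
    ])
    base = rng.normal(config.base_mean, config.base_sd, size=total_prec)

    run_offsets = rng.normal(0.0, config.run_effect_sd, size=n_runs)

    # log2 intensity matrix: precursor x run
    delta = np.column_stack([
        cond_effect[run_cond[r]].to_numpy()[parent] for r in run_ids])
    log2_mat = (base[:, None] + run_offsets[None, :] + delta
                + rng.normal(0.0, config.noise_sd, size=(total_prec, n_runs)))

    # two-component missingness: logistic left censoring, then MCAR
    detected = np.ones_like(log2_mat, dtype=bool)
    if config.mnar_midpoint is not None:
        p_det = expit(config.mnar_slope * (log2_mat - config.mnar_midpoint))
        detected &= rng.random(log2_mat.shape) < p_det
    if config.mcar_rate > 0:
        detected &= rng.random(log2_mat.shape) >= config.mcar_rate

    prec_idx, run_idx = np.nonzero(detected)
    records = pd.DataFrame({
        "run_id": np.array(run_ids)[run_idx],
        "protein_group": proteins[parent[prec_idx]],
        "precursor_id": prec_ids[prec_idx],
        "intensity": np.exp2(log2_mat[prec_idx, run_idx]),
    })
    records = records.sort_values(["run_id", "precursor_id"], kind="stable")
    records = records.reset_index(drop=True)

    truth = SimTruth(
        protein_effects=effects,
        precursors=pd.DataFrame({
            "precursor_id": prec_ids,
            "protein_group": proteins[parent],
            "base_log2": base,
        }),
        observed_log2=log2_mat[detected],
        missing_log2=log2_mat[~detected],
    )
    return records, design, truth


def _within_group_index(counts: np.ndarray) -> np.ndarray:
    """0..k-1 within each group of sizes ``counts`` (vectorized)."""
    total = int(counts.sum())
    idx = np.arange(total)
    starts = np.repeat(np.cumsum(counts) - counts, counts)
    return idx - starts


def truth_evaluation(
    protein_stats: pd.DataFrame,
    truth: SimTruth,
) -> pd.DataFrame:
    """Score estimated protein statistics against simulated ground truth.

    Per comparison, reports the bias and RMSE of estimated vs true log2FC
    over proteins present in the estimates, plus sensitivity (regulated
    proteins flagged / regulated proteins in truth — proteins the pipeline
    dropped count as misses) and the empirical FDR of the flag (NaN when
    there are no discoveries).

    Raises
    ------
    IntegrityError
        If the estimates contain proteins or comparisons unknown to truth.
    """
    unknown = set(protein_stats["protein_group"]) - set(
        truth.protein_effects.index)
    if unknown:
        raise IntegrityError(
            f"estimates contain proteins not in truth: {sorted(unknown)[:3]}")
    unknown_c = set(protein_stats["comparison"]) - set(
        truth.protein_effects.columns)
    if unknown_c:
        raise IntegrityError(
            f"estimates contain comparisons not in truth: {sorted(unknown_c)}")

    rows = []
    for comp, grp in protein_stats.groupby("comparison", sort=True):
        true_fc = truth.protein_effects[comp]
        est = grp.set_index("protein_group")
        err = est["log2fc"] - true_fc.loc[est.index]
        regulated_truth = true_fc[true_fc != 0].index
        flagged = (
            set(est.index[est["regulated"]]) if "regulated" in est else set())
        tp = len(flagged & set(regulated_truth))
        fp = len(flagged - set(regulated_truth))
        rows.append({
            "comparison": comp,
            "n_evaluated": len(est),
            "bias": float(err.mean()),
            "rmse": float(np.sqrt((err ** 2).mean())),
            "n_true_regulated": len(regulated_truth),
            "n_flagged": len(flagged),
            "sensitivity": (tp / len(regulated_truth)
                            if len(regulated_truth) else float("nan")),
            "empirical_fdr": (fp / len(flagged) if flagged else float("nan")),
        })
    return pd.DataFrame(rows)


def write_simulation(
    records: pd.DataFrame,
    design: DesignTable,
    truth: SimTruth,
    config: SimConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write report/design/truth TSVs plus the config as JSON.

    The report and design files use exactly the dialects
    :mod:`diaquant.io_formats` reads back.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": out / "report.tsv",
        "design": out / "design.tsv",
        "truth_proteins": out / "truth_proteins.tsv",
        "truth_precursors": out / "truth_precursors.tsv",
        "config": out / "sim_config.json",
    }
    report = records.rename(columns={
        "run_id": "Run", "protein_group": "Protein.Group",
        "precursor_id": "Precursor.Id", "intensity": "Precursor.Quantity"})
    # default float repr round-trips float64 exactly (lossless re-read)
    report.to_csv(paths["report"], sep="\t", index=False)
    design.table.to_csv(paths["design"], sep="\t", index=False)
    truth.protein_effects.rename_axis("protein_group").reset_index().to_csv(
        paths["truth_proteins"], sep="\t", index=False, float_format="%.6f")
    truth.precursors.to_csv(paths["truth_precursors"], sep="\t", index=False,
                            float_format="%.6f")
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
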