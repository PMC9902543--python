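"""End-to-end orchestration of the downstream analysis.

Per compartment the stages run in fixed order: matrix build -> quantile
normalization -> minimum-observation filter -> left-censored imputation ->
per-precursor t-tests -> protein roll-up -> BH correction -> regulated
flags.  Across compartments the pipeline reports the identification overlap,
builds the regulated-protein profile matrix (combined across compartments or
per compartment), selects k by the gap statistic, partitions the profiles
and — when an annotation table is supplied — runs over-representation
analysis of each comparison's regulated set against that compartment's
MS-covered background.

A single global seed deterministically spawns per-stage substreams, so a
rerun with the same configuration produces byte-identical outputs and any
stage can be reproduced in isolation from the manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

import pandas as pd

from . import clustering, difftest, enrichment, io_formats, preprocess
from .errors import ConfigError
from .synthetic import SimConfig, simulate_experiment, write_simulation

#: order of per-stage RNG substreams spawned from the global seed
_STAGES = ("impute", "gap", "cluster")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run.

    Stage parameters default to the study pipeline's values: minimum 5
    observed runs (i.e. precursors seen in <= 4 runs are excluded), Gaussian
    imputation at the global 0.1th percentile with sd 0.2 log2 units,
    |log2FC| >= 1 and BH-adjusted p <= 0.05 for the regulated flag.
    """

    report: str | Path
    design: str | Path
    out_dir: str | Path
    annotation: str | Path | None = None
    column_map: dict[str, str] | None = None
    compartments: list[str] | None = None      # default: all in design
    reference_condition: str = "B"
    comparisons: list[str] | None = None       # test condition names; default all
    flip_sign: bool = False
    min_runs: int = preprocess.DEFAULT_MIN_RUNS
    center_quantile: float = preprocess.DEFAULT_CENTER_QUANTILE
    impute_sd: float = preprocess.DEFAULT_IMPUTE_SD
    lfc_threshold: float = difftest.DEFAULT_LFC_THRESHOLD
    fdr: float = difftest.DEFAULT_FDR
    cluster_mode: str = "combined"             # or "per_compartment"
    k_max: int = clustering.DEFAULT_K_MAX
    gap_B: int = clustering.DEFAULT_B
    restarts: int = clustering.DEFAULT_RESTARTS
    enrichment_sided: str = "over"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage substream seeds from the global seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {name: int(child.generate_state(1)[0] % (2 ** 31))
                for name, child in zip(_STAGES, children)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write result tables; returns the manifest dict."""
    records, load_report = io_formats.read_precursor_report(
        config.report, config.column_map)
    design = io_formats.read_design(config.design)
    annotation = (io_formats.read_annotation(config.annotation)
                  if config.annotation else None)

    compartments = config.compartments or design.compartments
    missing = set(compartments) - set(design.compartments)
    if missing:
        raise ConfigError(f"compartments not in design: {sorted(missing)}")

    # fail fast on comparison conditions before any computation
    if config.comparisons is not None:
        unknown = set(config.comparisons) - set(design.conditions)
        if unknown:
            raise ConfigError(
                f"comparison conditions not in design: {sorted(unknown)}")

    seeds = config.stage_seeds()
    manifest: dict = {
        "parameters": {k: io_formats._jsonable(v)
                       for k, v in dataclasses.asdict(config).items()},
        "stage_seeds": seeds,
        "load": dataclasses.asdict(load_report),
        "compartments": {},
    }

    all_stats = []
    enrich_frames = []
    compartment_ids: dict[str, set[str]] = {}
    for comp_idx, compartment in enumerate(compartments):
        counts: dict = {}
        matrix = preprocess.build_matrix(records, design, compartment)
        counts["precursors_built"] = matrix.n_precursors
        counts["runs"] = len(matrix.run_ids)
        compartment_ids[compartment] = matrix.protein_groups

        matrix = preprocess.quantile_normalize(matrix)
        matrix, dropped = preprocess.filter_min_observations(
            matrix, config.min_runs)
        counts["precursors_dropped_by_filter"] = dropped
        counts["precursors_tested"] = matrix.n_precursors
        n_missing = int(matrix.values.isna().to_numpy().sum())
        counts["entries_imputed"] = n_missing
        matrix = preprocess.impute_missing(
            matrix, config.center_quantile, config.impute_sd,
            seed=seeds["impute"] + comp_idx)

        testable = [c for c in design.condition_counts(compartment)
                    if len(design.runs_for(compartment, c)) >= 2]
        tests = config.comparisons or [
            c for c in sorted(testable) if c != config.reference_condition]
        comparisons = [difftest.Comparison(c, config.reference_condition)
                       for c in tests]
        prec_stats = difftest.precursor_tests(
            matrix, comparisons, flip_sign=config.flip_sign)
        prot = difftest.rollup_to_protein(prec_stats)
        prot.insert(0, "compartment", compartment)
        prot = difftest.adjust_bh(prot)
        prot = difftest.flag_regulated(prot, config.lfc_threshold, config.fdr)
        counts["proteins_tested"] = int(prot["protein_group"].nunique())
        counts["regulated_calls"] = int(prot["regulated"].sum())
        manifest["compartments"][compartment] = counts
        all_stats.append(prot)

        if annotation is not None:
            background = compartment_ids[compartment]
            for comparison_name, grp in prot.groupby("comparison"):
                fg = set(grp.loc[grp["regulated"], "protein_group"])
                if not fg:
                    continue
                rows = enrichment.fisher_overrepresentation(
                    fg, background, annotation, sided=config.enrichment_sided)
                rows.insert(0, "comparison", comparison_name)
                rows.insert(0, "compartment", compartment)
                enrich_frames.append(rows)

    protein_stats = pd.concat(all_stats, ignore_index=True)

    if len(compartments) == 2:
        a, b = compartments
        overlap = difftest.compartment_overlap(
            compartment_ids[a], compartment_ids[b])
        manifest["overlap"] = {"a": a, "b": b, **overlap.as_dict()}

    clusters, gap_info = _cluster_stage(protein_stats, compartments, config,
                                        seeds)
    manifest["clustering"] = gap_info

    enrich = (pd.concat(enrich_frames, ignore_index=True)
              if enrich_frames else None)
    paths = io_formats.write_results(
        protein_stats, clusters, enrich, config.out_dir, manifest)
    manifest["outputs"] = {k: str(v) for k, v in paths.items()}
    return manifest


def _cluster_stage(protein_stats, compartments, config, seeds):
    """Profile matrix -> gap statistic -> k-means, combined or per compartment."""
    if config.cluster_mode not in ("combined", "per_compartment"):
        raise ConfigError(
            f"cluster_mode must be 'combined' or 'per_compartment', "
            f"got {config.cluster_mode!r}")
    info: dict = {"mode": config.cluster_mode, "blocks": {}}
    frames = []

    if config.cluster_mode == "combined":
        stats = protein_stats.copy()
        # one column per compartment x comparison
        stats["comparison"] = (stats["compartment"] + ":"
                               + stats["comparison"])
        blocks = {"combined": stats}
    else:
        blocks = {c: protein_stats[protein_stats["compartment"] == c]
                  for c in compartments}

    for block_idx, (label, stats) in enumerate(sorted(blocks.items())):
        profiles = clustering.build_profile_matrix(
            stats, lfc_threshold=config.lfc_threshold, fdr=config.fdr)
        binfo: dict = {"n_profiles": len(profiles)}
        if len(profiles) <= config.k_max:
            binfo["skipped"] = ("too few regulated profiles for the "
                                "requested k range")
            info["blocks"][label] = binfo
            continue
        gap = clustering.gap_statistic(
            profiles, k_max=config.k_max, B=config.gap_B,
            seed=seeds["gap"] + block_idx, restarts=config.restarts)
        assignment = clustering.cluster_profiles(
            profiles, gap.chosen_k, seed=seeds["cluster"] + block_idx,
            restarts=config.restarts)
        binfo["chosen_k"] = gap.chosen_k
        binfo["gap_curve"] = [round(g, 6) for g in gap.gap]
        info["blocks"][label] = binfo
        frame = assignment.labels.rename("cluster").reset_index()
        frame.insert(0, "compartment", label)
        frames.append(frame)

    clusters = pd.concat(frames, ignore_index=True) if frames else None
    return clusters, info


def cmd_simulate(config: SimConfig, out_dir: str | Path) -> dict:
    """Generate a synthetic experiment and write report/design/truth files."""
    records, design, truth = simulate_experiment(config)
    paths = write_simulation(records, design, truth, config, out_dir)
    return {
        "n_records": len(records),
        "n_runs": len(design.run_ids),
        "n_proteins": config.n_proteins,
        "outputs": {k: str(v) for k, v in paths.items()},
    }
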