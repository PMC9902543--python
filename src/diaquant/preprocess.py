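"""Precursor matrix construction, normalization, filtering, imputation.

The pipeline order is fixed: log2 transform -> across-run quantile
normalization (observed entries only) -> minimum-observation filter ->
left-censored Gaussian imputation.  Imputed values therefore live on the
normalized scale, and rows are filtered on their pre-imputation observation
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import (ConfigError, ImputationError, IntegrityError,
                     NormalizationError)
from .io_formats import DesignTable

DEFAULT_MIN_RUNS = 5          # "observed in <= 4 MS runs" are excluded
DEFAULT_CENTER_QUANTILE = 0.001
DEFAULT_IMPUTE_SD = 0.2


@dataclass
class QuantMatrix:
    """Precursor x run log2-intensity matrix for one compartment.

    ``values`` is indexed by (precursor_id, protein_group) with one column
    per run; missing entries are NaN until imputation.  ``observed`` marks
    entries quantified in the input (imputation never touches them), so after
    :func:`impute_missing` the imputed positions are exactly
    ``~observed & values.notna()``.
    """

    values: pd.DataFrame
    observed: pd.DataFrame
    design: DesignTable
    compartment: str
    normalized: bool = False
    imputed: bool = False

    @property
    def n_precursors(self) -> int:
        return len(self.values)

    @property
    def run_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def protein_groups(self) -> set[str]:
        return set(self.values.index.get_level_values("protein_group"))

    def is_complete(self) -> bool:
        return not self.values.isna().any().any()


def build_matrix(
    records: pd.DataFrame,
    design: DesignTable,
    compartment: str,
) -> QuantMatrix:
    """Pivot long-format records into a log2 matrix for one compartment.

    Entries are ``log2(intensity)`` for quantified (precursor, run) pairs and
    NaN otherwise; columns are the design's runs for the compartment, in
    design order.
    """
    runs = design.runs_for(compartment)
    if not runs:
        raise ConfigError(f"design has no runs for compartment {compartment!r}")

    sub = records[records["run_id"].isin(runs)]
    if len(sub) and (sub["intensity"] <= 0).any():
        bad = sub.loc[sub["intensity"] <= 0].iloc[0]
        raise IntegrityError(
            f"non-positive intensity for precursor {bad['precursor_id']!r} "
            f"in run {bad['run_id']!r}")

    if len(sub) == 0:
        empty = pd.DataFrame(
            index=pd.MultiIndex.from_arrays(
                [[], []], names=["precursor_id", "protein_group"]),
            columns=pd.Index(runs, name="run_id"), dtype=float)
        return QuantMatrix(empty, empty.notna(), design, compartment)

    wide = sub.pivot_table(
        index=["precursor_id", "protein_group"], columns="run_id",
        values="intensity", aggfunc="first")
    wide = wide.reindex(columns=runs).sort_index()
    wide.columns.name = "run_id"
    values = np.log2(wide)
    return QuantMatrix(values, values.notna(), design, compartment)


def quantile_normalize(matrix: QuantMatrix) -> QuantMatrix:
    """Across-run quantile normalization on observed entries only.

    Within each run the observed values are ranked; the reference
    distribution is the mean across runs of each run's sorted observed
    values evaluated at matched quantiles (linear interpolation where runs
    have unequal observed counts), and every observed value is replaced by
    the reference value at its quantile.  Ties within a run receive the mean
    of the reference values they span.  Missing entries are untouched.
    """
    vals = matrix.values.copy()
    runs = list(vals.columns)
    sorted_obs: dict[str, np.ndarray] = {}
    for run in runs:
        v = vals[run].to_numpy()
        obs = np.sort(v[~np.isnan(v)])
        if obs.size == 0:
            raise NormalizationError(f"run {run!r} has no observed entries")
        sorted_obs[run] = obs

    for run in runs:
        col = vals[run].to_numpy()
        mask = ~np.isnan(col)
        x = col[mask]
        n = x.size
        p = np.array([0.5]) if n == 1 else np.arange(n) / (n - 1)
        ref = np.mean(
            [np.quantile(sorted_obs[r], p) for r in runs], axis=0)
        new = np.empty(n)
        new[np.argsort(x, kind="stable")] = ref
        # ties share the mean of the reference values they span
        new = pd.Series(new).groupby(pd.Series(x)).transform("mean").to_numpy()
        out = col.copy()
        out[mask] = new
        vals[run] = out

    return replace(matrix, values=vals, normalized=True)


def filter_min_observations(
    matrix: QuantMatrix,
    min_runs: int = DEFAULT_MIN_RUNS,
) -> tuple[QuantMatrix, int]:
    """Drop precursors observed in fewer than ``min_runs`` runs.

    Counting uses the pre-imputation observation flags across all runs of the
    compartment matrix (all conditions pooled).  The default of 5 implements
    the "observed in <= 4 runs are excluded" rule.  Returns the filtered
    matrix and the number of rows dropped.
    """
    if min_runs < 1:
        raise ConfigError("min_runs must be >= 1")
    counts = matrix.observed.sum(axis=1)
    keep = counts >= min_runs
    dropped = int((~keep).sum())
    return replace(matrix, values=matrix.values.loc[keep],
                   observed=matrix.observed.loc[keep]), dropped


def impute_missing(
    matrix: QuantMatrix,
    center_quantile: float = DEFAULT_CENTER_QUANTILE,
    sd: float = DEFAULT_IMPUTE_SD,
    seed: int | None = None,
) -> QuantMatrix:
    """Left-censored Gaussian imputation of all missing entries.

    Every missing entry is replaced by an independent draw from
    ``Normal(q, sd)`` where ``q`` is the ``center_quantile`` quantile (linear
    interpolation) of *all* observed entries of the matrix pooled — the
    default 0.001 anchors imputed values at the 0.1th percentile of the
    observed data, modelling detection-limited (left-censored) missingness.
    Observed entries are unchanged; identical seeds give identical fills.
    """
    if sd < 0:
        raise ConfigError("imputation sd must be >= 0")
    if not 0 <= center_quantile <= 1:
        raise ConfigError("center_quantile must be in [0, 1]")
    arr = matrix.values.to_numpy(copy=True)
    missing = np.isnan(arr)
    if not missing.any():
        return replace(matrix, imputed=True)
    observed_values = arr[~missing]
    if observed_values.size == 0:
        raise ImputationError("matrix has no observed entries to anchor on")
    q = float(np.quantile(observed_values, center_quantile))
    rng = np.random.default_rng(seed)
    arr[missing] = rng.normal(q, sd, size=int(missing.sum()))
    vals = pd.DataFrame(arr, index=matrix.values.index,
                        columns=matrix.values.columns)
    return replace(matrix, values=vals, imputed=True)
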