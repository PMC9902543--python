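"""Per-precursor t-tests, protein roll-up, BH correction, flagging.

Testing happens at the precursor level: for each precursor and each pair of
conditions a two-sided pooled-variance (classical Student) t-test is
computed on the log2 intensities.  Protein-level metrics are the arithmetic
means of the member precursors' log2 fold changes and p-values — this
mean-of-p summary is implemented exactly as specified but is not a
calibrated p-value combination rule (unlike Fisher's or Stouffer's method);
treat protein p-values as a ranking heuristic that the subsequent BH step
thresholds.  BH adjustment is applied within each comparison (and
compartment) family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, IntegrityError
from .preprocess import QuantMatrix

DEFAULT_LFC_THRESHOLD = 1.0   # |log2FC| >= 1  <=>  fold change >= 2
DEFAULT_FDR = 0.05


@dataclass(frozen=True)
class Comparison:
    """One two-group contrast; log2FC is test minus reference."""

    test: str
    reference: str

    @property
    def name(self) -> str:
        return f"{self.test}_vs_{self.reference}"


def default_comparisons(conditions, reference: str = "B") -> list[Comparison]:
    """Each non-reference condition versus the reference (default B)."""
    if reference not in conditions:
        raise ConfigError(f"reference condition {reference!r} not in design")
    return [Comparison(c, reference) for c in sorted(conditions)
            if c != reference]


def precursor_tests(
    matrix: QuantMatrix,
    comparisons: list[Comparison],
    flip_sign: bool = False,
) -> pd.DataFrame:
    """Two-sided pooled-variance t-test per precursor per comparison.

    Requires a complete (imputed) matrix.  Degenerate precursors with zero
    pooled variance get p=1 when the group means agree and p=0 otherwise,
    and are marked in the ``degenerate`` column.  ``flip_sign`` negates the
    log2FC (reference minus test) for studies reporting the opposite
    orientation.

    Returns a DataFrame with columns precursor_id, protein_group,
    comparison, log2fc, p, degenerate.
    """
    if not matrix.is_complete():
        raise ConfigError(
            "precursor_tests requires a complete matrix; run impute_missing")
    frames = []
    for comp in comparisons:
        a_runs = matrix.design.runs_for(matrix.compartment, comp.test)
        b_runs = matrix.design.runs_for(matrix.compartment, comp.reference)
        a_runs = [r for r in a_runs if r in matrix.values.columns]
        b_runs = [r for r in b_runs if r in matrix.values.columns]
        if len(a_runs) < 2 or len(b_runs) < 2:
            raise ConfigError(
                f"comparison {comp.name}: both groups need >= 2 runs "
                f"(got {len(a_runs)} vs {len(b_runs)})")
        A = matrix.values[a_runs].to_numpy()
        B = matrix.values[b_runs].to_numpy()
        na, nb = A.shape[1], B.shape[1]
        mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
        lfc = mean_a - mean_b
        var_a = A.var(axis=1, ddof=1)
        var_b = B.var(axis=1, ddof=1)
        pooled = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
        df = na + nb - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
            t = lfc / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        degenerate = pooled == 0
        zero_diff = degenerate & (lfc == 0)
        p = np.where(degenerate, np.where(zero_diff, 1.0, 0.0), p)
        out = pd.DataFrame({
            "precursor_id": matrix.values.index.get_level_values("precursor_id"),
            "protein_group": matrix.values.index.get_level_values("protein_group"),
            "comparison": comp.name,
            "log2fc": -lfc if flip_sign else lfc,
            "p": p,
            "degenerate": degenerate,
        })
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def rollup_to_protein(precursor_stats: pd.DataFrame) -> pd.DataFrame:
    """Summarize precursor statistics to protein level by arithmetic mean.

    Per (protein_group, comparison): log2fc and p are the means of the
    member precursors' values; n_precursors records the group size.
    """
    if len(precursor_stats) == 0:
        raise IntegrityError("no precursor statistics to roll up")
    grouped = precursor_stats.groupby(["protein_group", "comparison"],
                                      sort=True)
    out = grouped.agg(
        n_precursors=("precursor_id", "size"),
        log2fc=("log2fc", "mean"),
        p=("p", "mean"),
    ).reset_index()
    return out


def adjust_bh(protein_stats: pd.DataFrame) -> pd.DataFrame:
    """Benjamini–Hochberg step-up adjustment within each comparison family.

    The family is all proteins of one comparison (and compartment, when the
    stats carry one); adjusted values are capped at 1 and ties share the
    value of their rank position.
    """
    p = protein_stats["p"].to_numpy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise IntegrityError("p-values outside [0, 1]")
    family_cols = [c for c in ("compartment", "comparison")
                   if c in protein_stats.columns]
    out = protein_stats.copy()
    out["p_adj"] = np.nan
    if family_cols:
        for _, idx in out.groupby(family_cols).groups.items():
            out.loc[idx, "p_adj"] = multipletests(
                out.loc[idx, "p"], method="fdr_bh")[1]
    else:
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def flag_regulated(
    protein_stats: pd.DataFrame,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Flag proteins with |log2FC| >= threshold and adjusted p <= fdr.

    Both boundaries are inclusive (fold change >= 2 at the default
    threshold).  ``regulated`` and ``significant`` carry the same rule; the
    former names the clustering inclusion criterion, the latter the
    reporting criterion.
    """
    if lfc_threshold < 0 or fdr < 0:
        raise ConfigError("thresholds must be non-negative")
    out = protein_stats.copy()
    hit = (out["log2fc"].abs() >= lfc_threshold) & (out["p_adj"] <= fdr)
    out["regulated"] = hit
    out["significant"] = hit
    return out


@dataclass(frozen=True)
class OverlapReport:
    """Partition of two identification sets: exclusive and shared counts.

    Percentages are of the union total, rounded to the nearest integer
    (NaN for empty inputs).
    """

    a_only: int
    b_only: int
    shared: int

    @property
    def total(self) -> int:
        return self.a_only + self.b_only + self.shared

    def _pct(self, k: int) -> float:
        return round(100.0 * k / self.total) if self.total else float("nan")

    @property
    def a_only_pct(self) -> float:
        return self._pct(self.a_only)

    @property
    def b_only_pct(self) -> float:
        return self._pct(self.b_only)

    @property
    def shared_pct(self) -> float:
        return self._pct(self.shared)

    def as_dict(self) -> dict:
        return {
            "a_only": self.a_only, "b_only": self.b_only,
            "shared": self.shared, "total": self.total,
            "a_only_pct": self.a_only_pct, "b_only_pct": self.b_only_pct,
            "shared_pct": self.shared_pct,
        }


def compartment_overlap(ids_a: set, ids_b: set) -> OverlapReport:
    """Partition two protein identification sets (e.g. lung vs BALF)."""
    a, b = set(ids_a), set(ids_b)
    return OverlapReport(
        a_only=len(a - b), b_only=len(b - a), shared=len(a & b))
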