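"""Tabular I/O: precursor reports, design tables, annotation sets, results.

The quantification input is a long-format precursor report as produced by
library-based DIA search engines (one row per precursor per MS run, raw
linear-scale quantity).  Column names default to the DIA-NN report dialect
(``Run``, ``Protein.Group``, ``Precursor.Id``, ``Precursor.Quantity``) and can
be remapped for other tools.  Protein groups are kept as verbatim strings —
multiple accessions separated by ';' are a single quantification unit and are
never re-grouped or split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, IntegrityError

#: canonical field -> default report column name (DIA-NN dialect)
DEFAULT_REPORT_COLUMNS: dict[str, str] = {
    "run_id": "Run",
    "protein_group": "Protein.Group",
    "precursor_id": "Precursor.Id",
    "intensity": "Precursor.Quantity",
}

RECORD_COLUMNS = ["run_id", "protein_group", "precursor_id", "intensity"]


@dataclass(frozen=True)
class LoadReport:
    """Bookkeeping for one precursor-report load."""

    n_rows: int
    n_records: int
    n_skipped_nonquant: int
    n_deduplicated: int = 0


def read_precursor_report(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, LoadReport]:
    """Read a long-format precursor report.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Optional remapping ``canonical field -> column name in the file`` for
        the fields ``run_id``, ``protein_group``, ``precursor_id``,
        ``intensity``; unspecified fields use the DIA-NN defaults.

    Returns
    -------
    records, report
        ``records`` is a DataFrame with columns ``run_id, protein_group,
        precursor_id, intensity`` containing one row per quantified
        (run, precursor) pair, sorted by (run_id, precursor_id).  Rows whose
        quantity is empty, zero or negative are treated as *not quantified*
        and counted in ``report.n_skipped_nonquant``.

    Raises
    ------
    FormatError
        If a required column is missing.
    IntegrityError
        If a (run, precursor) pair occurs with conflicting quantities, or a
        precursor maps to more than one protein group.
    """
    columns = dict(DEFAULT_REPORT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(columns)
        if unknown:
            raise ConfigError(f"unknown column_map fields: {sorted(unknown)}")
        columns.update(column_map)

    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty precursor report: {path}") from exc

    for canonical, col in columns.items():
        if col not in df.columns:
            raise FormatError(
                f"precursor report is missing required column {col!r} "
                f"(field {canonical!r})"
            )
    df = df.rename(columns={v: k for k, v in columns.items()})[RECORD_COLUMNS]
    n_rows = len(df)

    df["intensity"] = pd.to_numeric(df["intensity"], errors="coerce")
    quantified = df["intensity"].notna() & (df["intensity"] > 0)
    records = df.loc[quantified].copy()
    n_skipped = int(n_rows - quantified.sum())

    # duplicate (run, precursor): equal quantities collapse, conflicts abort
    n_dedup = 0
    dup_mask = records.duplicated(["run_id", "precursor_id"], keep=False)
    if dup_mask.any():
        dups = records.loc[dup_mask]
        nun = dups.groupby(["run_id", "precursor_id"])["intensity"].nunique()
        conflicts = nun[nun > 1]
        if len(conflicts):
            run, prec = conflicts.index[0]
            raise IntegrityError(
                f"duplicate (run={run!r}, precursor={prec!r}) with "
                f"conflicting quantities"
            )
        before = len(records)
        records = records.drop_duplicates(["run_id", "precursor_id"])
        n_dedup = before - len(records)

    mapping = records.groupby("precursor_id")["protein_group"].nunique()
    multi = mapping[mapping > 1]
    if len(multi):
        raise IntegrityError(
            f"precursor {multi.index[0]!r} maps to multiple protein groups"
        )

    records = records.sort_values(["run_id", "precursor_id"], kind="stable")
    records = records.reset_index(drop=True)
    return records, LoadReport(n_rows, len(records), n_skipped, n_dedup)


@dataclass
class DesignTable:
    """Maps each MS run to its treatment condition and compartment.

    The default study layout has five conditions (B, BTH, DEX, TH, V) and two
    compartments (lung homogenate and BALF).  Conditions represented by a
    single run cannot be t-tested and are flagged as untestable.
    """

    table: pd.DataFrame  # columns: run_id, condition, compartment

    def __post_init__(self) -> None:
        required = {"run_id", "condition", "compartment"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"design table missing columns: {sorted(missing)}")
        if self.table["run_id"].duplicated().any():
            dup = self.table.loc[self.table["run_id"].duplicated(), "run_id"].iloc[0]
            raise IntegrityError(f"duplicated run_id in design: {dup!r}")
        self.table = self.table.reset_index(drop=True)

    @property
    def run_ids(self) -> list[str]:
        return list(self.table["run_id"])

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    @property
    def compartments(self) -> list[str]:
        return sorted(self.table["compartment"].unique())

    def runs_for(self, compartment: str | None = None,
                 condition: str | None = None) -> list[str]:
        t = self.table
        if compartment is not None:
            t = t[t["compartment"] == compartment]
        if condition is not None:
            t = t[t["condition"] == condition]
        return list(t["run_id"])

    def condition_counts(self, compartment: str | None = None) -> dict[str, int]:
        t = self.table
        if compartment is not None:
            t = t[t["compartment"] == compartment]
        return t["condition"].value_counts().to_dict()

    def untestable_conditions(self, compartment: str | None = None) -> list[str]:
        """Conditions with fewer than 2 runs (excluded from testing)."""
        counts = self.condition_counts(compartment)
        return sorted(c for c, n in counts.items() if n < 2)


def read_design(path: str | Path) -> DesignTable:
    """Read a run design TSV with columns run_id, condition, compartment.

    Conditions represented by a single run raise a :class:`UserWarning` and
    are reported by :meth:`DesignTable.untestable_conditions`.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty design file: {path}") from exc
    design = DesignTable(df)
    for compartment in design.compartments:
        bad = design.untestable_conditions(compartment)
        if bad:
            warnings.warn(
                f"conditions with a single run in compartment "
                f"{compartment!r} are untestable: {bad}",
                UserWarning,
                stacklevel=2,
            )
    return design


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    name: str
    proteins: frozenset[str]


@dataclass
class AnnotationTable:
    """Term -> protein-set map used for over-representation testing.

    Protein keys use the same verbatim protein-group strings as the
    quantification report.
    """

    terms: dict[str, AnnotationTerm] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term in self.terms.values():
            if not term.proteins:
                raise IntegrityError(f"annotation term {term.term_id!r} is empty")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterable[AnnotationTerm]:
        return iter(self.terms.values())


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read annotation sets from GMT or two-column TSV (term_id, protein).

    GMT lines are ``term_id<TAB>description<TAB>member...``.  The TSV form
    has one (term_id, protein_group) pair per line; a literal
    ``term_id\tprotein_group`` header is tolerated.
    """
    path = Path(path)
    terms: dict[str, AnnotationTerm] = {}
    if path.suffix.lower() == ".gmt":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line with <3 fields: {line[:50]!r}")
            term_id, name, members = parts[0], parts[1], parts[2:]
            terms[term_id] = AnnotationTerm(term_id, name or term_id,
                                            frozenset(m for m in members if m))
    else:
        try:
            df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        except pd.errors.EmptyDataError as exc:
            raise FormatError(f"empty annotation file: {path}") from exc
        if df.shape[1] < 2:
            raise FormatError("annotation TSV needs 2 columns (term_id, protein)")
        df = df.iloc[:, :2]
        df.columns = ["term_id", "protein_group"]
        if tuple(df.iloc[0]) == ("term_id", "protein_group"):
            df = df.iloc[1:]
        for term_id, grp in df.groupby("term_id"):
            terms[term_id] = AnnotationTerm(
                term_id, term_id, frozenset(grp["protein_group"])
            )
    return AnnotationTable(terms)


_FLOAT_FMT = "%.6f"


def write_results(
    protein_stats: pd.DataFrame | None,
    clusters: pd.DataFrame | None,
    enrichment: pd.DataFrame | None,
    out_dir: str | Path,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Write deterministic, sorted result tables plus a JSON run manifest.

    Missing components are written as header-only tables so a result
    directory always has the same shape.  Floats are fixed at 6 decimals;
    identical inputs produce byte-identical files.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out}: {exc}") from exc

    paths: dict[str, Path] = {}

    if protein_stats is None:
        protein_stats = pd.DataFrame(
            columns=["protein_group", "comparison", "n_precursors",
                     "log2fc", "p", "p_adj", "regulated", "significant"]
        )
    sort_cols = [c for c in ("compartment", "comparison", "protein_group")
                 if c in protein_stats.columns]
    protein_stats = protein_stats.sort_values(sort_cols, kind="stable")
    paths["proteins"] = out / "proteins.tsv"
    protein_stats.to_csv(paths["proteins"], sep="\t", index=False,
                         float_format=_FLOAT_FMT)

    if clusters is None:
        clusters = pd.DataFrame(columns=["protein_group", "cluster"])
    csort = [c for c in ("compartment", "cluster", "protein_group")
             if c in clusters.columns]
    clusters = clusters.sort_values(csort, kind="stable")
    paths["clusters"] = out / "clusters.tsv"
    clusters.to_csv(paths["clusters"], sep="\t", index=False,
                    float_format=_FLOAT_FMT)

    if enrichment is None:
        enrichment = pd.DataFrame(
            columns=["term_id", "name", "k", "n", "K", "N",
                     "fold_enrichment", "p", "p_adj"]
        )
    esort = [c for c in ("compartment", "comparison", "p", "term_id")
             if c in enrichment.columns]
    enrichment = enrichment.sort_values(esort, kind="stable")
    paths["enrichment"] = out / "enrichment.tsv"
    enrichment.to_csv(paths["enrichment"], sep="\t", index=False,
                      float_format=_FLOAT_FMT)

    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(_jsonable(manifest or {}), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def _jsonable(obj):
    """Coerce numpy scalars / paths so the manifest is plain JSON."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
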