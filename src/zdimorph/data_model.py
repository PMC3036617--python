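"""Core tabular containers and TSV readers/writers for the pipeline.

The pipeline joins everything against an :class:`ArrayDesign` — the mapping
from 25-mer perfect-match probes to ESTs (probe sets of 8-11 probes), from
ESTs to non-redundant genes, and from ESTs to chromosomes via the best BLAST
hit against the zebra finch genome assembly.  Probe-level intensities and
EST-level log2 expression travel as plain pandas DataFrames (samples in
columns) written as UTF-8 TSV with a single header row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EVALUE_THRESHOLD",
    "ArrayDesign",
    "SampleSheet",
    "DesignError",
    "MatrixError",
    "ValidationReport",
    "read_design",
    "write_design",
    "read_probe_matrix",
    "write_probe_matrix",
    "read_expression",
    "write_expression",
    "read_sample_sheet",
    "write_sample_sheet",
    "validate_experiment",
]

#: BLAST E-value cutoff below which a chromosome annotation counts as significant.
EVALUE_THRESHOLD = 1e-20

MIN_PROBES_PER_EST = 8
MAX_PROBES_PER_EST = 11


class DesignError(ValueError):
    """Raised when an array design violates a structural invariant."""


class MatrixError(ValueError):
    """Raised when an intensity/expression matrix violates an invariant."""


@dataclass
class ArrayDesign:
    """Probe ↔ EST ↔ gene ↔ chromosome mapping for one array layout.

    Parameters
    ----------
    table : pandas.DataFrame
        Indexed by ``est_id``, with columns ``probe_ids`` (tuple of probe
        identifiers, 8-11 per EST), ``gene_id`` (annotation key or None —
        ESTs sharing a gene_id are the same gene, ESTs without one are each
        their own gene), ``chromosome`` ("Z", an autosome name, or "none")
        and ``evalue`` (best BLAST-hit E-value, NaN when absent).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_ids", "gene_id", "chromosome", "evalue"}
        missing = required - set(self.table.columns)
        if missing:
            raise DesignError(f"design table missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise DesignError(f"duplicate est_id(s): {dups[:5]}")
        seen: dict[str, str] = {}
        for est_id, probes in self.table["probe_ids"].items():
            n = len(probes)
            if not (MIN_PROBES_PER_EST <= n <= MAX_PROBES_PER_EST):
                raise DesignError(
                    f"EST {est_id!r} has {n} probes; must be between "
                    f"{MIN_PROBES_PER_EST} and {MAX_PROBES_PER_EST}"
                )
            if len(set(probes)) != n:
                raise DesignError(f"EST {est_id!r} lists a probe twice")
            for p in probes:
                if p in seen:
                    raise DesignError(
                        f"probe {p!r} assigned to both EST {seen[p]!r} and {est_id!r}"
                    )
                seen[p] = str(est_id)
        self._probe_to_est = seen

    @property
    def est_ids(self) -> pd.Index:
        return self.table.index

    @property
    def n_ests(self) -> int:
        return len(self.table)

    @property
    def n_probes(self) -> int:
        return len(self._probe_to_est)

    def probes(self) -> list[str]:
        """All probe ids, in design (EST-major) order."""
        out: list[str] = []
        for probes in self.table["probe_ids"]:
            out.extend(probes)
        return out

    def probe_to_est(self) -> dict[str, str]:
        return dict(self._probe_to_est)

    def probe_counts(self) -> pd.Series:
        return self.table["probe_ids"].map(len).rename("n_probes")

    def effective_gene_ids(self) -> pd.Series:
        """gene_id per EST, with unannotated ESTs acting as their own gene."""
        gid = self.table["gene_id"]
        return pd.Series(
            np.where(gid.isna() | (gid == ""), self.table.index, gid),
            index=self.table.index,
            name="gene_id",
        )

    def annotation_issues(self) -> list[str]:
        """Soft consistency checks (chromosome vs E-value threshold)."""
        issues = []
        for est_id, row in self.table.iterrows():
            chrom, ev = row["chromosome"], row["evalue"]
            if chrom != "none" and (pd.isna(ev) or ev > EVALUE_THRESHOLD):
                issues.append(
                    f"EST {est_id}: chromosome {chrom!r} but E-value "
                    f"{ev!r} fails the {EVALUE_THRESHOLD:g} threshold"
                )
        return issues

    def fingerprint(self) -> str:
        """Stable hash of the probe/gene/chromosome structure.

        Used to refuse cross-species comparisons between different layouts.
        """
        import hashlib

        h = hashlib.sha256()
        for est_id, row in self.table.iterrows():
            h.update(str(est_id).encode())
            h.update(",".join(row["probe_ids"]).encode())
            h.update(str(row["gene_id"]).encode())
            h.update(str(row["chromosome"]).encode())
        return h.hexdigest()


@dataclass
class SampleSheet:
    """Sample metadata: sample_id, species, sex, optional population."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"species", "sex", "population"}
        missing = required - set(self.table.columns)
        if missing:
            raise MatrixError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise MatrixError("duplicate sample_id in sample sheet")
        bad_sex = set(self.table["sex"]) - {"male", "female"}
        if bad_sex:
            raise MatrixError(f"unknown sex label(s): {sorted(bad_sex)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def for_species(self, species: str) -> pd.DataFrame:
        return self.table[self.table["species"] == species]

    def sex_counts(self, species: str | None = None) -> pd.Series:
        tab = self.table if species is None else self.for_species(species)
        return tab.groupby(["species", "sex"]).size()

    def sex_labels(self, sample_ids: Sequence[str]) -> pd.Series:
        return self.table.loc[list(sample_ids), "sex"]


# ---------------------------------------------------------------------------
# TSV I/O


def _format_evalue(v: float) -> str:
    if pd.isna(v):
        return ""
    return f"{v:.6g}"


def write_design(design: ArrayDesign, path: str | Path) -> None:
    rows = []
    for est_id, row in design.table.iterrows():
        gid = row["gene_id"]
        rows.append(
            {
                "est_id": est_id,
                "probe_ids": ",".join(row["probe_ids"]),
                "gene_id": "" if gid is None or (isinstance(gid, float) and math.isnan(gid)) else gid,
                "chromosome": row["chromosome"] if row["chromosome"] else "",
                "evalue": _format_evalue(row["evalue"]),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> ArrayDesign:
    """Read a design TSV (est_id, probe_ids, gene_id, chromosome, evalue).

    gene_id/chromosome/evalue may be empty; an empty chromosome reads as
    "none".  Structural violations (duplicate probes, probe counts outside
    8-11) raise :class:`DesignError` naming the offender.
    """
    raw = pd.read_csv(
        path, sep="\t", dtype={"est_id": str, "probe_ids": str, "gene_id": str, "chromosome": str}
    )
    for col in ("est_id", "probe_ids"):
        if col not in raw.columns:
            raise DesignError(f"design file {path} missing column {col!r}")
    gene_raw = raw["gene_id"] if "gene_id" in raw.columns else pd.Series([None] * len(raw))
    chrom_raw = raw["chromosome"] if "chromosome" in raw.columns else pd.Series([""] * len(raw))
    ev_raw = raw["evalue"] if "evalue" in raw.columns else pd.Series([np.nan] * len(raw))
    table = pd.DataFrame(
        {
            "probe_ids": [tuple(s.split(",")) for s in raw["probe_ids"]],
            "gene_id": [None if pd.isna(g) or g == "" else str(g) for g in gene_raw],
            "chromosome": ["none" if pd.isna(c) or c == "" else str(c) for c in chrom_raw],
            "evalue": pd.to_numeric(ev_raw, errors="coerce").to_numpy(),
        },
        index=pd.Index(raw["est_id"].to_numpy(), name="est_id"),
    )
    return ArrayDesign(table)


def write_probe_matrix(matrix: pd.DataFrame, path: str | Path, precision: int = 6) -> None:
    """Write a probe×sample intensity matrix at a declared decimal precision."""
    matrix.rename_axis("probe_id").to_csv(path, sep="\t", float_format=f"%.{precision}f")


def read_probe_matrix(path: str | Path, design: ArrayDesign | None = None) -> pd.DataFrame:
    """Read a probe intensity TSV; entries must be strictly positive.

    When a design is supplied, probe ids not present in the design are a
    hard error.
    """
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    if m.isna().any().any():
        raise MatrixError(f"missing entries in probe matrix {path}")
    if (m.to_numpy() <= 0).any():
        bad = m.index[(m <= 0).any(axis=1)][:5].tolist()
        raise MatrixError(f"non-positive intensity for probe(s) {bad}; log2 undefined")
    if design is not None:
        known = set(design.probe_to_est())
        unknown = [p for p in m.index if p not in known]
        if unknown:
            raise MatrixError(f"probe id(s) not in design: {unknown[:5]}")
    return m


def write_expression(expr: pd.DataFrame, path: str | Path, precision: int = 6) -> None:
    expr.rename_axis("est_id").to_csv(path, sep="\t", float_format=f"%.{precision}f")


def read_expression(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    if m.isna().any().any():
        raise MatrixError(f"missing entries in expression matrix {path}")
    return m


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.rename_axis("sample_id").to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    t = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    t.index = t.index.astype(str)
    if "population" not in t.columns:
        t["population"] = ""
    t["population"] = t["population"].fillna("")
    return SampleSheet(t)


# ---------------------------------------------------------------------------
# Experiment-level validation


@dataclass
class ValidationReport:
    """Report-only consistency check of design + matrix + sample sheet."""

    issues: list[str] = field(default_factory=list)
    missing_probes: list[str] = field(default_factory=list)
    orphan_samples: list[str] = field(default_factory=list)
    replicate_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_experiment(
    design: ArrayDesign, matrix: pd.DataFrame, sheet: SampleSheet
) -> ValidationReport:
    """Cross-check the three inputs; never raises, only reports."""
    report = ValidationReport()
    design_probes = set(design.probe_to_est())
    matrix_probes = set(matrix.index)
    missing = sorted(design_probes - matrix_probes)
    if missing:
        report.missing_probes = missing
        report.issues.append(f"{len(missing)} design probe(s) missing from matrix")
    orphan = sorted(set(matrix.columns) - set(sheet.sample_ids))
    if orphan:
        report.orphan_samples = orphan
        report.issues.append(f"sample(s) in matrix but not sample sheet: {orphan}")
    counts = sheet.table.groupby(["species", "sex"]).size()
    report.replicate_counts = {k: int(v) for k, v in counts.items()}
    for (species, sex), n in report.replicate_counts.items():
        if n < 2:
            report.issues.append(f"species {species!r} has only {n} {sex} sample(s); need >=2")
    return report
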