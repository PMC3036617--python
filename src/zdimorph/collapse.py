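"""Collapse significant ESTs to non-redundant genes.

Several ESTs on the array can represent the same gene (shared annotation
id); ESTs without an annotation are each listed as their own non-redundant
gene.  A gene represented by both male-biased and female-biased significant
ESTs is 'ambiguous' — for Z-linked genes this can indicate that some of the
female-biased ESTs are actually W-chromosome homologues, so ambiguous Z
genes carry a W flag.  Chromosome class comes from the best BLAST hit,
counted only when the E-value passes 1e-20.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ArrayDesign, EVALUE_THRESHOLD

__all__ = [
    "GeneCall",
    "CollapseSummary",
    "classify_chromosome",
    "collapse",
    "summarize_table1",
    "round_sig",
]


@dataclass
class GeneCall:
    """Gene-level call after collapsing significant ESTs."""

    gene_id: str
    est_ids: list[str]
    direction: str  # "male", "female" or "ambiguous"
    chromosome_class: str  # "Z", "autosomal" or "none"
    mean_fc: float
    n_male_ests: int
    n_female_ests: int
    w_flag: bool = False  # ambiguous Z gene: female-biased members may be W homologues

    @property
    def majority_direction(self) -> str:
        """For ambiguous genes: the direction of most member ESTs ("tie" if equal)."""
        if self.n_male_ests > self.n_female_ests:
            return "male"
        if self.n_female_ests > self.n_male_ests:
            return "female"
        return "tie"


@dataclass
class CollapseSummary:
    n_significant_ests: int
    n_genes: int
    n_multi_est_genes: int
    n_ambiguous: int


def classify_chromosome(
    chromosome: str, evalue: float, threshold: float = EVALUE_THRESHOLD
) -> str:
    """Chromosome class of a single annotation: Z / autosomal / none.

    A named chromosome only counts when its BLAST E-value passes the
    threshold; weak or absent hits are "none".
    """
    if chromosome is None or chromosome == "none" or pd.isna(evalue) or evalue > threshold:
        return "none"
    return "Z" if chromosome == "Z" else "autosomal"


def _gene_chromosome_class(
    member_ests: list[str], design: ArrayDesign, threshold: float
) -> str:
    classes = [
        classify_chromosome(
            design.table.at[e, "chromosome"], design.table.at[e, "evalue"], threshold
        )
        for e in member_ests
    ]
    counts = Counter(classes)
    if len(counts) > 1:
        warnings.warn(
            f"gene members {member_ests} map to multiple chromosome classes {dict(counts)}"
        )
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            return "none"  # tie
    return counts.most_common(1)[0][0]


def collapse(
    est_calls: pd.DataFrame,
    design: ArrayDesign,
    evalue_threshold: float = EVALUE_THRESHOLD,
) -> tuple[list[GeneCall], CollapseSummary]:
    """Group significant ESTs into genes and derive gene-level calls.

    Parameters
    ----------
    est_calls : DataFrame indexed by est_id with columns ``direction``
        ("male"/"female") and ``fold_change``.
    design : ArrayDesign supplying gene ids and chromosome annotations.

    A gene's direction is that of its members, or "ambiguous" when both
    directions occur; its FC is the arithmetic mean of member FCs.
    """
    gene_of = design.effective_gene_ids()
    groups: dict[str, list[str]] = {}
    for est in est_calls.index:
        groups.setdefault(str(gene_of[est]), []).append(str(est))

    calls: list[GeneCall] = []
    n_multi = 0
    n_ambiguous = 0
    for gid, members in groups.items():
        dirs = est_calls.loc[members, "direction"]
        n_male = int((dirs == "male").sum())
        n_female = len(members) - n_male
        if n_male and n_female:
            direction = "ambiguous"
            n_ambiguous += 1
        else:
            direction = "male" if n_male else "female"
        if len(members) > 1:
            n_multi += 1
        chrom = _gene_chromosome_class(members, design, evalue_threshold)
        calls.append(
            GeneCall(
                gene_id=gid,
                est_ids=members,
                direction=direction,
                chromosome_class=chrom,
                mean_fc=float(est_calls.loc[members, "fold_change"].mean()),
                n_male_ests=n_male,
                n_female_ests=n_female,
                w_flag=(direction == "ambiguous" and chrom == "Z"),
            )
        )
    summary = CollapseSummary(
        n_significant_ests=len(est_calls),
        n_genes=len(calls),
        n_multi_est_genes=n_multi,
        n_ambiguous=n_ambiguous,
    )
    return calls, summary


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (the table-printing convention)."""
    if x == 0 or not np.isfinite(x):
        return x
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def summarize_table1(gene_calls: list[GeneCall], est_calls: pd.DataFrame) -> dict:
    """Per-direction accounting of significant ESTs and genes.

    EST percentages are over all significant ESTs; gene percentages are over
    the unambiguous (directional) genes; mean FC is the arithmetic mean of
    per-gene FCs.  Percentages are also reported rounded to two significant
    figures, the printing convention of summary tables of this kind.
    """
    n_ests = len(est_calls)
    directional = [g for g in gene_calls if g.direction in ("male", "female")]
    n_dir_genes = len(directional)
    out: dict = {
        "n_significant_ests": n_ests,
        "n_genes": len(gene_calls),
        "n_unambiguous_genes": n_dir_genes,
        "n_ambiguous_genes": sum(1 for g in gene_calls if g.direction == "ambiguous"),
    }
    for direction in ("male", "female"):
        est_n = int((est_calls["direction"] == direction).sum())
        genes = [g for g in directional if g.direction == direction]
        gene_n = len(genes)
        pct_ests = 100.0 * est_n / n_ests if n_ests else float("nan")
        pct_genes = 100.0 * gene_n / n_dir_genes if n_dir_genes else float("nan")
        out[direction] = {
            "n_ests": est_n,
            "n_genes": gene_n,
            "pct_ests": pct_ests,
            "pct_ests_rounded": round_sig(pct_ests),
            "pct_genes": pct_genes,
            "pct_genes_rounded": round_sig(pct_genes),
            "mean_fc_genes": float(np.mean([g.mean_fc for g in genes])) if genes else float("nan"),
        }
    return out
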