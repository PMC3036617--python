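"""Z-chromosome enrichment of sex-biased genes against the array background.

Sexually antagonistic and dosage-sensitive genes are expected to accumulate
on the Z chromosome, so the observed chromosomal distribution of sex-biased
genes is compared with the array's annotation background (by default the
EST-level counts of Z-annotated vs autosome-annotated targets) with a
two-sided Fisher exact test on the 2x2 table

    [[observed_Z, observed_autosomal],
     [background_Z - observed_Z, background_autosomal - observed_autosomal]]

using the method of small p-values (sum of hypergeometric probabilities of
tables no more probable than the observed one).  Genes without a
significant annotation are excluded from the test and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .collapse import GeneCall
from .data_model import ArrayDesign, EVALUE_THRESHOLD
from .collapse import classify_chromosome

__all__ = [
    "EnrichmentResult",
    "expected_proportion",
    "fisher_enrichment",
    "background_counts",
    "distribution_report",
]


@dataclass
class EnrichmentResult:
    observed_z: int
    observed_autosomal: int
    background_z: int
    background_autosomal: int
    observed_z_proportion: float
    expected_z_proportion: float
    p_value: float
    odds_ratio: float  # sample OR ad/bc; inf/nan when a cell is 0
    odds_ratio_haldane: float | None = None  # +0.5 correction, only when a cell is 0

    def to_dict(self) -> dict:
        return {
            "observed_z": self.observed_z,
            "observed_autosomal": self.observed_autosomal,
            "background_z": self.background_z,
            "background_autosomal": self.background_autosomal,
            "observed_z_proportion": self.observed_z_proportion,
            "observed_z_proportion_3dp": round(self.observed_z_proportion, 3),
            "expected_z_proportion": self.expected_z_proportion,
            "expected_z_proportion_3dp": round(self.expected_z_proportion, 3),
            "p_value": self.p_value,
            "odds_ratio": self.odds_ratio,
            "odds_ratio_haldane": self.odds_ratio_haldane,
        }


def expected_proportion(background_z: int, background_autosomal: int) -> float:
    """Z share of the annotation background: z / (z + autosomal)."""
    total = background_z + background_autosomal
    if total <= 0:
        raise ValueError("background counts must sum to > 0")
    return background_z / total


def fisher_enrichment(
    obs_z: int, obs_autosomal: int, background_z: int, background_autosomal: int
) -> EnrichmentResult:
    """Two-sided Fisher exact test of the observed set against background."""
    for name, obs, bg in (
        ("Z", obs_z, background_z),
        ("autosomal", obs_autosomal, background_autosomal),
    ):
        if obs < 0 or bg < 0:
            raise ValueError("counts must be non-negative")
        if obs > bg:
            raise ValueError(f"observed {name} count {obs} exceeds background {bg}")
    a, b = obs_z, obs_autosomal
    c, d = background_z - obs_z, background_autosomal - obs_autosomal
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
        haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
        haldane = None
    n_obs = obs_z + obs_autosomal
    return EnrichmentResult(
        observed_z=obs_z,
        observed_autosomal=obs_autosomal,
        background_z=background_z,
        background_autosomal=background_autosomal,
        observed_z_proportion=obs_z / n_obs if n_obs else float("nan"),
        expected_z_proportion=expected_proportion(background_z, background_autosomal),
        p_value=float(min(p, 1.0)),
        odds_ratio=float(odds),
        odds_ratio_haldane=None if haldane is None else float(haldane),
    )


def background_counts(
    design: ArrayDesign, evalue_threshold: float = EVALUE_THRESHOLD
) -> dict[str, int]:
    """EST-level annotation background: counts per chromosome class."""
    counts = {"Z": 0, "autosomal": 0, "none": 0}
    for est, row in design.table.iterrows():
        counts[classify_chromosome(row["chromosome"], row["evalue"], evalue_threshold)] += 1
    return counts


def distribution_report(
    gene_calls: Sequence[GeneCall],
    design: ArrayDesign,
    evalue_threshold: float = EVALUE_THRESHOLD,
) -> dict:
    """Per-direction chromosomal distribution with Fisher enrichment tests.

    Uses unambiguous genes only.  For each direction the Z/autosomal split
    is tested against the array background; the "none" class is excluded
    from the 2x2 test but reported for the distribution histogram.
    """
    bg = background_counts(design, evalue_threshold)
    report: dict = {"background": bg, "directions": {}}
    for direction in ("male", "female"):
        genes = [g for g in gene_calls if g.direction == direction]
        class_counts = {
            "Z": sum(1 for g in genes if g.chromosome_class == "Z"),
            "autosomal": sum(1 for g in genes if g.chromosome_class == "autosomal"),
            "none": sum(1 for g in genes if g.chromosome_class == "none"),
        }
        entry: dict = {"class_counts": class_counts, "n_genes": len(genes)}
        if class_counts["Z"] + class_counts["autosomal"] == 0:
            entry["test"] = None
            entry["note"] = "no annotated genes in this direction; test skipped"
        else:
            entry["test"] = fisher_enrichment(
                class_counts["Z"], class_counts["autosomal"], bg["Z"], bg["autosomal"]
            ).to_dict()
        report["directions"][direction] = entry
    n_ambiguous = sum(1 for g in gene_calls if g.direction == "ambiguous")
    report["n_ambiguous_excluded"] = n_ambiguous
    return report
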