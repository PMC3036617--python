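"""The two EST-level filters, with exact accounting.

1. SD filter — an EST is removed when the standard deviation of its
   (unlogged) normalized signal across arrays exceeds 30% of the median of
   that signal.  Applied per EST on the unlogged (2**x) scale of the
   normalized log2 expression; "median" is the per-EST median across that
   species' arrays.
2. CGH mask + retention filter — probes that failed the cross-species
   genomic hybridisation are masked; each EST is flagged with how many of
   its probes it retains, and only ESTs retaining at least 8 probes are
   analysed.  The minimum is an absolute count, so a short (8-probe) EST
   that loses any probe is removed.

Filters run SD-first, then retention, matching the original analysis
narrative; the accounting identity n_input = removed_sd + removed_retention
+ remaining always holds because the retention filter operates on the SD
survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import ArrayDesign, MatrixError

__all__ = [
    "FilterReport",
    "sd_filter",
    "apply_cgh_mask",
    "retention_filter",
    "filter_expression",
    "read_mask",
]


@dataclass
class FilterReport:
    """Accounting for one species' filtering run."""

    n_input: int = 0
    n_removed_sd: int = 0
    n_removed_retention: int = 0
    n_remaining: int = 0
    removed_sd: list[str] = field(default_factory=list)
    removed_retention: list[str] = field(default_factory=list)
    retained_probe_counts: dict[str, int] = field(default_factory=dict)
    loss_tallies: dict[str, int] = field(default_factory=dict)
    unknown_mask_ids: list[str] = field(default_factory=list)

    def check(self) -> None:
        if self.n_input - self.n_removed_sd - self.n_removed_retention != self.n_remaining:
            raise AssertionError("filter accounting identity violated")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_sd": self.n_removed_sd,
            "n_removed_retention": self.n_removed_retention,
            "n_remaining": self.n_remaining,
            "loss_tallies": self.loss_tallies,
            "n_unknown_mask_ids": len(self.unknown_mask_ids),
        }


def sd_filter(
    expr: pd.DataFrame, threshold: float = 0.30
) -> tuple[list[str], list[str]]:
    """Split ESTs into (kept, removed) by the relative-SD rule.

    An EST is removed iff sd(2**x across samples) > threshold * median(2**x
    across samples), with the sample standard deviation (ddof=1).
    """
    if expr.shape[1] < 2:
        raise MatrixError("sd_filter needs at least 2 samples")
    unlogged = np.exp2(expr.to_numpy(dtype=float))
    sd = unlogged.std(axis=1, ddof=1)
    med = np.median(unlogged, axis=1)
    if (med <= 0).any():
        raise MatrixError("non-positive median signal; intensities must be positive")
    removed_mask = sd > threshold * med
    kept = [e for e, r in zip(expr.index, removed_mask) if not r]
    removed = [e for e, r in zip(expr.index, removed_mask) if r]
    return kept, removed


def read_mask(path) -> list[str]:
    """Read a CGH mask file: one probe id per line, blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def apply_cgh_mask(
    design: ArrayDesign, mask: Iterable[str]
) -> tuple[pd.Series, list[str]]:
    """Annotate each EST with its retained probe count under the mask.

    Returns (retained counts indexed by est_id, mask entries not found in
    the design — reported, ignored).
    """
    mask_set = set(mask)
    probe_to_est = design.probe_to_est()
    unknown = sorted(mask_set - set(probe_to_est))
    lost = pd.Series(0, index=design.est_ids, dtype=int)
    for p in mask_set & set(probe_to_est):
        lost[probe_to_est[p]] += 1
    retained = design.probe_counts() - lost
    return retained.rename("retained_probes"), unknown


def retention_filter(
    retained: pd.Series,
    design: ArrayDesign,
    min_probes: int = 8,
    within: Sequence[str] | None = None,
) -> tuple[list[str], list[str], dict[str, int]]:
    """Keep ESTs retaining at least ``min_probes`` probes (absolute count).

    ``within`` restricts the filter to a subset of ESTs (e.g. the SD-filter
    survivors).  Also tallies how many ESTs lost exactly 0, 1, 2, 3 or >3
    probes among those considered.
    """
    ids = list(retained.index if within is None else within)
    original = design.probe_counts()
    kept: list[str] = []
    removed: list[str] = []
    tallies = {"0": 0, "1": 0, "2": 0, "3": 0, ">3": 0}
    for e in ids:
        n_lost = int(original[e] - retained[e])
        tallies[str(n_lost) if n_lost <= 3 else ">3"] += 1
        (kept if retained[e] >= min_probes else removed).append(e)
    return kept, removed, tallies


def filter_expression(
    expr: pd.DataFrame,
    design: ArrayDesign,
    cgh_mask: Iterable[str] | None = None,
    sd_threshold: float = 0.30,
    min_probes: int = 8,
) -> tuple[pd.DataFrame, FilterReport]:
    """SD filter, then (if a mask is given) the retention filter.

    Returns the filtered expression matrix and a :class:`FilterReport`
    whose accounting identity is checked before returning.
    """
    report = FilterReport(n_input=len(expr))
    kept_sd, removed_sd = sd_filter(expr, threshold=sd_threshold)
    report.removed_sd = removed_sd
    report.n_removed_sd = len(removed_sd)
    kept = kept_sd
    if cgh_mask is not None:
        retained, unknown = apply_cgh_mask(design, cgh_mask)
        report.unknown_mask_ids = unknown
        report.retained_probe_counts = {str(k): int(v) for k, v in retained.items()}
        kept, removed_ret, tallies = retention_filter(
            retained, design, min_probes=min_probes, within=kept_sd
        )
        report.removed_retention = removed_ret
        report.n_removed_retention = len(removed_ret)
        report.loss_tallies = tallies
    report.n_remaining = len(kept)
    report.check()
    return expr.loc[kept], report
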