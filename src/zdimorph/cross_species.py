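"""Cross-species comparison of gene-level sex-bias calls.

Both species are hybridised to the same array, so gene calls share one
gene-id namespace and can be intersected directly: genes sex-biased in both
species with the same direction, direction reversals, genes ambiguous in
both, and species-specific sets, each broken down by chromosome class.
Genes whose ESTs were all filtered away in the second species are reported
as "untestable" there rather than as evidence of species specificity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .collapse import GeneCall

__all__ = ["ComparisonResult", "compare", "overlap_check"]


@dataclass
class ComparisonResult:
    """Partition of the union of two species' sex-biased gene sets."""

    shared_same_direction: set[str] = field(default_factory=set)
    shared_ambiguous: set[str] = field(default_factory=set)
    discordant_ambiguous: set[str] = field(default_factory=set)
    reversed: set[str] = field(default_factory=set)
    unique_a: set[str] = field(default_factory=set)
    unique_b: set[str] = field(default_factory=set)
    untestable_in_b: set[str] = field(default_factory=set)
    class_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def categories(self) -> dict[str, set[str]]:
        return {
            "shared_same_direction": self.shared_same_direction,
            "shared_ambiguous": self.shared_ambiguous,
            "discordant_ambiguous": self.discordant_ambiguous,
            "reversed": self.reversed,
            "unique_a": self.unique_a,
            "unique_b": self.unique_b,
        }

    def to_dict(self) -> dict:
        out = {k: sorted(v) for k, v in self.categories().items()}
        out["untestable_in_b"] = sorted(self.untestable_in_b)
        out["counts"] = {k: len(v) for k, v in self.categories().items()}
        out["counts"]["untestable_in_b"] = len(self.untestable_in_b)
        out["class_counts"] = self.class_counts
        return out


def _match_direction(a: GeneCall, b: GeneCall) -> str:
    """Classify a gene called in both species."""
    if a.direction == "ambiguous" and b.direction == "ambiguous":
        return "shared_ambiguous"
    if a.direction == "ambiguous" or b.direction == "ambiguous":
        amb, direc = (a, b) if a.direction == "ambiguous" else (b, a)
        if amb.majority_direction == direc.direction:
            return "shared_same_direction"
        return "discordant_ambiguous"
    if a.direction == b.direction:
        return "shared_same_direction"
    return "reversed"


def compare(
    calls_a: Sequence[GeneCall],
    calls_b: Sequence[GeneCall],
    untestable_in_b: Iterable[str] = (),
    design_fingerprint_a: str | None = None,
    design_fingerprint_b: str | None = None,
) -> ComparisonResult:
    """Compare two species' gene-level call sets on the same design.

    A gene ambiguous in one species and directional in the other counts as
    shared only when the directional call matches the ambiguous gene's
    majority direction; otherwise it lands in the auditable
    "discordant_ambiguous" bucket.  Genes untestable in species B (all
    member ESTs filtered away there) are removed from ``unique_a``.
    """
    if (
        design_fingerprint_a is not None
        and design_fingerprint_b is not None
        and design_fingerprint_a != design_fingerprint_b
    ):
        raise ValueError("gene call sets come from different array designs")
    by_a = {g.gene_id: g for g in calls_a}
    by_b = {g.gene_id: g for g in calls_b}
    untestable = set(untestable_in_b)
    result = ComparisonResult()
    for gid in set(by_a) | set(by_b):
        if gid in by_a and gid in by_b:
            bucket = _match_direction(by_a[gid], by_b[gid])
            getattr(result, bucket).add(gid)
        elif gid in by_a:
            if gid in untestable:
                result.untestable_in_b.add(gid)
            else:
                result.unique_a.add(gid)
        else:
            result.unique_b.add(gid)

    def _classes(gids: set[str], primary: dict[str, GeneCall], fallback: dict[str, GeneCall]):
        c = Counter(
            (primary.get(g) or fallback[g]).chromosome_class for g in gids
        )
        return {k: int(v) for k, v in sorted(c.items())}

    for name, gids in result.categories().items():
        result.class_counts[name] = _classes(gids, by_a, by_b)
    return result


def overlap_check(set_1: Iterable[str], set_2: Iterable[str]) -> tuple[int, list[str]]:
    """Intersection count and identities of two id sets.

    Used e.g. to verify that genes differing between populations are not
    the ones driving the between-sex signal.
    """
    inter = sorted(set(set_1) & set(set_2))
    return len(inter), inter
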