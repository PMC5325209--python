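"""Identification-set comparisons: Jaccard similarity, overlap score
relative to the largest set, and proteome coverage percentages."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["SetComparison", "compare_sets", "coverage_summary", "mean_coverage", "round_half_up"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up rounding, matching how printed tables round."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SetComparison:
    """n-way set comparison summary.

    ``overlap_pct`` = 100 * |intersection| / max cardinality;
    ``jaccard`` = |intersection| / |union|.  Full precision is retained;
    use :meth:`rounded` for report output.
    """

    labels: tuple[str, ...]
    cardinalities: tuple[int, ...]
    intersection: int
    union: int

    def __post_init__(self) -> None:
        if self.intersection > min(self.cardinalities):
            raise ValueError("intersection exceeds the smallest set")
        if self.union < max(self.cardinalities):
            raise ValueError("union smaller than the largest set")

    @property
    def overlap_pct(self) -> float:
        return 100.0 * self.intersection / max(self.cardinalities)

    @property
    def jaccard(self) -> float:
        return self.intersection / self.union

    def rounded(self, ndigits: int = 2) -> tuple[float, float]:
        """(overlap %, Jaccard) rounded half-up for reporting."""
        return round_half_up(self.overlap_pct, ndigits), round_half_up(self.jaccard, ndigits)

    @classmethod
    def from_cardinalities(
        cls, labels, cardinalities, intersection: int, union: int
    ) -> "SetComparison":
        """Build from printed cardinalities without the member sets."""
        return cls(tuple(labels), tuple(int(c) for c in cardinalities),
                   int(intersection), int(union))


def compare_sets(sets: dict[str, set]) -> SetComparison:
    """Exact set algebra over 2 or 3 labeled accession sets."""
    if not 2 <= len(sets) <= 3:
        raise ValueError("compare_sets takes 2 or 3 sets")
    if any(len(s) == 0 for s in sets.values()):
        empty = [k for k, v in sets.items() if not v]
        raise ValueError(f"empty set(s): {empty}")
    labels = tuple(sets)
    members = [set(sets[k]) for k in labels]
    inter = set.intersection(*members)
    union = set.union(*members)
    return SetComparison(
        labels=labels,
        cardinalities=tuple(len(m) for m in members),
        intersection=len(inter),
        union=len(union),
    )


def coverage_summary(identified, reference_size: int) -> float:
    """100 * |identified| / reference_size.  ``identified`` may be a set
    or a pre-counted integer."""
    if reference_size <= 0:
        raise ValueError("reference_size must be > 0")
    n = identified if isinstance(identified, int) else len(identified)
    return 100.0 * n / reference_size


def mean_coverage(percentages) -> float:
    """Mean of per-dataset coverage percentages."""
    vals = list(percentages)
    return sum(vals) / len(vals)
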