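"""Genomic-localization taxonomy for symbols with multiple stable IDs.

A symbol carrying two or three Ensembl IDs can owe the duplication to very
different annotation situations: a second copy parked on an assembly
scaffold, paralogues on different chromosomes, X/Y gametologues, antisense
twins, or readthrough genes overlapping on the same strand.  The taxonomy
is an ordered decision list; each multiplied symbol receives exactly one
category, the earliest applicable one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Dict, List, Mapping, Sequence, Tuple

from .io import GenomicLocus

__all__ = [
    "LocusCategory",
    "ChromosomeNamespace",
    "SPECIES_NAMESPACES",
    "split_scaffold",
    "intervals_overlap",
    "classify_multiplied_symbol",
    "category_counts",
]


class LocusCategory(Enum):
    """Why one symbol carries several stable IDs, by genomic localization."""

    SCAFFOLD_INVOLVED = "scaffold_involved"
    DIFFERENT_CHROMOSOMES_AUTOSOMAL = "different_chromosomes_autosomal"
    SEX_CHROMOSOMES_XY = "sex_chromosomes_xy"
    SAME_CHROM_DIFFERENT_STRAND = "same_chrom_different_strand"
    SAME_CHROM_SAME_START = "same_chrom_same_start"
    SAME_CHROM_DIFF_START_OVERLAPPING = "same_chrom_diff_start_overlapping"
    SAME_CHROM_DIFF_START_NONOVERLAPPING = "same_chrom_diff_start_nonoverlapping"


@dataclass(frozen=True)
class ChromosomeNamespace:
    """Canonical chromosome names for one assembly; anything else is a scaffold.

    ``mt_autosomal`` controls whether MT counts as autosomal in the
    "different chromosomes including at least one autosome" rule.
    """

    autosomes: frozenset
    sex: frozenset = frozenset({"X", "Y"})
    mito: frozenset = frozenset({"MT"})
    mt_autosomal: bool = True

    def __post_init__(self) -> None:
        if self.autosomes & self.sex or (self.autosomes | self.sex) & self.mito:
            raise ValueError("autosome / sex / mito name sets must be disjoint")

    @property
    def chromosomes(self) -> frozenset:
        return self.autosomes | self.sex | self.mito

    def is_chromosome(self, region: str) -> bool:
        return region in self.chromosomes

    def is_autosome(self, region: str) -> bool:
        if region in self.autosomes:
            return True
        return self.mt_autosomal and region in self.mito

    @classmethod
    def for_range(cls, n: int, **kw) -> "ChromosomeNamespace":
        return cls(autosomes=frozenset(str(i) for i in range(1, n + 1)), **kw)


#: Assembly presets: human GRCh38, mouse GRCm39, rat mRatBN7.2, pig Sscrofa11.1.
SPECIES_NAMESPACES: Mapping[str, ChromosomeNamespace] = {
    "human": ChromosomeNamespace.for_range(22),
    "mouse": ChromosomeNamespace.for_range(19),
    "rat": ChromosomeNamespace.for_range(20),
    "pig": ChromosomeNamespace.for_range(18),
}

IdLocus = Tuple[str, GenomicLocus]


def split_scaffold(
    ids_with_loci: Sequence[IdLocus], ns: ChromosomeNamespace
) -> Tuple[List[IdLocus], List[IdLocus]]:
    """Partition (ID, locus) pairs into chromosome-placed and scaffold-placed.

    Membership is decided purely by region-name lookup in the namespace;
    input order is preserved in both outputs.
    """
    chromosomal = [p for p in ids_with_loci if ns.is_chromosome(p[1].region)]
    scaffold = [p for p in ids_with_loci if not ns.is_chromosome(p[1].region)]
    return chromosomal, scaffold


def intervals_overlap(a: GenomicLocus, b: GenomicLocus) -> bool:
    """True iff two loci share at least one base (1-based inclusive ends).

    Touching intervals (``a.end == b.start``) share that base and overlap.
    Caller guarantees same region and strand; violating that is a contract
    error, not a silent False.
    """
    if a.region != b.region:
        raise ValueError(f"loci on different regions: {a.region} vs {b.region}")
    if a.strand != b.strand:
        raise ValueError(f"loci on different strands: {a.strand} vs {b.strand}")
    return max(a.start, b.start) <= min(a.end, b.end)


def classify_multiplied_symbol(
    ids_with_loci: Sequence[IdLocus], ns: ChromosomeNamespace
) -> LocusCategory:
    """Assign the earliest applicable category to a multiplied symbol.

    Decision order: any scaffold placement wins; then >1 chromosome with at
    least one autosome; then placements confined to distinct sex
    chromosomes; then same chromosome on opposite strands; then identical
    start positions (ends may differ); finally the all-pairs interval
    overlap test separates overlapping from non-overlapping duplicates, over
    every pair regardless of the symbol's ID multiplicity.
    """
    if len(ids_with_loci) < 2:
        raise ValueError("a multiplied symbol needs at least two stable IDs")
    loci = [loc for _, loc in ids_with_loci]
    if any(not ns.is_chromosome(loc.region) for loc in loci):
        return LocusCategory.SCAFFOLD_INVOLVED
    regions = {loc.region for loc in loci}
    if len(regions) > 1:
        if any(ns.is_autosome(r) for r in regions):
            return LocusCategory.DIFFERENT_CHROMOSOMES_AUTOSOMAL
        if regions <= ns.sex:
            return LocusCategory.SEX_CHROMOSOMES_XY
        # distinct non-autosomal, non-sex chromosomes (MT in strict mode)
        return LocusCategory.DIFFERENT_CHROMOSOMES_AUTOSOMAL
    known_strands = {loc.strand for loc in loci if loc.strand is not None}
    if len(known_strands) > 1:
        return LocusCategory.SAME_CHROM_DIFFERENT_STRAND
    if len({loc.strand for loc in loci}) > 1:
        warnings.warn(
            "unknown strand among loci; strand agreement assumed for overlap test",
            stacklevel=2,
        )
    if len({loc.start for loc in loci}) == 1:
        return LocusCategory.SAME_CHROM_SAME_START
    if any(
        max(a.start, b.start) <= min(a.end, b.end)
        for a, b in combinations(loci, 2)
    ):
        return LocusCategory.SAME_CHROM_DIFF_START_OVERLAPPING
    return LocusCategory.SAME_CHROM_DIFF_START_NONOVERLAPPING


@dataclass
class CategoryCounts:
    """Category histogram over multiplied symbols, plus the chromosomal subtotal."""

    counts: Dict[LocusCategory, int]
    n_symbols: int
    n_all_chromosomal: int
    per_symbol: Dict[str, LocusCategory] = field(default_factory=dict)


def category_counts(
    multiplied: Mapping[str, Sequence[IdLocus]], ns: ChromosomeNamespace
) -> CategoryCounts:
    """Classify every multiplied symbol and tally categories.

    Counts always sum to the number of multiplied symbols; the subtotal
    reports symbols whose IDs are all chromosome-placed.
    """
    counts = {cat: 0 for cat in LocusCategory}
    per_symbol: Dict[str, LocusCategory] = {}
    n_all_chrom = 0
    for symbol in sorted(multiplied):
        cat = classify_multiplied_symbol(multiplied[symbol], ns)
        counts[cat] += 1
        per_symbol[symbol] = cat
        if cat is not LocusCategory.SCAFFOLD_INVOLVED:
            n_all_chrom += 1
    return CategoryCounts(
        counts=counts,
        n_symbols=len(multiplied),
        n_all_chromosomal=n_all_chrom,
        per_symbol=per_symbol,
    )
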