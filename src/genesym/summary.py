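"""Per-species summaries of protein-coding genes.

Partitions a gene table into three disjoint buckets — symbols with a single
stable ID, symbols carrying more than one stable ID ("multiplied" symbols,
e.g. readthrough loci annotated twice), and stable IDs with no symbol at all
(novel genes) — and counts symbol overlap between species.

Symbol uniqueness here is by verbatim symbol: official symbols within one
species are consistently cased in Ensembl, so case-folding is deferred to
the synonym analyses where conventions actually collide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Set, Tuple

from .io import GeneRecord

__all__ = ["GeneSetSummary", "summarize", "cross_species_overlap"]


class DataIntegrityError(ValueError):
    """A stable ID appears more than once with conflicting annotation."""


@dataclass
class GeneSetSummary:
    """Disjoint partition of a gene set by symbol multiplicity.

    Every stable ID lands in exactly one of: the single-ID symbol bucket,
    one ``multiplied`` list, or ``symbolless``; the three partitions sum to
    ``n_genes``.
    """

    n_genes: int
    n_unique_symbols: int
    single: Dict[str, str] = field(default_factory=dict)  # symbol -> ID
    multiplied: Dict[str, List[str]] = field(default_factory=dict)
    symbolless: List[str] = field(default_factory=list)

    @property
    def n_multiplied_symbols(self) -> int:
        return len(self.multiplied)


def summarize(
    records: Iterable[GeneRecord], type_filter: str | None = "protein_coding"
) -> GeneSetSummary:
    """Summarise a deduplicated gene table.

    ``type_filter`` keeps only records of that gene type (``None`` keeps
    all; records without a type annotation always pass).  A stable ID seen
    twice with conflicting symbols raises :class:`DataIntegrityError` —
    silent merging would mask fixture or export bugs.
    """
    by_id: Dict[str, GeneRecord] = {}
    for rec in records:
        if type_filter is not None and rec.gene_type not in (None, type_filter):
            continue
        prev = by_id.get(rec.ensembl_id)
        if prev is not None and prev.symbol != rec.symbol:
            raise DataIntegrityError(
                f"stable ID {rec.ensembl_id} carries conflicting symbols "
                f"{prev.symbol!r} / {rec.symbol!r}"
            )
        by_id.setdefault(rec.ensembl_id, rec)

    by_symbol: Dict[str, List[str]] = {}
    symbolless: List[str] = []
    for eid in sorted(by_id):
        rec = by_id[eid]
        if rec.symbol is None:
            symbolless.append(eid)
        else:
            by_symbol.setdefault(rec.symbol, []).append(eid)

    single = {s: ids[0] for s, ids in by_symbol.items() if len(ids) == 1}
    multiplied = {s: ids for s, ids in by_symbol.items() if len(ids) > 1}
    return GeneSetSummary(
        n_genes=len(by_id),
        n_unique_symbols=len(by_symbol),
        single=single,
        multiplied=multiplied,
        symbolless=symbolless,
    )


def cross_species_overlap(
    symbol_sets: Mapping[str, Set[str]], *, case_sensitive: bool = True
) -> Dict[Tuple[str, ...], int]:
    """Exclusive-region symbol counts for 2-4 named sets (Venn regions).

    Keys are sorted tuples of the set names a region belongs to; the value
    counts symbols present in exactly those sets.  By inclusion-exclusion
    the region counts sum to the size of the union.  ``case_sensitive=False``
    folds symbols before comparison.
    """
    if not 2 <= len(symbol_sets) <= 4:
        raise ValueError(f"need 2-4 named sets, got {len(symbol_sets)}")
    sets = {
        name: (set(s) if case_sensitive else {x.lower() for x in s})
        for name, s in symbol_sets.items()
    }
    names = sorted(sets)
    regions: Dict[Tuple[str, ...], int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo)) if len(
                combo
            ) < len(names) else set()
            regions[combo] = len(inside - outside)
    return regions
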