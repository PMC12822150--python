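"""Detection of ambiguous gene symbols.

Three ambiguity types threaten gene identification in literature data:

* **official-as-synonym** — a string that is the current official symbol of
  one gene and simultaneously a synonym (obsolete symbol) of a different
  gene; e.g. mouse *Arg1* is official for arginase-1 and a synonym of the
  gene now called *Tinagl1*.
* **ambiguous synonym** — a synonym attached to at least two different
  official symbols; e.g. *RAMP* can mean *Zmym2* or *Pamr1*.
* **combined** — a symbol caught by both detectors, such as *Cklf*, which
  is official for chemokine-like factor and a synonym of *Cmtm2a*, *Klf5*
  and *Klf15*.

All comparisons case-fold first (human *TTR* vs mouse *Ttr* conventions),
and self-matches — a synonym that simply became the official symbol of the
same gene, like *ADAM12*/*Adam12* — are never ambiguity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .io import GeneRecord, SynonymLink

__all__ = [
    "fold",
    "AmbiguityType",
    "Resolution",
    "AmbiguityReport",
    "find_ambiguous_official_symbols",
    "find_ambiguous_synonyms",
    "assign_combined",
    "genes_linked_to_ambiguous_symbols",
    "merge_with_input_ids",
]

logger = logging.getLogger(__name__)

_ASCII_SHIFT = ord("a") - ord("A")


def fold(symbol: str) -> str:
    """Locale-independent ASCII lowercase of a symbol (idempotent).

    Only A-Z are mapped; non-ASCII characters pass through byte-wise and
    are logged, avoiding locale case-mapping pitfalls (dotted/dotless I).
    """
    if not symbol:
        raise ValueError("cannot fold an empty symbol")
    if not symbol.isascii():
        logger.debug("non-ASCII symbol passed through fold: %r", symbol)
    return "".join(
        chr(ord(c) + _ASCII_SHIFT) if "A" <= c <= "Z" else c for c in symbol
    )


class AmbiguityType(Enum):
    OFFICIAL_AS_SYNONYM = "official_as_synonym"
    AMBIGUOUS_SYNONYM = "ambiguous_synonym"
    COMBINED = "combined"


@dataclass(frozen=True)
class Resolution:
    """One gene an ambiguous symbol can resolve to."""

    official_symbol: str
    ensembl_id: str
    gene_type: Optional[str] = None


@dataclass
class AmbiguityReport:
    """An ambiguous symbol together with every gene it can point to.

    ``cross_type`` is true when any resolution is not protein-coding (the
    *Parp2*/*Rpph1* situation); such reports are routed to a separate
    stream rather than the protein-to-protein list.  ``trigger_id`` is the
    stable ID of the trigger's own gene, attached by
    :func:`merge_with_input_ids` for official-symbol triggers.
    """

    trigger_symbol: str
    folded: str
    type: AmbiguityType
    resolutions: List[Resolution] = field(default_factory=list)
    cross_type: bool = False
    trigger_id: Optional[str] = None


def _sorted_resolutions(resolutions: Iterable[Resolution]) -> List[Resolution]:
    # deterministic: folded official symbol, then stable ID
    return sorted(set(resolutions), key=lambda r: (fold(r.official_symbol), r.ensembl_id))


def find_ambiguous_official_symbols(
    genes: Iterable[GeneRecord],
    synonyms: Iterable[SynonymLink],
    *,
    coding_type: str = "protein_coding",
    protein_coding_only: bool = True,
) -> List[AmbiguityReport]:
    """Official symbols that double as synonyms of other genes (type A).

    For every official symbol in ``genes`` whose folded form equals the
    folded form of a synonym attached to a *different* gene, one report is
    emitted listing the other gene(s).  Pairs identical under folding
    (*ADAM12* synonym of the *Adam12* gene itself) are self-matches and
    removed.  With ``protein_coding_only`` set, a report any of whose
    resolutions is a non-``coding_type`` gene is flagged ``cross_type``;
    downstream writers keep the two streams in separate files.
    """
    gene_list = list(genes)
    type_by_id = {g.ensembl_id: g.gene_type for g in gene_list}

    officials: Dict[str, List[GeneRecord]] = {}
    for g in gene_list:
        if g.symbol is not None:
            officials.setdefault(fold(g.symbol), []).append(g)

    hits: Dict[str, List[Resolution]] = {}
    for link in synonyms:
        key = fold(link.synonym)
        triggers = officials.get(key)
        if not triggers:
            continue
        if link.official_symbol is None:
            continue
        # self-match: the synonym belongs to a trigger gene itself, or the
        # gene's current official symbol folds to the same string
        if any(link.ensembl_id == g.ensembl_id for g in triggers):
            continue
        if fold(link.official_symbol) == key:
            continue
        hits.setdefault(key, []).append(
            Resolution(
                official_symbol=link.official_symbol,
                ensembl_id=link.ensembl_id,
                gene_type=link.gene_type or type_by_id.get(link.ensembl_id),
            )
        )

    reports: List[AmbiguityReport] = []
    for key in sorted(hits):
        resolutions = _sorted_resolutions(hits[key])
        trigger = min(g.symbol for g in officials[key])
        cross = protein_coding_only and any(
            r.gene_type is not None and r.gene_type != coding_type for r in resolutions
        )
        reports.append(
            AmbiguityReport(
                trigger_symbol=trigger,
                folded=key,
                type=AmbiguityType.OFFICIAL_AS_SYNONYM,
                resolutions=resolutions,
                cross_type=cross,
            )
        )
    return reports


def find_ambiguous_synonyms(
    synonyms: Iterable[SynonymLink], *, min_officials: int = 2
) -> List[AmbiguityReport]:
    """Synonyms attached to at least two distinct official symbols (type B).

    Rows without a synonym are assumed already filtered at read time; links
    whose gene has no official symbol cannot contribute a distinct official
    and are skipped.  Grouping is by folded synonym; a resolution whose
    official symbol folds to the synonym itself is a self-match and does
    not count.  Resolution lists are deterministically sorted.
    """
    groups: Dict[str, List[SynonymLink]] = {}
    verbatim: Dict[str, List[str]] = {}
    for link in synonyms:
        key = fold(link.synonym)
        groups.setdefault(key, []).append(link)
        verbatim.setdefault(key, []).append(link.synonym)

    reports: List[AmbiguityReport] = []
    for key in sorted(groups):
        resolutions = _sorted_resolutions(
            Resolution(link.official_symbol, link.ensembl_id, link.gene_type)
            for link in groups[key]
            if link.official_symbol is not None and fold(link.official_symbol) != key
        )
        distinct_officials = {fold(r.official_symbol) for r in resolutions}
        if len(distinct_officials) >= min_officials:
            reports.append(
                AmbiguityReport(
                    trigger_symbol=min(verbatim[key]),
                    folded=key,
                    type=AmbiguityType.AMBIGUOUS_SYNONYM,
                    resolutions=resolutions,
                )
            )
    return reports


def assign_combined(
    official_reports: Sequence[AmbiguityReport],
    synonym_reports: Sequence[AmbiguityReport],
) -> None:
    """Mark triggers present in both detector outputs as COMBINED (in place)."""
    official_keys = {r.folded for r in official_reports}
    synonym_keys = {r.folded for r in synonym_reports}
    both = official_keys & synonym_keys
    for r in official_reports:
        if r.folded in both:
            r.type = AmbiguityType.COMBINED
    for r in synonym_reports:
        if r.folded in both:
            r.type = AmbiguityType.COMBINED


def genes_linked_to_ambiguous_symbols(
    official_reports: Sequence[AmbiguityReport],
    synonym_reports: Sequence[AmbiguityReport],
) -> List[Tuple[str, Optional[str]]]:
    """Combined list of every gene reachable through an ambiguous symbol.

    Integrates both detector outputs: for official-symbol triggers the
    trigger's own gene counts (it can be misidentified too), for synonym
    triggers only the resolutions do (the synonym is not itself a gene).
    Deduplicated by folded official symbol + stable ID, sorted.
    """
    seen: Dict[Tuple[str, Optional[str]], Tuple[str, Optional[str]]] = {}
    for r in official_reports:
        seen.setdefault((r.folded, r.trigger_id), (r.trigger_symbol, r.trigger_id))
        for res in r.resolutions:
            key = (fold(res.official_symbol), res.ensembl_id)
            seen.setdefault(key, (res.official_symbol, res.ensembl_id))
    for r in synonym_reports:
        for res in r.resolutions:
            key = (fold(res.official_symbol), res.ensembl_id)
            seen.setdefault(key, (res.official_symbol, res.ensembl_id))
    return sorted(seen.values(), key=lambda t: (fold(t[0]), t[1] or ""))


def merge_with_input_ids(
    reports: Sequence[AmbiguityReport], id_map: Mapping[str, str]
) -> List[AmbiguityReport]:
    """Attach each trigger's own stable ID from the unique-symbol table.

    ``id_map`` maps official symbol to stable ID (built by
    :func:`genesym.summary.summarize`); lookup is by folded symbol.
    Triggers without a match — typically symbols corrupted by an internal
    space — are dropped and logged, mirroring the removal of unpaired
    input/output rows.
    """
    folded_map = {fold(sym): eid for sym, eid in id_map.items()}
    merged: List[AmbiguityReport] = []
    for r in reports:
        eid = folded_map.get(r.folded)
        if eid is None:
            logger.warning(
                "dropping ambiguity report for %r: no stable ID for trigger",
                r.trigger_symbol,
            )
            continue
        merged.append(
            AmbiguityReport(
                trigger_symbol=r.trigger_symbol,
                folded=r.folded,
                type=r.type,
                resolutions=list(r.resolutions),
                cross_type=r.cross_type,
                trigger_id=eid,
            )
        )
    return merged
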