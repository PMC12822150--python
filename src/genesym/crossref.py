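"""Verification of NCBI and nomenclature-committee identifiers.

An annotation view may lack an external ID a gene actually has (a gap in
information exchange between databases), or attach one external ID to two
different official symbols.  Both findings are checked against the
authority's own ("proprietary") export, which is treated as the truth for
the identifiers it assigns.  The module also fills symbols for Ensembl
genes that have a stable ID but no symbol, using cross-database joins and
discarding NCBI ``LOC``-placeholder identifiers, which mark the *absence*
of established nomenclature rather than a symbol.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .ambiguity import fold
from .io import Authority, ExternalIdRecord

__all__ = [
    "ReconciliationStatus",
    "find_missing_ids",
    "find_multiplied_ids",
    "reconcile",
    "is_loc_identifier",
    "SymbollessResolution",
    "resolve_symbolless",
]


class ReconciliationStatus(Enum):
    CONFIRMED_IN_PROPRIETARY = "confirmed"
    REFUTED_IN_PROPRIETARY = "refuted"
    ABSENT_IN_PROPRIETARY = "absent"


class ConfigurationError(ValueError):
    pass


def _id_of(record: ExternalIdRecord, authority: Authority) -> Optional[str]:
    return record.ncbi_id if authority is Authority.NCBI else record.committee_id


def find_missing_ids(
    records: Iterable[ExternalIdRecord], authority: Authority
) -> List[Tuple[Optional[str], Optional[str], Authority]]:
    """Rows lacking the authority's identifier, as (symbol, ensembl_id, authority)."""
    if not isinstance(authority, Authority):
        raise ConfigurationError(f"unknown authority {authority!r}")
    return [
        (r.symbol, r.ensembl_id, authority)
        for r in records
        if _id_of(r, authority) is None
    ]


def find_multiplied_ids(
    records: Iterable[ExternalIdRecord], authority: Authority
) -> Dict[str, List[str]]:
    """External IDs attached to more than one official symbol (verbatim).

    Groups the annotation view by the authority's ID and keeps groups with
    at least two distinct symbols, each mapped to its sorted symbol list.
    """
    if not isinstance(authority, Authority):
        raise ConfigurationError(f"unknown authority {authority!r}")
    groups: Dict[str, set] = {}
    for r in records:
        ext = _id_of(r, authority)
        if ext is not None and r.symbol is not None:
            groups.setdefault(ext, set()).add(r.symbol)
    return {ext: sorted(syms) for ext, syms in sorted(groups.items()) if len(syms) > 1}


def reconcile(
    multiplied_or_missing,
    proprietary: Iterable[ExternalIdRecord],
    authority: Authority,
    *,
    strict_case: bool = False,
) -> Dict:
    """Check questionable ID assignments against the authority's own export.

    For a *multiplied* mapping (``external_id -> symbols``): CONFIRMED when
    the proprietary table also attaches >=2 of those symbols to the ID,
    REFUTED when it attaches exactly one, ABSENT when it does not know the
    ID.  For a *missing* list (``(symbol, ensembl_id, authority)`` tuples):
    REFUTED when the symbol does exist with an ID in the proprietary table
    (the annotation view simply lags), ABSENT otherwise.

    Symbol comparison is case-folded by default, since capitalisation
    conventions differ across databases; ``strict_case`` compares verbatim.
    Idempotent and invariant to proprietary row order.
    """
    norm = (lambda s: s) if strict_case else fold
    prop_by_id: Dict[str, set] = {}
    prop_symbols: Dict[str, set] = {}
    for r in proprietary:
        ext = _id_of(r, authority)
        if r.symbol is not None:
            if ext is not None:
                prop_by_id.setdefault(ext, set()).add(norm(r.symbol))
                prop_symbols.setdefault(norm(r.symbol), set()).add(ext)
            else:
                prop_symbols.setdefault(norm(r.symbol), set())

    statuses: Dict = {}
    if isinstance(multiplied_or_missing, Mapping):
        for ext, symbols in multiplied_or_missing.items():
            ours = {norm(s) for s in symbols}
            theirs = prop_by_id.get(ext)
            if theirs is None:
                statuses[ext] = ReconciliationStatus.ABSENT_IN_PROPRIETARY
            elif len(theirs & ours) >= 2:
                statuses[ext] = ReconciliationStatus.CONFIRMED_IN_PROPRIETARY
            else:
                statuses[ext] = ReconciliationStatus.REFUTED_IN_PROPRIETARY
    else:
        for symbol, ensembl_id, _auth in multiplied_or_missing:
            key = (symbol, ensembl_id)
            ids = prop_symbols.get(norm(symbol)) if symbol is not None else None
            if ids:
                statuses[key] = ReconciliationStatus.REFUTED_IN_PROPRIETARY
            else:
                statuses[key] = ReconciliationStatus.ABSENT_IN_PROPRIETARY
    return statuses


_LOC_PATTERN = re.compile(r"^LOC[0-9]+$")
_ENSEMBL_ID_PATTERN = re.compile(r"^ENS[A-Z]*G[0-9]{6,}$")


def is_loc_identifier(symbol: str) -> bool:
    """True for NCBI placeholder identifiers: ``LOC`` + numeric GeneID."""
    return bool(_LOC_PATTERN.match(symbol))


@dataclass
class SymbollessResolution:
    """Cross-database symbol search result for one symbol-less Ensembl gene."""

    ensembl_id: str
    symbols_found: Dict[Authority, List[str]] = field(default_factory=dict)
    multi_symbol: bool = False  # >1 symbol within a single authority

    @property
    def n_alternative_symbols(self) -> int:
        return len({s for syms in self.symbols_found.values() for s in syms})

    @property
    def resolved(self) -> bool:
        return self.n_alternative_symbols >= 1


def resolve_symbolless(
    symbolless_ids: Sequence[str],
    ensembl_external_ids: Iterable[ExternalIdRecord],
    proprietary_tables: Mapping[Authority, Iterable[ExternalIdRecord]],
) -> Tuple[List[SymbollessResolution], int]:
    """Fill symbols for symbol-less Ensembl genes from alternative databases.

    Joins run in both directions: from the external IDs the annotation view
    attaches to each gene, and from the Ensembl stable IDs the proprietary
    tables carry.  ``LOC`` placeholders never count as symbols, and
    proprietary rows whose "symbol" is actually an Ensembl stable ID are
    screened out.  Returns one resolution per input ID plus the corrected
    symbol-less count (original minus resolved).
    """
    ours: Dict[str, List[ExternalIdRecord]] = {}
    for r in ensembl_external_ids:
        if r.ensembl_id is not None:
            ours.setdefault(r.ensembl_id, []).append(r)

    results: List[SymbollessResolution] = []
    for eid in symbolless_ids:
        res = SymbollessResolution(ensembl_id=eid)
        ext_records = ours.get(eid, [])
        for authority, table in proprietary_tables.items():
            our_ids = {
                _id_of(r, authority) for r in ext_records if _id_of(r, authority)
            }
            found = set()
            for prow in table:
                if prow.symbol is None:
                    continue
                if is_loc_identifier(prow.symbol):
                    continue
                if _ENSEMBL_ID_PATTERN.match(prow.symbol):
                    continue
                joined = prow.ensembl_id == eid or (
                    _id_of(prow, authority) in our_ids if our_ids else False
                )
                if joined:
                    found.add(prow.symbol)
            if found:
                res.symbols_found[authority] = sorted(found)
                if len(found) > 1:
                    res.multi_symbol = True
        results.append(res)

    corrected = len(symbolless_ids) - sum(1 for r in results if r.resolved)
    return results, corrected
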