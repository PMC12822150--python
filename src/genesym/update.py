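"""Offline updating of literature gene-symbol lists to current nomenclature.

A literature symbol may be a current official symbol, an obsolete synonym,
or both at once, and either lookup route alone misses matches.  The updater
therefore runs a *double search* — an official-symbol index and a synonym
index, both case-folded — and unites the hits.  Design points that
distinguish it from naive lookups:

* no perfect-match shortcut: an exact official-symbol hit never suppresses
  synonym hits, so *Cklf* always returns all four candidate genes;
* case-insensitive throughout: *ttr*, *Ttr* and *TTR* match the same gene;
* symbols are treated verbatim otherwise — no whitespace tokenisation, so
  a corrupted symbol with an internal space either matches itself or comes
  back unmatched, never as two spurious genes;
* unmatched inputs are preserved in the output, flagged, never dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import pandas as pd

from .ambiguity import fold
from .io import (
    NA_TOKEN,
    ExternalIdRecord,
    GeneRecord,
    SynonymLink,
    anchor_symbol,
)

__all__ = [
    "Indexes",
    "UpdateResult",
    "build_indexes",
    "update_symbols",
    "attach_annotations",
    "read_input_symbols",
    "write_update_results",
    "INPUT_COLUMN",
]

logger = logging.getLogger(__name__)

INPUT_COLUMN = "Input_gene_symbols"

AS_OFFICIAL = "AS_OFFICIAL"
AS_SYNONYM = "AS_SYNONYM"

Hit = Tuple[str, str]  # (official symbol, ensembl id)


@dataclass
class Indexes:
    """Folded-key lookup tables; payloads keep verbatim symbols."""

    official: Dict[str, Set[Hit]]
    synonym: Dict[str, Set[Hit]]


def build_indexes(
    genes: Iterable[GeneRecord], synonyms: Iterable[SynonymLink]
) -> Indexes:
    """Build the two lookup indexes of the double search."""
    official: Dict[str, Set[Hit]] = {}
    synonym: Dict[str, Set[Hit]] = {}
    for g in genes:
        if g.symbol is not None:
            official.setdefault(fold(g.symbol), set()).add((g.symbol, g.ensembl_id))
    for link in synonyms:
        if link.official_symbol is not None:
            synonym.setdefault(fold(link.synonym), set()).add(
                (link.official_symbol, link.ensembl_id)
            )
    return Indexes(official=official, synonym=synonym)


@dataclass
class UpdateResult:
    """Outcome of the double search for one input symbol."""

    input_symbol: str
    matched_officials: List[Hit] = field(default_factory=list)
    match_route: Set[str] = field(default_factory=set)
    external_ids: Dict[str, Dict[str, Optional[str]]] = field(default_factory=dict)
    descriptions: Dict[str, str] = field(default_factory=dict)

    @property
    def unmatched(self) -> bool:
        return not self.matched_officials

    @property
    def ambiguous(self) -> bool:
        return len({(fold(s), e) for s, e in self.matched_officials}) >= 2


def update_symbols(
    inputs: Sequence[str], indexes: Indexes
) -> List[UpdateResult]:
    """Run the double search for every input symbol, echoing each occurrence.

    Blank inputs are dropped with a log entry; everything else produces a
    result row, matched or not.
    """
    results: List[UpdateResult] = []
    for raw in inputs:
        if raw is None or str(raw) == "":
            logger.warning("dropping blank input row")
            continue
        symbol = str(raw)
        key = fold(symbol)
        official_hits = indexes.official.get(key, set())
        synonym_hits = indexes.synonym.get(key, set())
        route = set()
        if official_hits:
            route.add(AS_OFFICIAL)
        if synonym_hits:
            route.add(AS_SYNONYM)
        merged: Dict[Tuple[str, str], Hit] = {}
        for sym, eid in official_hits | synonym_hits:
            merged.setdefault((fold(sym), eid), (sym, eid))
        matched = sorted(merged.values(), key=lambda h: (fold(h[0]), h[1]))
        results.append(
            UpdateResult(input_symbol=symbol, matched_officials=matched, match_route=route)
        )
    return results


def attach_annotations(
    results: Sequence[UpdateResult],
    external: Iterable[ExternalIdRecord],
    descriptions: Optional[Mapping[str, str]] = None,
) -> List[UpdateResult]:
    """Join NCBI/committee IDs (and optional descriptions) onto matches.

    IDs absent from the external table stay at the missing-value sentinel;
    unmatched results pass through untouched.
    """
    by_id: Dict[str, Dict[str, Optional[str]]] = {}
    for r in external:
        if r.ensembl_id is None:
            continue
        slot = by_id.setdefault(
            r.ensembl_id, {"ncbi_id": None, "committee_id": None, "authority": None}
        )
        if r.ncbi_id is not None:
            slot["ncbi_id"] = r.ncbi_id
        if r.committee_id is not None:
            slot["committee_id"] = r.committee_id
            slot["authority"] = r.authority.value
    for res in results:
        for _sym, eid in res.matched_officials:
            if eid in by_id:
                res.external_ids[eid] = dict(by_id[eid])
            if descriptions and eid in descriptions:
                res.descriptions[eid] = descriptions[eid]
    return list(results)


def read_input_symbols(path: Union[str, Path]) -> List[str]:
    """Read the one-column input contract: a CSV with ``Input_gene_symbols``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if INPUT_COLUMN not in df.columns:
        raise ValueError(f"input file must have a column named {INPUT_COLUMN!r}")
    return [s for s in df[INPUT_COLUMN].tolist()]


def write_update_results(
    results: Sequence[UpdateResult], path: Union[str, Path], *, anchor: bool = True
) -> Path:
    """Write long-format results: one row per input x matched official.

    Unmatched inputs keep their single row with sentinel fields, so the
    output never silently loses an input symbol.
    """
    rows = []
    for res in results:
        base = {
            INPUT_COLUMN: res.input_symbol,
            "Updated_gene_symbol": NA_TOKEN,
            "Gene_stable_ID": NA_TOKEN,
            "Match_route": ";".join(sorted(res.match_route)) or NA_TOKEN,
            "Ambiguous": "yes" if res.ambiguous else "no",
            "Unmatched": "yes" if res.unmatched else "no",
            "NCBI_ID": NA_TOKEN,
            "Committee_ID": NA_TOKEN,
            "Description": NA_TOKEN,
        }
        if anchor:
            base["Anchored_updated_symbol"] = NA_TOKEN
        if res.unmatched:
            rows.append(base)
            continue
        for sym, eid in res.matched_officials:
            row = dict(base)
            row["Updated_gene_symbol"] = sym
            row["Gene_stable_ID"] = eid
            ids = res.external_ids.get(eid, {})
            row["NCBI_ID"] = ids.get("ncbi_id") or NA_TOKEN
            row["Committee_ID"] = ids.get("committee_id") or NA_TOKEN
            row["Description"] = res.descriptions.get(eid, NA_TOKEN)
            if anchor:
                row["Anchored_updated_symbol"] = anchor_symbol(sym)
            rows.append(row)
    columns = [
        INPUT_COLUMN,
        "Updated_gene_symbol",
        "Gene_stable_ID",
        "Match_route",
        "Ambiguous",
        "Unmatched",
        "NCBI_ID",
        "Committee_ID",
        "Description",
    ] + (["Anchored_updated_symbol"] if anchor else [])
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False, lineterminator="\n")
    return Path(path)
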