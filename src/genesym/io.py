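"""Record types and readers/writers for BioMart-dialect annotation tables.

The Ensembl BioMart export dialect is the default: comma- or tab-delimited
text with headers such as ``Gene stable ID``, ``Gene name``, ``Gene Synonym``
and ``Chromosome/scaffold name``.  Proprietary-database exports (NCBI Gene,
MGI marker lists, RGD GENES_RAT, HGNC and VGNC reports) are read through a
column-mapping *dialect* that renames their physical headers onto the same
semantic fields.

Missing values: the literal strings ``NA`` and ``""`` and absent cells are
all read as the single sentinel ``None``; ``NA`` is written on export.
Symbols are stored verbatim — no trimming and no case change happen at I/O
time; comparisons case-fold explicitly downstream (:func:`genesym.ambiguity.fold`).
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "Authority",
    "GenomicLocus",
    "GeneRecord",
    "SynonymLink",
    "ExternalIdRecord",
    "ParseReport",
    "ParsedTable",
    "MalformedSymbolReport",
    "BIOMART_DIALECT",
    "COMMITTEE_COLUMNS",
    "read_annotation_table",
    "write_table",
    "anchor_symbol",
    "strip_anchor",
    "detect_malformed_symbols",
    "load_dialect",
]

#: Canonical missing-value token written on export.
NA_TOKEN = "NA"

OFFICIAL_PREFIX = "Gene_"
SYNONYM_PREFIX = "Gene_synonym_"


class Authority(str, Enum):
    """Identifier-assigning database: NCBI or a nomenclature committee."""

    NCBI = "NCBI"
    MGI = "MGI"
    RGD = "RGD"
    HGNC = "HGNC"
    VGNC = "VGNC"


_COMMITTEE_ID_PATTERNS = {
    Authority.MGI: re.compile(r"^MGI:\d+$"),
    Authority.RGD: re.compile(r"^(RGD:)?\d+$"),
    Authority.HGNC: re.compile(r"^HGNC:\d+$"),
    Authority.VGNC: re.compile(r"^VGNC:\d+$"),
}


@dataclass(frozen=True)
class GenomicLocus:
    """A gene locus in 1-based inclusive coordinates, as BioMart exports them.

    ``strand`` is +1 (forward), -1 (reverse) or ``None`` when unknown;
    unknown strands are excluded from strand-dependent logic downstream.
    """

    region: str
    start: int
    end: int
    strand: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.region:
            raise ValueError("locus region name must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in (None, 1, -1):
            raise ValueError(f"strand must be +1, -1 or None, got {self.strand!r}")


@dataclass(frozen=True)
class GeneRecord:
    """One stable-ID row: Ensembl ID, optional official symbol, type, locus."""

    ensembl_id: str
    symbol: Optional[str] = None
    gene_type: Optional[str] = None
    locus: Optional[GenomicLocus] = None

    def __post_init__(self) -> None:
        if not self.ensembl_id:
            raise ValueError("ensembl_id must be non-empty")
        if self.symbol == "":
            raise ValueError("empty-string symbol; use None for a missing symbol")


@dataclass(frozen=True)
class SynonymLink:
    """A (synonym, official symbol, stable ID) triple from a synonym export.

    ``gene_type`` mirrors the optional ``Gene type`` attribute of the export
    and types the gene the synonym points at; when absent it can be filled
    from a gene table.
    """

    synonym: str
    official_symbol: Optional[str]
    ensembl_id: str
    gene_type: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.synonym:
            raise ValueError("synonym must be non-empty")
        if not self.ensembl_id:
            raise ValueError("ensembl_id must be non-empty")


@dataclass(frozen=True)
class ExternalIdRecord:
    """Cross-reference row carrying NCBI and/or committee identifiers."""

    authority: Authority
    ensembl_id: Optional[str] = None
    symbol: Optional[str] = None
    ncbi_id: Optional[str] = None
    committee_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ensembl_id is None and self.symbol is None:
            raise ValueError("need at least one of ensembl_id / symbol")
        if self.committee_id is not None:
            pat = _COMMITTEE_ID_PATTERNS.get(self.authority)
            if pat is not None and not pat.match(self.committee_id):
                raise ValueError(
                    f"committee_id {self.committee_id!r} does not match the "
                    f"{self.authority.value} convention"
                )


# ---------------------------------------------------------------------------
# Dialects

#: semantic field -> physical header, BioMart export defaults.
BIOMART_DIALECT: Mapping[str, str] = {
    "ensembl_id": "Gene stable ID",
    "symbol": "Gene name",
    "synonym": "Gene Synonym",
    "gene_type": "Gene type",
    "region": "Chromosome/scaffold name",
    "start": "Gene start (bp)",
    "end": "Gene end (bp)",
    "strand": "Strand",
    "ncbi_id": "NCBI gene (formerly Entrezgene) ID",
}

#: committee-ID column per authority in BioMart exports.
COMMITTEE_COLUMNS: Mapping[Authority, str] = {
    Authority.MGI: "MGI ID",
    Authority.RGD: "RGD ID",
    Authority.HGNC: "HGNC ID",
    Authority.VGNC: "VGNC ID",
}

ANCHOR_COLUMN = "Anchored symbol"


class DialectError(ValueError):
    """A requested record kind cannot be built from the columns present."""


def load_dialect(path: Union[str, Path]) -> dict:
    """Load a column-mapping dialect from a YAML or JSON file."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        return dict(yaml.safe_load(text))
    return dict(json.loads(text))


@dataclass
class ParseReport:
    """Row accounting for one table read.

    Invariant: ``rows_in == rows_kept + duplicates_dropped + rows_errored``.
    """

    rows_in: int = 0
    rows_kept: int = 0
    duplicates_dropped: int = 0
    rows_errored: int = 0
    missing_symbols: int = 0
    missing_synonyms: int = 0
    errors: list = field(default_factory=list)  # (row_index, message)


@dataclass
class ParsedTable:
    """All record kinds the table's columns supported, plus the parse report."""

    genes: list
    synonyms: list
    external: list
    report: ParseReport


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def _clean(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value)
    return None if s == "" or s == NA_TOKEN else s


def _parse_strand(raw: Optional[str]) -> Optional[int]:
    if raw is None:
        return None
    v = int(raw)
    if v not in (1, -1):
        raise ValueError(f"strand must be 1 or -1, got {raw!r}")
    return v


def read_annotation_table(
    path: Union[str, Path],
    dialect: Optional[Mapping[str, str]] = None,
    *,
    delimiter: Optional[str] = None,
    authority: Optional[Authority] = None,
    require: Sequence[str] = (),
) -> ParsedTable:
    """Read a delimited annotation table into typed records.

    Parameters
    ----------
    path
        CSV or TSV file; the delimiter is auto-detected (comma vs tab)
        unless ``delimiter`` is given.
    dialect
        Mapping of semantic field names to physical headers; defaults to the
        BioMart export headers.  Proprietary tables supply their own mapping.
    authority
        Force the authority of emitted :class:`ExternalIdRecord` rows, for
        proprietary tables whose committee column is not a BioMart header.
    require
        Record kinds (``"genes"``, ``"synonyms"``, ``"external"``) that must
        be constructible; a missing mandatory column raises
        :class:`DialectError` naming the column.

    Returns a :class:`ParsedTable`; every record kind supported by the
    columns present is populated, exact duplicate rows are collapsed, and the
    parse report accounts for every input row.
    """
    path = Path(path)
    dia = dict(BIOMART_DIALECT)
    if dialect:
        dia.update(dialect)
    sep = delimiter or _sniff_delimiter(path)

    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    present = set(df.columns)

    def col(fieldname: str) -> Optional[str]:
        header = dia.get(fieldname)
        return header if header in present else None

    committee_auth = None
    committee_col = None
    for auth, header in COMMITTEE_COLUMNS.items():
        if header in present:
            committee_auth, committee_col = auth, header
            break
    if "committee_id" in dia and dia["committee_id"] in present:
        committee_col = dia["committee_id"]
        committee_auth = authority or committee_auth

    can_genes = col("ensembl_id") is not None
    can_synonyms = col("synonym") is not None and col("ensembl_id") is not None
    can_external = (col("symbol") is not None or col("ensembl_id") is not None) and (
        col("ncbi_id") is not None or committee_col is not None
    )
    for kind, ok, needed in (
        ("genes", can_genes, dia["ensembl_id"]),
        ("synonyms", can_synonyms, dia["synonym"]),
        ("external", can_external, dia["ncbi_id"]),
    ):
        if kind in require and not ok:
            raise DialectError(f"cannot build {kind!r}: missing column {needed!r}")

    report = ParseReport(rows_in=len(df))

    # collapse exact duplicate rows before record extraction
    deduped = df.drop_duplicates()
    report.duplicates_dropped = len(df) - len(deduped)

    has_locus_cols = col("region") is not None and col("start") is not None

    genes: list = []
    synonyms: list = []
    external: list = []
    ext_auth = authority or committee_auth or Authority.NCBI

    for idx, row in deduped.iterrows():
        try:
            ensembl_id = _clean(row[col("ensembl_id")]) if can_genes else None
            symbol = _clean(row[col("symbol")]) if col("symbol") else None
            gene_type = _clean(row[col("gene_type")]) if col("gene_type") else None

            locus = None
            if has_locus_cols:
                region = _clean(row[col("region")])
                start_raw = _clean(row[col("start")])
                end_raw = _clean(row[col("end")]) if col("end") else None
                if region is not None and start_raw is not None:
                    try:
                        start = int(start_raw)
                        end = int(end_raw) if end_raw is not None else start
                    except ValueError:
                        raise ValueError(
                            f"unparseable coordinate {start_raw!r}/{end_raw!r}"
                        ) from None
                    strand = (
                        _parse_strand(_clean(row[col("strand")]))
                        if col("strand")
                        else None
                    )
                    locus = GenomicLocus(region, start, end, strand)

            if can_genes and ensembl_id is not None:
                if symbol is None:
                    report.missing_symbols += 1
                genes.append(GeneRecord(ensembl_id, symbol, gene_type, locus))

            if can_synonyms:
                syn = _clean(row[col("synonym")])
                if syn is None:
                    report.missing_synonyms += 1
                elif ensembl_id is not None:
                    synonyms.append(SynonymLink(syn, symbol, ensembl_id, gene_type))

            if can_external:
                ncbi = _clean(row[col("ncbi_id")]) if col("ncbi_id") else None
                committee = _clean(row[committee_col]) if committee_col else None
                if ensembl_id is not None or symbol is not None:
                    external.append(
                        ExternalIdRecord(
                            authority=ext_auth,
                            ensembl_id=ensembl_id,
                            symbol=symbol,
                            ncbi_id=ncbi,
                            committee_id=committee,
                        )
                    )
        except ValueError as exc:
            report.rows_errored += 1
            report.errors.append((int(idx), str(exc)))
            continue

    report.rows_kept = len(deduped) - report.rows_errored
    # derived record lists drop duplicates created by projection
    genes = list(dict.fromkeys(genes))
    synonyms = list(dict.fromkeys(synonyms))
    external = list(dict.fromkeys(external))
    return ParsedTable(genes=genes, synonyms=synonyms, external=external, report=report)


# ---------------------------------------------------------------------------
# Writing


def anchor_symbol(symbol: str, kind: str = "official") -> str:
    """Prefix a symbol with an Excel-safe anchor token.

    Spreadsheet software silently converts bare symbols such as ``SEPT4`` or
    ``MARCH1`` to dates; ``Gene_SEPT4`` survives the import.  ``kind`` is
    ``"official"`` (``Gene_`` prefix) or ``"synonym"`` (``Gene_synonym_``).
    """
    if not symbol:
        raise ValueError("cannot anchor an empty symbol")
    if kind == "official":
        return OFFICIAL_PREFIX + symbol
    if kind == "synonym":
        return SYNONYM_PREFIX + symbol
    raise ValueError(f"unknown anchor kind {kind!r}")


def strip_anchor(anchored: str) -> str:
    """Inverse of :func:`anchor_symbol`; returns the verbatim symbol."""
    if anchored.startswith(SYNONYM_PREFIX):
        return anchored[len(SYNONYM_PREFIX):]
    if anchored.startswith(OFFICIAL_PREFIX):
        return anchored[len(OFFICIAL_PREFIX):]
    raise ValueError(f"{anchored!r} carries no anchor prefix")


def _na(value: Optional[object]) -> str:
    return NA_TOKEN if value is None else str(value)


def write_table(
    records: Sequence,
    path: Union[str, Path],
    *,
    anchor: bool = False,
    kind: Optional[str] = None,
    delimiter: str = ",",
) -> Path:
    """Write a homogeneous record collection as a BioMart-dialect table.

    When ``anchor`` is true an extra column holds Excel-safe anchored
    symbols.  ``kind`` ("genes" | "synonyms" | "external") is only needed
    for an empty collection, where it selects the header row; re-reading the
    written file reproduces the records field-for-field.
    """
    path = Path(path)
    records = list(records)
    kinds = {type(r).__name__ for r in records}
    if len(kinds) > 1:
        raise ValueError(f"mixed record kinds: {sorted(kinds)}")
    if records:
        kind = {
            "GeneRecord": "genes",
            "SynonymLink": "synonyms",
            "ExternalIdRecord": "external",
        }[kinds.pop()]
    elif kind is None:
        kind = "genes"

    d = BIOMART_DIALECT
    rows: list[list[str]] = []
    if kind == "genes":
        with_locus = any(r.locus is not None for r in records)
        with_type = any(r.gene_type is not None for r in records)
        header = [d["ensembl_id"], d["symbol"]]
        if with_type:
            header.append(d["gene_type"])
        if with_locus:
            header += [d["region"], d["start"], d["end"], d["strand"]]
        for r in records:
            row = [r.ensembl_id, _na(r.symbol)]
            if with_type:
                row.append(_na(r.gene_type))
            if with_locus:
                loc = r.locus
                row += (
                    [loc.region, str(loc.start), str(loc.end), _na(loc.strand)]
                    if loc
                    else [NA_TOKEN] * 4
                )
            if anchor:
                row.append(anchor_symbol(r.symbol) if r.symbol else NA_TOKEN)
            rows.append(row)
    elif kind == "synonyms":
        with_type = any(r.gene_type is not None for r in records)
        header = [d["synonym"], d["symbol"], d["ensembl_id"]]
        if with_type:
            header.append(d["gene_type"])
        for r in records:
            row = [r.synonym, _na(r.official_symbol), r.ensembl_id]
            if with_type:
                row.append(_na(r.gene_type))
            if anchor:
                row.append(anchor_symbol(r.synonym, "synonym"))
            rows.append(row)
    elif kind == "external":
        auths = {r.authority for r in records}
        committee_header = (
            COMMITTEE_COLUMNS[next(iter(auths))]
            if len(auths) == 1 and next(iter(auths)) in COMMITTEE_COLUMNS
            else None
        )
        header = [d["symbol"], d["ensembl_id"], d["ncbi_id"]]
        if committee_header:
            header.append(committee_header)
        for r in records:
            row = [_na(r.symbol), _na(r.ensembl_id), _na(r.ncbi_id)]
            if committee_header:
                row.append(_na(r.committee_id))
            if anchor:
                row.append(anchor_symbol(r.symbol) if r.symbol else NA_TOKEN)
            rows.append(row)
    else:
        raise ValueError(f"unknown record kind {kind!r}")

    if anchor:
        header = header + [ANCHOR_COLUMN]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)
    return path


# ---------------------------------------------------------------------------
# Malformed symbols


@dataclass
class MalformedSymbolReport:
    """Symbols whose whitespace would break downstream lookups.

    ``internal``: whitespace inside the symbol (an annotation error — a
    symbol like ``Igsf7 l1`` splits into two tokens in naive search tools).
    ``edge``: leading/trailing whitespace only, a distinct trim-variant
    category.  Records are never mutated; symbols flow downstream verbatim.
    """

    internal: list  # (symbol, ensembl_id)
    edge: list  # (symbol, ensembl_id)


_INTERNAL_WS = re.compile(r"\S\s+\S")


def detect_malformed_symbols(records: Iterable[GeneRecord]) -> MalformedSymbolReport:
    """Flag gene symbols containing whitespace, split by where it occurs."""
    internal, edge = [], []
    for r in records:
        if r.symbol is None:
            continue
        if _INTERNAL_WS.search(r.symbol):
            internal.append((r.symbol, r.ensembl_id))
        elif r.symbol != r.symbol.strip():
            edge.append((r.symbol, r.ensembl_id))
    return MalformedSymbolReport(internal=internal, edge=edge)
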