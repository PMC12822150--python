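"""Seeded generator of annotation-table fixtures with known ground truth.

Every structure the toolkit detects — the three ambiguity types, multi-ID
locus categories, symbol-less genes, ``LOC`` placeholders, missing and
multiplied external IDs, case variants, malformed symbols — is planted
deliberately and recorded in a manifest, so detector outputs can be
compared against exact expectations without any database download.

The background emulates a BioMart protein-coding export: one row per
stable ID, symbols unique within the species, roughly twice as many
synonyms as official symbols (the ratio observed in rodent and human gene
sets), arbitrary but internally consistent coordinates.  It does not model
real genome structure or nomenclature history.

Generation is pure: the same (seed, config) yields byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from math import exp
from pathlib import Path
from random import Random
from typing import Dict, List, Mapping, Optional, Tuple, Union

from .ambiguity import fold
from .io import (
    Authority,
    ExternalIdRecord,
    GeneRecord,
    GenomicLocus,
    SynonymLink,
    write_table,
)
from .loci import SPECIES_NAMESPACES, ChromosomeNamespace, LocusCategory

__all__ = ["FixtureConfig", "FixtureManifest", "FixtureBundle", "generate", "preset"]

#: stable-ID prefix, committee authority and committee-ID prefix per species
_SPECIES: Mapping[str, Tuple[str, Authority, str]] = {
    "mouse": ("ENSMUSG", Authority.MGI, "MGI:"),
    "rat": ("ENSRNOG", Authority.RGD, ""),
    "human": ("ENSG", Authority.HGNC, "HGNC:"),
    "pig": ("ENSSSCG", Authority.VGNC, "VGNC:"),
}

_CONSONANTS = "bcdfghklmnprstvz"
_VOWELS = "aeiou"


@dataclass
class FixtureConfig:
    """Knobs for one synthetic annotation table; all counts are planted exactly."""

    n_genes: int = 200
    species: str = "mouse"
    frac_symbolless: float = 0.05
    n_per_locus_category: Mapping[LocusCategory, int] = field(default_factory=dict)
    n_type_a: int = 2
    n_type_b: int = 2
    n_type_c: int = 1
    n_cross_type: int = 1
    synonyms_per_gene_mean: float = 2.0
    frac_missing_ncbi: float = 0.02
    frac_missing_committee: float = 0.01
    n_multiplied_ncbi: int = 1
    n_multiplied_committee: int = 0
    frac_symbolless_resolvable: float = 0.4
    frac_loc_placeholders: float = 0.3
    n_double_symbol: int = 1
    case_noise: float = 0.1
    n_malformed: int = 1
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "frac_symbolless",
            "frac_missing_ncbi",
            "frac_missing_committee",
            "frac_symbolless_resolvable",
            "frac_loc_placeholders",
            "case_noise",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.species not in _SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        n_symbolless = round(self.frac_symbolless * self.n_genes)
        reserved = (
            2 * self.n_type_a
            + 2 * self.n_type_b
            + 3 * self.n_type_c
            + self.n_cross_type
            + sum(self.n_per_locus_category.values())
            + self.n_malformed
        )
        available = self.n_genes - n_symbolless
        if reserved > available:
            raise ValueError(
                f"planted structures need {reserved} symbol-bearing genes but only "
                f"{available} are available (n_genes={self.n_genes}, "
                f"frac_symbolless={self.frac_symbolless})"
            )
        if self.frac_symbolless_resolvable + self.frac_loc_placeholders > 1.0:
            raise ValueError(
                "frac_symbolless_resolvable + frac_loc_placeholders must be <= 1"
            )


@dataclass
class FixtureManifest:
    """Ground truth for every planted structure (folded keys where noted)."""

    species: str
    n_genes_total: int
    expected_symbolless: List[str] = field(default_factory=list)
    expected_multiplied_symbols: Dict[str, List[str]] = field(default_factory=dict)
    expected_locus_category: Dict[str, str] = field(default_factory=dict)
    expected_type_a: Dict[str, List[str]] = field(default_factory=dict)
    expected_type_b: Dict[str, List[str]] = field(default_factory=dict)
    expected_combined: List[str] = field(default_factory=list)
    expected_cross_type: List[str] = field(default_factory=list)
    expected_genes_linked: List[List[Optional[str]]] = field(default_factory=list)
    expected_malformed: List[List[str]] = field(default_factory=list)
    expected_missing_ids: Dict[str, List[List[Optional[str]]]] = field(
        default_factory=dict
    )
    expected_multiplied_ids: Dict[str, Dict[str, List[str]]] = field(
        default_factory=dict
    )
    expected_reconciliation: Dict[str, Dict[str, str]] = field(default_factory=dict)
    expected_resolvable: List[str] = field(default_factory=list)
    expected_multi_symbol: List[str] = field(default_factory=list)
    expected_corrected_symbolless: int = 0

    def check_consistency(self) -> None:
        """Internal cross-checks, e.g. combined triggers exist in both type sets."""
        for key in self.expected_combined:
            if key not in self.expected_type_a or key not in self.expected_type_b:
                raise AssertionError(f"combined trigger {key!r} missing from A or B")
        n_res = len(self.expected_resolvable)
        if self.expected_corrected_symbolless != len(self.expected_symbolless) - n_res:
            raise AssertionError("corrected symbol-less count inconsistent")


@dataclass
class FixtureBundle:
    """In-memory fixture tables plus their ground-truth manifest."""

    genes: List[GeneRecord]
    synonyms: List[SynonymLink]
    external: List[ExternalIdRecord]
    proprietary: Dict[Authority, List[ExternalIdRecord]]
    manifest: FixtureManifest
    species: str
    namespace: ChromosomeNamespace
    config: Optional[FixtureConfig] = None
    inputs: Optional[List[str]] = None

    def write(self, outdir: Union[str, Path]) -> Dict[str, Path]:
        """Emit CSV tables + JSON manifest; returns role -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": write_table(self.genes, outdir / "genes.csv", kind="genes"),
            "synonyms": write_table(
                self.synonyms, outdir / "synonyms.csv", kind="synonyms"
            ),
            "external": write_table(
                self.external, outdir / "external.csv", kind="external"
            ),
        }
        for auth, rows in sorted(self.proprietary.items(), key=lambda kv: kv[0].value):
            paths[f"proprietary_{auth.value}"] = write_table(
                rows, outdir / f"proprietary_{auth.value}.csv", kind="external"
            )
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(
            json.dumps(asdict(self.manifest), indent=1, sort_keys=True) + "\n"
        )
        paths["manifest"] = manifest_path
        if self.inputs is not None:
            input_path = outdir / "InputData.csv"
            input_path.write_text(
                "Input_gene_symbols\n" + "".join(s + "\n" for s in self.inputs)
            )
            paths["inputs"] = input_path
        return paths


# ---------------------------------------------------------------------------
# generation helpers


class _SymbolFactory:
    """Pronounceable, folded-unique symbol strings."""

    def __init__(self, rng: Random, style: str) -> None:
        self.rng = rng
        self.style = style  # "mouse"-style Abc1 vs "human"-style ABC1
        self.used_folded: set = set()

    def _candidate(self, n_syllables: int) -> str:
        s = "".join(
            self.rng.choice(_CONSONANTS) + self.rng.choice(_VOWELS)
            for _ in range(n_syllables)
        )
        if self.rng.random() < 0.7:
            s += str(self.rng.randrange(1, 30))
        return s.upper() if self.style == "human" else s.capitalize()

    def symbol(self, n_syllables: int = 3) -> str:
        while True:
            cand = self._candidate(n_syllables)
            if fold(cand) not in self.used_folded:
                self.used_folded.add(fold(cand))
                return cand

    def synonym(self) -> str:
        # synonyms look like historical shorthands: letters+digits, mixed case
        while True:
            n = self.rng.randrange(3, 9)
            cand = "".join(
                self.rng.choice("abcdefghiklmnoprstuvwxyz0123456789-")
                for _ in range(n)
            )
            if self.rng.random() < 0.5:
                cand = cand.upper()
            if cand[0] in "0123456789-":
                cand = "p" + cand
            if fold(cand) not in self.used_folded:
                self.used_folded.add(fold(cand))
                return cand


def _permute_case(rng: Random, s: str) -> str:
    return "".join(c.upper() if rng.random() < 0.5 else c.lower() for c in s)


def _poisson(rng: Random, mean: float) -> int:
    # Knuth's method; means here are small
    limit = exp(-mean)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def _random_locus(rng: Random, ns: ChromosomeNamespace, region: str = None,
                  strand: int = None) -> GenomicLocus:
    if region is None:
        region = rng.choice(sorted(ns.autosomes))
    start = rng.randrange(100_000, 100_000_000)
    length = rng.randrange(1_000, 100_000)
    return GenomicLocus(region, start, start + length, strand or rng.choice((1, -1)))


def _twin_locus(
    rng: Random, ns: ChromosomeNamespace, host: GenomicLocus, category: LocusCategory,
    scaffold_name: str,
) -> GenomicLocus:
    """Second locus for a multiplied symbol, realising one category."""
    if category is LocusCategory.SCAFFOLD_INVOLVED:
        return _random_locus(rng, ns, region=scaffold_name)
    if category is LocusCategory.DIFFERENT_CHROMOSOMES_AUTOSOMAL:
        other = rng.choice(sorted(ns.autosomes - {host.region}))
        return _random_locus(rng, ns, region=other)
    if category is LocusCategory.SEX_CHROMOSOMES_XY:
        return _random_locus(rng, ns, region="Y")
    if category is LocusCategory.SAME_CHROM_DIFFERENT_STRAND:
        return _random_locus(rng, ns, region=host.region, strand=-host.strand)
    if category is LocusCategory.SAME_CHROM_SAME_START:
        return GenomicLocus(host.region, host.start, host.end + 5_000, host.strand)
    if category is LocusCategory.SAME_CHROM_DIFF_START_OVERLAPPING:
        span = host.end - host.start
        return GenomicLocus(
            host.region, host.start + max(1, span // 2), host.end + 4_000, host.strand
        )
    if category is LocusCategory.SAME_CHROM_DIFF_START_NONOVERLAPPING:
        return GenomicLocus(
            host.region, host.end + 5_000, host.end + 60_000, host.strand
        )
    raise ValueError(category)


def generate(config: FixtureConfig) -> FixtureBundle:
    """Generate one fixture bundle with every planted structure manifested."""
    config.validate()
    rng = Random(config.seed)
    prefix, committee, committee_prefix = _SPECIES[config.species]
    ns = SPECIES_NAMESPACES[config.species]
    factory = _SymbolFactory(rng, "human" if config.species == "human" else "mouse")
    manifest = FixtureManifest(species=config.species, n_genes_total=0)

    next_id = [0]

    def new_id() -> str:
        next_id[0] += 1
        return f"{prefix}{next_id[0]:011d}"

    n_symbolless = round(config.frac_symbolless * config.n_genes)
    n_named = config.n_genes - n_symbolless

    genes: List[GeneRecord] = []
    for _ in range(n_named):
        genes.append(
            GeneRecord(
                ensembl_id=new_id(),
                symbol=factory.symbol(),
                gene_type="protein_coding",
                locus=_random_locus(rng, ns),
            )
        )
    for _ in range(n_symbolless):
        genes.append(
            GeneRecord(
                ensembl_id=new_id(),
                symbol=None,
                gene_type="protein_coding",
                locus=_random_locus(rng, ns),
            )
        )
    manifest.expected_symbolless = [g.ensembl_id for g in genes if g.symbol is None]

    # pool of unreserved symbol-bearing genes; draw structures from the front
    pool = [i for i, g in enumerate(genes) if g.symbol is not None]
    rng.shuffle(pool)

    def take(n: int) -> List[int]:
        out = [pool.pop() for _ in range(n)]
        return out

    # -- malformed symbols (internal whitespace), kept out of other structures
    for i in take(config.n_malformed):
        broken = genes[i].symbol[:-1] + " " + genes[i].symbol[-1]
        factory.used_folded.add(fold(broken))
        genes[i] = GeneRecord(
            genes[i].ensembl_id, broken, genes[i].gene_type, genes[i].locus
        )
        manifest.expected_malformed.append([broken, genes[i].ensembl_id])

    # -- multiplied symbols per locus category
    scaffold_counter = [0]
    for category, count in sorted(
        config.n_per_locus_category.items(), key=lambda kv: kv[0].value
    ):
        for i in take(count):
            host = genes[i]
            if category is LocusCategory.SEX_CHROMOSOMES_XY:
                host = GeneRecord(
                    host.ensembl_id,
                    host.symbol,
                    host.gene_type,
                    _random_locus(rng, ns, region="X"),
                )
                genes[i] = host
            scaffold_counter[0] += 1
            twin = GeneRecord(
                ensembl_id=new_id(),
                symbol=host.symbol,
                gene_type=host.gene_type,
                locus=_twin_locus(
                    rng, ns, host.locus, category,
                    f"SCAFFOLD_{scaffold_counter[0]:04d}",
                ),
            )
            genes.append(twin)
            manifest.expected_multiplied_symbols[host.symbol] = [
                host.ensembl_id, twin.ensembl_id,
            ]
            manifest.expected_locus_category[host.symbol] = category.value

    synonyms: List[SynonymLink] = []

    def plant_synonym(syn: str, target: GeneRecord) -> None:
        if config.case_noise and rng.random() < config.case_noise:
            syn = _permute_case(rng, syn)
        synonyms.append(
            SynonymLink(syn, target.symbol, target.ensembl_id, target.gene_type)
        )

    # -- type A: official symbol of one gene used as synonym of another
    for _ in range(config.n_type_a):
        trig_i, other_i = take(2)
        trig, other = genes[trig_i], genes[other_i]
        plant_synonym(trig.symbol, other)
        manifest.expected_type_a[fold(trig.symbol)] = [fold(other.symbol)]
        manifest.expected_genes_linked += [
            [trig.symbol, trig.ensembl_id], [other.symbol, other.ensembl_id],
        ]

    # -- type B: one synonym string attached to two different genes
    for _ in range(config.n_type_b):
        a_i, b_i = take(2)
        a, b = genes[a_i], genes[b_i]
        syn = factory.synonym()
        plant_synonym(syn, a)
        plant_synonym(syn, b)
        manifest.expected_type_b[fold(syn)] = sorted(
            [fold(a.symbol), fold(b.symbol)]
        )
        manifest.expected_genes_linked += [
            [a.symbol, a.ensembl_id], [b.symbol, b.ensembl_id],
        ]

    # -- type C: official symbol that is also a synonym of >=2 other genes
    for _ in range(config.n_type_c):
        trig_i, o1_i, o2_i = take(3)
        trig, o1, o2 = genes[trig_i], genes[o1_i], genes[o2_i]
        plant_synonym(trig.symbol, o1)
        plant_synonym(trig.symbol, o2)
        key = fold(trig.symbol)
        manifest.expected_type_a[key] = sorted([fold(o1.symbol), fold(o2.symbol)])
        manifest.expected_type_b[key] = sorted([fold(o1.symbol), fold(o2.symbol)])
        manifest.expected_combined.append(key)
        manifest.expected_genes_linked += [
            [trig.symbol, trig.ensembl_id],
            [o1.symbol, o1.ensembl_id],
            [o2.symbol, o2.ensembl_id],
        ]

    # -- cross-type: official symbol used as synonym of a non-coding gene
    for _ in range(config.n_cross_type):
        (trig_i,) = take(1)
        trig = genes[trig_i]
        nc = GeneRecord(
            ensembl_id=new_id(),
            symbol=factory.symbol(),
            gene_type="lncRNA",
            locus=_random_locus(rng, ns),
        )
        genes.append(nc)
        plant_synonym(trig.symbol, nc)
        manifest.expected_cross_type.append(fold(trig.symbol))

    # -- background synonyms (fresh unique strings; never ambiguous)
    for g in genes:
        if g.symbol is None or g.gene_type != "protein_coding":
            continue
        for _ in range(_poisson(rng, config.synonyms_per_gene_mean)):
            plant_synonym(factory.synonym(), g)

    # -- external IDs
    ncbi_counter = [100_000]
    committee_counter = [50_000]

    def new_ncbi() -> str:
        ncbi_counter[0] += 1
        return str(ncbi_counter[0])

    def new_committee() -> str:
        committee_counter[0] += 1
        return f"{committee_prefix}{committee_counter[0]}"

    external: List[ExternalIdRecord] = []
    true_ncbi: Dict[str, str] = {}
    true_committee: Dict[str, str] = {}
    for g in genes:
        true_ncbi[g.ensembl_id] = new_ncbi()
        true_committee[g.ensembl_id] = new_committee()

    named = [g for g in genes if g.symbol is not None]
    # multiplied external IDs: pairs of genes sharing one ID in the Ensembl view
    shared_ncbi: Dict[str, str] = {}
    shared_committee: Dict[str, str] = {}
    manifest.expected_multiplied_ids = {Authority.NCBI.value: {}, committee.value: {}}
    pairs_pool = [g for g in named]
    rng.shuffle(pairs_pool)
    for _ in range(config.n_multiplied_ncbi):
        a, b = pairs_pool.pop(), pairs_pool.pop()
        shared_ncbi[b.ensembl_id] = true_ncbi[a.ensembl_id]
        manifest.expected_multiplied_ids[Authority.NCBI.value][
            true_ncbi[a.ensembl_id]
        ] = sorted([a.symbol, b.symbol])
    for _ in range(config.n_multiplied_committee):
        a, b = pairs_pool.pop(), pairs_pool.pop()
        shared_committee[b.ensembl_id] = true_committee[a.ensembl_id]
        manifest.expected_multiplied_ids[committee.value][
            true_committee[a.ensembl_id]
        ] = sorted([a.symbol, b.symbol])

    # missing external IDs in the Ensembl view
    missing_ncbi: set = set()
    missing_committee: set = set()
    manifest.expected_missing_ids = {Authority.NCBI.value: [], committee.value: []}
    multiplied_ids = set(shared_ncbi) | set(shared_committee) | {
        eid for eid in true_ncbi
        if true_ncbi[eid] in manifest.expected_multiplied_ids[Authority.NCBI.value]
    } | {
        eid for eid in true_committee
        if true_committee[eid] in manifest.expected_multiplied_ids[committee.value]
    }
    for g in named:
        if g.ensembl_id in multiplied_ids:
            continue
        if rng.random() < config.frac_missing_ncbi:
            missing_ncbi.add(g.ensembl_id)
            manifest.expected_missing_ids[Authority.NCBI.value].append(
                [g.symbol, g.ensembl_id]
            )
        elif rng.random() < config.frac_missing_committee:
            missing_committee.add(g.ensembl_id)
            manifest.expected_missing_ids[committee.value].append(
                [g.symbol, g.ensembl_id]
            )

    for g in genes:
        eid = g.ensembl_id
        external.append(
            ExternalIdRecord(
                authority=committee,
                ensembl_id=eid,
                symbol=g.symbol,
                ncbi_id=None if eid in missing_ncbi
                else shared_ncbi.get(eid, true_ncbi[eid]),
                committee_id=None if eid in missing_committee
                else shared_committee.get(eid, true_committee[eid]),
            )
        )

    # -- proprietary tables, derived from truth then perturbed
    prop_ncbi: List[ExternalIdRecord] = []
    prop_committee: List[ExternalIdRecord] = []
    manifest.expected_reconciliation = {Authority.NCBI.value: {}, committee.value: {}}

    for g in named:
        eid = g.ensembl_id
        if eid in missing_ncbi:
            # gap in information exchange vs genuinely absent, 50/50
            if rng.random() < 0.5:
                prop_ncbi.append(
                    ExternalIdRecord(
                        authority=Authority.NCBI, ensembl_id=eid,
                        symbol=g.symbol, ncbi_id=true_ncbi[eid],
                    )
                )
                manifest.expected_reconciliation[Authority.NCBI.value][
                    g.symbol
                ] = "refuted"
            else:
                manifest.expected_reconciliation[Authority.NCBI.value][
                    g.symbol
                ] = "absent"
            continue
        # proprietary never repeats the Ensembl-side ID sharing: each gene
        # keeps its own true ID, so every multiplied ID comes back refuted
        prop_ncbi.append(
            ExternalIdRecord(
                authority=Authority.NCBI, ensembl_id=eid,
                symbol=g.symbol, ncbi_id=true_ncbi[eid],
            )
        )
    for ext_id in manifest.expected_multiplied_ids[Authority.NCBI.value]:
        manifest.expected_reconciliation[Authority.NCBI.value][ext_id] = "refuted"

    for g in named:
        eid = g.ensembl_id
        if eid in missing_committee:
            if rng.random() < 0.5:
                prop_committee.append(
                    ExternalIdRecord(
                        authority=committee, ensembl_id=eid,
                        symbol=g.symbol, committee_id=true_committee[eid],
                    )
                )
                manifest.expected_reconciliation[committee.value][g.symbol] = "refuted"
            else:
                manifest.expected_reconciliation[committee.value][g.symbol] = "absent"
            continue
        prop_committee.append(
            ExternalIdRecord(
                authority=committee, ensembl_id=eid,
                symbol=g.symbol, committee_id=true_committee[eid],
            )
        )
    for ext_id in manifest.expected_multiplied_ids[committee.value]:
        manifest.expected_reconciliation[committee.value][ext_id] = "refuted"

    # -- symbol-less resolution rows in the proprietary tables
    n_double_left = config.n_double_symbol
    for eid in manifest.expected_symbolless:
        r = rng.random()
        if r < config.frac_symbolless_resolvable:
            target = prop_ncbi if rng.random() < 0.5 else prop_committee
            auth = Authority.NCBI if target is prop_ncbi else committee
            sym = factory.symbol()
            target.append(
                ExternalIdRecord(
                    authority=auth, ensembl_id=eid, symbol=sym,
                    ncbi_id=true_ncbi[eid] if auth is Authority.NCBI else None,
                    committee_id=(
                        true_committee[eid] if auth is not Authority.NCBI else None
                    ),
                )
            )
            if n_double_left > 0:
                target.append(
                    ExternalIdRecord(
                        authority=auth, ensembl_id=eid, symbol=factory.symbol(),
                        ncbi_id=true_ncbi[eid] if auth is Authority.NCBI else None,
                        committee_id=(
                            true_committee[eid] if auth is not Authority.NCBI else None
                        ),
                    )
                )
                manifest.expected_multi_symbol.append(eid)
                n_double_left -= 1
            manifest.expected_resolvable.append(eid)
        elif r < config.frac_symbolless_resolvable + config.frac_loc_placeholders:
            # a LOC placeholder is not a symbol
            prop_ncbi.append(
                ExternalIdRecord(
                    authority=Authority.NCBI, ensembl_id=eid,
                    symbol=f"LOC{true_ncbi[eid]}", ncbi_id=true_ncbi[eid],
                )
            )
    manifest.expected_corrected_symbolless = len(manifest.expected_symbolless) - len(
        manifest.expected_resolvable
    )

    manifest.n_genes_total = len(genes)
    manifest.expected_genes_linked = sorted(
        {tuple(p) for p in manifest.expected_genes_linked}
    )
    manifest.expected_genes_linked = [list(p) for p in manifest.expected_genes_linked]
    manifest.check_consistency()

    return FixtureBundle(
        genes=genes,
        synonyms=synonyms,
        external=external,
        proprietary={Authority.NCBI: prop_ncbi, committee: prop_committee},
        manifest=manifest,
        species=config.species,
        namespace=ns,
        config=config,
    )


# ---------------------------------------------------------------------------
# hand-built presets reproducing printed worked examples


def _mouse_gene(num: int, symbol: Optional[str], gene_type: str = "protein_coding",
                locus: Optional[GenomicLocus] = None) -> GeneRecord:
    return GeneRecord(f"ENSMUSG{num:011d}", symbol, gene_type, locus)


def _ambiguity_exemplars() -> FixtureBundle:
    """The three mouse ambiguity exemplars: Arg1 (A), RAMP (B), Cklf (C).

    Also carries the ADAM12/Adam12 self-match (must produce no report) and
    the Parp2/Rpph1 protein-vs-ribozyme pair (must route cross-type).
    Integrating the protein-to-protein reports links exactly eight genes.
    """
    g = {
        "Arg1": _mouse_gene(1001, "Arg1"),
        "Tinagl1": _mouse_gene(1002, "Tinagl1"),
        "Zmym2": _mouse_gene(1003, "Zmym2"),
        "Pamr1": _mouse_gene(1004, "Pamr1"),
        "Cklf": _mouse_gene(1005, "Cklf"),
        "Cmtm2a": _mouse_gene(1006, "Cmtm2a"),
        "Klf5": _mouse_gene(1007, "Klf5"),
        "Klf15": _mouse_gene(1008, "Klf15"),
        "Adam12": _mouse_gene(1009, "Adam12"),
        "Parp2": GeneRecord("ENSMUSG00000036023", "Parp2", "protein_coding"),
        "Rpph1": GeneRecord("ENSMUSG00000092837", "Rpph1", "ribozyme"),
    }

    def link(syn: str, target: str) -> SynonymLink:
        t = g[target]
        return SynonymLink(syn, t.symbol, t.ensembl_id, t.gene_type)

    synonyms = [
        link("Arg1", "Tinagl1"),
        link("RAMP", "Zmym2"),
        link("RAMP", "Pamr1"),
        link("Cklf", "Cmtm2a"),
        link("Cklf", "Klf5"),
        link("Cklf", "Klf15"),
        link("ADAM12", "Adam12"),  # self under folding: not ambiguity
        link("Parp2", "Rpph1"),  # cross-type
    ]
    manifest = FixtureManifest(
        species="mouse",
        n_genes_total=len(g),
        expected_type_a={
            "arg1": ["tinagl1"],
            "cklf": ["cmtm2a", "klf15", "klf5"],
        },
        expected_type_b={
            "ramp": ["pamr1", "zmym2"],
            "cklf": ["cmtm2a", "klf15", "klf5"],
        },
        expected_combined=["cklf"],
        expected_cross_type=["parp2"],
        expected_genes_linked=sorted(
            [s, g[s].ensembl_id]
            for s in (
                "Arg1", "Tinagl1", "Zmym2", "Pamr1",
                "Cklf", "Cmtm2a", "Klf5", "Klf15",
            )
        ),
    )
    return FixtureBundle(
        genes=list(g.values()),
        synonyms=synonyms,
        external=[],
        proprietary={},
        manifest=manifest,
        species="mouse",
        namespace=SPECIES_NAMESPACES["mouse"],
    )


def _multiplied_loci() -> FixtureBundle:
    """Multiplied-ID loci with printed coordinates: Gcat, Pakap, TUBB.

    Strands are not printed for these pairs; the Gcat and Pakap twins are
    placed on the same (forward) strand.
    """
    rows = [
        GeneRecord(
            "ENSMUSG00000006378", "Gcat", "protein_coding",
            GenomicLocus("15", 78_915_074, 78_922_553, 1),
        ),
        GeneRecord(
            "ENSMUSG00000116378", "Gcat", "protein_coding",
            GenomicLocus("15", 78_915_101, 78_926_731, 1),
        ),
        GeneRecord(
            "ENSMUSG00000090053", "Pakap", "protein_coding",
            GenomicLocus("4", 57_434_247, 57_712_016, 1),
        ),
        GeneRecord(
            "ENSMUSG00000038729", "Pakap", "protein_coding",
            GenomicLocus("4", 57_717_657, 57_896_984, 1),
        ),
        GeneRecord(
            "ENSG00000196230", "TUBB", "protein_coding",
            GenomicLocus("6", 30_717_435, 30_725_538, 1),
        ),
        GeneRecord(
            "ENSG00000224156", "TUBB", "protein_coding",
            GenomicLocus("HSCHR6_MHC_APD_CTG1", 2_049_704, 2_054_929, 1),
        ),
    ]
    manifest = FixtureManifest(
        species="mouse",
        n_genes_total=len(rows),
        expected_multiplied_symbols={
            "Gcat": ["ENSMUSG00000006378", "ENSMUSG00000116378"],
            "Pakap": ["ENSMUSG00000090053", "ENSMUSG00000038729"],
            "TUBB": ["ENSG00000196230", "ENSG00000224156"],
        },
        expected_locus_category={
            "Gcat": LocusCategory.SAME_CHROM_DIFF_START_OVERLAPPING.value,
            "Pakap": LocusCategory.SAME_CHROM_DIFF_START_NONOVERLAPPING.value,
            "TUBB": LocusCategory.SCAFFOLD_INVOLVED.value,
        },
    )
    return FixtureBundle(
        genes=rows,
        synonyms=[],
        external=[],
        proprietary={},
        manifest=manifest,
        species="mouse",
        namespace=SPECIES_NAMESPACES["mouse"],
    )


def _update_trial() -> FixtureBundle:
    """Trial input list exercising every double-search behaviour at once."""
    exemplars = _ambiguity_exemplars()
    extra = [
        GeneRecord("ENSMUSG00000061808", "Ttr", "protein_coding"),
        _mouse_gene(2001, "Gcat"),
        _mouse_gene(2002, "Erg"),
    ]
    genes = exemplars.genes + extra
    erg = extra[2]
    synonyms = exemplars.synonyms + [
        SynonymLink("D030036I24Rik", erg.symbol, erg.ensembl_id, erg.gene_type),
    ]
    external = [
        ExternalIdRecord(
            authority=Authority.MGI,
            ensembl_id="ENSMUSG00000061808",
            symbol="Ttr",
            ncbi_id="22139",
            committee_id="MGI:98865",
        ),
    ]
    bundle = FixtureBundle(
        genes=genes,
        synonyms=synonyms,
        external=external,
        proprietary={},
        manifest=exemplars.manifest,
        species="mouse",
        namespace=SPECIES_NAMESPACES["mouse"],
        inputs=["Ttr", "Gcat", "D030036I24Rik", "Adam12", "Arg1", "Ramp", "Cklf", "XXXXXX"],
    )
    bundle.manifest.n_genes_total = len(genes)
    return bundle


def _ras_synonyms_rat() -> FixtureBundle:
    """Four obsolete rat Ras symbols that all collapse onto Hras and Nras."""
    hras = GeneRecord("ENSRNOG00000000301", "Hras", "protein_coding")
    nras = GeneRecord("ENSRNOG00000000302", "Nras", "protein_coding")
    synonyms = [
        SynonymLink(syn, g.symbol, g.ensembl_id, g.gene_type)
        for syn in ("c-H-ras", "H-Ras-1", "HRAS1", "p21ras")
        for g in (hras, nras)
    ]
    manifest = FixtureManifest(
        species="rat",
        n_genes_total=2,
        expected_type_b={
            fold(s): ["hras", "nras"]
            for s in ("c-H-ras", "H-Ras-1", "HRAS1", "p21ras")
        },
        expected_genes_linked=[
            ["Hras", hras.ensembl_id], ["Nras", nras.ensembl_id],
        ],
    )
    return FixtureBundle(
        genes=[hras, nras],
        synonyms=synonyms,
        external=[],
        proprietary={},
        manifest=manifest,
        species="rat",
        namespace=SPECIES_NAMESPACES["rat"],
    )


_PRESETS = {
    "ambiguity_exemplars": _ambiguity_exemplars,
    "multiplied_loci": _multiplied_loci,
    "update_trial": _update_trial,
    "ras_synonyms_rat": _ras_synonyms_rat,
}


def preset(name: str) -> FixtureBundle:
    """Hand-built fixture bundles encoding the printed worked examples."""
    try:
        builder = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    return builder()
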