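# Methods

## Data model and I/O conventions

The toolkit consumes delimited text tables in the Ensembl BioMart export
dialect (`Gene stable ID`, `Gene name`, `Gene Synonym`, `Gene type`,
`Chromosome/scaffold name`, `Gene start (bp)`, `Gene end (bp)`, `Strand`,
`NCBI gene (formerly Entrezgene) ID`, committee-ID columns). Proprietary
exports (NCBI Gene, MGI marker lists, RGD GENES_RAT, HGNC and VGNC
reports) are mapped onto the same semantic fields through a YAML/JSON
column dialect; only the reduced view (symbol, external ID, Ensembl ID)
is used.

Missing values: the literal strings `NA` and `""` and absent cells all
read as one sentinel (`None` in memory) and are written back as `NA`.
This tolerates dialect variation while keeping a single canonical missing
marker. Symbols are stored verbatim at I/O time — no trimming, no case
change — because both behaviours matter downstream: detection of corrupted
symbols (an internal space as in *Igsf7 l1*) requires the raw string,
while grouping requires explicit folding. Coordinates are 1-based
inclusive (the Ensembl convention); strand is +1/−1, with unknown strand
permitted and excluded from strand-dependent decisions (a warning is
emitted and strand agreement is assumed for the overlap test).

Parse accounting is conservative by construction:
`rows_in = rows_kept + duplicates_dropped + rows_errored`. Exact duplicate
rows are collapsed before record extraction — synonym exports may repeat a
(synonym, gene) pair across transcripts, and collapsing identical rows is
the only deduplication applied. A row with an unparseable coordinate is
excluded and reported with its row index rather than aborting the read.

## Case folding

All symbol comparison goes through one fold function: plain ASCII
lowercase, locale-independent, idempotent. Unicode case folding is
deliberately avoided — official human/rodent/pig symbols are ASCII, and
locale-sensitive mappings (Turkish dotted/dotless I) would make folding
environment-dependent. Non-ASCII characters pass through unchanged and
are logged at debug level.

## Ambiguity detection

The official-as-synonym detector indexes official symbols by folded key
and scans the synonym table for collisions. Two exclusions prevent
spurious reports: a synonym attached to the trigger gene itself, and a
synonym whose *current* official symbol folds to the same string (the
*ADAM12*/*Adam12* pattern — a past synonym that simply became official).
The ambiguous-synonym detector groups the synonym table by folded synonym
and reports groups with ≥ 2 distinct folded official symbols, with the
same self-exclusion. A trigger caught by both detectors is re-labelled
*combined* post hoc rather than by a third scan.

The protein-coding restriction is a parameter, not a hard-coded filter.
With it active, a report any of whose resolutions has a non-protein-coding
gene type is routed in full to a separate cross-type stream (the
*Parp2*/*Rpph1* case: a protein-coding official symbol that is a synonym
of a ribozyme gene). Resolutions with an unknown gene type are treated as
protein-coding, since absence of annotation is not evidence of another
type. Whether a synonym shared between a protein-coding and a non-coding
gene should count toward type-B ambiguity is genuinely open; the detector
counts it (the link is real), and callers can pre-filter the synonym
table if they want the narrower behaviour.

Integration unions, over both report streams, every (official symbol,
stable ID) pair reachable through an ambiguous symbol: for
official-symbol triggers the trigger's own gene is included (it is
equally liable to misidentification); for synonym triggers only the
resolutions are (the synonym is not a gene). Trigger-side stable IDs are
attached by a folded-key join against the unique-symbol table; triggers
without a match — in practice symbols corrupted by whitespace — are
dropped with a logged warning rather than silently merged.

Determinism: resolution lists are sorted by (folded official symbol,
stable ID) and report lists by folded trigger, so outputs are byte-stable
across runs.

## Locus classification

A symbol with ≥ 2 stable IDs is assigned exactly one category by an
ordered decision list, evaluated in the sequence: any scaffold placement;
more than one chromosome with at least one autosome; placements confined
to distinct sex chromosomes; same chromosome on opposite strands; same
chromosome and identical start positions; otherwise an all-pairs interval
overlap test separating overlapping from non-overlapping duplicates. The
taxonomy rows are disjoint but no precedence is published for symbols
whose ≥ 3 IDs would satisfy several late rules; first-match-wins over
this ordering makes the classification total and order-invariant, and a
symbol receives the earliest applicable category. Two further choices:
equal starts with different ends still count as "same start" (the
category is named by start position alone), and touching intervals
(`a.end == b.start`) overlap, since 1-based inclusive coordinates mean
they share a base. MT is counted as autosomal for the "at least one
autosome" rule by default (`mt_autosomal=False` reverses this).
Chromosome namespaces ship as presets — human 1–22, mouse 1–19, rat
1–20, pig 1–18, each plus X/Y/MT — and any region name outside the
namespace is a scaffold; no pattern matching on scaffold names is
attempted.

## External-ID verification

For a chosen authority, the annotation view is scanned for rows lacking
the authority's ID (missing) and for IDs attached to ≥ 2 distinct
symbols (multiplied). Both findings are then reconciled against the
authority's own export, which is treated as the truth for the IDs it
assigns: a multiplied ID is *confirmed* if the proprietary table also
attaches ≥ 2 of those symbols to it, *refuted* if exactly one, *absent*
if the ID is unknown there; a missing ID is *refuted* when the symbol
exists with an ID in the proprietary table (an information-exchange gap
between databases) and *absent* otherwise. Symbol comparison during
reconciliation is case-folded by default because capitalization
conventions differ across databases; a strict mode compares verbatim.
Conflicting answers from different authorities are reported side by side,
never auto-merged.

Symbol-less Ensembl genes are resolved by joining in both directions —
from the external IDs the annotation view attaches to the gene, and from
Ensembl stable IDs carried by the proprietary tables. `LOC`-prefixed
identifiers (`^LOC[0-9]+$`) are placeholders marking the *absence* of
nomenclature and never count as symbols; proprietary rows whose "symbol"
is itself an Ensembl stable ID are screened out. The corrected
symbol-less count is the original count minus resolved genes, and genes
receiving more than one symbol within a single authority are flagged.

## Symbol updating (double search)

The updater builds two folded-key indexes — official symbols and
synonyms — and unites the hits for each input. Contracts: no
perfect-match shortcut (an exact official hit never suppresses synonym
hits); case-insensitive matching; inputs treated verbatim otherwise (no
whitespace tokenisation); unmatched inputs preserved and flagged;
repeated inputs echoed once per occurrence, since a literature list's
duplicates may be meaningful to the caller. Output is long-format (one
row per input × matched gene) with ambiguity and route flags, plus NCBI
and committee IDs joined on the stable ID. A live-BioMart adapter is out
of scope; the same index-building contract applies to any table source.

## Synthetic fixtures

The generator emulates a per-species BioMart export with planted,
manifest-recorded structures. Defaults: 200 genes, 5 % symbol-less, a
mean of 2 synonyms per gene (mouse/rat/human gene sets carry roughly
twice as many synonyms as official symbols), 2 type-A, 2 type-B, 1
type-C and 1 cross-type ambiguity, one multiplied NCBI ID, 2 % missing
NCBI and 1 % missing committee IDs, 40 % of symbol-less genes resolvable
in a proprietary table with 30 % additional LOC-only placeholders, 10 %
case noise on synonym strings, and one malformed (internal-whitespace)
symbol. Background symbols and synonyms are drawn folded-unique, so no
ambiguity exists except where planted; proprietary tables are derived
from the generator's truth and then perturbed per config so every
reconciliation status is predictable. Coordinates are arbitrary
consistent integers on the species' chromosome namespace — the generator
does not model gene density, nomenclature history, or real assembly
structure, so passing tests demonstrate procedural correctness on
BioMart-shaped data, not robustness to every quirk of a real release.
Generation is pure: identical (seed, config) produces byte-identical
files.

Four hand-built presets encode published worked examples verbatim: the
mouse *Arg1*/*RAMP*/*Cklf* ambiguity structures (with the
*ADAM12*/*Adam12* self-match and the *Parp2*/*Rpph1* cross-type pair),
the *Gcat*/*Pakap*/*TUBB* multiplied-ID loci with their printed
coordinates (strands are not published for these pairs and are set equal,
which the non-overlap/overlap classification requires anyway), the
trial update list (*Ttr*, *Gcat*, *D030036I24Rik*, *Adam12*, *Arg1*,
*Ramp*, *Cklf*, plus the nonsense control *XXXXXX*), and the four rat
Ras synonyms mapping to *Hras*/*Nras*.

## Problem sizes

The test suite and the acceptance script run on deliberately small
instances — fixtures of 40–500 genes, 50 seeds for the recovery and
case-invariance studies, 200-gene fixtures for full-pipeline recovery —
chosen because every operation here is exact set/string manipulation
whose behaviour does not change with scale; the whole suite completes in
a few seconds.

## Known limitations

* The toolkit never adjudicates which gene an ambiguous literature symbol
  "really" meant; it only enumerates the candidates.
* Genome-wide censuses (counts per species per release) depend on the
  specific Ensembl release exported and are out of scope; the package
  computes them for whatever tables it is given.
* Cross-species overlap counts are computed verbatim by default; whether
  published cross-species comparisons folded case is not stated, so both
  modes are exposed.
* Only comma and tab delimiters are auto-detected; other dialects need an
  explicit delimiter.
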