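# genesym

An offline toolkit for disambiguating gene nomenclature in annotation
tables exported from the Ensembl BioMart genome browser (human, mouse, rat
and pig), and for updating gene-symbol lists taken from the literature to
current official nomenclature.

## The problem

Gene symbols are abbreviations of full gene names, and decades of renaming
have left tens of thousands of them in circulation. A single string can be
**ambiguous** in three ways:

* **official-as-synonym (type A)** — the current official symbol of one
  gene is also a recorded synonym of a different gene. Mouse *Arg1* is
  official for arginase-1 *and* a synonym of the gene now called *Tinagl1*
  ("androgen-regulated gene 1").
* **ambiguous synonym (type B)** — one synonym attaches to two or more
  official symbols: *RAMP* can mean *Zmym2* or *Pamr1*.
* **combined (type C)** — both at once: *Cklf* is official for
  chemokine-like factor and a synonym of *Cmtm2a*, *Klf5* and *Klf15*.

A literature list that contains such symbols silently conflates genes.
The toolkit detects all three types from a pair of BioMart-style exports
(gene table + synonym table), integrates them into the set of every gene
reachable through an ambiguous symbol, and cross-checks gene identifiers
(Ensembl stable IDs, NCBI GeneIDs, MGI/RGD/HGNC/VGNC committee IDs)
against the assigning database's own export. Symbols with several stable
Ensembl IDs are classified by genomic localization (scaffold copies,
different chromosomes, X/Y pairs, antisense twins, overlapping or disjoint
readthrough-style duplicates), with interval overlap defined on 1-based
inclusive coordinates: loci *a* and *b* overlap iff
`max(a.start, b.start) <= min(a.end, b.end)`.

All symbol comparison is case-folded (ASCII lowercase), because
capitalization conventions differ between species (*TTR* / *Ttr*) and are
routinely mangled by software; symbols are otherwise treated verbatim —
never trimmed, tokenised, or auto-"corrected". Exported symbol columns can
be anchored (`Gene_Usp9y`, `Gene_synonym_nd1`) so spreadsheet software
cannot convert them to dates.

## Worked example

Update a literature symbol list against a mouse annotation bundle:

```sh
genesym simulate --preset update_trial --out fx
genesym update-symbols --input fx/InputData.csv --genes fx/genes.csv \
    --synonyms fx/synonyms.csv --external fx/external.csv --out upd
```

prints

```
inputs=8 unmatched=1 ambiguous=3
```

and `upd/Final_search_results.csv` begins

```
Input_gene_symbols,Updated_gene_symbol,Gene_stable_ID,Match_route,Ambiguous,Unmatched,NCBI_ID,Committee_ID,...
Ttr,Ttr,ENSMUSG00000061808,AS_OFFICIAL,no,no,22139,MGI:98865,...
D030036I24Rik,Erg,ENSMUSG00000002002,AS_SYNONYM,no,no,NA,NA,...
Arg1,Arg1,ENSMUSG00000001001,AS_OFFICIAL;AS_SYNONYM,yes,no,NA,NA,...
Arg1,Tinagl1,ENSMUSG00000001002,AS_OFFICIAL;AS_SYNONYM,yes,no,NA,NA,...
...
XXXXXX,NA,NA,NA,no,yes,NA,NA,...
```

Reading the output: *Ttr* is already official (matched only through the
official-symbol index, with its NCBI and MGI IDs attached); the obsolete
clone name *D030036I24Rik* updates to *Erg* through the synonym index;
*Arg1* is ambiguous — the double search returns both its own gene and
*Tinagl1*, and **no perfect-match shortcut** hides the alternative; the
nonsense control *XXXXXX* survives as an explicitly unmatched row. One
output row per input × matched gene, so ambiguous inputs expand and
nothing is dropped. Lookups are case-insensitive: `ttr` and `TTR` return
the same rows.

The other stages follow the same file-based pattern: `summary`
(unique / multiplied / symbol-less partition), `loci` (multiplied-symbol
classification), `ambiguity` (type A/B/C detection and gene integration),
`verify-ids` (missing and multiplied external IDs with reconciliation
against the authority's own export) and `resolve-novel` (cross-database
symbol fill for symbol-less genes, excluding `LOC` placeholders).

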