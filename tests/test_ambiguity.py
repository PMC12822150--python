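"""Ambiguity detectors: case folding, the three types, integration."""

import random

import pytest

from genesym.ambiguity import (
    AmbiguityType,
    assign_combined,
    find_ambiguous_official_symbols,
    find_ambiguous_synonyms,
    fold,
    genes_linked_to_ambiguous_symbols,
    merge_with_input_ids,
)
from genesym.io import GeneRecord, SynonymLink


class TestFold:
    def test_examples(self):
        assert fold("ADAM12") == "adam12"
        assert fold("ttr") == "ttr"

    def test_idempotent(self):
        for s in ("Cklf", "c-H-ras", "D030036I24Rik"):
            assert fold(fold(s)) == fold(s)

    def test_random_case_permutations_collide(self):
        rng = random.Random(0)
        for base in ["tinagl1", "hras1", "d030036i24rik"] * 5:
            permuted = "".join(
                c.upper() if rng.random() < 0.5 else c for c in base
            )
            assert fold(permuted) == base

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fold("")


def _pipeline(bundle, protein_coding_only=True):
    off = find_ambiguous_official_symbols(
        bundle.genes, bundle.synonyms, protein_coding_only=protein_coding_only
    )
    syn = find_ambiguous_synonyms(bundle.synonyms)
    assign_combined(off, syn)
    id_map = {g.symbol: g.ensembl_id for g in bundle.genes if g.symbol}
    off = merge_with_input_ids(off, id_map)
    return off, syn


class TestOfficialAsSynonym:
    def test_arg1_maps_to_tinagl1(self, exemplars):
        off, _ = _pipeline(exemplars)
        arg1 = next(r for r in off if r.folded == "arg1")
        assert arg1.type is AmbiguityType.OFFICIAL_AS_SYNONYM
        assert [res.official_symbol for res in arg1.resolutions] == ["Tinagl1"]
        assert not arg1.cross_type

    def test_parp2_routes_cross_type(self, exemplars):
        off, _ = _pipeline(exemplars)
        parp2 = next(r for r in off if r.folded == "parp2")
        assert parp2.cross_type
        assert parp2.resolutions[0].gene_type == "ribozyme"

    def test_adam12_self_match_removed(self, exemplars):
        off, syn = _pipeline(exemplars)
        assert all(r.folded != "adam12" for r in off)
        assert all(r.folded != "adam12" for r in syn)

    def test_cklf_combined_with_three_resolutions(self, exemplars):
        off, _ = _pipeline(exemplars)
        cklf = next(r for r in off if r.folded == "cklf")
        assert cklf.type is AmbiguityType.COMBINED
        assert sorted(res.official_symbol for res in cklf.resolutions) == [
            "Cmtm2a",
            "Klf15",
            "Klf5",
        ]


class TestAmbiguousSynonyms:
    def test_ramp_two_officials(self, exemplars):
        _, syn = _pipeline(exemplars)
        ramp = next(r for r in syn if r.folded == "ramp")
        assert ramp.type is AmbiguityType.AMBIGUOUS_SYNONYM
        assert sorted(res.official_symbol for res in ramp.resolutions) == [
            "Pamr1",
            "Zmym2",
        ]

    def test_hras_family_synonyms(self, hras):
        _, syn = _pipeline(hras)
        assert {r.folded for r in syn} == {"c-h-ras", "h-ras-1", "hras1", "p21ras"}
        for r in syn:
            assert sorted(fold(res.official_symbol) for res in r.resolutions) == [
                "hras",
                "nras",
            ]

    def test_single_official_is_not_ambiguous(self):
        links = [SynonymLink("Tt", "Ttr", "E1")]
        assert find_ambiguous_synonyms(links) == []


class TestIntegration:
    def test_exemplars_link_eight_genes(self, exemplars):
        off, syn = _pipeline(exemplars)
        pp = [r for r in off if not r.cross_type]
        linked = genes_linked_to_ambiguous_symbols(pp, syn)
        assert len(linked) == 8
        assert {s for s, _ in linked} == {
            "Arg1", "Tinagl1", "Zmym2", "Pamr1", "Cklf", "Cmtm2a", "Klf5", "Klf15",
        }

    def test_hras_synonyms_collapse_to_two_genes(self, hras):
        off, syn = _pipeline(hras)
        linked = genes_linked_to_ambiguous_symbols(
            [r for r in off if not r.cross_type], syn
        )
        assert len(linked) == 2
        assert {s for s, _ in linked} == {"Hras", "Nras"}

    def test_empty_reports_empty_list(self):
        assert genes_linked_to_ambiguous_symbols([], []) == []

    def test_linked_count_at_least_component_sizes(self, make_bundle):
        b = make_bundle(seed=4)
        off, syn = _pipeline(b)
        pp = [r for r in off if not r.cross_type]
        linked = genes_linked_to_ambiguous_symbols(pp, syn)
        assert len(linked) >= len(pp)
        distinct_b_officials = {
            fold(res.official_symbol) for r in syn for res in r.resolutions
        }
        assert len(linked) >= len(distinct_b_officials)


class TestMergeWithInputIds:
    def test_trigger_id_attached(self, exemplars):
        off = find_ambiguous_official_symbols(exemplars.genes, exemplars.synonyms)
        merged = merge_with_input_ids(off, {"Arg1": "E_arg1", "Cklf": "E_cklf", "Parp2": "E_p"})
        arg1 = next(r for r in merged if r.folded == "arg1")
        assert arg1.trigger_id == "E_arg1"

    def test_unpaired_trigger_dropped_and_logged(self, exemplars, caplog):
        off = find_ambiguous_official_symbols(exemplars.genes, exemplars.synonyms)
        with caplog.at_level("WARNING", logger="genesym.ambiguity"):
            merged = merge_with_input_ids(off, {"Arg1": "E_arg1"})
        assert {r.folded for r in merged} == {"arg1"}
        assert any("no stable ID" in rec.message for rec in caplog.records)

    def test_all_present_count_unchanged(self, make_bundle):
        b = make_bundle(seed=6)
        off = find_ambiguous_official_symbols(b.genes, b.synonyms)
        id_map = {g.symbol: g.ensembl_id for g in b.genes if g.symbol}
        assert len(merge_with_input_ids(off, id_map)) == len(off)


def _brute_force_reports(genes, synonyms):
    """All-pairs folded-string comparison, independent of the indexed path."""
    officials = [(g.symbol, g.ensembl_id) for g in genes if g.symbol]
    type_a = {}
    for sym, eid in officials:
        others = set()
        for link in synonyms:
            if (
                link.official_symbol is not None
                and fold(link.synonym) == fold(sym)
                and link.ensembl_id != eid
                and fold(link.official_symbol) != fold(sym)
            ):
                others.add((fold(link.official_symbol), link.ensembl_id))
        if others:
            type_a[fold(sym)] = others
    type_b = {}
    for link in synonyms:
        key = fold(link.synonym)
        if key in type_b:
            continue
        hits = {
            (fold(l.official_symbol), l.ensembl_id)
            for l in synonyms
            if l.official_symbol is not None
            and fold(l.synonym) == key
            and fold(l.official_symbol) != key
        }
        if len({o for o, _ in hits}) >= 2:
            type_b[key] = hits
    return type_a, type_b


@pytest.mark.parametrize("seed", [0, 13])
def test_detectors_match_brute_force_oracle(make_bundle, seed):
    b = make_bundle(seed=seed, n_genes=120)
    oracle_a, oracle_b = _brute_force_reports(b.genes, b.synonyms)
    off = find_ambiguous_official_symbols(b.genes, b.synonyms)
    syn = find_ambiguous_synonyms(b.synonyms)
    got_a = {
        r.folded: {(fold(res.official_symbol), res.ensembl_id) for res in r.resolutions}
        for r in off
    }
    got_b = {
        r.folded: {(fold(res.official_symbol), res.ensembl_id) for res in r.resolutions}
        for r in syn
    }
    assert got_a == oracle_a
    assert got_b == oracle_b


def _permute_all_case(bundle, seed):
    rng = random.Random(seed)

    def pc(s):
        return "".join(c.upper() if rng.random() < 0.5 else c.lower() for c in s)

    genes = [
        GeneRecord(g.ensembl_id, pc(g.symbol) if g.symbol else None, g.gene_type, g.locus)
        for g in bundle.genes
    ]
    synonyms = [
        SynonymLink(pc(l.synonym), pc(l.official_symbol) if l.official_symbol else None,
                    l.ensembl_id, l.gene_type)
        for l in bundle.synonyms
    ]
    return genes, synonyms


@pytest.mark.parametrize("seed", range(8))
def test_case_fold_invariance_of_detectors(exemplars, make_bundle, seed):
    """Randomly permuting letter case everywhere leaves folded report sets unchanged."""
    for bundle in (exemplars, make_bundle(seed=seed, n_genes=60)):
        base_off = find_ambiguous_official_symbols(bundle.genes, bundle.synonyms)
        base_syn = find_ambiguous_synonyms(bundle.synonyms)
        genes, synonyms = _permute_all_case(bundle, seed)
        perm_off = find_ambiguous_official_symbols(genes, synonyms)
        perm_syn = find_ambiguous_synonyms(synonyms)

        def key_sets(reports):
            return {
                r.folded: {(fold(res.official_symbol), res.ensembl_id) for res in r.resolutions}
                for r in reports
            }

        assert key_sets(perm_off) == key_sets(base_off)
        assert key_sets(perm_syn) == key_sets(base_syn)


@pytest.mark.parametrize("seed", [1, 7])
def test_no_self_ambiguity(make_bundle, seed):
    b = make_bundle(seed=seed, n_genes=80)
    off, syn = _pipeline(b)
    for r in off:
        for res in r.resolutions:
            assert fold(res.official_symbol) != r.folded
            assert res.ensembl_id != r.trigger_id
    for r in syn:
        for res in r.resolutions:
            assert fold(res.official_symbol) != r.folded
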