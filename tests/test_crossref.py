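"""External-ID verification, reconciliation and symbol-less resolution."""

import pytest

from genesym.crossref import (
    ConfigurationError,
    ReconciliationStatus,
    find_missing_ids,
    find_multiplied_ids,
    is_loc_identifier,
    reconcile,
    resolve_symbolless,
)
from genesym.io import Authority, ExternalIdRecord


def rec(symbol, eid, ncbi=None, committee=None, authority=Authority.NCBI):
    return ExternalIdRecord(
        authority=authority, ensembl_id=eid, symbol=symbol,
        ncbi_id=ncbi, committee_id=committee,
    )


class TestMissingIds:
    def test_sentinel_listed_and_present_not(self):
        records = [
            rec("Ttr", "E1", ncbi="22139"),
            rec("Novel1", "E2", ncbi=None),
        ]
        missing = find_missing_ids(records, Authority.NCBI)
        assert missing == [("Novel1", "E2", Authority.NCBI)]

    def test_unknown_authority_rejected(self):
        with pytest.raises(ConfigurationError):
            find_missing_ids([], "NOT_A_DB")

    def test_planted_count_recovered(self, make_bundle):
        b = make_bundle(seed=8, n_genes=300, frac_missing_ncbi=0.05)
        missing = find_missing_ids(b.external, Authority.NCBI)
        expected = b.manifest.expected_missing_ids[Authority.NCBI.value]
        assert sorted((s, e) for s, e, _ in missing) == sorted(map(tuple, expected))


class TestMultipliedIds:
    def test_ccl27_example(self):
        records = [
            rec("Ccl27a", "E1", ncbi="100040048"),
            rec("Ccl27b", "E2", ncbi="100040048"),
            rec("Ttr", "E3", ncbi="22139"),
        ]
        assert find_multiplied_ids(records, Authority.NCBI) == {
            "100040048": ["Ccl27a", "Ccl27b"]
        }

    def test_unique_ids_give_empty_mapping(self):
        records = [rec("A", "E1", ncbi="1"), rec("B", "E2", ncbi="2")]
        assert find_multiplied_ids(records, Authority.NCBI) == {}

    def test_planted_groups_recovered(self, make_bundle):
        b = make_bundle(seed=8, n_multiplied_ncbi=3)
        got = find_multiplied_ids(b.external, Authority.NCBI)
        assert got == b.manifest.expected_multiplied_ids[Authority.NCBI.value]


class TestReconcile:
    def test_multiplied_id_refuted_by_proprietary(self):
        multiplied = {"100040048": ["Ccl27a", "Ccl27b"]}
        proprietary = [rec("Ccl27b", "E2", ncbi="100040048")]
        statuses = reconcile(multiplied, proprietary, Authority.NCBI)
        assert statuses["100040048"] is ReconciliationStatus.REFUTED_IN_PROPRIETARY

    def test_multiplied_id_confirmed_when_proprietary_agrees(self):
        multiplied = {"9": ["A", "B"]}
        proprietary = [rec("A", "E1", ncbi="9"), rec("B", "E2", ncbi="9")]
        statuses = reconcile(multiplied, proprietary, Authority.NCBI)
        assert statuses["9"] is ReconciliationStatus.CONFIRMED_IN_PROPRIETARY

    def test_multiplied_id_absent_when_unknown(self):
        statuses = reconcile({"9": ["A", "B"]}, [rec("C", "E3", ncbi="1")], Authority.NCBI)
        assert statuses["9"] is ReconciliationStatus.ABSENT_IN_PROPRIETARY

    def test_missing_id_refuted_when_symbol_known_elsewhere(self):
        # the symbol exists with an ID in the proprietary table: an
        # information-exchange gap, not a genuinely absent gene
        missing = [("Gm123", "E1", Authority.NCBI)]
        statuses = reconcile(missing, [rec("Gm123", None, ncbi="555")], Authority.NCBI)
        assert statuses[("Gm123", "E1")] is ReconciliationStatus.REFUTED_IN_PROPRIETARY

    def test_missing_id_absent_when_symbol_unknown(self):
        missing = [("Gm123", "E1", Authority.NCBI)]
        statuses = reconcile(missing, [rec("Other", None, ncbi="1")], Authority.NCBI)
        assert statuses[("Gm123", "E1")] is ReconciliationStatus.ABSENT_IN_PROPRIETARY

    def test_case_folded_by_default_strict_on_request(self):
        missing = [("TTR", "E1", Authority.NCBI)]
        prop = [rec("Ttr", None, ncbi="22139")]
        assert (
            reconcile(missing, prop, Authority.NCBI)[("TTR", "E1")]
            is ReconciliationStatus.REFUTED_IN_PROPRIETARY
        )
        assert (
            reconcile(missing, prop, Authority.NCBI, strict_case=True)[("TTR", "E1")]
            is ReconciliationStatus.ABSENT_IN_PROPRIETARY
        )

    def test_idempotent_and_order_invariant(self):
        multiplied = {"9": ["A", "B"], "7": ["C", "D"]}
        prop = [rec("A", "E1", ncbi="9"), rec("C", "E3", ncbi="7"), rec("B", "E2", ncbi="9")]
        first = reconcile(multiplied, prop, Authority.NCBI)
        assert first == reconcile(multiplied, prop, Authority.NCBI)
        assert first == reconcile(multiplied, list(reversed(prop)), Authority.NCBI)

    def test_every_refuted_multiplied_id_has_one_proprietary_symbol(self, make_bundle):
        b = make_bundle(seed=3, n_multiplied_ncbi=4)
        multiplied = find_multiplied_ids(b.external, Authority.NCBI)
        prop = b.proprietary[Authority.NCBI]
        statuses = reconcile(multiplied, prop, Authority.NCBI)
        for ext_id, status in statuses.items():
            if status is ReconciliationStatus.REFUTED_IN_PROPRIETARY:
                prop_symbols = {
                    r.symbol for r in prop
                    if r.ncbi_id == ext_id
                    and r.symbol in set(multiplied[ext_id])
                }
                assert len(prop_symbols) == 1


class TestLocIdentifier:
    @pytest.mark.parametrize(
        "symbol,expected",
        [("LOC100040048", True), ("Ttr", False), ("LOC", False), ("LOC12x", False)],
    )
    def test_pattern(self, symbol, expected):
        assert is_loc_identifier(symbol) is expected


class TestResolveSymbolless:
    def _fixture(self):
        """10 symbol-less genes: 4 resolvable, 1 of them double-symbol, 2 LOC-only."""
        ids = [f"E{i}" for i in range(10)]
        ensembl_side = [rec(None, e, ncbi=str(100 + i)) for i, e in enumerate(ids)]
        prop = [
            rec("Newgene0", "E0", ncbi="100"),
            rec("Newgene1", "E1", ncbi="101"),
            rec("Newgene2", "E2", ncbi="102"),
            rec("Newgene2b", "E2", ncbi="102"),  # double symbol in one authority
            rec("Newgene3", "E3", ncbi="103"),
            rec("LOC104", "E4", ncbi="104"),
            rec("LOC105", "E5", ncbi="105"),
        ]
        return ids, ensembl_side, prop

    def test_planted_accounting(self):
        ids, ensembl_side, prop = self._fixture()
        resolutions, corrected = resolve_symbolless(
            ids, ensembl_side, {Authority.NCBI: prop}
        )
        resolved = [r for r in resolutions if r.resolved]
        assert len(resolved) == 4
        assert corrected == 6
        flagged = [r for r in resolutions if r.multi_symbol]
        assert [r.ensembl_id for r in flagged] == ["E2"]
        assert corrected + len(resolved) == len(ids)

    def test_loc_only_is_not_a_symbol(self):
        resolutions, corrected = resolve_symbolless(
            ["E9"], [rec(None, "E9", ncbi="12345")],
            {Authority.NCBI: [rec("LOC12345", "E9", ncbi="12345")]},
        )
        assert not resolutions[0].resolved and corrected == 1

    def test_ensembl_id_used_as_symbol_screened_out(self):
        resolutions, _ = resolve_symbolless(
            ["E9"], [rec(None, "E9", ncbi="1")],
            {Authority.NCBI: [rec("ENSRNOG00000048771", "E9", ncbi="1")]},
        )
        assert not resolutions[0].resolved

    def test_committee_authority_resolves(self):
        resolutions, corrected = resolve_symbolless(
            ["E9"], [],
            {Authority.VGNC: [rec("NEWPIG1", "E9", committee="VGNC:123",
                                  authority=Authority.VGNC)]},
        )
        assert resolutions[0].resolved
        assert resolutions[0].symbols_found[Authority.VGNC] == ["NEWPIG1"]
        assert corrected == 0

    @pytest.mark.parametrize("seed", [0, 5])
    def test_conservation_on_generated_fixtures(self, make_bundle, seed):
        b = make_bundle(seed=seed, n_genes=250, frac_symbolless=0.2)
        resolutions, corrected = resolve_symbolless(
            b.manifest.expected_symbolless, b.external, b.proprietary
        )
        n_resolved = sum(1 for r in resolutions if r.resolved)
        assert corrected + n_resolved == len(b.manifest.expected_symbolless)
        assert sorted(r.ensembl_id for r in resolutions if r.resolved) == sorted(
            b.manifest.expected_resolvable
        )
        assert corrected == b.manifest.expected_corrected_symbolless
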