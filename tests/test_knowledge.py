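"""Catalog/enzyme/annotation loaders and the packaged fixture."""

import pytest

from lignolink.knowledge import (
    CatalogError,
    builtin_fixture,
    load_compound_catalog,
    load_enzyme_map,
    load_genome_annotation,
)

COMPOUND_HEADER = "id\tname\tsmiles\tpartition\txref\n"


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestCompoundCatalog:
    def test_valid_file_loads_all_rows(self, tmp_path):
        p = write(
            tmp_path,
            "c.tsv",
            COMPOUND_HEADER
            + "a\tA\tCCO\tLDCC\t\n"
            + "b\tB\tCCC\tLDCC\t\n"
            + "c\tC\tOC(=O)C\tPDCC\t\n"
            + "d\tD\tc1ccccc1\tPDCC\t\n"
            + "e\tE\tOc1ccccc1\tLDCC\t\n",
        )
        assert len(load_compound_catalog(p)) == 5

    def test_lenient_drops_bad_smiles_with_warning(self, tmp_path, caplog):
        p = write(
            tmp_path,
            "c.tsv",
            COMPOUND_HEADER
            + "a\tA\tCCO\tLDCC\t\n"
            + "bad\tB\tC1CC\tLDCC\t\n"
            + "c\tC\tCCC\tPDCC\t\n",
        )
        with caplog.at_level("WARNING"):
            records = load_compound_catalog(p, strict=False)
        assert [r.id for r in records] == ["a", "c"]
        assert "bad" in caplog.text

    def test_strict_aborts_with_row_report(self, tmp_path):
        p = write(tmp_path, "c.tsv", COMPOUND_HEADER + "bad\tB\tC1CC\tLDCC\t\n")
        with pytest.raises(CatalogError, match="bad"):
            load_compound_catalog(p)

    def test_duplicate_id_always_fatal(self, tmp_path):
        p = write(
            tmp_path,
            "c.tsv",
            COMPOUND_HEADER + "a\tA\tCCO\tLDCC\t\n" + "a\tA2\tCCC\tLDCC\t\n",
        )
        with pytest.raises(CatalogError, match="duplicate.*'a'"):
            load_compound_catalog(p, strict=False)

    def test_missing_header_column_fatal(self, tmp_path):
        p = write(tmp_path, "c.tsv", "id\tname\tsmiles\na\tA\tCCO\n")
        with pytest.raises(CatalogError, match="partition"):
            load_compound_catalog(p)

    def test_loading_twice_is_pure(self, tmp_path):
        p = write(tmp_path, "c.tsv", COMPOUND_HEADER + "a\tA\tCCO\tLDCC\t\n")
        assert load_compound_catalog(p) == load_compound_catalog(p)


class TestEnzymeMap:
    @pytest.fixture
    def compounds(self, tmp_path):
        p = write(
            tmp_path,
            "c.tsv",
            COMPOUND_HEADER
            + "vanillate\tvanillate\tCOc1cc(ccc1O)C(=O)O\tLDCC\t\n"
            + "tpa\tterephthalic acid\tOC(=O)c1ccc(cc1)C(=O)O\tPDCC\t\n",
        )
        return load_compound_catalog(p)

    def test_single_substrate_resolves(self, tmp_path, compounds):
        p = write(
            tmp_path,
            "e.tsv",
            "id\tname\tec\tko\tsubstrates\n"
            + "vanA\tvanillate monooxygenase\t1.14.13.82\tK03862\tvanillate\n",
        )
        records = load_enzyme_map(p, compounds)
        assert len(records) == 1
        assert records[0].ec == "1.14.13.82"
        assert records[0].substrates == ("vanillate",)

    def test_pdcc_substrate_is_a_resolution_error(self, tmp_path, compounds):
        p = write(
            tmp_path,
            "e.tsv",
            "id\tname\tec\tko\tsubstrates\nweird\tW\t\t\ttpa\n",
        )
        with pytest.raises(CatalogError, match="PDCC"):
            load_enzyme_map(p, compounds)

    def test_empty_ec_and_ko_are_valid(self, tmp_path, compounds):
        p = write(
            tmp_path, "e.tsv", "id\tname\tec\tko\tsubstrates\ne1\tE\t\t\tvanillate\n"
        )
        rec = load_enzyme_map(p, compounds)[0]
        assert rec.ec is None and rec.ko == ()

    def test_zero_resolvable_substrates_dropped_in_lenient_mode(
        self, tmp_path, compounds, caplog
    ):
        p = write(
            tmp_path,
            "e.tsv",
            "id\tname\tec\tko\tsubstrates\n"
            + "ok\tOK\t\t\tvanillate\n"
            + "orphan\tO\t\t\tnothing\n",
        )
        with caplog.at_level("WARNING"):
            records = load_enzyme_map(p, compounds, strict=False)
        assert [r.id for r in records] == ["ok"]
        assert "orphan" in caplog.text


class TestGenomeAnnotation:
    def test_lookup_and_default_zero(self, tmp_path, caplog):
        p = write(
            tmp_path,
            "g.tsv",
            "genome_id\tenzyme_id\tgene_count\nMAG1\tmuconate_cycloisomerase\t2\n",
        )
        ann = load_genome_annotation(p)
        assert ann.count("MAG1", "muconate_cycloisomerase") == 2
        with caplog.at_level("WARNING"):
            assert ann.count("MAG9", "anything") == 0
        assert "defaulting to 0" in caplog.text

    @pytest.mark.parametrize("count,msg", [("-1", "negative"), ("two", "non-integer")])
    def test_bad_counts_rejected(self, tmp_path, count, msg):
        p = write(
            tmp_path, "g.tsv", f"genome_id\tenzyme_id\tgene_count\nMAG1\te1\t{count}\n"
        )
        with pytest.raises(CatalogError, match=msg):
            load_genome_annotation(p)


class TestBuiltinFixture:
    def test_loads_without_validation_errors(self, fixture_data):
        compounds, enzymes, annotation = fixture_data
        assert compounds and enzymes and annotation.genome_ids == ["MAG1", "MAG4", "MAG5"]

    def test_partition_sizes(self, fixture_data):
        compounds, _, _ = fixture_data
        assert sum(c.partition == "PDCC" for c in compounds) >= 5
        assert sum(c.partition == "LDCC" for c in compounds) >= 7

    @pytest.mark.parametrize(
        "enzyme_id,ec",
        [
            ("muconate_cycloisomerase", "5.5.1.1"),
            ("benzoate_12_dioxygenase", "1.14.12.10"),
            ("vanillate_monooxygenase", "1.14.13.82"),
            ("hydroxybenzoate_3_monooxygenase", "1.14.13.2"),
            ("salicylate_1_hydroxylase", "1.14.13.1"),
        ],
    )
    def test_enzyme_commission_anchors(self, fixture_data, enzyme_id, ec):
        _, enzymes, _ = fixture_data
        by_id = {e.id: e for e in enzymes}
        assert by_id[enzyme_id].ec == ec

    def test_referential_integrity(self, fixture_data):
        compounds, enzymes, annotation = fixture_data
        ldcc = {c.id for c in compounds if c.partition == "LDCC"}
        enzyme_ids = {e.id for e in enzymes}
        for e in enzymes:
            assert set(e.substrates) <= ldcc
        for genome in annotation.genome_ids:
            assert set(annotation.counts[genome]) <= enzyme_ids

    def test_fixture_smiles_cross_checked_against_rdkit(self, fixture_data):
        rdkit = pytest.importorskip("rdkit")
        from rdkit import Chem

        compounds, _, _ = fixture_data
        for c in compounds:
            assert Chem.MolFromSmiles(c.smiles) is not None, c.id

    def test_loading_twice_identical(self, fixture_data):
        again = builtin_fixture()
        assert again[0] == fixture_data[0]
        assert again[1] == fixture_data[1]
        assert again[2].counts == fixture_data[2].counts
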