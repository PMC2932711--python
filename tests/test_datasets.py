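import numpy as np
import pytest

from seednet.datasets import (
    ExpressionDataset,
    FormatError,
    SymbolRegistry,
    normalize_symbol,
    read_expression_matrix,
    read_homolog_map,
    read_seed_network,
    write_expression_matrix,
    write_network_sif,
    packaged_homolog_map_path,
    packaged_seed_network_path,
)
from seednet.correlation import CorrelationEdge


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestReadExpressionMatrix:
    def test_round_trip(self, tmp_path):
        text = (
            "gene\tt1\tt2\tt3\tt4\n"
            "a1\t1.5\t2.5\t\t4.0\n"
            "b2\t0.0\t-1.0\t2.0\t3.0\n"
            "c3\t10\t20\t30\t40\n"
        )
        ds = read_expression_matrix(write(tmp_path, "m.tsv", text), "I", "continuous")
        out = tmp_path / "roundtrip.tsv"
        write_expression_matrix(ds, out)
        ds2 = read_expression_matrix(out, "I", "continuous")
        assert ds2.genes == ds.genes
        assert ds2.conditions == ds.conditions
        np.testing.assert_array_equal(ds.values, ds2.values)  # NaN-safe equality

    def test_duplicate_rows_collapse_to_median(self, tmp_path):
        text = (
            "gene\tt1\tt2\tt3\n"
            "GeneA\t1\t2\t3\n"
            "GeneA\t3\t4\t5\n"
        )
        ds = read_expression_matrix(write(tmp_path, "m.tsv", text), "I", "continuous")
        assert ds.genes == ["GeneA"]
        # per-column median of (1,2,3) and (3,4,5), derived by hand
        np.testing.assert_array_equal(ds.row("GeneA"), [2.0, 3.0, 4.0])

    def test_collapse_is_row_order_independent(self, tmp_path):
        rows = ["x\t1\t2\t3", "y\t9\t8\t7", "x\t5\t6\t7", "z\t0\t0\t1"]
        header = "gene\tt1\tt2\tt3"
        d1 = read_expression_matrix(
            write(tmp_path, "a.tsv", "\n".join([header] + rows) + "\n"),
            "I", "continuous")
        d2 = read_expression_matrix(
            write(tmp_path, "b.tsv", "\n".join([header] + rows[::-1]) + "\n"),
            "I", "continuous")
        assert d1.genes == d2.genes
        np.testing.assert_array_equal(d1.values, d2.values)

    def test_header_only_is_valid_empty(self, tmp_path):
        ds = read_expression_matrix(
            write(tmp_path, "m.tsv", "gene\tt1\tt2\n"), "I", "continuous")
        assert ds.n_genes == 0
        assert ds.conditions == ["t1", "t2"]

    def test_non_numeric_cell_names_location(self, tmp_path):
        text = "gene\tt1\tt2\ng1\t1.0\toops\n"
        with pytest.raises(FormatError, match="oops"):
            read_expression_matrix(write(tmp_path, "m.tsv", text), "I", "continuous")

    def test_too_few_condition_columns(self, tmp_path):
        with pytest.raises(FormatError, match="condition"):
            read_expression_matrix(
                write(tmp_path, "m.tsv", "gene\tt1\ng1\t1\n"), "I", "continuous")

    def test_empty_file(self, tmp_path):
        with pytest.raises(FormatError, match="empty"):
            read_expression_matrix(write(tmp_path, "m.tsv", ""), "I", "continuous")

    def test_missing_cells_become_nan(self, tmp_path):
        text = "gene\tt1\tt2\tt3\ng1\t\t2\tNA\n"
        ds = read_expression_matrix(write(tmp_path, "m.tsv", text), "I", "continuous")
        row = ds.row("g1")
        assert np.isnan(row[0]) and row[1] == 2.0 and np.isnan(row[2])

    def test_case_variant_symbols_collapse(self, tmp_path):
        text = "gene\tt1\tt2\nPax6\t1\t2\nPAX6\t3\t4\n"
        ds = read_expression_matrix(write(tmp_path, "m.tsv", text), "I", "continuous")
        assert ds.genes == ["Pax6"]
        np.testing.assert_array_equal(ds.row("Pax6"), [2.0, 3.0])


class TestSymbolNormalization:
    def test_whitespace_and_case(self, registry):
        assert registry.normalize("Pax6") == "Pax6"
        assert registry.normalize("  pax6 ") == "Pax6"

    def test_packaged_synonym(self):
        assert normalize_symbol("Sdccag33") == "Tshz1"

    def test_empty_raises(self, registry):
        with pytest.raises(ValueError):
            registry.normalize("  ")

    def test_idempotent(self, registry):
        for raw in ["Pax6", " six3 ", "Sdccag33", "NOTCH1"]:
            once = registry.normalize(raw)
            assert registry.normalize(once) == once


class TestHomologMap:
    def test_slash_separated_paralogs(self, tmp_path):
        p = write(tmp_path, "h.tsv", "fly_gene\tmouse_genes\nso\tSix1/Six2\n")
        hmap = read_homolog_map(p)
        assert hmap["so"] == {"Six1", "Six2"}

    def test_optix_paralogs(self, tmp_path):
        p = write(tmp_path, "h.tsv", "optix\tSix3/Six6\n")
        hmap = read_homolog_map(p)
        assert hmap["optix"] == {"Six3", "Six6"}

    def test_many_to_one_merges_in_mouse_set(self, tmp_path):
        p = write(tmp_path, "h.tsv", "toy\tPax6\ney\tPax6\n")
        hmap = read_homolog_map(p)
        assert hmap.mouse_symbols() == {"Pax6"}

    def test_empty_mouse_field_is_error(self, tmp_path):
        p = write(tmp_path, "h.tsv", "so\t\n")
        with pytest.raises(FormatError):
            read_homolog_map(p)

    def test_duplicate_fly_rows_merge(self, tmp_path, caplog):
        p = write(tmp_path, "h.tsv", "eya\tEya1\neya\tEya2,Eya3\n")
        hmap = read_homolog_map(p)
        assert hmap["eya"] == {"Eya1", "Eya2", "Eya3"}

    def test_packaged_map_applies_synonyms(self):
        hmap = read_homolog_map(packaged_homolog_map_path())
        assert hmap["tsh"] == {"Tshz1"}
        assert len(hmap.entries) == 18


class TestSeedNetworkSpec:
    def test_read_signs_and_provenance(self, tmp_path):
        p = write(tmp_path, "n.tsv",
                  "gene_a\tgene_b\tsign\nA\tB\t+\nB\tC\t-\tsomething\n")
        spec = read_seed_network(p)
        assert (("A", "B", 1) in spec.fly_edges) and (("B", "C", -1) in spec.fly_edges)
        assert spec.provenance[("B", "C")] == "something"

    def test_packaged_network_is_wellformed(self):
        spec = read_seed_network(packaged_seed_network_path())
        assert len(spec.fly_nodes) == 18
        hmap = read_homolog_map(packaged_homolog_map_path())
        assert all(n in hmap for n in spec.fly_nodes)

    def test_self_edge_rejected(self, tmp_path):
        p = write(tmp_path, "n.tsv", "A\tA\t+\n")
        with pytest.raises(ValueError):
            read_seed_network(p)

    def test_duplicate_pair_rejected(self, tmp_path):
        p = write(tmp_path, "n.tsv", "A\tB\t+\nB\tA\t-\n")
        with pytest.raises(ValueError):
            read_seed_network(p)


class TestWriteNetworkSif:
    def test_positive_and_negative_relations(self, tmp_path):
        edges = [
            CorrelationEdge("Pax6", "Notch1", 0.891, 6, "II"),
            CorrelationEdge("Shh", "Atoh7", -0.922, 6, "IV"),
        ]
        out = tmp_path / "net.sif"
        write_network_sif(edges, out)
        lines = out.read_text().splitlines()
        assert "Notch1 pos Pax6" in lines
        assert "Atoh7 neg Shh" in lines
        scores = (tmp_path / "net.sif.scores.tsv").read_text()
        assert "0.891" in scores and "II" in scores

    def test_empty_edge_list(self, tmp_path):
        out = tmp_path / "net.sif"
        write_network_sif([], out)
        assert out.read_text() == ""
        assert (tmp_path / "net.sif.scores.tsv").read_text() == ""


class TestExpressionDatasetInvariants:
    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            ExpressionDataset("x", "continuous", ["a"], ["t1", "t2"],
                              np.zeros((2, 2)))

    def test_unknown_platform(self):
        with pytest.raises(ValueError):
            ExpressionDataset("x", "sage", ["a"], ["t1", "t2"], np.zeros((1, 2)))
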