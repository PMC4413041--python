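import numpy as np
import pandas as pd
import pytest

from coexshift.expression_io import (
    ExpressionIOError,
    GeneList,
    collapse_probes,
    load_design,
    load_expression,
    load_gene_list,
    subset_to_genes,
)
from conftest import make_matrix


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadExpression:
    def test_tsv_round_trip(self, tmp_path):
        path = write(tmp_path, "m.tsv",
                     "probe\tS1\tS2\tS3\tS4\n"
                     "p1\t1\t2\t3\t4\n"
                     "p2\t5\t6\t7\t8\n"
                     "p3\t9\t10\t11\t12\n")
        pm = load_expression(path, format="tsv")
        assert pm.values.shape == (3, 4)
        assert pm.values.loc["p2", "S3"] == 7
        assert pm.probe_to_gene is None

    def test_series_matrix_with_platform_block(self, tmp_path):
        path = write(tmp_path, "gse.txt",
                     "!Series_title\t\"toy\"\n"
                     "!platform_table_begin\n"
                     "ID\tGENE_SYMBOL\n"
                     "p1\tNPM1\n"
                     "p2\tRPL6\n"
                     "!platform_table_end\n"
                     "!series_matrix_table_begin\n"
                     "\"ID_REF\"\t\"GSM1\"\t\"GSM2\"\t\"GSM3\"\n"
                     "\"p1\"\t1.5\t2.5\t3.5\n"
                     "\"p2\"\t4.0\t5.0\t6.0\n"
                     "!series_matrix_table_end\n")
        pm = load_expression(path, format="series_matrix")
        assert pm.values.shape == (2, 3)
        assert pm.probe_to_gene == {"p1": "NPM1", "p2": "RPL6"}

    def test_non_numeric_cell_names_location(self, tmp_path):
        path = write(tmp_path, "bad.tsv",
                     "probe\tS1\tS2\np1\t1\toops\np2\t3\t4\n")
        with pytest.raises(ExpressionIOError, match=r"p1.*S2|S2.*p1"):
            load_expression(path, format="tsv")

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        path = write(tmp_path, "dup.tsv", "probe\tS1\tS1\np1\t1\t2\n")
        with pytest.raises(ExpressionIOError, match="duplicate sample"):
            load_expression(path, format="tsv")

    def test_missing_file(self, tmp_path):
        with pytest.raises(ExpressionIOError, match="not found"):
            load_expression(tmp_path / "nope.tsv")


class TestCollapseProbes:
    def test_one_probe_per_gene_is_identity(self, tmp_path):
        df = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["p1", "p2"],
                          columns=["S1", "S2"])
        out = collapse_probes(df, {"p1": "A", "p2": "B"})
        np.testing.assert_array_equal(out.to_numpy(), df.to_numpy())
        assert list(out.index) == ["A", "B"]

    def test_two_probe_average(self):
        df = pd.DataFrame([[1, 3, 5], [3, 5, 7]], index=["p1", "p2"],
                          columns=["S1", "S2", "S3"], dtype=float)
        out = collapse_probes(df, {"p1": "G", "p2": "G"})
        np.testing.assert_allclose(out.loc["G"].to_numpy(), [2.0, 4.0, 6.0])

    def test_matches_bruteforce_mean(self, rng):
        probes = [f"p{k}" for k in range(5)]
        gene_of = dict(zip(probes, ["A", "B", "A", "A", "B"]))
        df = pd.DataFrame(rng.normal(size=(5, 4)), index=probes,
                          columns=list("WXYZ"))
        out = collapse_probes(df, gene_of)
        for gene in ("A", "B"):
            members = [p for p in probes if gene_of[p] == gene]
            for col in df.columns:
                expected = sum(df.loc[p, col] for p in members) / len(members)
                assert out.loc[gene, col] == pytest.approx(expected, abs=1e-12)

    def test_idempotent_on_gene_level_matrix(self, rng):
        df = pd.DataFrame(rng.normal(size=(4, 3)), index=list("ABCD"),
                          columns=["S1", "S2", "S3"])
        once = collapse_probes(df, {g: g for g in df.index})
        twice = collapse_probes(once, {g: g for g in once.index})
        pd.testing.assert_frame_equal(once, twice)

    def test_unmapped_and_ambiguous_probes_dropped(self):
        df = pd.DataFrame(np.ones((3, 2)), index=["p1", "p2", "p3"],
                          columns=["S1", "S2"])
        out = collapse_probes(df, {"p1": "A", "p2": "X /// Y"})
        assert list(out.index) == ["A"]

    def test_all_unmapped_is_error(self):
        df = pd.DataFrame(np.ones((2, 2)), index=["p1", "p2"], columns=["S1", "S2"])
        with pytest.raises(ExpressionIOError, match="no probe maps"):
            collapse_probes(df, {})

    def test_missing_values_rejected_by_default(self):
        df = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]], index=["p1", "p2"],
                          columns=["S1", "S2"])
        with pytest.raises(ExpressionIOError, match="missing"):
            collapse_probes(df, {"p1": "A", "p2": "B"})

    def test_group_mean_imputation(self):
        groups = pd.Series({"S1": "disease", "S2": "disease", "S3": "normal",
                            "S4": "normal"})
        df = pd.DataFrame([[1.0, np.nan, 5.0, 7.0]], index=["p1"],
                          columns=["S1", "S2", "S3", "S4"])
        out = collapse_probes(df, {"p1": "A"}, groups=groups, missing="impute")
        assert out.values.loc["A", "S2"] == pytest.approx(1.0)  # disease-group mean

    def test_sample_order_and_groups_preserved(self, random_matrix):
        out = collapse_probes(random_matrix.values,
                              {g: g for g in random_matrix.gene_ids},
                              groups=random_matrix.groups)
        assert out.sample_ids == random_matrix.sample_ids
        assert (out.groups == random_matrix.groups).all()


class TestSubsetToGenes:
    def test_93_of_116_candidates_found(self, rng):
        # synthetic stand-in for a 116-symbol candidate list of which 93
        # appear on the platform
        candidates = [f"CAND{k:03d}" for k in range(116)]
        present = candidates[:93]
        extra = [f"OTHER{k}" for k in range(30)]
        matrix = make_matrix(rng.normal(size=(123, 17)), 9, 8, genes=present + extra)
        res = subset_to_genes(matrix, GeneList(candidates))
        assert res.n_found == 93
        assert res.n_missing == 23
        assert res.matrix.n_genes == 93

    def test_identity_subset_unchanged(self, random_matrix):
        res = subset_to_genes(random_matrix, GeneList(random_matrix.gene_ids))
        pd.testing.assert_frame_equal(res.matrix.values, random_matrix.values)

    def test_disjoint_list_is_error(self, random_matrix):
        with pytest.raises(ExpressionIOError, match="no candidate gene"):
            subset_to_genes(random_matrix, GeneList(["ZZZ1", "ZZZ2"]))

    def test_list_order_preserved_and_case_insensitive(self, rng):
        matrix = make_matrix(rng.normal(size=(3, 6)), 3, 3, genes=["Aaa", "Bbb", "Ccc"])
        res = subset_to_genes(matrix, GeneList(["CCC", "AAA"]))
        assert res.matrix.gene_ids == ["Ccc", "Aaa"]


class TestDesignAndGeneList:
    def test_design_round_trip(self, tmp_path):
        path = write(tmp_path, "design.tsv", "S1\tdisease\nS2\tNormal\n")
        groups = load_design(path)
        assert groups["S2"] == "normal"

    def test_duplicate_design_samples_rejected(self, tmp_path):
        path = write(tmp_path, "design.tsv", "S1\tdisease\nS1\tnormal\n")
        with pytest.raises(ExpressionIOError, match="duplicate"):
            load_design(path)

    def test_gene_list_dedupes_preserving_order(self, tmp_path):
        path = write(tmp_path, "genes.txt", "# comment\nNPM1\nRPL6\nnpm1\nEEF2\n")
        gl = load_gene_list(path)
        assert gl.symbols == ["NPM1", "RPL6", "EEF2"]
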