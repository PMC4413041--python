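import math
from itertools import combinations

import numpy as np
import pytest

from coexshift.classify import classify_pairs
from coexshift.expression_io import GeneList
from coexshift.go_mapping import (
    annotated_pairs,
    bonferroni,
    fisher_one_sided,
    map_all_terms,
    map_term,
    read_annotation,
)
from conftest import make_pc


def fisher_enumeration_oracle(a, b, c, d):
    """Full hypergeometric enumeration of tables with the observed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0
    denom = math.comb(n, c1)
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    return sum(
        math.comb(r1, x) * math.comb(n - r1, c1 - x) for x in range(a, hi + 1)
    ) / denom if a <= hi else 0.0


@pytest.fixture
def toy_classes(rng):
    """Classification over 8 genes (28 pairs) at cutoff 0.5."""
    pc = make_pc(rng.uniform(size=28), rng.uniform(size=28),
                 genes=list("ABCDEFGH"))
    return classify_pairs(pc, 0.5)


class TestAnnotatedPairs:
    def test_five_genes_give_ten_pairs(self):
        assert len(annotated_pairs(list("ABCDE"), GeneList(list("ABCDEFGH")))) == 10

    def test_single_gene_gives_empty(self):
        assert annotated_pairs(["A"], GeneList(list("ABC"))) == set()

    def test_matches_nested_loop_enumeration(self, rng):
        universe = [f"G{k}" for k in range(12)]
        term = list(rng.choice(universe, size=8, replace=False)) + ["NOT_THERE"]
        got = annotated_pairs(term, GeneList(universe))
        present = [g for g in term if g in universe]
        expected = set()
        for x, y in combinations(sorted(present, key=universe.index), 2):
            expected.add((x, y))
        assert got == expected

    def test_case_insensitive_matching(self):
        got = annotated_pairs(["npm1", "RPL6"], GeneList(["NPM1", "Rpl6"]))
        assert got == {("NPM1", "Rpl6")}


class TestMapTerm:
    def test_disjoint_pairs_give_zero_table(self, toy_classes):
        assert map_term({("X", "Y")}, toy_classes) == (0, 0, 0, 0)

    def test_matches_set_intersection_oracle(self, rng, toy_classes):
        genes = toy_classes.pc.genes
        term_pairs = annotated_pairs(list("ABCD"), GeneList(genes))
        a, b, c, d = map_term(term_pairs, toy_classes)
        norm = lambda s: {frozenset(p) for p in s}
        tp = norm(term_pairs)
        assert a == len(tp & norm(toy_classes.disease_specific_strong))
        assert b == len(tp & norm(toy_classes.disease_specific_weak))
        assert c == len(tp & norm(toy_classes.normal_specific_strong))
        assert d == len(tp & norm(toy_classes.normal_specific_weak))

    def test_table_symmetry_holds(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            pc = make_pc(r.uniform(size=45), r.uniform(size=45))
            classes = classify_pairs(pc, r.uniform(0.2, 0.8))
            term_pairs = annotated_pairs(pc.genes[:6], GeneList(pc.genes))
            a, b, c, d = map_term(term_pairs, classes)
            assert a == d and b == c


class TestFisherOneSided:
    def test_zero_observed_a_gives_one(self):
        assert fisher_one_sided(0, 5, 7, 3) == pytest.approx(1.0)

    def test_all_zero_table(self):
        assert fisher_one_sided(0, 0, 0, 0) == 1.0

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(0, 8, size=4)
            assert fisher_one_sided(a, b, c, d) == pytest.approx(
                fisher_enumeration_oracle(a, b, c, d), rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_one_sided(-1, 2, 3, 4)


class TestBonferroni:
    def test_identity_at_m_one(self):
        assert bonferroni(0.3, 1) == 0.3

    def test_uncapped_by_default_capped_on_request(self):
        assert bonferroni(0.193, 18) == pytest.approx(3.474)
        assert bonferroni(0.193, 18, cap_at_1=True) == 1.0

    def test_order_preserving(self, rng):
        ps = rng.uniform(size=30)
        corrected = [bonferroni(p, 12) for p in ps]
        assert list(np.argsort(ps)) == list(np.argsort(corrected))


class TestMapAllTerms:
    def test_composition_matches_manual_pipeline(self, rng, toy_classes):
        annotation = {"t1": {"A", "B", "C"}, "t2": {"D", "E", "F", "G"},
                      "t3": {"A", "H"}}
        results = map_all_terms(annotation, toy_classes)
        assert all(r.m == 3 for r in results)
        universe = GeneList(toy_classes.pc.genes)
        for r in results:
            pairs = annotated_pairs(annotation[r.term], universe)
            a, b, c, d = map_term(pairs, toy_classes)
            assert (r.a, r.b, r.c, r.d) == (a, b, c, d)
            p = fisher_one_sided(a, b, c, d)
            assert r.p == pytest.approx(p)
            assert r.p_corrected == pytest.approx(bonferroni(p, 3))

    def test_single_term_correction_is_identity(self, toy_classes):
        results = map_all_terms({"only": {"A", "B", "C", "D"}}, toy_classes)
        assert len(results) == 1
        assert results[0].m == 1
        assert results[0].p_corrected == pytest.approx(results[0].p)

    def test_terms_without_pairs_excluded_from_m(self, toy_classes):
        results = map_all_terms(
            {"big": {"A", "B", "C"}, "lonely": {"A"}, "absent": {"X", "Y"}},
            toy_classes)
        assert [r.term for r in results] == ["big"]
        assert results[0].m == 1

    def test_empty_annotation_rejected(self, toy_classes):
        with pytest.raises(ValueError):
            map_all_terms({}, toy_classes)

    def test_significance_needs_both_raw_and_corrected(self, toy_classes):
        for r in map_all_terms({"t": set("ABCDE")}, toy_classes):
            assert r.significant == (r.p < 0.05 and r.p_corrected < 0.05)


class TestReadAnnotation:
    def test_gmt_and_two_column_dialects(self, tmp_path):
        gmt = tmp_path / "a.gmt"
        gmt.write_text("term1\tdesc\tA\tB\tC\nterm2\tdesc\tB\tD\n")
        ann = read_annotation(gmt)
        assert ann == {"term1": {"A", "B", "C"}, "term2": {"B", "D"}}
        tsv = tmp_path / "a.tsv"
        tsv.write_text("term1\tA\nterm1\tB\nterm2\tC\n")
        assert read_annotation(tsv) == {"term1": {"A", "B"}, "term2": {"C"}}
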