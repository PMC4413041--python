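"""Mapping annotated gene pairs onto the specificity classes, per GO term.

For each GO term the annotated genes (restricted to the analyzed gene
universe) are paired in all combinations; intersecting those pairs with the
four specificity classes gives the 2x2 table

    a  = mapped disease-specific strong pairs
    b  = mapped disease-specific weak pairs
    c  = mapped normal-specific strong pairs
    d  = mapped normal-specific weak pairs

which is scored with a one-sided Fisher exact test (alternative: *a* larger
than expected under fixed margins, i.e. genes more coexpressed in the
disease group) and Bonferroni-corrected over the terms mapped in the run.
Because disease-specific strong equals normal-specific weak and vice versa,
``a == d`` and ``b == c`` in every table.

Corrected p-values are reported uncapped by default (p * m may exceed 1);
conventional capping at 1 is available via ``cap_at_1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from coexshift.classify import PairClassification
from coexshift.expression_io import GeneList

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass
class TermMappingResult:
    term: str
    a: int
    b: int
    c: int
    d: int
    p: float
    p_corrected: float
    m: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05 and self.p_corrected < 0.05


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """Read a term -> gene-set annotation.

    Accepts GMT (term, description, gene, gene, ...) or a two-column TSV of
    (term, gene); the format is detected per line by column count.
    """
    annotation: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 2:
            term, gene = fields
            annotation.setdefault(term.strip(), set()).add(gene.strip())
        elif len(fields) >= 3:
            term, _desc, *genes = fields
            annotation.setdefault(term.strip(), set()).update(
                g.strip() for g in genes if g.strip()
            )
        else:
            raise ValueError(f"{path}: malformed annotation line: {line!r}")
    if not annotation:
        raise ValueError(f"{path}: empty annotation")
    return annotation


def annotated_pairs(term_genes: Iterable[str], universe: GeneList | Iterable[str]) -> set[Pair]:
    """All unordered pairs among a term's genes present in the gene universe.

    Matching is case-insensitive; pairs are returned in the universe's symbol
    spelling with members ordered by universe position.  Terms with fewer
    than two genes in the universe yield the empty set.
    """
    symbols = list(universe.symbols if isinstance(universe, GeneList) else universe)
    pos = {s.casefold(): k for k, s in enumerate(symbols)}
    present = sorted(
        {pos[g.casefold()] for g in term_genes if g.casefold() in pos}
    )
    return {(symbols[i], symbols[j]) for i, j in combinations(present, 2)}


def _normalize_pair(pair: Pair) -> frozenset:
    return frozenset(s.casefold() for s in pair)


def map_term(term_pairs: set[Pair], classes: PairClassification) -> tuple[int, int, int, int]:
    """Intersect a term's annotated pairs with the four specific classes.

    Returns ``(a, b, c, d)``; unordered matching is symbol-case-insensitive.
    """
    wanted = {_normalize_pair(p) for p in term_pairs}
    a = len(wanted & {_normalize_pair(p) for p in classes.disease_specific_strong})
    b = len(wanted & {_normalize_pair(p) for p in classes.disease_specific_weak})
    c = len(wanted & {_normalize_pair(p) for p in classes.normal_specific_strong})
    d = len(wanted & {_normalize_pair(p) for p in classes.normal_specific_weak})
    return a, b, c, d


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Exact hypergeometric tail ``P(X >= a)`` with all margins fixed;
    the all-zero table returns 1.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def bonferroni(p: float, m: int, cap_at_1: bool = False) -> float:
    """Multiply the raw p by the number of terms tested; uncapped by default."""
    if m < 1:
        raise ValueError("m must be >= 1")
    out = p * m
    return min(1.0, out) if cap_at_1 else out


def map_all_terms(
    annotation: Mapping[str, Iterable[str]],
    classes: PairClassification,
    cap_at_1: bool = False,
) -> list[TermMappingResult]:
    """Score every term with at least one annotated pair in the universe.

    The Bonferroni factor ``m`` is the number of terms actually mapped in
    this run, not the number of terms in the annotation file.  A term whose
    genes yield no pair is skipped and logged.
    """
    if not annotation:
        raise ValueError("empty annotation")
    universe = GeneList(classes.pc.genes)
    per_term: dict[str, tuple[int, int, int, int]] = {}
    for term, genes in annotation.items():
        pairs = annotated_pairs(genes, universe)
        if not pairs:
            logger.info("map_all_terms: term %r has <2 genes in universe, skipped", term)
            continue
        per_term[term] = map_term(pairs, classes)
    m = len(per_term)
    results = []
    for term, (a, b, c, d) in per_term.items():
        p = fisher_one_sided(a, b, c, d)
        results.append(
            TermMappingResult(
                term=term, a=a, b=b, c=c, d=d,
                p=p, p_corrected=bonferroni(p, m, cap_at_1=cap_at_1), m=m,
            )
        )
    results.sort(key=lambda r: (r.p, r.term))
    return results


def results_to_frame(results: list[TermMappingResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "a": [r.a for r in results],
            "b": [r.b for r in results],
            "c": [r.c for r in results],
            "d": [r.d for r in results],
            "p": [r.p for r in results],
            "p_corrected": [r.p_corrected for r in results],
            "significant": [r.significant for r in results],
        }
    )
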