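"""Edge-list export of class-specific coexpression networks.

Writes the intersection of a specificity class with a term's annotated pairs
as a tab-delimited edge list (gene_i, gene_j, c_normal, c_disease), and
optionally as GraphML for graph tools.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd

from coexshift.classify import PairClassification

logger = logging.getLogger(__name__)

_CLASS_MASKS = {
    "disease_specific_strong": "disease_specific_strong_mask",
    "normal_specific_strong": "normal_specific_strong_mask",
    "disease_specific_weak": "disease_specific_weak_mask",
    "normal_specific_weak": "normal_specific_weak_mask",
    "strong_disease": "strong_disease_mask",
    "strong_normal": "strong_normal_mask",
}


def class_edges(
    classes: PairClassification,
    which: str,
    term_pairs: Iterable[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Edges of one specificity class, optionally restricted to a term's
    annotated pairs (unordered, case-insensitive matching)."""
    if which not in _CLASS_MASKS:
        raise ValueError(f"unknown class {which!r}; choose from {sorted(_CLASS_MASKS)}")
    mask = getattr(classes, _CLASS_MASKS[which])
    df = classes.pc.to_frame().loc[mask]
    if term_pairs is not None:
        wanted = {frozenset(s.casefold() for s in p) for p in term_pairs}
        keep = [
            frozenset((a.casefold(), b.casefold())) in wanted
            for a, b in zip(df["gene_i"], df["gene_j"])
        ]
        df = df.loc[keep]
    return df.reset_index(drop=True)


def export_network(
    classes: PairClassification,
    path: str | Path,
    which: str = "disease_specific_strong",
    term_pairs: Iterable[tuple[str, str]] | None = None,
    fmt: str = "tsv",
) -> pd.DataFrame:
    """Write the chosen class's edges to ``path`` (``tsv`` or ``graphml``).

    An empty intersection produces a header-only file and a warning.
    Returns the edge frame.
    """
    edges = class_edges(classes, which, term_pairs=term_pairs)
    path = Path(path)
    if edges.empty:
        logger.warning("export_network: class %r has no edges for this selection", which)
    if fmt == "tsv":
        edges.to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif fmt == "graphml":
        import networkx as nx

        g = nx.Graph()
        for _, row in edges.iterrows():
            g.add_edge(
                row["gene_i"], row["gene_j"],
                c_normal=float(row["c_normal"]), c_disease=float(row["c_disease"]),
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return edges
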