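"""Per-group absolute Pearson coexpression for all unordered gene pairs.

The coexpression level of genes *i* and *j* in group *g* is ``|r|``, the
absolute sample Pearson correlation of their expression profiles across that
group's samples.  Taking the absolute value treats strong negative and strong
positive coexpression alike: both indicate a tight linear relationship.
Correlations are computed strictly within-group, never on pooled samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coexshift.expression_io import GROUP_DISEASE, GROUP_NORMAL, ExpressionMatrix

logger = logging.getLogger(__name__)


class CoexpressionError(ValueError):
    """Raised for inputs on which |r| is undefined or unreliable."""


@dataclass
class PairCoexpression:
    """|r| per unordered gene pair, one vector per group.

    Pairs are ordered lexicographically by gene position in the input matrix
    and stored once with ``i`` before ``j``; this ordering is part of the
    output contract so downstream class memberships are reproducible.
    """

    genes: list[str]
    pair_index: np.ndarray = field(repr=False)  # (n_pairs, 2) int positions, i < j
    c_disease: np.ndarray = field(repr=False)
    c_normal: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        g = len(self.genes)
        expected = g * (g - 1) // 2
        for name, vec in (("c_disease", self.c_disease), ("c_normal", self.c_normal)):
            if len(vec) != expected:
                raise CoexpressionError(
                    f"{name} has {len(vec)} values, expected {expected} for {g} genes"
                )

    @property
    def n_pairs(self) -> int:
        return len(self.c_disease)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [(self.genes[i], self.genes[j]) for i, j in self.pair_index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_i": [self.genes[i] for i, _ in self.pair_index],
                "gene_j": [self.genes[j] for _, j in self.pair_index],
                "c_normal": self.c_normal,
                "c_disease": self.c_disease,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _abs_corr_group(x: np.ndarray, genes: list[str], group: str, zero_var: str) -> np.ndarray:
    """Upper-triangle |r| for one group's genes-by-samples block."""
    if x.shape[1] < 3:
        raise CoexpressionError(
            f"group '{group}' has {x.shape[1]} samples; at least 3 are required"
        )
    sd = x.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        offenders = [genes[k] for k in flat]
        if zero_var == "error":
            raise CoexpressionError(
                f"zero-variance genes in group '{group}': {offenders}"
            )
        logger.warning(
            "assigning |r|=0 for pairs involving zero-variance genes in group '%s': %s",
            group, offenders,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.abs(r)
    if flat.size:
        r[flat, :] = 0.0
        r[:, flat] = 0.0
    iu, ju = np.triu_indices(x.shape[0], k=1)
    vals = r[iu, ju]
    # guard against |r| creeping past 1 by floating error
    return np.clip(vals, 0.0, 1.0)


def pairwise_abs_pearson(matrix: ExpressionMatrix, zero_var: str = "error") -> PairCoexpression:
    """Compute |Pearson r| for every unordered gene pair in each group.

    Parameters
    ----------
    matrix:
        Gene-level expression with a two-group design; each group needs at
        least 3 samples.
    zero_var:
        ``"error"`` (default) raises when a gene is constant within a group,
        since a silent zero would distort the distribution the cutoff is
        computed from; ``"as-zero"`` assigns 0 to its pairs and logs.

    Returns
    -------
    PairCoexpression
        ``g*(g-1)/2`` aligned values per group for ``g`` genes.
    """
    if zero_var not in ("error", "as-zero"):
        raise ValueError(f"zero_var must be 'error' or 'as-zero', got {zero_var!r}")
    genes = matrix.gene_ids
    if len(genes) < 2:
        raise CoexpressionError("need at least 2 genes to form a pair")
    c_d = _abs_corr_group(matrix.group_values(GROUP_DISEASE), genes, GROUP_DISEASE, zero_var)
    c_n = _abs_corr_group(matrix.group_values(GROUP_NORMAL), genes, GROUP_NORMAL, zero_var)
    iu, ju = np.triu_indices(len(genes), k=1)
    return PairCoexpression(
        genes=genes,
        pair_index=np.column_stack([iu, ju]),
        c_disease=c_d,
        c_normal=c_n,
    )


def read_pair_tsv(path) -> PairCoexpression:
    """Rebuild a :class:`PairCoexpression` from the TSV written by
    :meth:`PairCoexpression.to_tsv` (columns gene_i, gene_j, c_normal,
    c_disease, pairs in lexicographic gene order)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_i": str, "gene_j": str})
    genes: list[str] = []
    pos: dict[str, int] = {}
    for g in pd.concat([df["gene_i"], df["gene_j"]]):
        if g not in pos:
            pos[g] = len(genes)
            genes.append(g)
    idx = np.array([[pos[a], pos[b]] for a, b in zip(df["gene_i"], df["gene_j"])])
    order = np.lexsort((idx[:, 1], idx[:, 0]))
    return PairCoexpression(
        genes=genes,
        pair_index=idx[order],
        c_disease=df["c_disease"].to_numpy(dtype=float)[order],
        c_normal=df["c_normal"].to_numpy(dtype=float)[order],
    )
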