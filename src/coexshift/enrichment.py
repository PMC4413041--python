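"""GO-term enrichment with the EASE score and BH false-discovery control.

The EASE score is a conservative variant of the one-sided Fisher exact
enrichment p-value: one gene is removed from the list-term overlap before
computing the hypergeometric upper tail, which penalises terms supported by
very few list genes (an overlap of a single gene scores 1).  Terms are
selected when EASE < 0.05 and Benjamini-Hochberg FDR < 0.05, both strict.

This reproduces the enrichment statistics on a user-supplied annotation and
background so runs are self-contained; the background defaults to all genes
appearing in the annotation.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def ease_score(k, n, K, N):
    """EASE score for ``k`` list hits of a term, list size ``n``, ``K``
    background hits, background size ``N``.

    One-sided Fisher upper tail with the list-hit count reduced by one:
    ``P(X >= k-1)`` for ``X ~ Hypergeom(N, K, n)``; ``k <= 1`` scores 1.
    Accepts scalars or equal-length arrays (broadcast elementwise).
    """
    k = np.asarray(k, dtype=int)
    n = np.asarray(n, dtype=int)
    K = np.asarray(K, dtype=int)
    N = np.asarray(N, dtype=int)
    if np.any(k < 0) or np.any(k > np.minimum(n, K)) or np.any(K > N) or np.any(n > N):
        raise ValueError("inconsistent margins: need 0 <= k <= min(n, K) and n, K <= N")
    # sf(k-2) = P(X >= k-1); the k<=1 branch is the EASE penalty to one
    p = np.where(k <= 1, 1.0, hypergeom.sf(k - 2, N, K, n))
    p = np.minimum(p, 1.0)
    return float(p) if p.ndim == 0 else p


def fisher_enrichment(k, n, K, N):
    """Unmodified one-sided Fisher enrichment tail ``P(X >= k)``; the
    reference point the EASE score is conservative against."""
    k = np.asarray(k, dtype=int)
    p = np.minimum(hypergeom.sf(k - 1, np.asarray(N, int), np.asarray(K, int), np.asarray(n, int)), 1.0)
    return float(p) if p.ndim == 0 else p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, order-preserving)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr: empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    background: Iterable[str] | None = None,
    ease_max: float = 0.05,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Score every annotation term against a query gene list.

    Returns a frame with columns term, k (list hits), n (list size), K
    (background hits), N (background size), ease_p, fdr_q, selected; sorted
    by ease_p.  Symbol matching is case-insensitive.  Genes outside the
    background are ignored for counting.
    """
    if not annotation:
        raise ValueError("empty annotation")
    if background is None:
        background = {g for genes in annotation.values() for g in genes}
    bg = {str(g).casefold() for g in background}
    q = {str(g).casefold() for g in query} & bg
    n = len(q)
    N = len(bg)
    rows = []
    for term, genes in annotation.items():
        term_bg = {str(g).casefold() for g in genes} & bg
        K = len(term_bg)
        if K == 0:
            continue
        k = len(q & term_bg)
        rows.append((term, k, n, K, N, ease_score(k, n, K, N)))
    df = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "ease_p"])
    if df.empty:
        raise ValueError("no annotation term overlaps the background")
    df["fdr_q"] = bh_fdr(df["ease_p"])
    df["selected"] = (df["ease_p"] < ease_max) & (df["fdr_q"] < fdr_max)
    return df.sort_values(["ease_p", "term"], ignore_index=True)


def select_terms(
    results: pd.DataFrame,
    annotation: Mapping[str, Iterable[str]],
    ease_max: float = 0.05,
    fdr_max: float = 0.05,
) -> dict[str, set[str]]:
    """Subset the annotation to terms passing both strict thresholds."""
    keep = results.loc[
        (results["ease_p"] < ease_max) & (results["fdr_q"] < fdr_max), "term"
    ]
    selected = {t: set(annotation[t]) for t in keep if t in annotation}
    if not selected:
        import logging

        logging.getLogger(__name__).warning(
            "select_terms: no term passed EASE < %g and FDR < %g", ease_max, fdr_max
        )
    return selected
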