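"""Gene-pair classification at the disease-specific cutoff.

A pair is *strong* in a group when its coexpression level there is ``>= C``
(the same inequality the survival curve uses, which is what makes the
strong/weak counts consistent with the maximum deviation D).  Crossing the
two per-group labels gives four group-specific classes; by construction the
disease-specific strong pairs are exactly the normal-specific weak pairs and
vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from coexshift.coexpress import PairCoexpression

BOTH_STRONG = "both_strong"
BOTH_WEAK = "both_weak"
DISEASE_SPECIFIC_STRONG = "disease_specific_strong"
NORMAL_SPECIFIC_STRONG = "normal_specific_strong"

CLASS_LABELS = (BOTH_STRONG, BOTH_WEAK, DISEASE_SPECIFIC_STRONG, NORMAL_SPECIFIC_STRONG)


@dataclass
class PairClassification:
    """Strong/weak membership per group and the derived specific classes."""

    pc: PairCoexpression = field(repr=False)
    cutoff: float
    strong_disease_mask: np.ndarray = field(repr=False)
    strong_normal_mask: np.ndarray = field(repr=False)

    # -- per-group strong/weak counts (Table-1-style) -------------------
    @property
    def n_strong_disease(self) -> int:
        return int(self.strong_disease_mask.sum())

    @property
    def n_weak_disease(self) -> int:
        return int((~self.strong_disease_mask).sum())

    @property
    def n_strong_normal(self) -> int:
        return int(self.strong_normal_mask.sum())

    @property
    def n_weak_normal(self) -> int:
        return int((~self.strong_normal_mask).sum())

    # -- the four specific classes --------------------------------------
    @property
    def disease_specific_strong_mask(self) -> np.ndarray:
        return self.strong_disease_mask & ~self.strong_normal_mask

    @property
    def normal_specific_strong_mask(self) -> np.ndarray:
        return self.strong_normal_mask & ~self.strong_disease_mask

    # weak in one group only; equal to the opposite group's specific-strong
    # masks as a consequence of the two-class split, not by construction here
    @property
    def disease_specific_weak_mask(self) -> np.ndarray:
        return ~self.strong_disease_mask & self.strong_normal_mask

    @property
    def normal_specific_weak_mask(self) -> np.ndarray:
        return ~self.strong_normal_mask & self.strong_disease_mask

    def _pairs_of(self, mask: np.ndarray) -> set[tuple[str, str]]:
        genes = self.pc.genes
        return {(genes[i], genes[j]) for i, j in self.pc.pair_index[mask]}

    @property
    def disease_specific_strong(self) -> set[tuple[str, str]]:
        return self._pairs_of(self.disease_specific_strong_mask)

    @property
    def disease_specific_weak(self) -> set[tuple[str, str]]:
        return self._pairs_of(self.disease_specific_weak_mask)

    @property
    def normal_specific_strong(self) -> set[tuple[str, str]]:
        return self._pairs_of(self.normal_specific_strong_mask)

    @property
    def normal_specific_weak(self) -> set[tuple[str, str]]:
        return self._pairs_of(self.normal_specific_weak_mask)

    @property
    def strong_disease(self) -> set[tuple[str, str]]:
        return self._pairs_of(self.strong_disease_mask)

    @property
    def strong_normal(self) -> set[tuple[str, str]]:
        return self._pairs_of(self.strong_normal_mask)

    def class_labels(self) -> np.ndarray:
        """One label per pair: both_strong / both_weak / disease_specific_strong
        / normal_specific_strong."""
        labels = np.where(
            self.strong_disease_mask & self.strong_normal_mask, BOTH_STRONG,
            np.where(
                ~self.strong_disease_mask & ~self.strong_normal_mask, BOTH_WEAK,
                np.where(self.strong_disease_mask, DISEASE_SPECIFIC_STRONG,
                         NORMAL_SPECIFIC_STRONG),
            ),
        )
        return labels

    def class_of(self) -> dict[tuple[str, str], str]:
        genes = self.pc.genes
        labels = self.class_labels()
        return {
            (genes[i], genes[j]): lab
            for (i, j), lab in zip(self.pc.pair_index, labels)
        }

    def to_frame(self) -> pd.DataFrame:
        df = self.pc.to_frame()
        df["class"] = self.class_labels()
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def classify_pairs(pc: PairCoexpression, C: float) -> PairClassification:
    """Partition gene pairs into strong/weak classes per group at cutoff C."""
    if not 0.0 <= C <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {C}")
    return PairClassification(
        pc=pc,
        cutoff=float(C),
        strong_disease_mask=pc.c_disease >= C,
        strong_normal_mask=pc.c_normal >= C,
    )


def strong_proportion_test(
    k_d: int, n_d: int, k_n: int, n_n: int, method: str = "binomial"
) -> float:
    """One-sided test that the disease group's strong-pair proportion exceeds
    the normal group's.

    ``method="binomial"`` (default): exact binomial tail ``P(X >= k_d)`` with
    ``X ~ Binomial(n_d, p0 = k_n/n_n)``, alternative greater.
    ``method="ztest"``: two-proportion z-test (pooled), alternative greater.
    """
    for k, n in ((k_d, n_d), (k_n, n_n)):
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    p0 = k_n / n_n
    if method == "binomial":
        if p0 == 0.0:
            return 0.0 if k_d > 0 else 1.0
        return float(stats.binomtest(k_d, n_d, p0, alternative="greater").pvalue)
    if method == "ztest":
        from statsmodels.stats.proportion import proportions_ztest

        _, p = proportions_ztest([k_d, k_n], [n_d, n_n], alternative="larger")
        return float(p)
    raise ValueError(f"unknown method {method!r}")
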