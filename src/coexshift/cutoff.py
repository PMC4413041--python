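"""Disease-specific cutoff selection via the two-sample KS maximum deviation.

The two groups' coexpression values are summarised by empirical survival
curves ``F_g(t) = Prob(C_g >= t)``.  The maximum deviation

    D = max_t | F_d(t) - F_n(t) |

is the two-sample Kolmogorov-Smirnov statistic, and the threshold ``C``
attaining it is the disease-specific cutoff used to split gene pairs into
strong (``|r| >= C``) and weak (``|r| < C``) coexpression classes.  The
supremum over real thresholds is attained on the pooled multiset of observed
values, which is therefore the candidate grid; when several thresholds attain
D the smallest is returned (the most inclusive strong class), a deterministic
tie-break.

Significance is the classical asymptotic two-sided KS p-value

    p = 2 * sum_{k>=1} (-1)^(k-1) * exp(-2 k^2 lambda^2),
    lambda = sqrt(n*m/(n+m)) * D

with no small-sample correction.  The pair-level values within a group share
genes and are therefore not strictly independent observations; the test
treats them as such, a known approximation of the procedure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from coexshift.coexpress import PairCoexpression

_SERIES_TOL = 1e-30  # truncate the alternating series when terms drop below this
_P_FLOOR = 1e-30


@dataclass
class CutoffResult:
    """Maximum deviation D, cutoff C, asymptotic p and sample sizes."""

    D: float
    C: float
    p_value: float
    n_disease: int
    n_normal: int
    tie_count: int = 1  # thresholds attaining D; >1 means a plateau, smallest returned

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def survival_curve(values, t: float) -> float:
    """Empirical complement-CDF: the proportion of ``values`` >= ``t``."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("survival_curve: empty input")
    return float(np.count_nonzero(values >= t)) / values.size


def deviation_curve(c_disease, c_normal) -> pd.DataFrame:
    """Evaluate both survival curves and their deviation on the pooled grid.

    Returns a frame with columns ``threshold``, ``f_disease``, ``f_normal``,
    ``deviation`` (absolute), sorted by threshold — the data behind a
    deviation-vs-cutoff plot.
    """
    c_d = np.asarray(c_disease, dtype=float)
    c_n = np.asarray(c_normal, dtype=float)
    if c_d.size == 0 or c_n.size == 0:
        raise ValueError("deviation_curve: both groups must be non-empty")
    grid = np.unique(np.concatenate([c_d, c_n]))
    # F(t) = P(X >= t): count of sorted values at or above t
    f_d = 1.0 - np.searchsorted(np.sort(c_d), grid, side="left") / c_d.size
    f_n = 1.0 - np.searchsorted(np.sort(c_n), grid, side="left") / c_n.size
    return pd.DataFrame(
        {
            "threshold": grid,
            "f_disease": f_d,
            "f_normal": f_n,
            "deviation": np.abs(f_d - f_n),
        }
    )


def ks_asymptotic_p(D: float, n: int, m: int) -> float:
    """Two-sided asymptotic KS significance of deviation ``D`` at sizes n, m.

    Alternating-series evaluation of the Kolmogorov distribution tail,
    truncated when terms fall below 1e-30 and clamped to [1e-30, 1].
    """
    if not 0.0 <= D <= 1.0:
        raise ValueError(f"D must be in [0, 1], got {D}")
    if n < 1 or m < 1:
        raise ValueError("sample sizes must be >= 1")
    lam = math.sqrt(n * m / (n + m)) * D
    if lam == 0.0:
        return 1.0
    total = 0.0
    for k in range(1, 100001):
        term = math.exp(-2.0 * k * k * lam * lam)
        if term < _SERIES_TOL:
            break
        total += (-1.0) ** (k - 1) * term
    p = 2.0 * total
    return float(min(1.0, max(p, _P_FLOOR)))


def ks_cutoff(pc: PairCoexpression | None = None, *, c_disease=None, c_normal=None) -> CutoffResult:
    """Locate the disease-specific cutoff at the maximum deviation.

    Accepts either a :class:`PairCoexpression` or explicit per-group value
    vectors.  Degenerate input where every value is identical in both groups
    yields ``D = 0``, ``C`` = that value, ``p = 1``.
    """
    if pc is not None:
        c_disease, c_normal = pc.c_disease, pc.c_normal
    dev = deviation_curve(c_disease, c_normal)
    d_max = float(dev["deviation"].max())
    at_max = dev.index[np.isclose(dev["deviation"], d_max, rtol=0.0, atol=1e-12)]
    c = float(dev.loc[at_max[0], "threshold"])  # grid sorted ascending -> smallest
    n_d = int(np.asarray(c_disease).size)
    n_n = int(np.asarray(c_normal).size)
    return CutoffResult(
        D=d_max,
        C=c,
        p_value=ks_asymptotic_p(d_max, n_d, n_n),
        n_disease=n_d,
        n_normal=n_n,
        tie_count=int(len(at_max)),
    )
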