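"""Model comparison, multiple-testing correction and related summaries.

Nested models are compared by likelihood-ratio test (chi2 = difference
in -2LL, df = difference in parameter count); non-nested pairs with
equal parameter counts (M vs DS) by the difference in AIC.  Families of
repeated tests are corrected with the sequential Bonferroni (Holm)
step-down procedure.  Also provides the Nm conversion (immigrants per
generation) and the Pearson chi-square heterogeneity test used to check
that colour frequencies are homogeneous within a site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import chi2_contingency

__all__ = [
    "ComparisonRecord", "NESTED_PAIRS", "lrt", "delta_aic",
    "sequential_bonferroni", "nm_from_rate", "heterogeneity_test",
]

#: (reduced, full) model pairs with a valid likelihood-ratio test.
#: DS is HA with w_AA = w_colour, w_aa = 1, and FD with b = 0; the
#: constrained FD model is FD with b tied to a.
NESTED_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("DS", "HA"), ("DS", "FD"), ("FDC", "FD"),
)

_LRT_TOL = 1e-6


@dataclass(frozen=True)
class ComparisonRecord:
    """One model-pair comparison, by LRT (nested) or delta AIC."""

    model_a: str
    model_b: str
    neg2LL_a: float
    neg2LL_b: float
    k_a: int
    k_b: int
    statistic: str  # "chi2" | "delta_aic"
    value: float
    df: Optional[int] = None
    p_value: Optional[float] = None
    reject: Optional[bool] = None


def lrt(neg2LL_full: float, neg2LL_reduced: float, df: int
        ) -> Tuple[float, float]:
    """Likelihood-ratio test of a full against a nested reduced model.

    chi2 is the drop in -2LL (clamped at zero against numerical
    jitter); a reduced model fitting better than the full one beyond
    tolerance indicates an upstream optimisation failure and raises.
    """
    if df < 1:
        raise ValueError("df must be at least 1")
    chi2 = neg2LL_reduced - neg2LL_full
    if chi2 < -_LRT_TOL:
        raise ValueError(
            f"reduced model fits better than full by {-chi2:.3g}: "
            "full-model optimisation failed upstream")
    chi2 = max(chi2, 0.0)
    return chi2, float(chi2_dist.sf(chi2, df))


def delta_aic(neg2LL_a: float, k_a: int, neg2LL_b: float, k_b: int) -> float:
    """AIC(A) - AIC(B) with AIC = -2LL + 2k; negative means model B is
    the better (lower-AIC) model."""
    return (neg2LL_a + 2 * k_a) - (neg2LL_b + 2 * k_b)


def sequential_bonferroni(p_values: Sequence[float], alpha: float = 0.05
                          ) -> List[bool]:
    """Holm step-down correction: ordered p_(i) is rejected while
    p_(i) < alpha/(m - i + 1); the first failure stops the procedure.

    Returns per-test decisions in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    reject = np.zeros(m, dtype=bool)
    order = np.argsort(p, kind="stable")
    for i, idx in enumerate(order):
        if p[idx] < alpha / (m - i):
            reject[idx] = True
        else:
            break
    return reject.tolist()


def nm_from_rate(m: float, N: float) -> float:
    """Immigrants per population per generation, Nm = N * m."""
    if not (0.0 <= m <= 1.0):
        raise ValueError("m must lie in [0, 1]")
    if N <= 0:
        raise ValueError("N must be positive")
    return N * m


def heterogeneity_test(counts_a: Sequence[int], counts_b: Sequence[int]
                       ) -> Tuple[float, int, float]:
    """Pearson chi-square test of homogeneity between two samples over
    the same phenotype categories (2 x c table, df = c - 1).

    Categories empty in both samples are dropped.  Typically used with
    c = 2 (focal morph vs all others)."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("count vectors must be 1-D with matching categories")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    if a.size < 2 or a.sum() == 0 or b.sum() == 0:
        raise ValueError("need two non-empty samples over >=2 categories")
    chi2, p, df, _ = chi2_contingency(np.vstack([a, b]), correction=False)
    return float(chi2), int(df), float(p)
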