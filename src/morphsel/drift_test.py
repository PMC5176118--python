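"""Drift-rejection test on consecutive-sample phenotype frequencies.

Under drift plus binomial sampling alone, the expected phenotype
frequency in one sample equals the frequency in the previous sample, so
a regression of P' on P has slope 1 and intercept 0 — also on the logit
scale.  The test fits a binomial GLM of the next-sample counts on the
empirical logit of the previous-sample frequency and compares its
deviance against the zero-parameter drift model (offset = previous
logit) with a chi-square on 2 degrees of freedom.  Where the fitted
slope is below 1, the regression crosses the line of no change
(P' = P) at a stable equilibrium frequency, a signature of balancing
selection.

Each transition pair is independent under the null because the change
in one interval does not influence the change in the next.  The
previous-sample frequency is treated as a fixed covariate; drift
contributes extra-binomial noise that the GLM does not model, so the
test is approximate (slightly liberal for small populations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import warnings

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
from scipy.special import expit, xlogy
from scipy.stats import chi2 as chi2_dist

from morphsel.likelihood_fit import SampleSeries

__all__ = [
    "TransitionPair", "DriftTestResult", "transition_pairs",
    "fit_transition_glm", "drift_lrt", "inferred_equilibrium",
]


def _empirical_logit(k: int, n: int) -> float:
    """Haldane–Anscombe empirical logit, finite at k = 0 and k = n."""
    return math.log((k + 0.5) / (n - k + 0.5))


@dataclass(frozen=True)
class TransitionPair:
    """Counts at two consecutive sampling occasions of one series."""

    prev_k: int
    prev_n: int
    next_k: int
    next_n: int

    @property
    def prev_logit(self) -> float:
        return _empirical_logit(self.prev_k, self.prev_n)


@dataclass
class DriftTestResult:
    """Logit-scale transition regression and its test against drift."""

    intercept: float
    intercept_se: float
    slope: float
    slope_se: float
    n_pairs: int
    chi2: float
    df: int
    p_value: float
    equilibrium: Optional[float]
    flags: List[str]


def transition_pairs(series: SampleSeries) -> List[TransitionPair]:
    """One pair per pair of consecutive sampling occasions.

    Occasions where nothing was scored (total 0) are skipped, and their
    two flanking intervals are discarded rather than bridged — a pair
    spanning an empty occasion would mix two intervals' worth of
    change."""
    if series.n_occasions < 2:
        raise ValueError("need at least two occasions to form pairs")
    pairs = []
    for i in range(series.n_occasions - 1):
        if series.totals[i] == 0 or series.totals[i + 1] == 0:
            continue
        pairs.append(TransitionPair(series.counts[i], series.totals[i],
                                    series.counts[i + 1], series.totals[i + 1]))
    if not pairs:
        raise ValueError("no usable consecutive pairs")
    return pairs


def fit_transition_glm(pairs: Sequence[TransitionPair]
                       ) -> Tuple[float, float, float, float, float, List[str]]:
    """Binomial GLM of next-sample counts on the previous empirical logit.

    Returns (intercept, slope, intercept SE, slope SE, deviance, flags).
    Fitted by iteratively reweighted least squares via statsmodels.
    Degenerate designs (constant predictor) and non-convergence are
    flagged rather than raised.
    """
    if len(pairs) < 3:
        raise ValueError("need at least three pairs for a 2-parameter GLM")
    flags: List[str] = []
    x = np.array([p.prev_logit for p in pairs])
    endog = np.array([[p.next_k, p.next_n - p.next_k] for p in pairs],
                     dtype=float)
    if np.ptp(x) < 1e-12:
        flags.append("constant predictor: slope unidentifiable")
        exog = np.ones((len(pairs), 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        return (float(res.params[0]), float(np.nan), float(res.bse[0]),
                float(np.nan), float(res.deviance), flags)
    exog = sm.add_constant(x)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", PerfectSeparationWarning)
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
        flags.append("possible separation")
    if not res.converged:
        flags.append("IRLS did not converge")
    if np.any(np.abs(res.params) > 50):
        flags.append("possible separation")
    return (float(res.params[0]), float(res.params[1]),
            float(res.bse[0]), float(res.bse[1]),
            float(res.deviance), flags)


def _null_deviance(pairs: Sequence[TransitionPair]) -> float:
    """Deviance of the drift model (intercept 0, slope 1): the fitted
    mean is just the inverse logit of the previous empirical logit, no
    free parameters."""
    dev = 0.0
    for pair in pairs:
        mu = expit(pair.prev_logit)
        k, n = pair.next_k, pair.next_n
        dev += 2.0 * (xlogy(k, k / (n * mu)) + xlogy(n - k, (n - k) / (n * (1.0 - mu))))
    return float(dev)


def drift_lrt(pairs: Sequence[TransitionPair]) -> DriftTestResult:
    """Likelihood-ratio test of the free transition regression against
    the drift expectation (intercept 0, slope 1), chi-square with 2 df.

    The statistic is the deviance of the offset-only drift model minus
    the deviance of the fitted 2-parameter model; it is invariant to
    the binomial-constant convention and clamped at 0 against numerical
    jitter."""
    intercept, slope, int_se, slope_se, deviance, flags = \
        fit_transition_glm(pairs)
    chi2 = max(_null_deviance(pairs) - deviance, 0.0)
    df = 2
    p = float(chi2_dist.sf(chi2, df))
    eq = inferred_equilibrium(intercept, slope) if np.isfinite(slope) else None
    return DriftTestResult(intercept=intercept, intercept_se=int_se,
                           slope=slope, slope_se=slope_se,
                           n_pairs=len(pairs), chi2=float(chi2), df=df,
                           p_value=p, equilibrium=eq, flags=flags)


def inferred_equilibrium(intercept: float, slope: float) -> Optional[float]:
    """Phenotype frequency where the fitted logit-scale regression
    crosses the line of no change P' = P: invlogit(intercept/(1-slope)).

    Only meaningful (and only returned) when slope < 1, where the
    crossing is a stable point; None otherwise."""
    if slope >= 1.0:
        return None
    return float(expit(intercept / (1.0 - slope)))
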