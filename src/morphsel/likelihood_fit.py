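"""Binomial maximum-likelihood fitting of morph-frequency time series.

Each population is a series of sampling occasions (calendar year, count
of the focal colour morph, total snails scored).  A dynamic model (M,
DS, HA, FD, or FD constrained to a fixed equilibrium) is iterated one
generation per year between occasions; the starting allele frequency at
the first occasion, p0, is a free parameter of every fit.  Observed
counts are treated as binomial draws from the predicted phenotype
frequency, and parameters are estimated by minimising -2 log L with
multi-start bounded quasi-Newton (L-BFGS-B) runs over a fixed grid, so
fits are deterministic.  Confidence intervals use the profile
likelihood method.

The -2 log L includes the binomial coefficient term; it is constant in
the parameters for fixed data, so likelihood-ratio and AIC comparisons
are unaffected by the convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize, brentq
from scipy.special import gammaln, xlogy, xlog1py
from scipy.stats import chi2 as chi2_dist

from morphsel.core_models import (
    DirectionalParams,
    FDParams,
    HAParams,
    MigrationParams,
    ModelParams,
    allele_from_phenotype,
    phenotype_freq,
    step,
)

__all__ = [
    "SampleSeries", "FitSpec", "FitResult", "FitError",
    "predict_series", "neg2_loglik", "fit", "profile_ci",
    "fit_combined", "fit_pooled", "fit_fd_constrained",
    "background_equilibrium",
]

# Parameters estimated for each model kind, excluding p0.  "FDC" is the
# FD model with slope b tied to a so that the equilibrium (1-a)/b equals
# a fixed background phenotype frequency.
MODEL_PARAM_NAMES: Dict[str, Tuple[str, ...]] = {
    "M": ("m",),
    "DS": ("w_colour",),
    "HA": ("w_AA", "w_aa"),
    "FD": ("a", "b"),
    "FDC": ("a",),
}

_P0_EPS = 1e-6
#: Default box constraints per parameter.  w_AA is bounded at [0.001, 1]
#: and w_aa below at 0.001; m is a proper fraction.
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "m": (0.0, 1.0),
    "w_colour": (1e-3, 3.0),
    "w_AA": (1e-3, 1.0),
    "w_aa": (1e-3, 10.0),
    "a": (1e-3, 5.0),
    "b": (-5.0, 5.0),
    "p0": (_P0_EPS, 1.0 - _P0_EPS),
}

_P0_STARTS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
_MODEL_STARTS: Dict[str, Tuple[Tuple[float, ...], ...]] = {
    "M": tuple((m,) for m in (0.01, 0.05, 0.1)),
    "DS": tuple((w,) for w in (0.8, 0.9, 1.0, 1.1)),
    "HA": tuple(itertools.product((0.3, 0.6, 0.9, 1.0), (0.9, 1.0, 1.05))),
    "FD": tuple(itertools.product((0.9, 1.0, 1.1, 1.2), (-1.0, -0.5, 0.0, 0.5))),
    "FDC": tuple((a,) for a in (1.01, 1.1, 1.3, 1.5)),
}

_BOUNDARY_TOL = 1e-6
_N2LL_TIE_TOL = 1e-8
# finite stand-in for an impossible likelihood inside the optimizer,
# so L-BFGS-B's finite differences stay defined
_PENALTY = 1e12


class FitError(RuntimeError):
    """Raised when no optimisation start converges to a finite optimum."""


@dataclass(frozen=True)
class SampleSeries:
    """One population's time series of focal-morph counts.

    Occasions where nothing was scored (total 0, e.g. a census crash
    year) may be recorded; they carry no likelihood information and are
    dropped from fits, and the drift test refuses to bridge across
    them.  Use :meth:`usable` for the series restricted to occasions
    with a positive total.
    """

    population_id: str
    morph: str
    years: Tuple[int, ...]
    counts: Tuple[int, ...]
    totals: Tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.years) == len(self.counts) == len(self.totals)):
            raise ValueError("years, counts and totals must have equal lengths")
        if any(y2 <= y1 for y1, y2 in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")
        for k, n in zip(self.counts, self.totals):
            if n < 0 or not (0 <= k <= n):
                raise ValueError(f"count {k} outside [0, total={n}]")

    @classmethod
    def from_counts(cls, population_id: str, morph: str,
                    years: Sequence[int], counts: Sequence[int],
                    totals: Sequence[int]) -> "SampleSeries":
        return cls(population_id, morph, tuple(int(y) for y in years),
                   tuple(int(k) for k in counts), tuple(int(n) for n in totals))

    def usable(self) -> "SampleSeries":
        """The series restricted to occasions with a positive total."""
        kept = [(y, k, n) for y, k, n in
                zip(self.years, self.counts, self.totals) if n > 0]
        if not kept:
            raise ValueError("no usable occasions (all totals are zero)")
        ys, ks, ns = zip(*kept)
        return SampleSeries(self.population_id, self.morph, ys, ks, ns)

    @property
    def n_occasions(self) -> int:
        return len(self.years)

    @property
    def frequencies(self) -> Tuple[float, ...]:
        """Observed sample frequencies at occasions with a positive total."""
        return tuple(k / n for k, n in zip(self.counts, self.totals) if n > 0)


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how: model kind, fixed inputs, box bounds and the
    multi-start grid.  ``p_eq`` (source-pool allele frequency) is
    required for M; ``P_bg`` (background equilibrium phenotype
    frequency) for the constrained FD model."""

    kind: str
    p_eq: Optional[float] = None
    P_bg: Optional[float] = None
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MODEL_PARAM_NAMES:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "M" and self.p_eq is None:
            raise ValueError("migration model requires p_eq")
        if self.kind == "FDC":
            if self.P_bg is None or not (0.0 < self.P_bg < 1.0):
                raise ValueError("constrained FD requires P_bg in (0, 1)")

    def param_names(self) -> Tuple[str, ...]:
        return MODEL_PARAM_NAMES[self.kind]

    def bound_for(self, name: str) -> Tuple[float, float]:
        if name in self.bounds:
            return self.bounds[name]
        if name == "a" and self.kind == "FDC":
            # equilibrium constraint requires a > 1
            return (1.0 + 1e-9, DEFAULT_BOUNDS["a"][1])
        return DEFAULT_BOUNDS[name]

    def make_params(self, values: Sequence[float]) -> ModelParams:
        """Materialise a parameter object from the free-parameter vector."""
        if self.kind == "M":
            return MigrationParams(m=values[0], p_eq=self.p_eq)
        if self.kind == "DS":
            return DirectionalParams(w_colour=values[0])
        if self.kind == "HA":
            return HAParams(w_AA=values[0], w_aa=values[1])
        if self.kind == "FD":
            return FDParams(a=values[0], b=values[1])
        # FDC: b tied so that (1 - a)/b = P_bg
        a = values[0]
        return FDParams(a=a, b=(1.0 - a) / self.P_bg)

    def step_kind(self) -> str:
        return "FD" if self.kind == "FDC" else self.kind


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit.

    ``estimates`` maps parameter names to MLEs; multi-series fits use
    ``p0[population_id]`` keys for per-series starting frequencies.
    ``profile_cis`` endpoints are None where the profile reaches the
    parameter's allowed bound before crossing the confidence threshold.
    """

    kind: str
    estimates: Dict[str, float]
    neg2LL: float
    k_params: int
    converged: bool
    boundary_hits: Dict[str, bool]
    profile_cis: Dict[str, Tuple[Optional[float], Optional[float]]] = field(
        default_factory=dict)
    n_starts: int = 0
    flags: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Prediction and likelihood


def predict_series(kind: str, params: ModelParams, p0: float,
                   years: Sequence[int]) -> np.ndarray:
    """Expected phenotype frequency at each sampling occasion.

    The first occasion anchors generation 0 at allele frequency p0; each
    later occasion is reached by one model step per calendar year of
    gap (generation time 1 year, non-overlapping generations).
    """
    years = list(years)
    if any(y2 <= y1 for y1, y2 in zip(years, years[1:])):
        raise ValueError("years must be strictly increasing")
    P = np.empty(len(years))
    p = p0
    P[0] = phenotype_freq(p)
    for i, (y1, y2) in enumerate(zip(years, years[1:]), start=1):
        for _ in range(int(round(y2 - y1))):
            p = step(kind, p, params)
        P[i] = phenotype_freq(p)
    return P


def _binom_neg2ll(counts: np.ndarray, totals: np.ndarray,
                  P: np.ndarray) -> float:
    """-2 sum log Binom(k | n, P), binomial coefficient included.

    Returns +inf when some predicted P is impossible for the observed
    count (P=0 with k>0, or P=1 with k<n)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (gammaln(totals + 1) - gammaln(counts + 1)
              - gammaln(totals - counts + 1)
              + xlogy(counts, P) + xlog1py(totals - counts, -P))
    total = ll.sum()
    if not np.isfinite(total):
        return math.inf
    return -2.0 * total


def neg2_loglik(kind: str, params: ModelParams, p0: float,
                series: SampleSeries) -> float:
    """-2 log-likelihood of one series under the given model; lower is
    better.  Zero-total occasions are dropped; impossible predictions
    yield +inf, not an exception."""
    series = series.usable()
    P = predict_series(kind, params, p0, series.years)
    return _binom_neg2ll(np.asarray(series.counts, dtype=float),
                         np.asarray(series.totals, dtype=float), P)


# ---------------------------------------------------------------------------
# Single-series fitting


def _objective_single(spec: FitSpec, series: SampleSeries
                      ) -> Callable[[np.ndarray], float]:
    series = series.usable()
    counts = np.asarray(series.counts, dtype=float)
    totals = np.asarray(series.totals, dtype=float)
    years = series.years
    kind = spec.step_kind()

    def obj(x: np.ndarray) -> float:
        try:
            params = spec.make_params(x[:-1])
            P = predict_series(kind, params, x[-1], years)
        except ValueError:
            return _PENALTY
        return min(_binom_neg2ll(counts, totals, P), _PENALTY)

    return obj


def _run_starts(obj: Callable[[np.ndarray], float],
                starts: Sequence[Sequence[float]],
                bounds: Sequence[Tuple[float, float]],
                names: Sequence[str]) -> Tuple[np.ndarray, float, bool,
                                               Dict[str, bool], int]:
    """Best of multi-start L-BFGS-B runs.  Ties within 1e-8 on -2LL are
    broken by fewest boundary hits, then by grid order."""
    best = None  # (neg2LL, n_boundary, order, x, converged)
    for order, x0 in enumerate(starts):
        x0 = np.clip(np.asarray(x0, dtype=float),
                     [lo for lo, _ in bounds], [hi for _, hi in bounds])
        if obj(x0) >= _PENALTY:
            continue
        res = minimize(obj, x0, method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun) or res.fun >= _PENALTY:
            continue
        hits = {n: (abs(x - lo) < _BOUNDARY_TOL or abs(x - hi) < _BOUNDARY_TOL)
                for n, x, (lo, hi) in zip(names, res.x, bounds)}
        cand = (res.fun, sum(hits.values()), order, res.x, bool(res.success), hits)
        if best is None:
            best = cand
        elif cand[0] < best[0] - _N2LL_TIE_TOL:
            best = cand
        elif abs(cand[0] - best[0]) <= _N2LL_TIE_TOL and cand[1] < best[1]:
            best = cand
    if best is None:
        raise FitError("no optimisation start reached a finite optimum")
    fun, _, _, x, success, hits = best
    return x, fun, success, hits, len(list(starts))


def _starts_for(spec: FitSpec, p0_starts: Sequence[float]
                ) -> List[Tuple[float, ...]]:
    return [tuple(ms) + (p0,)
            for ms in _MODEL_STARTS[spec.kind] for p0 in p0_starts]


def fit(series: SampleSeries, spec: FitSpec) -> FitResult:
    """Maximum-likelihood fit of one dynamic model to one series.

    Free parameters are the model's own parameters plus the starting
    allele frequency p0 at the first occasion.
    """
    if series.usable().n_occasions < 2:
        raise ValueError("need at least two usable occasions to fit a model")
    names = list(spec.param_names()) + ["p0"]
    bounds = [spec.bound_for(n) for n in names]
    obj = _objective_single(spec, series)
    x, n2ll, success, hits, n_starts = _run_starts(
        obj, _starts_for(spec, _P0_STARTS), bounds, names)
    estimates = dict(zip(names, map(float, x)))
    return FitResult(kind=spec.kind, estimates=estimates, neg2LL=float(n2ll),
                     k_params=len(names), converged=success,
                     boundary_hits=hits, n_starts=n_starts)


# ---------------------------------------------------------------------------
# Profile-likelihood confidence intervals


def _ci_from_profile(profile: Callable[[float], float], mle: float,
                     n2ll_min: float, lo_bound: float, hi_bound: float,
                     level: float = 0.95,
                     ) -> Tuple[Optional[float], Optional[float], List[str]]:
    """Find where the profiled -2LL crosses n2ll_min + chi2_1 quantile.

    Walks outward from the MLE with geometrically growing steps to
    bracket the crossing on each side, then bisects.  An endpoint is
    None when the parameter bound is reached while the profile is still
    below the threshold.  Non-monotone profiles keep the outermost
    crossing and add a flag.
    """
    flags: List[str] = []
    if level <= 0.0:
        return mle, mle, flags
    threshold = n2ll_min + chi2_dist.ppf(level, df=1)

    def crossing(bound: float) -> Optional[float]:
        span = abs(bound - mle)
        if span < 1e-12:
            return None  # MLE sits on the bound: endpoint absent
        direction = 1.0 if bound > mle else -1.0
        xs = [mle]
        fs = [n2ll_min]
        stp = span / 64.0
        x = mle
        while True:
            x = x + direction * stp
            if (x - bound) * direction >= 0:
                x = bound
            xs.append(x)
            fs.append(profile(x))
            if fs[-1] >= threshold or x == bound:
                break
            stp *= 1.7
        # outermost adjacent sign change of f - threshold
        brackets = [(xs[i], xs[i + 1]) for i in range(len(xs) - 1)
                    if (fs[i] - threshold) * (fs[i + 1] - threshold) <= 0
                    and fs[i + 1] >= threshold]
        if not brackets:
            return None  # hit the bound below threshold
        if len(brackets) > 1:
            flags.append("non-monotone profile")
        a, b = brackets[-1]
        if a == b:
            return a
        return brentq(lambda v: profile(v) - threshold, a, b, xtol=1e-8)

    return crossing(lo_bound), crossing(hi_bound), flags


def profile_ci(series: SampleSeries, spec: FitSpec, fit_result: FitResult,
               param: str, level: float = 0.95,
               ) -> Tuple[Optional[float], Optional[float]]:
    """Profile-likelihood CI for one parameter of a single-series fit.

    At each trial value of ``param`` the remaining parameters are
    re-optimised (warm-started from the incumbent solution).  Endpoints
    are None where the parameter's allowed range is exhausted first —
    the fit cannot bound the parameter on that side.
    """
    if not fit_result.converged:
        raise ValueError("profile CI requires a converged fit")
    names = list(spec.param_names()) + ["p0"]
    if param not in names:
        raise ValueError(f"unknown parameter {param!r} for model {spec.kind}")
    idx = names.index(param)
    free_idx = [i for i in range(len(names)) if i != idx]
    bounds_all = [spec.bound_for(n) for n in names]
    obj = _objective_single(spec, series)
    x_mle = np.array([fit_result.estimates[n] for n in names])
    incumbent = {"x": x_mle[free_idx].copy()}

    def profiled(value: float) -> float:
        if not free_idx:
            x = x_mle.copy()
            x[idx] = value
            return obj(x)

        def inner(xfree: np.ndarray) -> float:
            x = x_mle.copy()
            x[idx] = value
            x[free_idx] = xfree
            return obj(x)

        starts = [incumbent["x"], x_mle[free_idx]]
        best = math.inf
        best_x = incumbent["x"]
        for x0 in starts:
            res = minimize(inner, x0, method="L-BFGS-B",
                           bounds=[bounds_all[i] for i in free_idx])
            if np.isfinite(res.fun) and res.fun < best:
                best, best_x = res.fun, res.x
        incumbent["x"] = best_x
        return best

    lo, hi, flags = _ci_from_profile(profiled, float(x_mle[idx]),
                                     fit_result.neg2LL, *bounds_all[idx],
                                     level=level)
    fit_result.profile_cis[param] = (lo, hi)
    fit_result.flags.extend(flags)
    return lo, hi


# ---------------------------------------------------------------------------
# Multi-population fits


def fit_combined(series_list: Sequence[SampleSeries], spec: FitSpec
                 ) -> FitResult:
    """Independent fits to each series, summed: -2LL and parameter
    counts add, every population keeps its own dynamics and p0."""
    if len(series_list) < 1:
        raise ValueError("need at least one series")
    if len(series_list) == 1:
        return fit(series_list[0], spec)
    fits = [fit(s, spec) for s in series_list]
    estimates: Dict[str, float] = {}
    hits: Dict[str, bool] = {}
    for s, f in zip(series_list, fits):
        for name, v in f.estimates.items():
            estimates[f"{name}[{s.population_id}]"] = v
        for name, h in f.boundary_hits.items():
            hits[f"{name}[{s.population_id}]"] = h
    return FitResult(kind=spec.kind, estimates=estimates,
                     neg2LL=float(sum(f.neg2LL for f in fits)),
                     k_params=sum(f.k_params for f in fits),
                     converged=all(f.converged for f in fits),
                     boundary_hits=hits,
                     n_starts=sum(f.n_starts for f in fits))


def _empirical_p0(series: SampleSeries) -> float:
    f0 = min(max(series.frequencies[0], 0.01), 0.99)
    return allele_from_phenotype(f0)


def fit_pooled(series_list: Sequence[SampleSeries], spec: FitSpec,
               mode: str = "pooled-I") -> FitResult:
    """Joint fit over several populations of the same manipulated morph.

    pooled-I shares everything including a single p0 (k = model params
    + 1); pooled-II shares the dynamics but gives each site its own p0
    (k = model params + n_sites).  -2LL is the joint sum.
    """
    if mode not in ("pooled-I", "pooled-II"):
        raise ValueError("mode must be 'pooled-I' or 'pooled-II'")
    if len(series_list) < 2:
        raise ValueError("pooled fits need at least two series")
    model_names = list(spec.param_names())
    n_sites = len(series_list)
    if mode == "pooled-I":
        names = model_names + ["p0"]
        p0_bounds = [spec.bound_for("p0")]
    else:
        names = model_names + [f"p0[{s.population_id}]" for s in series_list]
        p0_bounds = [spec.bound_for("p0")] * n_sites
    bounds = [spec.bound_for(n) for n in model_names] + p0_bounds

    usable = [s.usable() for s in series_list]
    data = [(np.asarray(s.counts, dtype=float),
             np.asarray(s.totals, dtype=float), s.years) for s in usable]
    kind = spec.step_kind()
    n_model = len(model_names)

    def obj(x: np.ndarray) -> float:
        try:
            params = spec.make_params(x[:n_model])
        except ValueError:
            return _PENALTY
        total = 0.0
        for i, (counts, totals, years) in enumerate(data):
            p0 = x[n_model] if mode == "pooled-I" else x[n_model + i]
            try:
                P = predict_series(kind, params, p0, years)
            except ValueError:
                return _PENALTY
            total += _binom_neg2ll(counts, totals, P)
            if total >= _PENALTY:
                return _PENALTY
        return total

    if mode == "pooled-I":
        starts = [tuple(ms) + (p0,)
                  for ms in _MODEL_STARTS[spec.kind] for p0 in _P0_STARTS]
    else:
        site_p0 = tuple(_empirical_p0(s) for s in series_list)
        starts = [tuple(ms) + site_p0 for ms in _MODEL_STARTS[spec.kind]]
        starts += [tuple(ms) + (p0,) * n_sites
                   for ms in _MODEL_STARTS[spec.kind] for p0 in (0.2, 0.4)]

    x, n2ll, success, hits, n_starts = _run_starts(obj, starts, bounds, names)
    return FitResult(kind=spec.kind, estimates=dict(zip(names, map(float, x))),
                     neg2LL=float(n2ll), k_params=len(names),
                     converged=success, boundary_hits=hits, n_starts=n_starts)


def fit_fd_constrained(series: SampleSeries, P_bg: float) -> FitResult:
    """FD fit with the equilibrium pinned at the background phenotype
    frequency: b = (1 - a)/P_bg with a > 1 free, plus p0."""
    return fit(series, FitSpec(kind="FDC", P_bg=P_bg))


def background_equilibrium(nonfocal_series_list: Sequence[SampleSeries]
                           ) -> Tuple[float, float]:
    """Equilibrium (phenotype, allele) frequency of a morph estimated as
    the unweighted mean of its per-occasion sample frequencies across
    all populations where it was not manipulated."""
    if not nonfocal_series_list:
        raise ValueError("need at least one nonfocal series")
    freqs = [f for s in nonfocal_series_list for f in s.frequencies]
    P_bar = float(np.mean(freqs))
    return P_bar, allele_from_phenotype(P_bar)
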