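"""Pipeline orchestration and report tables.

``run_pipeline`` executes the full analysis on a count table (real or
synthetic): the drift-rejection test per population, maximum-likelihood
fits of the requested dynamic models (per population, plus combined and
pooled variants per morph group), pairwise model comparisons, and
optional profile confidence intervals and constrained-FD fits.  The
result is a :class:`ReportBundle` of three tables mirroring the
standard presentation:

* drift table — logit-scale transition regression per population with
  the chi-square test against drift and the inferred equilibrium;
* model table — -2LL per model and population plus pairwise
  comparisons (delta AIC for equal parameter counts, chi-square
  otherwise, following the published layout);
* parameter table — per-model estimates, profile CIs (NA endpoints
  where a bound was reached) and implied equilibria.

Multiple tests within a morph family are corrected with the sequential
Bonferroni (Holm) procedure before significance stars are assigned.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from morphsel import __version__ as _version
from morphsel.core_models import equilibrium_fd, equilibrium_ha, HAParams, FDParams
from morphsel.drift_test import drift_lrt, transition_pairs
from morphsel.io import CountTable
from morphsel.likelihood_fit import (
    FitResult,
    FitSpec,
    SampleSeries,
    background_equilibrium,
    fit,
    fit_combined,
    fit_fd_constrained,
    fit_pooled,
    profile_ci,
)
from morphsel.model_compare import delta_aic, lrt, nm_from_rate, sequential_bonferroni

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "write_reports"]

#: Comparison layout: (model A, model B, statistic).  Pairs with equal
#: parameter counts are compared by delta AIC, the others by the drop
#: in -2LL referred to chi-square with df = parameter difference.
COMPARISON_LAYOUT: Tuple[Tuple[str, str, str], ...] = (
    ("M", "DS", "delta_aic"), ("M", "HA", "chi2"), ("M", "FD", "chi2"),
    ("DS", "HA", "chi2"), ("DS", "FD", "chi2"), ("HA", "FD", "delta_aic"),
)


@dataclass(frozen=True)
class PipelineConfig:
    """What to analyse and how.

    ``focal_map`` names the manipulated morph of each population;
    ``p_eq`` (per-morph source-pool allele frequency for the migration
    model) is estimated from nonfocal series in the table where
    available, with this mapping as fallback.
    """

    focal_map: Dict[str, str]
    models: Tuple[str, ...] = ("M", "DS", "HA", "FD")
    alpha: float = 0.05
    N: float = 1500.0
    p_eq: Dict[str, float] = field(default_factory=dict)
    profile_cis: bool = False
    fd_constrained: bool = False
    seed: int = 0


@dataclass
class ReportBundle:
    drift_table: pd.DataFrame
    model_table: pd.DataFrame
    param_table: pd.DataFrame
    metadata: Dict[str, str]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for df in (self.drift_table, self.model_table, self.param_table):
            h.update(df.to_csv(index=False).encode())
        return h.hexdigest()


def _stars(p_adj: float) -> str:
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    if p_adj < 0.1:
        return "†"  # dagger: suggestive
    return ""


def _holm_adjust(p_values: Sequence[float]) -> List[float]:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, min(1.0, (m - i) * p[idx]))
        adj[idx] = running
    return adj.tolist()


def _fmt(x: Optional[float], nd: int = 3) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    return f"{x:.{nd}f}"


def _model_equilibrium(kind: str, est: Dict[str, float]) -> Optional[float]:
    if kind == "HA":
        eq = equilibrium_ha(HAParams(est["w_AA"], est["w_aa"]))
        return None if eq is None else eq[1]
    if kind == "FD":
        return equilibrium_fd(FDParams(est["a"], est["b"]))
    return None


def run_pipeline(table: CountTable, config: PipelineConfig) -> ReportBundle:
    """Run the full analysis on a count table; deterministic given the
    table and configuration."""
    pops = [p for p in table.populations if p in config.focal_map]
    if not pops:
        raise ValueError("focal_map matches no population in the table")
    series: Dict[str, SampleSeries] = {
        pop: table.series(pop, config.focal_map[pop]) for pop in pops}

    # --- background (source-pool) frequencies per morph
    p_eq: Dict[str, float] = dict(config.p_eq)
    for morph in sorted(set(config.focal_map.values())):
        nonfocal = [s for s in table.nonfocal_series(morph, config.focal_map)
                    if sum(s.counts) > 0]
        if nonfocal:
            _, p_eq[morph] = background_equilibrium(nonfocal)

    # --- drift test
    drift_rows = []
    for pop in pops:
        r = drift_lrt(transition_pairs(series[pop]))
        drift_rows.append({
            "population": pop, "morph": config.focal_map[pop],
            "intercept": r.intercept, "intercept_se": r.intercept_se,
            "slope": r.slope, "slope_se": r.slope_se, "n_pairs": r.n_pairs,
            "chi2": r.chi2, "df": r.df, "p_value": r.p_value,
            "equilibrium": r.equilibrium,
        })
    drift_table = pd.DataFrame(drift_rows)
    drift_table["p_adjusted"] = _holm_adjust(drift_table["p_value"])
    drift_table["significance"] = [_stars(p) for p in drift_table["p_adjusted"]]
    drift_table["reject_drift"] = sequential_bonferroni(
        drift_table["p_value"], config.alpha)

    # --- model fits: per population, then combined / pooled per morph
    def spec_for(kind: str, morph: str) -> FitSpec:
        if kind == "M":
            if morph not in p_eq:
                raise ValueError(f"no source-pool frequency for morph "
                                 f"{morph!r}: provide config.p_eq")
            return FitSpec(kind="M", p_eq=p_eq[morph])
        return FitSpec(kind=kind)

    fits: Dict[Tuple[str, str], FitResult] = {}
    units: List[Tuple[str, str, List[SampleSeries]]] = [
        (pop, config.focal_map[pop], [series[pop]]) for pop in pops]
    by_morph: Dict[str, List[str]] = {}
    for pop in pops:
        by_morph.setdefault(config.focal_map[pop], []).append(pop)
    for morph, group in sorted(by_morph.items()):
        if len(group) >= 2:
            group_series = [series[p] for p in group]
            units.append((f"{morph} combined", morph, group_series))
            units.append((f"{morph} pooled-I", morph, group_series))
            units.append((f"{morph} pooled-II", morph, group_series))

    param_rows = []
    for unit, morph, unit_series in units:
        for kind in config.models:
            spec = spec_for(kind, morph)
            if unit.endswith("combined"):
                res = fit_combined(unit_series, spec)
            elif unit.endswith("pooled-I"):
                res = fit_pooled(unit_series, spec, mode="pooled-I")
            elif unit.endswith("pooled-II"):
                res = fit_pooled(unit_series, spec, mode="pooled-II")
            else:
                res = fit(unit_series[0], spec)
                if config.profile_cis:
                    for name in spec.param_names():
                        profile_ci(unit_series[0], spec, res, name)
            fits[(unit, kind)] = res
            row = {"population": unit, "morph": morph, "model": kind,
                   "neg2LL": res.neg2LL, "k_params": res.k_params,
                   "converged": res.converged,
                   "boundary_hits": ";".join(
                       n for n, h in res.boundary_hits.items() if h),
                   "equilibrium": (_model_equilibrium(kind, res.estimates)
                                   if len(unit_series) == 1 or not
                                   unit.endswith("combined") else None)}
            for name, v in res.estimates.items():
                row[f"est_{name}"] = v
                if name in res.profile_cis:
                    lo, hi = res.profile_cis[name]
                    row[f"ci_lo_{name}"], row[f"ci_hi_{name}"] = lo, hi
            if kind == "M" and "m" in res.estimates:
                row["Nm"] = nm_from_rate(res.estimates["m"], config.N)
            param_rows.append(row)
        if config.fd_constrained and not unit.endswith(("combined", "pooled-I",
                                                        "pooled-II")):
            P_bg_morph = None
            nonfocal = [s for s in table.nonfocal_series(morph, config.focal_map)
                        if sum(s.counts) > 0]
            if nonfocal:
                P_bg_morph, _ = background_equilibrium(nonfocal)
            if P_bg_morph and 0 < P_bg_morph < 1:
                res = fit_fd_constrained(unit_series[0], P_bg_morph)
                fits[(unit, "FDC")] = res
                param_rows.append({
                    "population": unit, "morph": morph, "model": "FDC",
                    "neg2LL": res.neg2LL, "k_params": res.k_params,
                    "converged": res.converged, "boundary_hits": "",
                    "equilibrium": P_bg_morph,
                    **{f"est_{n}": v for n, v in res.estimates.items()}})
    param_table = pd.DataFrame(param_rows)

    # --- model comparisons per analysis unit (published table layout)
    comp_rows = []
    for unit, morph, unit_series in units:
        row: Dict[str, object] = {"population": unit, "morph": morph}
        for kind in config.models:
            row[f"neg2LL_{kind}"] = fits[(unit, kind)].neg2LL
        for a, b, stat in COMPARISON_LAYOUT:
            if a not in config.models or b not in config.models:
                continue
            fa, fb = fits[(unit, a)], fits[(unit, b)]
            if stat == "delta_aic":
                row[f"{a}_vs_{b}"] = delta_aic(fa.neg2LL, fa.k_params,
                                               fb.neg2LL, fb.k_params)
            else:
                df = abs(fb.k_params - fa.k_params)
                if (a, b) in (("DS", "HA"), ("DS", "FD")):
                    chi2, p = lrt(fb.neg2LL, fa.neg2LL, df)
                else:
                    # published-layout chi-square for non-nested pairs
                    chi2 = max(fa.neg2LL - fb.neg2LL, 0.0)
                    p = float(_chi2_dist.sf(chi2, df))
                row[f"{a}_vs_{b}"] = chi2
                row[f"{a}_vs_{b}_p"] = p
        # constrained vs free FD
        if (unit, "FDC") in fits and "FD" in config.models:
            fc, ff = fits[(unit, "FDC")], fits[(unit, "FD")]
            chi2, p = lrt(ff.neg2LL, fc.neg2LL, ff.k_params - fc.k_params)
            row["FDC_vs_FD"], row["FDC_vs_FD_p"] = chi2, p
        comp_rows.append(row)
    model_table = pd.DataFrame(comp_rows)
    # Holm correction within each repeated-test family (per morph) for
    # each chi-square column
    for col in [c for c in model_table.columns if c.endswith("_p")]:
        adj = pd.Series(np.nan, index=model_table.index)
        for morph in model_table["morph"].unique():
            mask = model_table["morph"].eq(morph) & model_table[col].notna()
            if mask.any():
                adj[mask] = _holm_adjust(model_table.loc[mask, col].tolist())
        model_table[col.replace("_p", "_p_adj")] = adj
        model_table[col.replace("_p", "_sig")] = [
            "" if not np.isfinite(p) else _stars(p) for p in adj]

    metadata = {
        "version": _version,
        "seed": str(config.seed),
        "models": ",".join(config.models),
        "alpha": str(config.alpha),
        "N": str(config.N),
        "p_eq": json.dumps({k: round(v, 6) for k, v in sorted(p_eq.items())}),
        "focal_map": json.dumps(dict(sorted(config.focal_map.items()))),
        "profile_cis": str(config.profile_cis),
        "fd_constrained": str(config.fd_constrained),
    }
    bundle = ReportBundle(drift_table, model_table, param_table, metadata)
    bundle.metadata["content_hash"] = bundle.content_hash()
    return bundle


def write_reports(bundle: ReportBundle, out_dir: str | Path) -> List[Path]:
    """Write the bundle: one CSV per table, a flat key=value metadata
    file, and a human-readable text rendering with NA for absent CI
    endpoints and significance stars from the adjusted decisions."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in (("drift", bundle.drift_table),
                     ("models", bundle.model_table),
                     ("parameters", bundle.param_table)):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, na_rep="NA")
        paths.append(path)
    meta = out / "metadata.txt"
    meta.write_text("".join(f"{k}={v}\n" for k, v in bundle.metadata.items()))
    paths.append(meta)

    lines = ["Drift test (logit-scale transition regression)", ""]
    for _, r in bundle.drift_table.iterrows():
        lines.append(
            f"  {r['population']:<16} intercept {_fmt(r['intercept'])}"
            f"±{_fmt(r['intercept_se'])}  slope {_fmt(r['slope'])}"
            f"±{_fmt(r['slope_se'])}  n={r['n_pairs']}  "
            f"chi2(2)={_fmt(r['chi2'], 2)}{r['significance']}  "
            f"equilibrium {_fmt(r['equilibrium'])}")
    lines += ["", "Model -2 log-likelihoods", ""]
    n2_cols = [c for c in bundle.model_table.columns if c.startswith("neg2LL_")]
    for _, r in bundle.model_table.iterrows():
        cells = "  ".join(f"{c.removeprefix('neg2LL_')}={_fmt(r[c], 1)}"
                          for c in n2_cols)
        lines.append(f"  {r['population']:<16} {cells}")
    text = out / "report.txt"
    text.write_text("\n".join(lines) + "\n")
    paths.append(text)
    return paths
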