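"""Wright-Fisher generator emulating the perturbation experiment.

Simulates isolated populations founded with the conspicuous morph at
~50%, followed for 21 annual generations and sampled on 11 occasions.
Each generation the deterministic expectation from the chosen regime
(neutral drift, migration, directional selection, heterozygote
advantage, or frequency dependence) is computed first, then allele
counts are resampled binomially at the census size — i.e. selection
acts on Hardy-Weinberg proportions, drift follows.  Observed data are
binomial phenotype counts at each sampling occasion, capped at the
census when fewer snails than the sampling target are present.

Randomness is driven by a single master seed split deterministically
per population (and within a population, per stage), so adding a
population to a design never perturbs the others' streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from morphsel.core_models import ModelParams, phenotype_freq, step
from morphsel.core_models import DirectionalParams, FDParams, HAParams, MigrationParams
from morphsel.likelihood_fit import SampleSeries

__all__ = [
    "SimConfig", "SimOutput", "founder_p0", "simulate_wf", "sample_counts",
    "generate_experiment", "paper_like_configs",
]

#: Sampling-occasion offsets (years since establishment) for the
#: default design: 11 occasions spanning 21 annual generations.
DEFAULT_OCCASIONS: Tuple[int, ...] = (0, 2, 4, 6, 8, 10, 12, 14, 16, 18, 21)

#: Per-morph study conditions: source allele frequency of the colour
#: allele and mean per-occasion sample size.
MORPH_SOURCE_FREQ: Dict[str, float] = {"white": 0.024, "banded": 0.013,
                                       "red": 0.005}
MORPH_SAMPLE_SIZE: Dict[str, int] = {"white": 163, "banded": 168, "red": 198}


def founder_p0(p_src: float, lam: float) -> float:
    """Founder allele frequency for a transplant of all-coloured adults.

    ``lam`` is the fraction of first-sample offspring sired before the
    transplant (sires at the source frequency p_src); 1 - lam derive
    from introduced males at 0.5 + p_src/2.  lam = 1 gives the lower
    bound 0.25 + 0.75 p_src, lam = 0 the upper bound 0.5 + p_src/2.
    """
    if not (0.0 <= p_src <= 1.0):
        raise ValueError("p_src must lie in [0, 1]")
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lam must lie in [0, 1]")
    return lam * (0.25 + 0.75 * p_src) + (1.0 - lam) * (0.5 + p_src / 2.0)


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulated population.

    ``regime`` is 'neutral' or a model kind ('M', 'DS', 'HA', 'FD')
    with its parameters; ``N_t`` gives the census size per generation
    (length n_generations, supporting bottlenecks); the sampling plan
    pairs occasion years (offsets from generation 0) with target sample
    sizes.
    """

    population_id: str
    morph: str
    regime: str
    params: Optional[ModelParams]
    p_src: float
    lam: float  # pre-introduction paternity weight
    n_generations: int
    N_t: Tuple[int, ...]
    occasion_years: Tuple[int, ...]
    sample_sizes: Tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        if self.regime not in ("neutral", "M", "DS", "HA", "FD"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime != "neutral" and self.params is None:
            raise ValueError("non-neutral regime requires params")
        if len(self.N_t) != self.n_generations:
            raise ValueError("N_t must have one census per generation")
        if any(N < 1 for N in self.N_t):
            raise ValueError("census sizes must be >= 1")
        if len(self.occasion_years) != len(self.sample_sizes):
            raise ValueError("occasion_years and sample_sizes must match")
        if any(not (0 <= y <= self.n_generations) for y in self.occasion_years):
            raise ValueError("sampling years must lie within the simulated span")

    @property
    def p0(self) -> float:
        return founder_p0(self.p_src, self.lam)


@dataclass(frozen=True)
class SimOutput:
    """True trajectories, the observed count series, and an event log."""

    config: SimConfig
    p_traj: Tuple[float, ...]   # allele frequency, generations 0..n
    P_traj: Tuple[float, ...]   # phenotype frequency
    series: SampleSeries
    events: Tuple[str, ...]


def _deterministic_step(regime: str, p: float,
                        params: Optional[ModelParams]) -> float:
    if regime == "neutral":
        return p
    return step(regime, p, params)


def simulate_wf(config: SimConfig) -> SimOutput:
    """Run one Wright-Fisher population and sample it.

    Per generation: expected allele frequency from the regime's
    deterministic step, then drift as Binomial(2 N_t, p') / (2 N_t).
    Reproducible: the output is a pure function of the config.
    """
    ss = np.random.SeedSequence(config.seed)
    drift_rng, sample_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    events: List[str] = []
    p = config.p0
    p_traj = [p]
    for gen, N in enumerate(config.N_t, start=1):
        p_exp = _deterministic_step(config.regime, p, config.params)
        p = drift_rng.binomial(2 * N, p_exp) / (2.0 * N)
        p_traj.append(p)
        if N < 100:
            events.append(f"generation {gen}: bottleneck (N={N})")
        if p in (0.0, 1.0):
            events.append(f"generation {gen}: allele "
                          f"{'lost' if p == 0.0 else 'fixed'}")
    P_traj = [phenotype_freq(x) for x in p_traj]
    series = sample_counts(P_traj, config.occasion_years, config.sample_sizes,
                           sample_rng, population_id=config.population_id,
                           morph=config.morph,
                           census=(config.N_t[0],) + tuple(config.N_t))
    return SimOutput(config=config, p_traj=tuple(p_traj), P_traj=tuple(P_traj),
                     series=series, events=tuple(events))


def sample_counts(P_traj: Sequence[float], occasion_years: Sequence[int],
                  sample_sizes: Sequence[int],
                  rng: np.random.Generator | int,
                  population_id: str = "sim", morph: str = "white",
                  census: Optional[Sequence[int]] = None) -> SampleSeries:
    """Binomial phenotype counts at the planned occasions.

    k_t ~ Binomial(n_t, P_t) independently per occasion; the target
    sample size is capped at the census when fewer snails are present.
    Sampling is with replacement (binomial rather than hypergeometric),
    adequate while n is much smaller than the population.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    years, counts, totals = [], [], []
    for y, n in zip(occasion_years, sample_sizes):
        if not (0 <= y < len(P_traj)):
            raise ValueError(f"occasion year {y} outside simulated span")
        n_eff = int(n) if census is None else min(int(n), int(census[y]))
        k = int(rng.binomial(n_eff, P_traj[y])) if n_eff > 0 else 0
        years.append(int(y))
        counts.append(k)
        totals.append(n_eff)
    return SampleSeries(population_id, morph, tuple(years), tuple(counts),
                        tuple(totals))


def paper_like_configs(seed: int,
                       regimes: Optional[Dict[str, Tuple[str, Optional[ModelParams]]]] = None,
                       N: int = 1500, lam: float = 1.0,
                       occasions: Sequence[int] = DEFAULT_OCCASIONS,
                       ) -> List[SimConfig]:
    """Configs for the default design: 4 white + 3 banded + 1 red
    populations, 11 occasions over 21 generations, per-morph source
    frequencies and sample sizes as in the field study, census N
    constant at the average skerry size.

    ``regimes`` maps morph to (regime, params); default is neutral
    drift for every morph.  Seeds are split from the master seed, one
    child per population in design order.
    """
    design = ([("White", "white")] * 4 + [("Banded", "banded")] * 3
              + [("Red", "red")])
    children = np.random.SeedSequence(seed).spawn(len(design))
    configs = []
    counters: Dict[str, int] = {}
    for (label, morph), child in zip(design, children):
        counters[morph] = counters.get(morph, 0) + 1
        regime, params = (regimes or {}).get(morph, ("neutral", None))
        configs.append(SimConfig(
            population_id=f"{label}-{counters[morph]}",
            morph=morph, regime=regime, params=params,
            p_src=MORPH_SOURCE_FREQ[morph], lam=lam,
            n_generations=max(occasions),
            N_t=(N,) * max(occasions),
            occasion_years=tuple(int(y) for y in occasions),
            sample_sizes=(MORPH_SAMPLE_SIZE[morph],) * len(occasions),
            seed=int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF),
        ))
    return configs


def generate_experiment(preset: str = "paper-like", seed: int = 0,
                        configs: Optional[Sequence[SimConfig]] = None,
                        **preset_kwargs,
                        ) -> Tuple[List[SampleSeries], List[SimOutput]]:
    """Simulate a whole perturbation experiment.

    ``preset='paper-like'`` builds the default 8-population design (see
    :func:`paper_like_configs`, which accepts ``regimes``, ``N``,
    ``lam`` and ``occasions`` overrides); ``preset='custom'`` runs the
    explicitly supplied configs.  Returns the observed series and the
    full truth records.
    """
    if preset == "paper-like":
        configs = paper_like_configs(seed, **preset_kwargs)
    elif preset == "custom":
        if not configs:
            raise ValueError("custom preset requires configs")
    else:
        raise ValueError(f"unknown preset {preset!r}")
    outputs = [simulate_wf(c) for c in configs]
    return [o.series for o in outputs], outputs
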