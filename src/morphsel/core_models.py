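"""One-locus two-allele dynamics for a dominant colour morph.

The conspicuous colour is produced by a dominant allele A at frequency
``p``; under Hardy-Weinberg the conspicuous phenotype has frequency
``P = 1 - (1-p)**2``.  Four deterministic per-generation recursions are
provided:

* migration (M): replacement of a fraction ``m`` by immigrants from a
  source pool at allele frequency ``p_eq``;
* directional selection (DS): constant relative fitness ``w_colour`` of
  the colour phenotype (both AA and Aa) against cryptic ``aa`` at 1;
* heterozygote advantage (HA): homozygote fitnesses ``w_AA`` and
  ``w_aa`` relative to the heterozygote at 1 (overdominance when both
  are below 1);
* negative frequency dependence (FD): colour-phenotype fitness declining
  linearly with its own frequency, ``w = a + b*P``.

Selection recursions use the standard single-locus form with mean
fitness ``w_bar = w_AA p**2 + 2 w_Aa p q + w_aa q**2``; populations are
assumed at Hardy-Weinberg proportions before selection each generation,
with one generation per calendar year and non-overlapping generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

__all__ = [
    "MigrationParams", "DirectionalParams", "HAParams", "FDParams",
    "Trajectory", "ModelParams", "FD_FITNESS_FLOOR",
    "phenotype_freq", "allele_from_phenotype", "step_migration",
    "step_directional", "step_ha", "fd_fitness", "step_fd", "step",
    "equilibrium_fd", "equilibrium_ha", "iterate", "founder_p0_bounds",
]

#: Lower clamp for the FD fitness a + b*P, so that extreme parameter
#: proposals during optimisation remain evaluable.
FD_FITNESS_FLOOR = 1e-9


def _check_freq(x: float, name: str) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1]; got {x!r}")


@dataclass(frozen=True)
class MigrationParams:
    """Island-model migration: fraction ``m`` of each generation are
    immigrants drawn from a source pool at allele frequency ``p_eq``."""

    m: float
    p_eq: float

    def __post_init__(self) -> None:
        _check_freq(self.m, "m")
        _check_freq(self.p_eq, "p_eq")


@dataclass(frozen=True)
class DirectionalParams:
    """Constant selection: colour phenotype (AA, Aa) fitness ``w_colour``
    relative to cryptic aa at 1.  Selection coefficient s = 1 - w_colour."""

    w_colour: float

    def __post_init__(self) -> None:
        if self.w_colour <= 0:
            raise ValueError("w_colour must be positive")

    @property
    def s(self) -> float:
        return 1.0 - self.w_colour


@dataclass(frozen=True)
class HAParams:
    """Homozygote fitnesses relative to the heterozygote (w_Aa = 1).
    Protected polymorphism requires w_AA < 1 and w_aa < 1."""

    w_AA: float
    w_aa: float

    def __post_init__(self) -> None:
        if self.w_AA <= 0 or self.w_aa <= 0:
            raise ValueError("homozygote fitnesses must be positive")


@dataclass(frozen=True)
class FDParams:
    """Frequency-dependent colour fitness w = a + b*P, cryptic aa at 1.
    A stable polymorphism at P* = (1-a)/b requires a > 1 and b < 0."""

    a: float
    b: float


ModelParams = Union[MigrationParams, DirectionalParams, HAParams, FDParams]


@dataclass(frozen=True)
class Trajectory:
    """Deterministic trajectory: allele and phenotype frequency per
    generation, with generation 0 holding the starting frequency p0."""

    generations: Tuple[int, ...]
    p_values: Tuple[float, ...]
    P_values: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.generations) == len(self.p_values) == len(self.P_values)):
            raise ValueError("trajectory fields must have equal lengths")


def phenotype_freq(p: float) -> float:
    """Frequency of the dominant (conspicuous) phenotype under HWE,
    P = p**2 + 2 p (1-p) = 1 - (1-p)**2."""
    _check_freq(p, "p")
    return 1.0 - (1.0 - p) ** 2


def allele_from_phenotype(P: float) -> float:
    """Inverse HWE map for a dominant trait: p = 1 - sqrt(1 - P)."""
    _check_freq(P, "P")
    return 1.0 - math.sqrt(1.0 - P)


def step_migration(p: float, params: MigrationParams) -> float:
    """One generation of migration: p' = m*p_eq + (1-m)*p."""
    _check_freq(p, "p")
    return params.m * params.p_eq + (1.0 - params.m) * p


def step_directional(p: float, params: DirectionalParams) -> float:
    """One generation of constant selection on a dominant phenotype.

    p' = w (p**2 + p q) / (w p**2 + 2 w p q + q**2) with q = 1 - p.
    """
    _check_freq(p, "p")
    w = params.w_colour
    q = 1.0 - p
    num = w * (p * p + p * q)
    denom = w * p * p + 2.0 * w * p * q + q * q
    if denom == 0.0:
        # only reachable as w -> 0 with p = 1; the dominant phenotype is lethal
        return 0.0
    return num / denom


def step_ha(p: float, params: HAParams) -> float:
    """One generation of genotypic selection with w_Aa = 1.

    p' = (w_AA p**2 + p q) / w_bar,
    w_bar = w_AA p**2 + 2 p q + w_aa q**2.
    """
    _check_freq(p, "p")
    q = 1.0 - p
    num = params.w_AA * p * p + p * q
    denom = params.w_AA * p * p + 2.0 * p * q + params.w_aa * q * q
    return num / denom


def fd_fitness(P: float, params: FDParams) -> float:
    """Colour-phenotype fitness a + b*P, clamped below at
    :data:`FD_FITNESS_FLOOR` so optimisation proposals stay evaluable."""
    _check_freq(P, "P")
    return max(params.a + params.b * P, FD_FITNESS_FLOOR)


def step_fd(p: float, params: FDParams) -> float:
    """One generation of frequency-dependent selection: the colour
    fitness is evaluated at the current phenotype frequency and the DS
    recursion applied."""
    w = fd_fitness(phenotype_freq(p), params)
    return step_directional(p, DirectionalParams(w))


_STEPPERS = {
    "M": step_migration,
    "DS": step_directional,
    "HA": step_ha,
    "FD": step_fd,
}


def step(kind: str, p: float, params: ModelParams) -> float:
    """Dispatch one generation of the named model ('M', 'DS', 'HA', 'FD')."""
    try:
        stepper = _STEPPERS[kind]
    except KeyError:
        raise ValueError(f"unknown model kind {kind!r}; expected one of "
                         f"{sorted(_STEPPERS)}") from None
    return stepper(p, params)


def equilibrium_fd(params: FDParams) -> Optional[float]:
    """Stable FD equilibrium phenotype frequency P* = (1-a)/b, or None.

    The polymorphism is protected only for a > 1 and b < 0 with the
    equilibrium strictly inside (0, 1).
    """
    if params.a <= 1.0 or params.b >= 0.0:
        return None
    P_star = (1.0 - params.a) / params.b
    if not (0.0 < P_star < 1.0):
        return None
    return P_star


def equilibrium_ha(params: HAParams) -> Optional[Tuple[float, float]]:
    """Overdominance equilibrium (allele, phenotype) or None.

    p_hat = (1 - w_aa) / ((1 - w_AA) + (1 - w_aa)), defined (and
    protected) only when both homozygote fitnesses are below 1.
    """
    if params.w_AA >= 1.0 or params.w_aa >= 1.0:
        return None
    p_hat = (1.0 - params.w_aa) / ((1.0 - params.w_AA) + (1.0 - params.w_aa))
    return p_hat, phenotype_freq(p_hat)


def iterate(kind: str, params: ModelParams, p0: float, n_gens: int) -> Trajectory:
    """Iterate the named model deterministically for ``n_gens``
    generations starting from allele frequency ``p0`` at generation 0."""
    if n_gens < 0:
        raise ValueError("n_gens must be non-negative")
    _check_freq(p0, "p0")
    stepper = _STEPPERS.get(kind)
    if stepper is None:
        raise ValueError(f"unknown model kind {kind!r}")
    p_values = [p0]
    p = p0
    for _ in range(n_gens):
        p = stepper(p, params)
        p_values.append(p)
    return Trajectory(
        generations=tuple(range(n_gens + 1)),
        p_values=tuple(p_values),
        P_values=tuple(phenotype_freq(p) for p in p_values),
    )


def founder_p0_bounds(p_src: float) -> Tuple[float, float]:
    """Bounds on the founder allele frequency after a transplant of
    all-coloured adults from a source population at allele frequency
    ``p_src``.

    Every introduced snail carries at least one colour allele, so the
    introduced adults have allele frequency 0.5 + p_src/2.  If all
    first-sample offspring derive from matings that happened before the
    transplant (sires at p_src), the offspring allele frequency is
    0.25 + 0.75*p_src; if all derive from introduced sires it is
    0.5 + p_src/2.  Returns (lower, upper).
    """
    _check_freq(p_src, "p_src")
    return 0.25 + 0.75 * p_src, 0.5 + p_src / 2.0
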