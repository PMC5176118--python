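"""Recursions, equilibria and genotype-bookkeeping oracle checks."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from morphsel.core_models import (
    DirectionalParams,
    FDParams,
    HAParams,
    MigrationParams,
    allele_from_phenotype,
    equilibrium_fd,
    equilibrium_ha,
    fd_fitness,
    founder_p0_bounds,
    iterate,
    phenotype_freq,
    step_directional,
    step_fd,
    step_ha,
    step_migration,
)

freqs = st.floats(0.0, 1.0, allow_nan=False)


def genotype_oracle(p, w_AA, w_Aa, w_aa):
    """Brute-force one-generation step: HWE genotype frequencies,
    multiply by fitness, renormalise, count alleles."""
    q = 1.0 - p
    f = np.array([p * p * w_AA, 2 * p * q * w_Aa, q * q * w_aa])
    f = f / f.sum()
    return f[0] + f[1] / 2.0


@pytest.mark.parametrize("p, expected", [
    (0.0, 0.0), (1.0, 1.0), (0.005, 0.009975), (0.5, 0.75),
])
def test_phenotype_freq_dominant_hwe(p, expected):
    assert phenotype_freq(p) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("P, expected", [
    (0.0, 0.0), (0.75, 0.5), (0.071429, 0.036376),
])
def test_allele_from_phenotype_inverse(P, expected):
    p = allele_from_phenotype(P)
    assert p == pytest.approx(expected, abs=1e-6)
    assert phenotype_freq(p) == pytest.approx(P, abs=1e-12)


@pytest.mark.parametrize("bad", [-0.01, 1.01])
def test_frequency_domain_errors(bad):
    with pytest.raises(ValueError):
        phenotype_freq(bad)
    with pytest.raises(ValueError):
        allele_from_phenotype(bad)


@pytest.mark.parametrize("p, m, p_eq, expected", [
    (0.3, 0.0, 0.024, 0.3),      # no migration
    (0.3, 1.0, 0.024, 0.024),    # full replacement
    (0.3, 0.07, 0.005, 0.27935),
])
def test_step_migration(p, m, p_eq, expected):
    assert step_migration(p, MigrationParams(m, p_eq)) == pytest.approx(
        expected, abs=1e-12)


@pytest.mark.parametrize("p, w, expected", [
    (0.3, 1.0, 0.3),             # neutrality is the identity
    (0.3, 0.9, 0.27 / 0.949),    # one generation of s=0.1
])
def test_step_directional(p, w, expected):
    assert step_directional(p, DirectionalParams(w)) == pytest.approx(
        expected, abs=1e-12)


def test_step_directional_lethal_dominant():
    # w -> 0 removes every colour-allele carrier in one generation
    assert step_directional(0.3, DirectionalParams(1e-300)) == pytest.approx(
        0.0, abs=1e-12)
    with pytest.raises(ValueError):
        DirectionalParams(0.0)


def test_step_ha_symmetric_and_fixed_point():
    assert step_ha(0.5, HAParams(1.0, 1.0)) == pytest.approx(0.5)
    for w in (0.3, 0.7, 1.2):
        assert step_ha(0.5, HAParams(w, w)) == pytest.approx(0.5, abs=1e-12)
    # overdominance equilibrium of the strongest-selected population
    p_hat = equilibrium_ha(HAParams(0.30, 0.93))[0]
    assert abs(step_ha(p_hat, HAParams(0.30, 0.93)) - p_hat) < 1e-4
    assert abs(step_ha(0.0909, HAParams(0.30, 0.93)) - 0.0909) < 1e-4


@pytest.mark.parametrize("P, a, b, expected", [
    (0.0, 1.14, -0.70, 1.14),
    (0.071429, 1.03, -0.42, 1.0),
    (1.0, 0.5, -1.0, 1e-9),  # clamped
])
def test_fd_fitness(P, a, b, expected):
    assert fd_fitness(P, FDParams(a, b)) == pytest.approx(expected, rel=1e-4)


def test_step_fd_matches_ds_and_fixed_point():
    for p in (0.1, 0.3, 0.7):
        assert step_fd(p, FDParams(1.0, 0.0)) == pytest.approx(p, abs=1e-12)
        assert step_fd(p, FDParams(0.9, 0.0)) == pytest.approx(
            step_directional(p, DirectionalParams(0.9)), abs=1e-14)
    # equilibrium of the red-morph fit is a fixed point
    p_star = allele_from_phenotype((1 - 1.03) / -0.42)
    assert step_fd(p_star, FDParams(1.03, -0.42)) == pytest.approx(
        p_star, abs=1e-9)


@pytest.mark.parametrize("a, b, expected", [
    (1.03, -0.42, 0.0714),   # red morph: ~7% equilibrium
    (1.14, -0.70, 0.200),    # strongest white fit: 20%
    (1.0, -1.0, None),       # boundary, not protected
    (0.9, -0.5, None),
    (1.5, 0.2, None),
    (3.0, -1.5, None),       # (1-a)/b > 1: outside (0,1)
])
def test_equilibrium_fd(a, b, expected):
    eq = equilibrium_fd(FDParams(a, b))
    if expected is None:
        assert eq is None
    else:
        assert eq == pytest.approx(expected, abs=5e-4)


def test_equilibrium_ha():
    p_hat, P_hat = equilibrium_ha(HAParams(0.30, 0.93))
    assert p_hat == pytest.approx(0.0909, abs=5e-4)
    assert P_hat == pytest.approx(0.1735, abs=5e-4)  # the reported ~17%
    assert equilibrium_ha(HAParams(0.53, 1.00)) is None  # w_aa at bound
    for w in (0.3, 0.8):
        assert equilibrium_ha(HAParams(w, w))[0] == pytest.approx(0.5)


def test_iterate_trajectories():
    assert iterate("DS", DirectionalParams(1.0), 0.3, 5).p_values == (0.3,) * 6
    traj = iterate("M", MigrationParams(0.07, 0.005), 0.3, 2)
    assert traj.p_values[0] == 0.3
    assert traj.p_values[2] == pytest.approx(0.260145, abs=1e-6)
    assert iterate("FD", FDParams(1.0, 0.0), 0.4, 0).p_values == (0.4,)
    with pytest.raises(ValueError):
        iterate("XX", DirectionalParams(0.9), 0.3, 1)
    with pytest.raises(ValueError):
        iterate("DS", DirectionalParams(0.9), 0.3, -1)


@pytest.mark.parametrize("p_src, expected", [
    (0.0, (0.25, 0.5)), (1.0, (1.0, 1.0)), (0.024, (0.268, 0.512)),
])
def test_founder_p0_bounds(p_src, expected):
    lo, hi = founder_p0_bounds(p_src)
    assert (lo, hi) == pytest.approx(expected)
    assert lo <= hi


def test_selection_steps_match_genotype_oracle_on_grid():
    """Both selection recursions agree with explicit genotype
    bookkeeping (HWE -> fitness -> renormalise -> allele count) to
    1e-12 over a dense parameter grid."""
    ps = np.linspace(0.01, 0.99, 50)
    ws = np.linspace(0.05, 1.95, 50)
    for p in ps:
        for w in ws:
            assert step_directional(p, DirectionalParams(w)) == pytest.approx(
                genotype_oracle(p, w, w, 1.0), abs=1e-12)
    for p in ps[::7]:
        for w_AA in ws[::7]:
            for w_aa in ws[::7]:
                assert step_ha(p, HAParams(w_AA, w_aa)) == pytest.approx(
                    genotype_oracle(p, w_AA, 1.0, w_aa), abs=1e-12)


@settings(max_examples=200, derandomize=True)
@given(p=freqs, w=st.floats(0.01, 3.0), m=st.floats(0.0, 1.0),
       p_eq=freqs, w2=st.floats(0.01, 3.0),
       a=st.floats(0.0, 3.0), b=st.floats(-3.0, 3.0))
def test_steps_preserve_unit_interval(p, w, m, p_eq, w2, a, b):
    for p_next in (
        step_migration(p, MigrationParams(m, p_eq)),
        step_directional(p, DirectionalParams(w)),
        step_ha(p, HAParams(w, w2)),
        step_fd(p, FDParams(a, b)),
    ):
        assert 0.0 <= p_next <= 1.0


@settings(max_examples=200, derandomize=True)
@given(P=freqs)
def test_phenotype_allele_roundtrip(P):
    assert phenotype_freq(allele_from_phenotype(P)) == pytest.approx(
        P, abs=1e-12)


@settings(max_examples=50, derandomize=True)
@given(p0=st.floats(0.01, 0.99), w_AA=st.floats(0.05, 0.95),
       w_aa=st.floats(0.05, 0.95))
def test_ha_converges_to_equilibrium(p0, w_AA, w_aa):
    """With both homozygotes disfavoured, iteration from any interior
    start converges monotonically toward the overdominance point."""
    params = HAParams(w_AA, w_aa)
    p_hat = equilibrium_ha(params)[0]
    traj = iterate("HA", params, p0, 2000).p_values
    gaps = [abs(p - p_hat) for p in traj[1:]]
    assert gaps[-1] < 1e-5
    assert all(g2 <= g1 + 1e-12 for g1, g2 in zip(gaps, gaps[1:]))


@settings(max_examples=50, derandomize=True)
@given(p0=st.floats(0.01, 0.99), a=st.floats(1.1, 2.0),
       frac=st.floats(0.0, 1.0))
def test_fd_converges_to_equilibrium(p0, a, frac):
    # slope drawn so the colour fitness stays positive over all of
    # [0, 1] (a + b > 0): the trajectory never hits the clamping floor
    b = -(1.05 + frac * (a - 1.07)) if a > 1.07 else -1.0
    assume(a + b > 0.02 and b < 0)
    params = FDParams(a, b)
    P_star = equilibrium_fd(params)
    if P_star is None:
        return
    traj = iterate("FD", params, p0, 3000).P_values
    assert traj[-1] == pytest.approx(P_star, abs=1e-4)


def test_ds_is_nested_in_ha_by_fitness_rescaling():
    """Relative fitnesses only matter up to scale: DS with fitnesses
    (w, w, 1) equals HA with (1, 1, 1/w), so DS is a one-parameter
    submodel of HA."""
    for p in (0.1, 0.5, 0.9):
        for w in (0.5, 0.9, 1.1):
            assert step_directional(p, DirectionalParams(w)) == pytest.approx(
                step_ha(p, HAParams(1.0, 1.0 / w)), abs=1e-14)
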