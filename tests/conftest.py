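"""Shared fixtures: small deterministic series and simulated data."""

import numpy as np
import pytest

from morphsel.core_models import DirectionalParams, iterate
from morphsel.likelihood_fit import SampleSeries
from morphsel.synthetic_data import SimConfig, simulate_wf

OCCASIONS = (0, 2, 4, 6, 8, 10, 12, 14, 16, 18, 21)


def child_seeds(master: int, n: int) -> list[int]:
    """Deterministic 31-bit child seeds from a master seed."""
    return [int(s.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
            for s in np.random.SeedSequence(master).spawn(n)]


def wf_series(regime, params, seed, N=1500, n_sample=200, p_src=0.024,
              lam=1.0, occasions=OCCASIONS):
    """One simulated population under the default experimental design."""
    cfg = SimConfig("sim", "white", regime, params, p_src, lam,
                    max(occasions), (N,) * max(occasions), occasions,
                    (n_sample,) * len(occasions), seed)
    return simulate_wf(cfg)


@pytest.fixture(scope="session")
def declining_series() -> SampleSeries:
    """A noise-free decline generated by directional selection (w=0.9)
    from p0=0.3, rounded to counts of 10^6 — effectively exact."""
    traj = iterate("DS", DirectionalParams(0.9), 0.3, 21)
    n = 10 ** 6
    counts = tuple(round(traj.P_values[y] * n) for y in OCCASIONS)
    return SampleSeries("exact", "white", OCCASIONS, counts,
                        (n,) * len(OCCASIONS))


@pytest.fixture(scope="session")
def noisy_ds_series() -> SampleSeries:
    """One stochastic population under selection s=0.1 at the default
    design scale (N=1500, n=200)."""
    return wf_series("DS", DirectionalParams(0.9), seed=20260925).series
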