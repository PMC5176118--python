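# morphsel

Maximum-likelihood analysis of colour-morph frequency time series in
perturbed snail populations.

Conspicuous shell colours (white, red, banded) persist at low frequency in
populations of the marine snail *Littorina saxatilis* even though they should
be easy prey for visual predators. When isolated populations are re-founded
with a conspicuous morph pushed to ~50% and then followed for ~20 annual
generations, the trajectory of its decline carries information about *why*
the morph is normally rare: pure drift, recurrent immigration from
normal-frequency populations, constant selection against the colour, or some
form of balancing selection that would keep it polymorphic. This package
implements the full inference pipeline for such perturbation time series,
plus a Wright–Fisher simulator so every stage can be exercised on synthetic
data with known truth.

## Models

Each colour is a one-locus, two-allele system with the colour allele A
dominant: at allele frequency *p*, the conspicuous phenotype has frequency
*P* = 1 − (1 − *p*)² under Hardy–Weinberg proportions. Four per-generation
recursions are fitted (generation time one year, non-overlapping):

- **M (migration)** — *p*ₜ₊₁ = *m·p*_eq + (1 − *m*)*p*ₜ, with the source-pool
  frequency *p*_eq estimated from populations where the morph was not
  manipulated;
- **DS (directional selection)** — fitness *w*(colour) for AA and Aa against
  *w*(aa) = 1; selection coefficient *s* = 1 − *w*;
- **HA (heterozygote advantage)** — genotype fitnesses *w*(AA), 1, *w*(aa);
  protected polymorphism iff both homozygote fitnesses are below 1, with
  equilibrium *p̂* = (1 − *w*aa) / (2 − *w*AA − *w*aa);
- **FD (negative frequency dependence)** — colour fitness *a* + *bP*
  declining with its own phenotype frequency; stable equilibrium
  *P** = (1 − *a*)/*b* when *a* > 1 and *b* < 0.

Observed counts *k*ₜ of the focal morph out of *n*ₜ scored snails are
binomial around the predicted *P*ₜ; parameters (including the starting allele
frequency *p*₀) are estimated by minimising −2 log *L* with multi-start
bounded L-BFGS-B, confidence intervals come from the profile likelihood, and
models are compared by likelihood-ratio tests (nested) or AIC, with
sequential Bonferroni (Holm) correction across repeated tests. A separate
drift test regresses each sample's frequency on the previous one (logit
scale, binomial GLM) against the null of slope 1 and intercept 0; a slope
below 1 implies a stable equilibrium where the regression crosses the
no-change line, at inverse-logit(intercept / (1 − slope)).

## Worked example

```python
from morphsel.core_models import FDParams, HAParams, equilibrium_fd, equilibrium_ha
from morphsel.drift_test import inferred_equilibrium
from morphsel.model_compare import delta_aic, nm_from_rate

# where does a fitted transition regression predict the morph will settle?
print(round(inferred_equilibrium(-0.180, 0.812), 3))   # 0.277
print(round(inferred_equilibrium(-0.324, 0.707), 3))   # 0.249

# balancing-selection equilibria implied by fitted parameters
print(round(equilibrium_fd(FDParams(1.03, -0.42)), 4)) # 0.0714  (~7%)
print(round(equilibrium_ha(HAParams(0.30, 0.93))[1], 4))  # 0.1736 (~17%)

# migration vs directional selection (both 2-parameter models), by AIC
print(delta_aic(104.3, 2, 117.7, 2))  # -13.4 (migration preferred)

# migrants per generation implied by m = 0.07 at census N = 1500
print(nm_from_rate(0.07, 1500))       # 105.0
```

The first two numbers say that populations with transition slopes below 1
are heading for equilibria near 25–28% of the conspicuous morph; the FD and
HA equilibria show what the fitted balancing-selection parameters imply
(7% and 17%); the ΔAIC of −13.4 means migration beats constant selection
decisively for that population; and a 7% immigration rate at census 1500
would require an implausible 105 immigrants every generation.

## Analysis scripts

The `analysis/` drivers run the pipeline end to end on synthetic data and
write tables to `results/`:

```sh
python analysis/01_simulate.py        # 8-population synthetic experiment
python analysis/02_drift_test.py      # drift-rejection table
python analysis/03_fit_models.py      # model fits + comparisons (report tables)
python analysis/04_recovery_study.py  # estimator behaviour over replicates
python analysis/05_published_checks.py
```

There is also a CLI: `morphsel simulate --preset paper --seed 42 --out d/`,
`morphsel fit d/counts.csv --focal-morph White-1=white ... --out out/`, and
`morphsel drift-test d/counts.csv --focal-morph Red-1=red --out out/`.

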