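# isofeed

Stable-isotope indicator traits for feed efficiency in family-tank
aquaculture designs: simulation, phenotype derivation, genomic
relationship matrices, bivariate REML and predictive tank regression.

## The problem

Selective breeding for feed efficiency needs individual phenotypes, but
when fish are communally fed, feed conversion ratio (FCR = feed intake
per unit gain) can only be recorded per tank.  Feeding a diet enriched
in ¹⁵N and ¹³C for a fixed window lets each fish report its own
metabolism: the atom percent excess (APE) of a tissue over its
pre-experiment baseline is proportional to the fraction of nutrients
newly deposited during the window.  Per gram of gain this gives
individual indicator ratio traits

```
IFCR = FW · APE / (FW − IW)        IFER = 1 / IFCR
```

(FW, IW: final and initial weight).  Fish that exchange a larger share
of body mass per gram grown are less feed-efficient.  The package is
for quantitative geneticists who want to evaluate such indicator traits
in a family-tank design: it derives the traits, builds VanRaden's
genomic relationship matrix **G** and its tank-level analogue
**G_T = TT′** (tank-mean genotype deviations, scaled to mean diagonal
1), estimates heritabilities (h², h_t²), tank fractions (c²) and
genetic correlations with bivariate REML, and quantifies how much
tank-mean indicator traits improve leave-one-out prediction of tank FCR
(PRESS, R̂² = 1 − PRESS/SS_tot, backward elimination).  A
synthetic-data generator with known genetic architecture stands in for
the unreleased fish data, so every estimator is validated by parameter
recovery.

## Worked example

```python
import numpy as np
from isofeed import (SimulationConfig, simulate_genotypes, simulate_phenotypes,
                     derive_phenotypes, tank_g, vanraden_g,
                     ModelSpec, reml_fit, ratio_estimates, correlations)

cfg = SimulationConfig(n_families=10, n_fish_per_tank=20, n_snps=2000, seed=2024)
geno = simulate_genotypes(cfg)
ind, tanks, truth = simulate_phenotypes(geno, cfg)
ind, tanks, counts = derive_phenotypes(ind, tanks)
print(counts["total_missing"])          # 3  (growth filters: RG < 6.4% or > 49%)
print(round(tanks["fcr"].mean(), 3))    # 0.687

g  = vanraden_g(geno)                   # individual VanRaden GRM
gt = tank_g(geno, dict(zip(ind.fish_id, ind.tank)))
print(np.diag(gt.values).mean())        # 1.0  (exact, by construction)

fit = reml_fit(ModelSpec("wg", level="individual"), ind[~ind.growth_missing], g)
print(ratio_estimates(fit).round(3))    # h2 ~ 0.40, c2 ~ 0.09 (true 0.45 / 0.06)

pair = reml_fit(ModelSpec("fcr", "mean_rg", level="tank"), tanks, gt)
print(round(correlations(pair)["r_genetic"], 2))   # -0.65: faster-growing
                                                   # families convert feed better
```

The printed numbers come from the bundled analysis configuration
(`analysis/config.yaml`); the estimated heritability of weight gain
(0.40) and the negative tank-level genetic correlation between FCR and
mean relative gain (−0.65) recover the architecture the generator was
configured with.

The same chain runs from the shell:

```
isofeed all --config analysis/config.yaml --seed 2024 --out run/
# or stage by stage: isofeed simulate|derive|grm|fit|regress --out run/
```

and as numbered drivers, `analysis/01_simulate.py` …
`analysis/06_parameter_recovery.py`, each writing summary tables under
`results/`.

## Layout

```
src/isofeed/      library: simulate, isotopes, grm, reml, regression,
                  recovery, pipeline, cli
analysis/         numbered narrative drivers over the library
tests/            pytest suite (unit, property, acceptance)
scripts/          acceptance.py
docs/methods.md   model, assumptions, numerical choices, limitations
```
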