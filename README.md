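# charr-gsi

Genetic stock identification (GSI) for coastal fish metapopulations —
baseline construction, reporting-group design, self-assignment and
simulation-based power evaluation, Bayesian mixed-stock fishery analysis,
and spatial movement analysis against tag–recapture data. The package is
organised as an analysis project: the estimators live in the library
(`src/charr_gsi/`), and numbered drivers under `analysis/` run the study
on a fully synthetic dataset with known ground truth.

## Who this is for

Fisheries geneticists and quantitative ecologists who need to answer: can
individual rivers be told apart from multilocus genotypes; which rivers
must be pooled into reporting groups; what does each group contribute to
a mixed-stock coastal harvest; and how far from home are fish caught?

## The model

Assignment rests on the conditional Dirichlet-multinomial genotype
likelihood. Against a collection with allele counts *y* and total *n* at a
locus with *A* alleles (prior ξ_a = 1/A):

    P(a,b | y) = 2 (y_a + ξ_a)(y_b + ξ_b) / ((n+1)(n+2))     a ≠ b
    P(a,a | y) = (y_a + ξ_a)(y_a + ξ_a + 1) / ((n+1)(n+2))

summed in log over non-missing loci. Self-assignment is leave-one-out
(an individual's alleles are removed from its own collection's counts
first). Mixed-stock proportions π follow the Gibbs sampler
z_i | π ∝ π_c·P(g_i | c), π | z ~ Dirichlet(1/C + counts), with baseline
counts fixed, equal-tailed 95% credible intervals, and units excluded
when their interval encompasses zero. Around this core: Weir–Cockerham θ
(ratio-of-sums over loci), Cavalli-Sforza & Edwards chord and Nei
distances, neighbour joining with locus bootstrap, PCoA, F_ST-ranked
LD-pruned SNP panel selection with a train/holdout split, an iterative
reporting-group collapse rule (accuracy < 50% → merge with the NJ-sister
group within 15 km least-cost shore distance), Dijkstra least-cost marine
distances over a land/sea raster, and OLS regressions for drainage-area
and tagging-distance relationships. See `docs/methods.md` for details and
defaults.

## Worked example

Generate a two-region baseline, check differentiation, and recover a
fishery mixture:

```python
import numpy as np
from charr_gsi import (ScenarioConfig, allele_counts, fit_mixture,
                       generate_baseline, generate_mixture, wc_fst)

cfg = ScenarioConfig(n_regions=2, pops_per_region=(1, 1), f_region=0.15,
                     f_pop=0.0, n_loci_msat=100, inds_per_collection=50,
                     missing_rate=0.02, seed=1001)
baseline, sites, truth = generate_baseline(cfg)
print(round(wc_fst(allele_counts(baseline), "global"), 3))

mix, labels = generate_mixture(truth, {"P01": 0.7, "P02": 0.3}, 500,
                               seed=2001, exact=True)
est = fit_mixture(baseline, mix, iterations=2000, burn_in=200, seed=3001)
for u, m, lo, hi in zip(est.units, est.mean, est.ci_low, est.ci_high):
    print(f"{u}: {m:.3f} [{lo:.3f}, {hi:.3f}]")
```

prints

```
0.17
P01: 0.700 [0.660, 0.738]
P02: 0.300 [0.262, 0.340]
```

— realized θ near the configured 0.15, and the posterior mean of the
mixing proportions within a few thousandths of the true (0.7, 0.3) with
truth inside both 95% intervals.

## The analysis

Run the drivers in order from the repository root; each prints what it
found and writes tables under `results/`:

1. `analysis/01_simulate_study.py` — synthesise the study (28 rivers in 5
   coastal regions, ~100 microsatellites, 9 fishery mixtures, tagging
   records) and write all on-disk inputs (Genepop, sample tables, site and
   tag CSVs, coast raster).
2. `analysis/02_population_structure.py` — per-locus and pairwise θ,
   bootstrapped NJ trees (Newick), PCoA coordinates.
3. `analysis/03_reporting_groups.py` — leave-one-out self-assignment
   accuracy/efficiency, 100% simulations, and the iterative collapse of an
   engineered scenario from 28 collections to 25 reporting groups.
4. `analysis/04_panel_selection.py` — F_ST-ranked, LD-pruned SNP panels
   and holdout accuracy versus panel size.
5. `analysis/05_mixed_stock.py` — per-fishery mixture posteriors with the
   CI-excludes-zero rule, the fraction of assigned fish originating within
   200 km, and the drainage-area regression.
6. `analysis/06_tagging.py` — least-cost tag–recapture distances, the
   count-versus-distance regression, and per-stock homing percentages.

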