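# Methods

This package re-creates, end to end, a genetic stock identification (GSI)
workflow for a coastal fish metapopulation: building a reference baseline
of river populations, deciding which rivers can be told apart (and pooling
the ones that cannot), estimating the composition of mixed-stock fishery
catches, and comparing the spatial scale of genetic assignments with
tag–recapture data. All analyses run on synthetic data with known ground
truth; this note records the models, the defaults and why, and what the
synthetic results do and do not establish.

## Genotype likelihood

The assignment engine scores a diploid multilocus genotype against a
collection's allele counts with the conditional Dirichlet-multinomial
(posterior-predictive) model. At a locus with A alleles, counts y and
total n in the collection, with a per-allele prior ξ_a = 1/A (prior total
1):

    P(a, b | y) = 2 (y_a + ξ_a)(y_b + ξ_b) / ((n + 1)(n + 2))      a ≠ b
    P(a, a | y) = (y_a + ξ_a)(y_a + ξ_a + 1) / ((n + 1)(n + 2))

These probabilities sum to one over all unordered genotypes in the
registry (a property test asserts this). Log-likelihoods sum over
non-missing loci; a missing genotype contributes nothing (likelihood 1),
the standard conditional-GSI treatment. Alleles seen only in a query are
added to the registry with zero baseline count and scored on the prior
alone.

Self-assignment is leave-one-out: before scoring an individual against
its own collection, its two allele copies are subtracted from that
collection's counts. A table-wide invariant test checks that leave-one-out
self-support never exceeds the plug-in value.

## Mixed-stock model

Mixing proportions π over collections are estimated by Gibbs sampling:
latent origins z_i | π are categorical with probability ∝ π_c P(g_i | c),
then π | z ~ Dirichlet(1/C + counts). Baseline counts stay fixed — the
mixture never feeds back into the allele frequencies. Defaults are 20,000
sweeps with 1,000 burn-in, one chain, with an effective-sample-size
warning below 200. Reporting-unit proportions are member sums per sweep;
intervals are equal-tailed 2.5/97.5% quantiles of the post-burn-in trace.
A unit is "included" when its lower bound clears 1/(2·mixture size),
because a Dirichlet posterior never touches exactly zero.

## Population-genetic statistics

* **θ (F_ST)** is the Weir–Cockerham variance-components estimator in its
  two-level allele-based form (populations / gametes): genotypes are
  treated as random unions of gametes, so within-individual components are
  not estimated. Multi-locus, global and pairwise values are ratios of
  summed components, never means of per-locus ratios. Values are not
  clamped (slightly negative estimates are informative). Tests compare it
  to an independently coded indicator-variable ANOVA at 1e-12.
* **Chord distance** uses the convention
  D = √((2/L) Σ_l (1 − cos θ_l)), cos θ_l = Σ_a √(p1 p2). Packages differ
  in the constant; it does not affect NJ topology. Cosine deficits below
  1e-12 are snapped to zero so identical frequency vectors give exactly
  D = 0.
* **Nei's standard distance** D = −ln(J12 / √(J1 J2)) with the J terms
  averaged over loci; pairs sharing no alleles get +inf with a warning.
* **Neighbour joining** is the Saitou–Nei Q-criterion agglomeration with a
  deterministic tie-break (lowest index pair) and negative branch lengths
  clamped to zero with a note on the node. On additive matrices it
  reproduces topology and path lengths exactly (property-tested against a
  random-tree oracle and scikit-bio's implementation).
* **Bootstrap supports** resample loci (not individuals) with
  replacement; supports are the percentage of replicate trees containing
  each internal bipartition of the point-estimate tree.
* **PCoA** Gower-centres −D²/2 and eigendecomposes; axes with
  non-positive eigenvalues are dropped but the full spectrum is reported.
* **LD** is the squared Pearson correlation of allele dosages (composite
  genotypic LD) — no phasing, as appropriate for unphased diploids.

## Panel selection and reporting-group revision

SNP panels are built on a stratified, seeded 33% training split: loci are
ranked by training-set global θ, loci below 0.05 are dropped, and a greedy
scan admits loci whose training r² with every already-selected locus is at
most 0.2, stopping at the requested size or exhaustion. Holdout
individuals never inform selection; power is scored as holdout
leave-one-out assignment accuracy. With the LD ceiling at 1 the procedure
reduces to plain rank truncation (tested).

Reporting groups start as one per river and are revised iteratively: run
leave-one-out self-assignment, compute per-group accuracy (correct /
assigned, at a configurable probability threshold, default 0.5), and for
groups below 50% accuracy merge with a partner that is both the group's
cherry in the NJ tree built from the current grouping's chord distances
*and* within 15 km least-cost shore distance (minimum over member river
sites). One merge per round, lowest-accuracy group first, metrics rebuilt
between merges; the tree is rebuilt every round. The loop stops when all
groups clear the floor, no eligible merge remains, or a round cap is hit.
"Minimum accuracy" is read in its weakest consistent sense — iterate until
every group clears the floor or nothing eligible remains — and both
thresholds are configurable. The merge history is stored and replayable;
a test asserts replay reproduces the final map.

## Spatial machinery

Least-cost marine distances run over the sea cells of a land/sea raster:
8-connected, orthogonal steps cost one cell edge and diagonals √2 of it
(4-connectivity by flag). Sites snap to the nearest sea cell with
row-major tie-breaking; latitude/longitude convert to cell coordinates by
local equirectangular scaling at the grid's mean latitude, which is
adequate at study-area scale (hundreds of km). Dijkstra on a sparse graph
does the work; tests compare it against Bellman–Ford relaxation and
bounded path enumeration, and check the triangle inequality.

Fishery geography keeps individuals assigned to a reporting unit with
posterior probability above 0.8 and reports the fraction whose origin lies
within 200 km of the fishery (per fishery, pooled, and pooled after
excluding listed fisheries). The drainage regression pools
(area, within-fishery proportion) points from fisheries with more than two
contributing units and fits OLS; regression p-values come from the F test
(equivalently the slope t test), with no multiple-testing correction. The
tagging analysis produces one record per (stock, recapture site), a pooled
OLS of recapture count on least-cost distance, and per-stock percentages
of recaptures within the tagging region.

## Synthetic study generator

The generator is hierarchical Dirichlet drift, chosen over coalescent
simulation because it parameterises differentiation directly and is fast
to verify: ancestral frequencies per locus (symmetric Dirichlet for
microsatellites; uniform minor-allele frequency in [0.05, 0.5] for SNPs),
regional frequencies ~ Dirichlet(p·(1−F_region)/F_region), river
frequencies ~ Dirichlet(p_region·(1−F_pop)/F_pop). For a Dirichlet with
parameter a·p the standardised frequency variance is 1/(a+1) = F, so the
two levels set the expected θ directly; F = 0 copies frequencies exactly.
Genotypes are random unions of gametes; missingness is uniform per
genotype.

Defaults are the study conditions, fixed once:

| parameter | default | rationale |
|---|---|---|
| collections / regions | 28 in 5 (6,6,6,5,5) | study design |
| F_region / F_pop | 0.06 / 0.05 | cross-region pairwise θ ≈ Fr+(1−Fr)Fp ≈ 0.10 |
| per-locus drift spread | log-uniform ×[1/2.2, 2.2] | realizes per-locus θ ≈ 0.02–0.33 |
| microsatellite alleles | 3 + Poisson(4.3), clamped 3–15 | mean ≈ 7.3 per locus |
| individuals / collection | 30 | ~900 baseline fish desk-scaled |
| missing rate | 0.02 | typical panel dropout |
| river spacing | 40 km (6 km within clusters) | coastal scale; <15 km merge gate |
| dispersal kernel | exp(−d/60 km) | recaptures mostly within ~100 km |

Engineered scenarios add exactly-panmictic clusters (members share
frequencies) and "satellite" populations drifted weakly (F ≈ 0.02) from a
cluster's frequencies but placed beyond the 15-km gate. The satellites
matter: a clean two-member panmictic pair does not reliably fall below 50%
assignment accuracy (leave-one-out creates no systematic tilt, and the
fish that do assign confidently are enriched for correct calls), whereas
leaky neighbours drag the whole confusable neighbourhood below the merge
trigger — the mechanism behind regionally paraphyletic river clusters in
real baselines. Controlled experiments that state a single F (the
two-collection mixture recovery, the engineered collapse, divergence
sweeps) pin the per-locus spread to 1.

Mixture composition is multinomial by default; recovery experiments use
exact largest-remainder apportionment (`exact=True`) so that the measured
error is the estimator's, not the ±0.02 binomial noise of a 500-fish
composition draw. Tagging records choose recapture sites with probability
∝ effort × exp(−d/scale) and a Bernoulli recapture indicator.

What the generator does *not* emulate: family structure and relatedness,
linkage between loci, stepwise microsatellite mutation, ascertainment bias
of SNP panels, hybridisation, unsampled populations, and spatially
structured genotyping failure. Passing tests therefore demonstrate that
the estimators recover the truth of this drift model at study scale — not
that real-data accuracy would match; on clean HWE baselines with ~100
independent multiallelic loci, self-assignment saturates near 100%,
noticeably above what real baselines achieve.

## Problem sizes used by tests and the acceptance script

Simulation sizes are chosen at desk scale: mixture recovery uses 20
replicates of 500 fish against 50-fish-per-collection baselines with
2,000 sweeps; the collapse scenario uses 28 collections × 50 fish at 60
loci; panel power uses a 2,000-SNP, 12-collection baseline (36
fish/collection) with panels of 100–1,000 loci; the 100% simulations in
the acceptance script use 10 replicates of 50 fish. The analysis drivers
run the full-size settings (1,000 bootstrap replicates, 20,000 MCMC
sweeps).

## Numerical choices and degenerate inputs

Ties in MAP assignment break to the lowest collection index; NJ Q-ties to
the lowest index pair; site snapping ties row-major. Likelihoods are
computed in log space with per-row max subtraction before normalisation.
Monomorphic loci contribute 0/0 to θ and are skipped from the sums;
all-missing loci are dropped with a warning; empty groups are excluded
from distances with a warning; a Genepop write refuses allele codes wider
than the digit format and an empty table. Genepop carries no
reporting-unit concept, so the reader accepts an optional collection→unit
map (sidecar convention).

## Known limitations

Single-chain MCMC without cross-chain diagnostics (ESS warning only); the
fixed-baseline mixture posterior is slightly overconfident when the
baseline itself is small (coverage ≈ 92% at 50 fish/collection, ≈ 96% at
150 in probe runs); the collapse procedure is greedy and order-dependent
by design (it mirrors a sequential revision protocol, with the order
fixed and recorded); least-cost paths may cut corners diagonally between
two touching land cells; the equirectangular projection degrades far from
the grid's mean latitude.
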