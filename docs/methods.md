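# Methods

This note documents the models, conventions and numerical choices behind
`turtur`. It describes what the code computes and why the defaults are what
they are; every empirical number quoted here is produced by the test suite
or by `scripts/acceptance.py`.

## Demographic model

All inference is for a single panmictic population whose diploid effective
size `Ne(t)` is piecewise constant in time, measured in generations before
present (generation time 1 year for the turtle dove, configurable). Five
competing scenarios are compared:

| id | epochs (present → past) | interpretation |
|----|--------------------------|----------------|
| 1  | `N3` | constant size |
| 2  | `N3`, `N2` at `t1` | single change (growth toward the present) |
| 3  | `N3`, `N1` at `t1` | single change (decline toward the present) |
| 4  | `N3`, `N1` at `t1`, `N2` at `t2` | Holocene expansion then recent contraction |
| 5  | scenario 4 plus `N4` (≡ `N1`) beyond `t3` | adds a large last-interglacial epoch |

Scenario 4 encodes the biologically motivated history: a small
late-Pleistocene population (`N2`), a strong early-Holocene expansion to
`N1` at `t1`, and a recent contraction to the present size `N3`. Scenario 5
asks whether the data additionally support a large population during the
last interglacial; `t3` is fixed at 130 kyr, the midpoint of that period,
because the parameter is a boundary marker rather than a quantity of
interest. The scenario topologies are configuration data
(`SCENARIO_TOPOLOGIES`), so alternative variants can be tested without code
changes.

### Priors

Priors are truncated normals (lower bound 10 individuals/years, so that
degenerate non-positive draws are impossible) with ordering constraints
`t1 < t2 < t3` enforced by rejection sampling — rejection rather than
clipping preserves the normal shape on the feasible region. Defaults:

| parameter | prior | units |
|-----------|-------|-------|
| `N1` (= `N4`) | N(3.0e6, 1.0e6) | diploid individuals |
| `N2` | N(1.0e5, 5.0e4) | diploid individuals |
| `N3` | N(2.0e5, 1.0e5) | diploid individuals |
| `t1` | N(7.6e3, 2.0e3) | years |
| `t2` | N(7.8e4, 2.0e4) | years |
| `t3` | fixed 1.3e5 | years |

The means are centred on the mitochondrial-skyline-informed values that the
original analysis used to inform its priors; the standard deviations are
broad enough that the posterior-mean parameter vector sits well inside
every marginal. A configuration file (`PriorSpec.from_yaml`) can override
any of them, including the `N4 ≡ N1` tie.

A rejection cap (10,000 redraw rounds) turns an infeasible constraint
region into an explicit error instead of silent truncation.

## Coalescent simulation

The simulator is a standard n-coalescent with piecewise-constant size:
with `k` lineages in an epoch of diploid size `N`, the waiting time to the
next coalescence is exponential with rate `k(k-1)/2 / (s·N)` per
generation, where `s` is the ploidy scale (2 gene copies per diploid for
autosomal loci; 0.25 for mtDNA, i.e. an effective size of `N/4` for a
haploid, maternally inherited locus — the conventional expectation, and a
configurable scale factor). Epoch boundaries are handled by the
time-rescaling construction: in rescaled time `dτ = dt/(s·N(t))` the
inter-event times are iid `Exp(k(k-1)/2)`, and event times in generations
are recovered through the piecewise-linear inverse map.

Two routes sample the same process:

* **Explicit genealogies** (`simulate_genealogy`) with uniformly random
  topology, used for mtDNA alignments and for validation against closed
  forms (`E[T2] = 2N`, `E[S] = a1·θ`) and against an independent
  coalescent simulator (msprime) in the tests.
* **A vectorised frequency route** (`simulate_locus_counts_batch`) that
  never builds topologies: it samples event times for thousands of loci at
  once, places the retained mutation in an interval with probability
  proportional to `k × interval length`, and draws the derived-allele
  count from the exact distribution of the number of descendants of one of
  `k` exchangeable ancestors, `P(i | k) = C(m-i-1, k-2)/C(m-1, k-1)` for a
  sample of `m` copies. Assigning carriers uniformly at random then
  reproduces the genotype distribution of the explicit route for unlinked
  loci (exchangeability); a two-sample KS test between the two routes is
  part of the suite. This is what makes reference tables of 2.5 × 10⁴
  simulations a minutes-scale desk computation.

### Mutation models

SNP loci use a rate-based scheme: the number of mutations on a genealogy is
Poisson(`u_locus` × total branch length) with `u_locus = 2.5e-7` per locus
per generation by default (≈ 115 bp of RAD locus at ~2.2e-9 per site per
generation). Loci with zero mutations are monomorphic; polymorphic loci
retain exactly one mutation (uniform over branch length), mirroring the
one-SNP-per-locus filtering of the RAD data. A rate-based scheme rather
than a fixed one-mutation scheme keeps the "proportion of monomorphic
loci" statistic informative, which matters because the observed data
contain monomorphic RAD loci.

mtDNA alignments use a strict clock of 2.1 %/Myr interpreted as a
divergence (between-lineage) rate — the conventional reading of the avian
cytochrome-b calibration — so the per-lineage rate is 1.05e-2
substitutions/site/Myr. Mutations are Poisson on branches, each hitting a
uniformly random site (finite sites; repeat hits resolved
last-mutation-wins). At the θ values relevant here multiple hits are rare
and the model is effectively infinite-sites.

Missing genotypes are injected independently per call at a configurable
rate. The default for pseudo-observed data is 0.10, half the 20 %
per-locus cap that the study's filtering allowed, as a realistic
genome-wide average; the same rate is used in reference-table simulations
so observed and simulated statistics are computed under the same
missingness regime.

## Summary statistics

SNP statistics are the four single-population summaries the ABC
conditions on: proportion of monomorphic loci, mean and (unbiased)
variance of gene diversity across polymorphic loci, and mean gene
diversity across all loci. Gene diversity is Nei's unbiased estimator
`H = n/(n-1)(1 - Σ p_i²)` with `n` the non-missing gene copies at the
locus, which makes the statistic robust to per-locus missingness. A locus
is monomorphic iff one allele has frequency 1 among non-missing copies.
Datasets with fewer than two polymorphic loci leave the across-locus
variance undefined and are flagged degenerate (and dropped from reference
tables, with a logged count).

mtDNA statistics follow the classical sequence-tool conventions: complete
deletion of any alignment column containing a gap or ambiguity code before
anything is counted (a pairwise-deletion variant of π is available behind
a flag, since small convention differences can shift the third decimal of
published values); `S` = columns with more than one base; haplotypes =
distinct sequences over retained columns; `Hd` is gene diversity over
haplotype classes; `π_total` = mean pairwise differences, `π = π_total /
retained length`.

Tajima's D uses the standard constants (`a1, a2, b1, b2, c1, c2, e1, e2`
with sums to `n-1`); `S = 0` raises a distinguished no-segregation error
rather than returning a silent NaN. Fu's Fs is the logit of
`S' = P(K ≥ k_obs)` under the Ewens sampling formula with `θ = π_total`
(Fu's 1997 convention); unsigned Stirling numbers of the first kind are
evaluated in log space via the recurrence
`|s(n,k)| = |s(n-1,k-1)| + (n-1)|s(n-1,k)|`, and both tails are formed in
log space so the statistic is stable at `n = 95` where the raw Stirling
numbers overflow any fixed-precision type. `S'` numerically 0 or 1 yields
signed infinity with a warning flag. The engine is checked against an
exact rational-arithmetic oracle for all `n ≤ 8`.

Significance of D and Fs is estimated by constant-size coalescent
simulation with `θ̂ = π_total` (the procedure the classical tools actually
perform under the name "permutations", which the CLI flag keeps); `p` is
the lower-tail fraction `(1 + #{null ≤ observed})/(R + 1)`, both tests
being signed toward expansion. Calibration under the null (`n = 50`,
`θ = 5`): |mean D| < 0.15 and |mean Fs| < 0.6 over 1,000 replicates, as
verified in the suite.

## ABC inference

The reference table holds, per simulation, the scenario id, the parameter
draw and the four statistics, with equal allocation across scenarios.
Distances are Euclidean after standardising each statistic by its
reference-table standard deviation; zero-variance statistics are excluded
with a warning.

* **Direct (rejection) model choice**: the posterior probability of a
  scenario is its frequency among the accepted closest fraction (default
  tolerance 0.1 %); the 95 % CI is a nonparametric bootstrap (1,000
  resamples) over accepted rows — the bootstrap is this package's choice
  of CI construction, made explicit because rejection frequencies have no
  canonical closed-form interval.
* **Logistic model choice**: weighted multinomial logistic regression of
  scenario membership on the standardised statistics over the closest 1 %,
  with Epanechnikov weights in distance, evaluated at the observed point;
  the CI uses the weighted information matrix and the delta method for the
  softmax probabilities. Separation or non-convergence falls back to the
  direct estimate with a logged warning.
* **Parameter estimation**: Beaumont-style local-linear adjustment on
  log-transformed parameters (log is the natural scale for sizes and
  times, and keeps adjusted draws positive), Epanechnikov-weighted; the
  fitted trend is subtracted so each accepted draw is translated to the
  observed point, and summaries (mean, median, 2.5 %, 97.5 %) are weighted
  statistics of the back-transformed sample. Rank-deficient regressions
  fall back to the unadjusted rejection posterior with a warning; fixed
  parameters (zero prior variance) are reported as point masses.
* **Goodness of fit**: PCA of the standardised reference statistics; the
  observed point is projected and its distance to each scenario's centroid
  is ranked within that scenario's own distance distribution. All
  percentiles above 99 raise a poor-fit flag.

### Problem sizes

The study-scale run (10⁶ simulations per scenario) remains a configuration
value; the shipped defaults are desk-scale: reference tables of 5,000
simulations per scenario at 500 loci for model choice, and the `recover`
pipeline at 1,500 simulations per scenario, 300-locus tables against
1,000-locus pseudo-observed datasets of 50 diploids. At the reduced table
size the estimation tolerance is widened to 10 % so the regression
adjustment sees ~150 accepted draws; the model-choice tolerance stays at
1 %. These sizes were chosen so a complete model-choice recovery runs in
about a minute and a 20-replicate coverage experiment in minutes on one
core, while leaving the accepted-sample sizes large enough for stable
quantiles.

## Structure diagnostics

**AMOVA.** The Excoffier–Smouse–Quattro decomposition from squared
pairwise distances: for any set of units `SS = (1/n) Σ_{i<j} d²`, and the
nested levels (among groups / among populations within groups / among
individuals within populations / within individuals) give variance
components through the standard unequal-sample-size nested-ANOVA
coefficients. SNP data are expanded to gene copies with allele-mismatch
distances summed over pairwise-complete loci; heterozygous genotypes are
split into copies with an arbitrary phase, which is immaterial for every
sum of squares (each aggregates over all copy pairs) and serves as the
exchangeable-copy representation for the within-population copy
permutations. mtDNA runs the three-level haplotypic decomposition on
pairwise nucleotide differences over complete-deletion sites.

Permutation significance uses the level-appropriate schemes — whole
populations among groups (Φ_CT), individuals among populations within
groups (Φ_SC), gene copies among individuals within populations (Φ_IS);
`p = (1 + #{Φ* ≥ Φ})/(B + 1)`. Negative variance components are retained
(not truncated), matching the classical software, with a note attached to
the result. The identity `(1-Φ_IT) = (1-Φ_CT)(1-Φ_SC)(1-Φ_IS)` holds to
1e-9 on non-degenerate data and is asserted in the suite. Groups
containing a single population leave Φ_SC undefined and are reported as
such.

**PCA.** Missing genotypes are imputed with per-locus means, columns
centred (scaling optional), and the decomposition is by singular values;
coordinates and explained-variance fractions are returned.

## Synthetic data

`make_pseudo_observed` defaults to the study design — scenario 4 at the
reported posterior-mean parameters, 104 diploids × 2,954 unlinked loci,
10 % missingness. `make_structured_dataset` uses the Balding–Nichols model
(ancestral frequency Uniform(0.05, 0.95) — the bounds avoid
quasi-monomorphic loci that destabilise FST recovery — deme frequency
Beta-distributed at the requested FST, genotypes Binomial(2, p_deme));
Balding–Nichols was chosen over an island-model coalescent because its FST
is a closed-form input with no migration-rate ambiguity. Every generator
is a pure function of (configuration, seed), and the truth sidecar is
sufficient to regenerate a dataset bit-identically.

What the generators do *not* emulate: linked loci, the RAD
locus-discovery/ascertainment process beyond a flat missing-data rate,
sequencing error, or within-locus recombination. Passing tests therefore
demonstrate that the inference machinery is correct and calibrated for
unlinked, cleanly ascertained biallelic loci — not that those data
features are absent from real RAD datasets.

## Known limitations

* The per-scenario prior hyperparameters shipped as defaults are a
  reconstruction consistent with the published posterior and the stated
  prior sources; they are configuration, not ground truth.
* The logistic-regression CI is asymptotic; at small accepted counts the
  bootstrap CI of the direct method is the more honest interval.
* The within-individual AMOVA level assumes the arbitrary-phase copy
  expansion; with strong within-locus disequilibrium a haplotype-aware
  distance would differ.
* Fu's Fs p-values (and Fs itself) assume the Ewens formula's
  infinite-alleles haplotype process; finite-sites repeat hits at very
  high θ would bias the haplotype count downward.
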