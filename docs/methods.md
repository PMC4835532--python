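# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices and the known limitations of
`heatscan`.

## Trial design and adjustment cascade

The design is fixed throughout: six biparental populations from pairwise
crosses of four Dent (S058, S067, S070, P040) and four Flint (L043,
L017, L023, L012) inbreds, one population per alpha-lattice
subexperiment, two replications of six subexperiments per location, the
eight parents included once per subexperiment as standards, at two
standard-condition and two heat-condition locations. Conditions are
declared per location in the run configuration, never inferred from
temperatures; growing degree days (base 10 °C) are computed for
description and to pick the reference location (lowest GDD = least heat
stress).

Adjustment proceeds in four mixed-model stages, all REML:

1. **Standards model** (per location × trait): random standard and
   incomplete-block effects, fixed replication and
   subexperiment-within-replication effects under sum-to-zero
   constraints within each replication. The estimated subexperiment
   effects are subtracted from every plot. Sum-to-zero is required for
   the subtraction to be well defined; with one shifted subexperiment
   among k, least squares attributes δ(k−1)/k to it and −δ/k to the
   others, which still equalizes subexperiments after subtraction.
   Subexperiments without standard observations get effect 0 with a
   warning.
2. **Entry means per location**: fixed genotype and replication, random
   blocks. The AEM is the genotype marginal mean (intercept + sum-zero
   genotype effect). Standards are carried through as ordinary
   genotypes — their indices are needed downstream.
3. **Entry means per condition**: fixed genotype, location and
   replication-within-location (nested sum-to-zero coding), random
   blocks.
4. **Condition model over all locations**: fixed condition and
   location-within-condition; random replication, block, genotype,
   genotype × location and condition × genotype. The condition effect is
   Wald-F tested; the denominator df uses a containment-style
   approximation, (#conditions − 1) × (#genotypes − 1). Traits with
   P < 0.05 are flagged heat-dependent. Location marginal means from
   this model are the denominators of the ratio adjustment.

Missing plots are simply absent rows (no imputation). Negative variance
components cannot occur: ratios are optimized on a log scale and
truncated to zero at the boundary.

### REML engine

All models share one engine (`heatscan.mixed`): Henderson's mixed-model
equations assembled sparse, solved by LU factorization, with the
restricted likelihood profiled over the residual variance and maximized
over log variance ratios. Multi-component models use cyclic
coordinate descent with bounded 1-D searches; the trial models contain
nested random terms (blocks within replications, genotype within its
interactions) whose likelihood ridges derail simplex methods, while
coordinate descent converges reliably (verified against closed-form
ANOVA estimators on balanced layouts and by simulation recovery).
Entry means additionally have a `method="mean"` fast path — plain
genotype means of the adjusted observations — which coincides with the
mixed-model means on balanced complete layouts and is used inside
Monte-Carlo validation loops; the reference analysis path is REML.

## Heat-susceptibility index

For each heat-dependent trait, genotype and location entry means are
scaled by their reference-location values and the per-genotype ratios
are regressed (unweighted OLS, all four locations equally) on the
location-mean ratios; the slope is the HSI. Genotypes with fewer than
three usable locations, or a degenerate ratio vector, get a missing HSI
with a reason code — a two-point slope is noise. The flowering-adjusted
yield index is the OLS residual of HSI_DY on HSI_FF (zero mean,
uncorrelated with HSI_FF by construction). The PCA standardizes the
five HSI columns (their scales are incommensurate) and fixes signs so
the largest-|loading| trait of each component is positive.

## Heritability

Variance components for the population-specific summaries are obtained
by fitting the relevant model on that population's individuals alone.
Because each population occupies its own subexperiment, populations
share no blocks, so per-population subsetting is equivalent to a
heterogeneous-variance genotype-within-population term while being far
cheaper. The condition × population form uses
σ²g/(σ²g + σ²gl/U + σ²e/(U·E)) with U = 2 and E = 2; the per-location
form σ²g/(σ²g + σ²e/E) is its U = 1, σ²gl = 0 special case. Zero total
variance yields a missing value rather than 0/0.

## Synthetic-data generator

The generator is the package's test bed; its defaults *are* the study
conditions.

**Genotypes.** Each individual is built from two F1 gametes with
Haldane recombination along the map (crossovers independent across
intervals; the map function is a modeling choice — no interference)
followed by log2(1/het) generations of selfing tracked at the marker
loci: two generations (F3) for the default 25 % heterozygosity target.
Single-marker class frequencies are (3/8, 1/4, 3/8).

**Map.** 161 markers on 10 chromosomes (21, 19, 18, 19, 18, 13, 15,
14, 12, 12 per chromosome), chromosome spans proportional to marker
count and summing to 1823.5 cM, marker positions condensed toward
chromosome centers on the cM axis while physical positions spread —
emulating suppressed centromeric recombination with a monotone bp↔cM
relation.

**Phenotypes.** A genotype's expected value for trait *t* at location
*j* is

    (mu_t + P_i) * (1 + b_it * (m_tj - 1)) + gl_ij

with growth potential P_i ~ N(0, σ²g), location stress multiplier m_tj
(1 at the reference), susceptibility coefficient
b_it = 1 + QTL effects + polygenic deviation, and genotype × location
deviations gl_ij whose SD is larger under heat. Plot values add
replication, subexperiment, block and residual noise. This
multiplicative form makes the population mean track mu·m_j (so the
condition-effect test has power), makes the Finlay–Wilkinson slope of a
noise-free genotype exactly b_i, and gives susceptibility QTL a
first-order effect on the index. An additive form in which the stress
multiplier scales only the genetic value leaves location means almost
condition-independent and reduces QTL effects on the slope to second
order, so it cannot generate the phenomena the estimators are meant to
recover; the multiplicative form is the package's design choice.

A latent per-genotype heat-escape factor correlates the polygenic
susceptibility across traits (positive for the two flowering traits,
negative for yield), encoding the escape trade-off: genotypes that keep
flowering late under heat lose more yield. The male/female flowering
multipliers are tied so the anthesis-silking interval carries no
condition effect. Leaf scorching is generated on a latent scale and
discretized to the 1–9 score; dry yield is generated directly and the
field book stores fresh yield and grain moisture back-derived from it
so the trait-derivation code is exercised.

**Ground truth.** QTL are realized at their nearest mapped marker
(genotypes are tracked at marker loci only; the realized position is
reported). "True" entry means include the genotype × location
deviations — they are biology, part of what a multi-environment index
measures — but no design noise; the true HSI is the stability slope of
those entry means, which in the gl-free limit equals b_i analytically.
Recovery correlations therefore quantify robustness to design noise
only.

**Default magnitudes** were chosen once to give per-location
heritabilities in the high range for flowering and yield and low for
leaf scorching under standard conditions, condition-level
heritabilities visibly lower under heat (heat gl and residual SDs are
inflated), location-mean ratios of roughly 0.45–0.5 for yield and grain
moisture and 0.7 for flowering at the heat sites, susceptibility SDs of
0.08–0.25, and susceptibility QTL with homozygous contrasts of 0.2–0.4
— the size such loci show on ratio-based indices. Five loci are
planted: a yield/flowering pair with opposite-signed effects on
chromosomes 2 and 3 (with dominance in population 1), a flowering locus
on 8, a leaf-scorching locus on 9 and a grain-moisture locus on 5. At
these settings the leaf-scorching locus is usually below the
genome-wide threshold (score discretization costs power) — a realistic
outcome, not a target.

## QTL mapping

**Marker QC** removes markers with within-population allele frequencies
deviating from 1:1 (χ² goodness of fit, P < 0.001 in any population)
and markers monomorphic everywhere.

**Ancestry probabilities.** The F3 two-locus distribution is computed
by exact recursion over unordered haplotype pairs (10 states) through
two selfing generations; grid-point probabilities condition on the
nearest informative flanking markers through the resulting
genotype-to-genotype kernel, treating the chain as Markov along the
chromosome (exact at markers; validated against Monte-Carlo simulation
between them). Uninformative positions fall back to the (3/8, 1/4,
3/8) prior.

**Scan model.** Expected-design regression: probabilities enter as
expected allele doses rather than through a full mixture likelihood.
At ~11 cM marker density the information loss is small, and the choice
makes the scan exactly equal to two-model OLS at fully informative
markers — the engine's oracle test. The base model always contains
population intercepts (population mean differences are structure, not
QTL signal). The crossing scheme splits the eight parents into two
disjoint quartets; additive effects are therefore encoded sum-to-zero
within each connected component (6 free columns), which makes the
reported eight effects unique. Dominance is one coefficient per
population, weighted by the heterozygosity probability. Reported
additive effects are per allele.

**Thresholds and cofactors.** Phenotypes are permuted within
populations (preserving population means); the genome-wide max-F
distribution over 1000 permutations gives the 5 % threshold. Cofactors
are markers chosen by greedy forward selection at 90 % of the
threshold, minimum spacing 10 cM, ties broken to the lowest chromosome
and position. During a scan, cofactors within 10 cM of the tested
position are excluded from the base model.

**Detection loop.** Scan → declare peaks (local maxima above the
threshold, thinned so no two peaks lie within the spacing; peaks at
exactly the spacing distance are merged to the higher one, which
suppresses ghost peaks at the exclusion-window edge) → move cofactors
to the peaks → repeat until the peak set is stable, with peak drift
within the spacing window counted as stable; cycles return the last
iteration with a warning. Support intervals use the 1.5-LOD drop with
linear interpolation between grid points, clipped at chromosome ends,
computed from a scan conditioned on the *other* detected loci only (so
a locus' own cofactor cannot truncate its interval). Explained
variances come from a simultaneous fit of all loci over the
population-intercept baseline: total R² = 1 − RSS_full/RSS_base,
per-locus R² by sequential drop.

**Post-hoc tests.** Dominance coefficients get two-sided normal tests
(stars at 0.05/0.01/0.001); additive effects get all 28 pairwise
comparisons against the studentized range (k = 8, residual df) and an
insert-and-absorb compact letter display — parents sharing a letter are
not significantly different. Differences between parents in different
crossing-graph components are estimable only under the chosen
constraints; their comparisons inherit the minimum-norm covariance and
should be read as conventional.

## Candidate genes

Genes are projected by linear interpolation between the two bp-nearest
markers (interval genes by midpoint), extrapolated from the terminal
pair and flagged when outside the mapped range, clamped to the flanking
pair's cM range when a consensus-map inversion makes bp and cM order
disagree. Colocation uses closed intervals; hot spots are maximal
unions of overlapping support intervals per chromosome.

## Validation problem sizes

The test suite validates by parameter recovery at the following sizes,
chosen as the package's own verification settings: HSI recovery over
200 full-scale simulated studies (dry yield only in the loop); H²
recovery over 200 trials at 600 genotypes × 2 replications; permutation
threshold calibration over 200 null studies with 200 permutations each;
planted-QTL support-interval coverage over 100 studies at a
within-population R² of 15 %; plus one complete timed pipeline run.
Smaller layouts (6 × 15 individuals, 3 chromosomes) stand in wherever
full scale adds nothing.

## Limitations

- The generator models neither spatial field trends nor selection or
  mortality, and alpha-lattice incompleteness is emulated by random
  block assignment, not optimal lattice construction; design-efficiency
  questions are out of scope.
- The scan is expected-design regression, not full interval-mapping
  mixture likelihood; at sparse marker density (> 20 cM gaps) it loses
  more power than the mixture would.
- Wald denominator df use containment approximations, not
  Kenward–Roger-type corrections.
- Epistasis, multi-QTL model selection beyond the iterative loop, and
  Bayesian mapping are not implemented.
- Passing recovery tests on synthetic data shows the estimators invert
  the generator's model class; field data add spatial structure,
  non-Gaussian errors and confounded environmental factors that the
  generator does not emulate.
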