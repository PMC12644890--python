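# Methods

## Scope and data model

The package analyzes paired-site successional surveys of soil microbiomes.
The design unit is a *pair*: one grassland site at an ordered land-use stage
(managed < recently abandoned < late-successional) matched to an adjacent
forest site representing its afforestation endpoint.  Four tables flow
through the pipeline: an OTU count table (features × samples), a gene-family
count table from metagenomes, a taxa × gene-family trait matrix (copy
numbers, with each family assigned to the C, N or P cycle and C families to
a substrate class), and a per-sample SIR table (basal rate plus six
substrate-induced rates).  Tables are TSV; sample metadata carries stage,
pair id, pair distance, and environmental covariates.  Missing covariates
are dropped by the operations that need them, never imputed.

## Normalization

OTU tables are normalized by scaling with ranked subsampling (SRS): each
sample's counts are multiplied by cmin/total, integer parts are kept, and
the remaining units are assigned one each down the ranking of fractional
parts.  Output depths equal cmin exactly and the procedure is deterministic.
Ties between equal fractional parts are broken by the larger original count,
then by feature index — a deterministic rule chosen so results are exactly
reproducible; a seeded random tie-break is available for users who prefer
the stochastic variant.  Default cmin is 3000 for 16S-like tables and 200
for ITS-like tables; samples below 3000 (bacteria) or 100 (fungi) reads are
discarded first, with the boundary sample (exactly at the threshold) kept.
Gene-family tables are rarefied instead (multivariate hypergeometric draws
at the observed minimum depth, seeded), matching common practice for
functional matrices.

## Diversity and tests

Shannon H′ uses natural logarithms (nats; the base is configurable) and
Simpson dominance is D = Σp².  Beta diversity uses Bray–Curtis distances;
ordination is classical PCoA (double-centering of −d²/2, eigendecomposition;
negative eigenvalues are reported, not corrected).

perMANOVA partitions squared distances: SS_total = Σ_{i<j} d²/N and
SS_within = Σ_g Σ_{i<j∈g} d²/n_g; pseudo-F = (SS_between/df_b)/(SS_within/
df_w).  The p-value is (1 + #{F_perm ≥ F_obs})/(1 + n_perm) under seeded
label permutations (default 10 000 for community tests, 9 999 for ternary
tests).  Permutations are unrestricted by default; a strata argument
permutes within blocks (site pairs) for the paired design.  Degenerate
partitions (no within- or total variation) are flagged rather than tested.

Paired grassland–forest contrasts use a two-way fixed-effects ANOVA with
ecosystem and pair (block) factors; the published analysis used mixed models
with pair and pair distance as random factors, which we deliberately
approximate by fixed pair-blocking — the estimand (the ecosystem contrast
within pairs) is the same, and the fixed version is deterministic and
exactly testable.  The effect size is partial
ω² = (SS_eff − df_eff·MS_err)/(SS_eff + (N − df_eff)·MS_err); its 95% CI
comes from a seeded nonparametric bootstrap over pairs (2000 resamples), a
choice we made because no analytic CI is standard for ω² in blocked designs.
Forests are the successional reference level, so directional contrasts are
reported grassland-minus-forest (and SIR effect sizes forest-minus-
grassland, so positive means faster degradation in forests).  Hedges'
g applies the small-sample correction J = 1 − 3/(4·dof − 1) with a normal-
approximation CI.  Across-stage comparisons use Kruskal–Wallis (omnibus) and
pairwise rank-sum tests; Benjamini–Hochberg correction is applied within
each logical family of pairwise tests, never pooled across analyses.

### Response-shape classification

Covariate and diversity trajectories over the four ordered stages are
classified as flat, linear, unimodal or threshold.  A one-way ANOVA of the
stage factor gates the decision: if stage explains no significant variation
at α the shape is *flat*.  This gate calibrates the classifier's false-
positive rate to α exactly under Gaussian noise — selecting among non-
constant models by information criterion alone would call spurious shapes at
a rate set by the penalty, not by α.  Past the gate, three least-squares
fits compete by AICc: linear in stage rank, quadratic (reported as
*unimodal*), and a step at the forest stage (*threshold*); a winning margin
under 2 AICc units sets an `ambiguous` flag.

## Niche overlap

A gene family's niche is its occupancy across the samples of one stage.
Levin's breadth is B = 1/Σpⱼ² (standardized (B−1)/(N−1)); the directional
overlap of families f and g is O_fg = Σ f·g/Σ g², which can exceed 1; the
symmetric summary is the clipped mean of both directions.  Stage summaries
average the upper triangle of pairwise symmetric overlaps within each
nutrient class (or substrate class).

The limit of quantification is operationalized as a signal-to-noise rule: a
family is quantifiable when its mean relative abundance is at least
q × SE of that mean, with q = 1.65 (the one-sided 95% normal point).  The
literature this follows cites only the threshold value, not a formula, so
the rule is our declaration and both the rule's threshold and its scope are
exposed in the API.  Because the niche space of a stage is that stage's
sample set, the rule is applied twice: once across all samples (global
pre-filter) and again within each stage before overlaps are averaged, so a
family abundant in forests but unquantifiable in grasslands does not enter
the grassland mean.

Stage trends in mean overlap are fit on stage rank by OLS and by a
second-order polynomial; the quadratic is preferred only when its squared
term survives a nested F-test at α = 0.05, and the linear slope sign is
always reported.

## The redundancy–specialization ternary

Traits are gene-family columns min–max scaled to [0, 1].  For each land-use
stage, the metacommunity is the set of taxa with nonzero total relative
abundance across that stage's samples; Euclidean distances among those taxa
are divided by the stage-specific maximum, so d ∈ [0, 1] with max = 1.
Then, per sample: D = Σp², Q = Σᵢⱼ pᵢpⱼdᵢⱼ (full double sum),
R = (1 − D) − Q and U = Q/(1 − D).  With the full double sum and d ≤ 1,
Q ≤ 1 − D is an identity, which guarantees R ≥ 0 and the exact closure
D + Q + R = 1 the ternary plot requires.  Inputs with d > 1 are rejected,
never clipped: silent clipping would break the closure invisibly.
Ecosystem separation of the (D, Q, R) triples is tested by perMANOVA on
their Bray–Curtis distances (9 999 permutations by default), with the
grassland/forest dichotomy as the default grouping (all four stages can be
used instead).

Decoupling regressions fit functional H′ ~ taxonomic H′ by OLS within each
ecosystem; the slope contrast between ecosystems is the F-test of the
ecosystem × H′ interaction in the pooled model.  Average genome size, when
supplied, enters all models as a covariate so gene counts that merely scale
with genome size cannot masquerade as diversity coupling.  Slope CIs are
classical normal-theory intervals.

Hierarchical partitioning attributes the full-model R² to up to six
standardized predictors by all-subsets OLS: each predictor's independent
contribution is its marginal R² gain averaged within each hierarchy level
and then across levels, which sums exactly to the full-model R².  More than
six predictors are refused (the subset space doubles per predictor); callers
should pre-select.

## SIR and MSIR

Basal (water-only) respiration is subtracted from every substrate rate to
remove the moisture-pulse effect.  Negative net rates are retained and
flagged — flooring them would bias the aggregate upward.  MSIR is the sum of
net rates over the fixed six-substrate panel.  Rates are assumed to be in
consistent rate units (already normalized for incubation time); a flag can
divide by stated hours when raw totals are supplied.  MSIR is regressed on
candidate diversity predictors per ecosystem and pooled, with a slope-
homogeneity interaction F and Pearson r reported.

## The synthetic generator

The generator produces the statistical structure the analysis assumes, not
sequences.  Per pair it draws one grassland sample (stage assigned
round-robin) and one forest sample.  Covariates follow configurable response
shapes (flat / linear / unimodal / step at a threshold stage) on top of
Gaussian site noise; defaults place a threshold pH drop of −1.7 (6.2 → 4.5)
and C:N/SOC rises at the forest stage, with LDMC rising linearly — the
canonical abiotic signature of afforestation in boreal systems.

Taxa belong to two guilds.  Generalists draw repertoires covering ~80% of a
shared core pool per nutrient cycle and have high pH optima (6.4 ± 0.2);
specialists split into six guilds with private gene blocks and low pH optima
(4.3 ± 0.2).  The disjointness parameter δ sets the fraction of a
specialist's repertoire drawn from its private block (δ = 0 reduces
specialists to core-sharers; δ = 1 makes cross-guild repertoires fully
disjoint).  Repertoire sizes scale with a lognormal genome-size multiplier
(specialists 1.2× larger on average); copy numbers are 1 + Poisson(0.5).

Abundances follow Gaussian environmental filtering on pH only — other
covariates are correlated outcomes, not filters, which keeps the model
identifiable — with niche width 0.7 pH units and a hard niche limit at 1.8
widths from the optimum (taxa cannot persist beyond their niche edge; this
makes guild turnover between ecosystems complete rather than fractional).
Expected abundance multiplies the pH fitness by a fixed lognormal taxon
effect (σ = 0.8 for generalists, 1.4 for specialists, making forest
communities more dominance-prone, hence their lower H′), a per-sample
lognormal jitter (σ = 0.7) and a per-sample *guild* factor (σ = 1.0)
representing microhabitat swings of whole specialist guilds — the mechanism
that makes private gene blocks co-fluctuate and produces the programmed
niche-overlap decline.  Counts are multinomial at negative-binomial depths
(mean 4 000, dispersion 10 — one tenth of a typical 16S survey, a
desk-speed choice).  Gene tables are the trait-matrix product of the counts,
Poisson-resampled; SIR rates couple each substrate to the Shannon diversity
of the C genes of its substrate class with slope β (default 1), plus a
per-sample basal rate and Gaussian noise.  Because MSIR sums six per-
substrate rates, the matching genetic predictor is the *summed* per-class
Shannon diversity (`catabolic_sum`), whose regression slope recovers β
directly.

All randomness flows through one `numpy` generator seeded from the config,
so identical config + seed reproduces every table byte for byte.

**What the generator does not emulate:** sequencing error, chimeras,
compositional artifacts of primer bias, phylogenetic structure, a
fungal/bacterial kingdom split (kingdoms are simply separate tables),
spatial autocorrelation beyond the pair distance column, and any coupling
between covariates other than their shared stage profile.  Passing recovery
tests therefore shows the *estimators* track the generating parameters
under the stated model — not that real soil data meet these assumptions.

## Study conditions used in the checks

Recovery checks run the programmed-effect configuration (threshold pH drop,
δ = 0.8, β = 1) at 40 pairs across 100 seeds, and require the generated
orderings (grassland H′ > forest; forest Q > grassland; grassland R >
forest), ecosystem separation of the ternary at α = 0.05, β recovered
within 2 SE, and the pH covariate classified as threshold, each in ≥ 95%
(slope: ≥ 90%) of seeds.  Niche checks compare δ = 1 against δ = 0 at the
same size.  Type-I checks run the null configuration (flat shapes, δ = 0,
β = 0, guild-free optima) at 20 pairs across 500 seeds and require
false-positive rates of the perMANOVA, the decoupling slope, the slope-
difference interaction and the shape classifier to sit within exact binomial
99% bounds of α = 0.05.  Permutation counts inside these loops are 199–999;
single analyses use the 10⁴/9 999 defaults.

## Known limitations

* The fixed-block approximation ignores between-pair heteroscedasticity a
  random-effects model would absorb; with many pairs the ecosystem contrast
  is unaffected, but variance components are not estimated.
* The LOQ rule is a declared operationalization; other definitions (e.g.
  blank-based chemical LOQ) would retain different feature sets.
* Directional Levin overlaps above 1 are only clipped in the symmetric
  summary; users averaging directional overlaps should handle the tail.
* Bootstrap CIs for partial ω² can be degenerate when pair resamples
  collapse; such resamples are skipped, slightly narrowing the interval.
* PCoA reports negative eigenvalues but produces no axes for them; strongly
  non-Euclidean distance matrices lose that variation from the ordination.
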