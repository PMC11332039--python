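# Methods

`coralpopgen` implements the population-genomic inference chain used in
basin-scale, multi-species coral surveys: from a filtered SNP matrix to
clone removal, population structure, windowed differentiation, admixture
statistics, isolation-by-distance/-environment tests, genotype–environment
association, a divergent-selection scan, and the final synthesis that asks
whether temperature-associated SNPs co-locate with islands of species
differentiation and signatures of divergent selection. This note records
the models, the defaults and why, and what the synthetic data do and do
not establish.

## The genotype model and filters

Genotypes are diploid alternate-allele dosages over {0, 1, 2, missing} at
biallelic SNPs. Site curation keeps sites with minor allele frequency
≥ 0.05 (inclusive), site quality ≥ 30, and no missing calls; these
thresholds are conventional for metagenome-derived host SNP sets where
depth-based filters have already been applied upstream of the VCF.
LD pruning discards a candidate site whose squared Pearson dosage
correlation with any of the previous 999 *retained* sites reaches 0.2,
in a single left-to-right pass per contig. Counting the window over
retained sites (rather than raw file order) makes the pass idempotent:
re-pruning a pruned set changes nothing, and the output contains no
within-window pair at or above the threshold. r² is composite LD on
dosages, appropriate for unphased genotypes; r² against a monomorphic
site is defined as 0.

## Clone detection

Clonal replicates (ramets of one genet) are detected from Prevosti
allele-sharing distances, d(i,j) = mean over co-typed sites of
|dosage_i − dosage_j| / 2. The clonal threshold is found from the
pairwise-distance histogram: pairs below 10% of the median distance form
the near-zero clonal mode, and the threshold is the left edge of the
first empty Freedman–Diaconis bin after that mode. When no near-zero
pair exists the threshold is 0 (no clones). Multilocus lineages (MLLs)
are the connected components of the graph with edges at distance ≤
threshold (single linkage, mirroring distance-based MLG filtering), and
one ramet per genet — the lexicographically smallest sample id, an
arbitrary but deterministic choice — is retained downstream. The
histogram-gap rule is a formalization choice: with exact clonal copies
the clonal mode sits at 0 and any rule that finds the gap recovers the
planted partition; with somatic variation or genotyping error the gap
blurs, which the synthetic data do not emulate.

## Population structure

PCA operates on column-centered, unscaled dosages (scaling is exposed as
an option but off by default, matching common practice for allele-count
PCA). Ancestry coefficients come from a simplex-constrained ridge
factorization of one-hot-encoded genotypes: minimize
½‖W∘(QG − Y)‖² + ½α‖Q‖² with Q rows on the K-simplex and G in [0,1],
by alternating projected-gradient block updates with exact Lipschitz
steps (each block update is monotone in the objective). W masks missing
or held-out entries. The ridge acts on the admixture coefficients, as in
the sparse-NMF formulation this simplifies; α = 10 by default. At
desk-scale locus counts (hundreds to thousands of SNPs) this penalty is
proportionally stronger than at the hundreds of thousands of SNPs the
regularization was designed for, so admixture coefficients are mildly
smoothed toward the interior; cluster assignments are unaffected.
Components are seeded from distinct randomly chosen samples and the
admixture block is updated first — without this, alternating updates can
collapse all samples onto one component.

K is selected by a masked cross-entropy criterion: 5% of genotype
entries are hidden during fitting and scored under the model's predicted
genotype-class probabilities; the best K minimizes this held-out
cross-entropy. Second-round subclustering reruns the procedure within
each first-round cluster (assignment by largest admixture coefficient),
skipping clusters with fewer than 4 samples.

## Differentiation

The site-level estimator is the Weir–Cockerham (1984) two-population
variance decomposition into among-population (a), among-individual (b)
and within-individual (c) components, computed from per-population
allele frequencies and observed heterozygosities; θ̂ = a/(a+b+c), left
undefined when the denominator is 0 and negative estimates retained.
Windowed FST uses non-overlapping 500 bp bins from the contig start,
aggregated as a ratio of sums Σa/Σ(a+b+c) — the standard low-bias
aggregation; the among-lineage value of a bin is the unweighted mean of
the pairwise values. Genomic islands of differentiation (GIDs) are the
top ceil(1% · W) bins by mean among-lineage FST, with ties at the cut
broken by genomic coordinate so the count is exact and reproducible.
Genome-wide group FST matrices (for lineage and lineage×island groups)
use the same ratio-of-sums aggregation over all sites.

## f-statistics

f2(A,B) averages per-site (p̂A − p̂B)² with the finite-sample correction
−p̂(1−p̂)/(n−1) per population (n = allele count). f4 is evaluated
through its f2 representation, f4(A,B;C,D) = (f2(AD)+f2(BC)−f2(AC)−f2(BD))/2,
with coefficients aggregated per unordered pair so repeated labels
cancel exactly; for four distinct groups this equals the familiar
(p̂A−p̂B)(p̂C−p̂D) estimator. Standard errors use a weighted
delete-one-block jackknife over contiguous blocks of 500 SNPs (SNP-count
blocks are adequate on LD-pruned input; bp-defined blocks are an
option), and |Z| ≥ 3 is flagged significant.

## Isolation by distance and environment

Genetic distance is linearized FST/(1−FST) (small negative FST estimates
pass through and are flagged, never clamped). Geographic distance is the
great circle (haversine, R = 6371 km) between island coordinates, each
island placed at the mean of its site coordinates; overwater routing
around land is out of scope, a documented simplification. Environmental
distance is Euclidean distance on the leading principal components of
the standardized temperature descriptors — the smallest number of PCs
reaching 80% cumulative variance, capped at 5. The Mantel statistic is
the Pearson correlation of lower triangles, tested one-sided ("greater",
since isolation by distance is directional) by simultaneous row/column
permutation with p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm); the +1
smoothing avoids p = 0.

## Genotype–environment association (RDA)

Each sample inherits its site's retained temperature PCs. The centered
genotype matrix is regressed on the (standardized, full-rank) predictors
and the fitted-value matrix is decomposed by SVD; the right singular
vectors are per-SNP loadings on the constrained axes. The number of
retained axes defaults to those above the broken-stick expectation
(minimum 1, maximum the number of predictors). Per-SNP Mahalanobis D²
of the retained loadings is rescaled by a genomic inflation factor
λ = median(D²)/χ²_median(df), converted to upper-tail χ² p-values, and
BH-corrected; q < 0.1 defines temperature outliers and the 100 lowest-p
SNPs (ties by larger D², then coordinate) form the top set used in the
enrichment synthesis. The χ² p-values are approximate — per-SNP loading
variances depend on allele frequency — so null p-values are uniform to
a few percent, not exactly; FDR-level calibration is what the tests
assert.

## Divergent-selection scan (F-model)

The logistic F-model decomposes locus-by-population differentiation as
FST_{l,p} = logistic(α_l + β_p): α_l is a locus (selection) effect, β_p
a population (drift) effect. Population allele frequencies follow
Balding–Nichols Beta(θp̄_l, θ(1−p̄_l)) with θ = exp(−(α_l + β_p)) around
a Uniform ancestral frequency p̄_l, and observed ALT counts are binomial.
A spike-and-slab prior on α (point mass at 0 with prior inclusion 0.1;
slab N(0, 2²)) is sampled by Metropolis-within-Gibbs: logit random walks
for p and p̄, birth/death moves proposing α from the slab (so the slab
density cancels and the acceptance ratio is the likelihood ratio times
the prior odds) plus random-walk refinement when the locus is active,
and per-population random walks for β under a N(−1, 1.8²) prior.
All locus-level updates are vectorized; because the likelihood separates
by population column, all β_p are proposed and accepted independently in
one pass. Convergence is monitored by split-R̂ on the β draws (warning
above 1.1). Default chains are 20,000 iterations with 5,000 burn-in and
thinning 10 — sized for desk-scale locus counts where the posterior is
dominated by a few hundred loci per chain; production scans simply raise
the counts. A two-pass contig-wise mode first estimates β on the largest
contig and then fixes it while fitting locus effects per contig,
mirroring scans that share demographic parameters across genome chunks.

Divergent selection is α > 0 (excess differentiation). Calls use the
posterior-FDR rule: rank loci by P(divergent) = P(δ=1, α>0) and flag the
largest prefix whose mean posterior neutrality 1 − P stays at or below
the target FDR. This module replicates the *behavior* of hierarchical
F-model software (calibration under the null, ranking of strong
divergent loci, drift-parameter ordering), not its coefficients: the
original nested group/population sampler is collapsed to one level per
comparison, with "population" units set to the hierarchy level under
test (lineages for among-species divergence).

## Enrichment synthesis

The report joins three per-SNP facts on the LD-pruned SNP universe:
temperature-outlier status (q < 0.1, percent computed against the
unlinked total — stated in the report header), membership of the top-100
outliers in GID windows (1-based SNP position P in 0-based half-open
window [s,e) iff s ≤ P−1 < e), and divergent-selection flags. Percentages
are exact count arithmetic rounded half-up to 2 decimals, with raw
fractions alongside; enrichment ratios compare the selected fraction
among (GID-)outliers with the genome-wide selected fraction.

## The synthetic-data generator

The generator runs the F-model forwards as a two-level Balding–Nichols
hierarchy: ancestral frequency p̄ ~ Uniform(0.05, 0.95) per locus;
species frequencies Beta-distributed around p̄ at drift f_species = 0.15;
island-within-species frequencies around the species frequency at
f_island = 0.02; genotypes Binomial(2, p_island). The sampling design is
11 islands × 3 sites × 3 colonies with 3 latent species in sympatry
(round-robin within sites), i.e. 99 colonies — the shape of a basin-wide
multi-island survey. Temperature descriptors (63 per site) are noisy
affine images of a single latent island gradient tied to island
longitude plus site noise, which makes them strongly inter-correlated
(first PC tracks the gradient at |r| > 0.9) and ties environmental to
geographic distance, as in real sea-surface-temperature descriptor sets.
Selected loci receive a logit-scale shift cline_slope · z_island
(default slope 2.0 — chosen for testability; no per-species effect sizes
are available to calibrate against) with species-specific multipliers
(1 ± 0.5, mean 1), so selected loci carry both a pooled environment
association (detectable by RDA) and excess among-species differentiation
where the gradient is steep (so they enrich in GIDs and in divergent-
selection calls — the joint signal the synthesis is designed to detect).
Clones are exact genotype copies of another colony at the same site;
QUAL is Uniform(30, 60) so the default filters act deterministically;
missingness is optional and applied last. A single seeded RNG stream
drives everything: identical configs give byte-identical outputs.

What the generator does **not** emulate: linkage beyond positional
adjacency (loci are independent draws, so LD pruning is exercised by
construction of duplicated/jittered columns in tests rather than by the
simulator), genotyping error and somatic variation (clone distances are
exactly 0), selection dynamics over time, and realistic geographic
range limits per species (all species span all islands). Passing tests
therefore establish internal consistency and statistical calibration of
the estimators, not robustness to these real-data complications.

## Problem sizes and numerical choices

Default test and acceptance runs use 600–20,000 SNPs and the 99-sample
design — sizes at which each stage's statistical behavior (drift
recovery within 10%, FDR calibration, K recovery in ≥8/10 replicates)
is measurable in minutes on one CPU. Degenerate inputs are handled
explicitly: monomorphic loci are skipped by the selection scan and give
r² = 0 in pruning; FST with a + b + c = 0 is excluded from sums; groups
below two samples are dropped with a warning; constant environment
descriptors are dropped before PCA; a pair of samples with no co-typed
site is an error. Ties are always broken by genomic coordinate, and
every stochastic routine takes an explicit seed.
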