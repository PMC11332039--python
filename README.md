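# coralpopgen

Population-genomic inference for basin-scale, multi-species coral
surveys. Reef-building corals sampled by morphology routinely turn out
to contain several cryptic species, clonal replicates, and
island-structured populations; deciding whether their divergence tracks
the environment — past temperature regimes in particular — or mere
drift requires a long chain of analyses that this package implements
end to end:

- **Variant curation** — biallelic SNP dosages from VCF; MAF ≥ 0.05,
  QUAL ≥ 30, no-missing-data filters; LD pruning at r² ≥ 0.2 in a
  1000-site window.
- **Clone detection** — Prevosti allele-sharing distances, automatic
  clonal-threshold detection from the distance-histogram gap,
  single-linkage multilocus lineages (MLLs), one ramet per genet.
- **Population structure** — PCA on centered dosages; admixture
  coefficients Q by simplex-constrained ridge factorization of one-hot
  genotypes, with the number of ancestral populations K chosen by a
  masked cross-entropy criterion and optional second-round
  subclustering.
- **Differentiation** — Weir–Cockerham (1984) FST: per-site variance
  components, 500 bp windows aggregated as Σa/Σ(a+b+c), genomic islands
  of differentiation (GIDs) as the top 1% of windows by mean
  among-lineage FST, and genome-wide pairwise group FST matrices.
- **f-statistics** — bias-corrected f2 distances and f4 admixture tests
  with block-jackknife Z-scores (|Z| ≥ 3 significant).
- **Isolation by distance / environment** — FST/(1−FST) against
  great-circle island distances and Euclidean distances on the leading
  PCs (≥80% variance, ≤5 PCs) of per-site temperature descriptors, by
  one-sided Mantel permutation tests.
- **Genotype–environment association** — RDA of centered genotypes on
  sample-level temperature PCs; per-SNP Mahalanobis D² over retained
  constrained axes, genomic-inflation rescaling, χ² p-values, BH
  q-values (q < 0.1 outliers, top-100 rule).
- **Divergent selection** — a logistic F-model
  FST_{l,p} = logistic(α_l + β_p) with a spike-and-slab prior on the
  locus effects, sampled by Metropolis-within-Gibbs; loci flagged by a
  posterior false-discovery-rate rule.
- **Enrichment synthesis** — how many temperature-outlier SNPs fall in
  GIDs and under divergent selection, versus the genome-wide baseline.

A forward simulator (`coralpopgen.synthetic_data`) generates surveys
with the full hierarchical structure — latent species, islands within
species (two-level Balding–Nichols), temperature clines at selected
loci, correlated environment descriptors, exact clonal replicates — so
the whole chain is testable without any download.

## Worked example

Simulate a survey in the default design (11 islands × 3 sites × 3
colonies, 3 latent species, 2,000 SNPs of which 50 carry temperature
clines, 2 clone pairs) and run the whole chain:

```python
from coralpopgen import SimulationConfig, run_all
from coralpopgen.selection import McmcSettings

cfg = SimulationConfig(n_sites_genomic=2000, n_selected=50,
                       n_clone_pairs=2, seed=1)
result = run_all(cfg, k_range=range(1, 5),
                 mcmc=McmcSettings(n_iter=8000, burn_in=2000, seed=1))
print(result.report.to_text())
print("best_k", result.best_k, "| n_mll", result.clones.n_mll)
print("mantel geography: r=%.3f p=%.3f" % (result.mantel_geo.r, result.mantel_geo.p))
```

which prints (seed 1):

```
Temperature-outlier / GID / selection enrichment
(outlier percent uses the unlinked SNP total as denominator)
  SNPs tested:                 1387
  outliers (q<0.1):            16 (1.15%)
  top outliers considered:     100
  ... in GIDs:                 0 (0.00%)
  ... under divergent sel.:    10 (10.00%)
  ... in GIDs and selected:    0 (n/a of GID outliers)
  genome under divergent sel.: 1.37%
  enrichment (top outliers selected vs genome):        7.30x
  enrichment (GID outliers selected vs genome):        n/a

best_k 3 | n_mll 97
mantel geography: r=0.792 p=0.001
```

Reading it: of the 2,000 simulated SNPs, 1,387 survive the MAF/QUAL and
LD filters; 1.15% of them associate with the temperature PCs at q < 0.1.
The two planted clone pairs are detected (97 multilocus lineages among
99 colonies), the three latent species are recovered by the
cross-entropy criterion (best K = 3), and island-level genetic distance
correlates with geography (the temperature clines are tied to island
longitude). Of the 100 strongest temperature outliers, 10 are called
under divergent selection across lineage × island units — 7.3× the
genome-wide selected fraction of 1.37%. That joint excess is the
signature of environment-driven divergence the pipeline is built to
detect; at this desk scale none of the top outliers happen to fall in
the 1%-of-windows GID set, so the GID-conditional ratio is reported as
n/a rather than extrapolated. On a survey simulated without selected
loci (`n_selected=0`) the outlier fraction drops to the false-positive
level and the enrichment ratio collapses toward 1.

The same chain is scriptable from the shell:

```bash
coralpopgen simulate --out-prefix toy --n-sites 2000 --n-selected 40 --seed 1
coralpopgen filter toy.vcf toy.filtered.vcf
coralpopgen prune toy.filtered.vcf toy.unlinked.vcf
coralpopgen clones toy.unlinked.vcf toy.mll.tsv
coralpopgen fst toy.unlinked.vcf toy.metadata.tsv toy.windows.tsv
coralpopgen gid toy.windows.tsv toy.gids.tsv
coralpopgen rda toy.unlinked.vcf toy.metadata.tsv toy.environment.tsv toy.rda.tsv
coralpopgen scan toy.unlinked.vcf toy.metadata.tsv toy.scan.tsv --pop-col lineage
coralpopgen enrich --outliers toy.rda.tsv --gids toy.gids.tsv --scan toy.scan.tsv
```

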