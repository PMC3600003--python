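# circenrich

**LD-aware annotation enrichment for trait-associated variants, with a
chromosome-bound circular-permutation null.**

`circenrich` is for statistical geneticists and regulatory genomicists who
want to know whether GWAS hits co-occur with genomic annotations — genic
features, conserved elements, chromatin states — more (or less) often than
chance. The hard part of that question is the null: SNPs cluster along the
genome, annotations cluster, and linkage disequilibrium (LD) means one
causal signal tags a whole run of neighbouring SNPs. A null that samples
SNPs uniformly ignores all three and calls false positives freely (the
package's own demo measures a ~39% false-positive rate at α = 0.05 for the
uniform null on clustered null data, against ~5% for the circular null).

## The method

Every SNP in a genome-wide catalog is marked as overlapping an annotation
if **it or any of its LD partners** (r² > 0.9, within 250 kb per side)
lies inside the annotation's intervals. This LD-expanded SNP × annotation
incidence matrix is computed once.

**Circular permutation null.** Association status (significant at
p < 5 × 10⁻⁸, suggestive at 5 × 10⁻⁸–5 × 10⁻⁵, or background) is rotated
along the positional SNP order within each chromosome, wrapping at the
end, with one uniform offset per chromosome per permutation. Rotation
preserves the number of associated SNPs per chromosome, their clustering,
and the entire annotation/LD landscape — only the alignment between labels
and genome moves. For each annotation the permuted hit counts form an
empirical null; enrichment is summarized by the odds ratio

    OR = (hits_real · nonhits_null) / (nonhits_real · hits_null)

with the null cells taken from the mean permuted count, an empirical CI
from the null-count quantiles, an empirical P-value (floored at 1/n
permutations, e.g. < 5 × 10⁻⁵ at 20,000), and the fold enrichment
observed/mean-permuted (≈ OR for rare annotations).

**Platform-sampling null** (the classical comparison method): random
background SNP sets of matched size, drawn per genotyping-platform group
proportionally to the real trait-SNP composition, with Wald CIs and
normal-approximation P-values on ln OR.

**Joint logistic model.** Association status (1/0) is regressed on all
annotation incidences at once, platform indicators forced, candidates
entering and leaving by bidirectional stepwise AIC. Each term is reported
with its estimate, SE, β-coefficient (estimate/SE, the Wald z) and
P-value; whole-model comparisons use the deviance χ² test and fit quality
McFadden's and McKelvey–Zavoina's pseudo-r². An upstream distance-to-TSS
covariate (minimum over the SNP's LD expansion, strand-aware) is
available.

**Synthetic genomes.** A first-class generator produces catalogs with
clustered SNP positions, block-structured LD under the distance cap,
clustered annotation tracks of configurable coverage, platform groups, and
association labels planted at a target odds ratio towards a chosen track —
returning the realized ground-truth 2×2 table, so every stage is testable
offline against a known truth.

## Worked example

Simulate a 60,000-SNP genome (3 chromosomes), plant 600 associated SNPs at
odds ratio 3 towards `track03`, and run both nulls and the joint model:

```sh
cat > sim.yaml <<'YAML'
simulate:
  n_chromosomes: 3
  snps_per_chromosome: 20000
  chromosome_length: 60000000
  n_assoc: 600
  planted_or: {track03: 3.0}
  seed: 42
permutation: {n_permutations: 2000, seed: 1}
sampling: {n_samples: 100, seed: 2}
YAML
circenrich run --config sim.yaml --outdir out
```

`out/enrichment_perm_significant.tsv` (abridged):

```
annotation  hits_obs  n_assoc  null_mean  odds_ratio  ci_low      ci_high    pvalue
track02     89        600      78.7865    1.1522135   0.91438356  1.4845774  0.12
track03     316       600      148.7455   3.3755648   2.8144159   4.102993   0.0005
track04     164       600      155.1035   1.0789337   0.89892707  1.3080926  0.2045
```

316 of the 600 associated SNPs (or their LD partners) fall inside
`track03` against a mean of 148.7 across 2,000 permuted genomes: OR 3.38
[2.81–4.10], empirical P at its floor (no permutation was as extreme; with
2,000 permutations the bound is < 5 × 10⁻⁴). The realized ground truth in
`out/manifest.json` is (316·44896)/(284·14504) = 3.44 — inside the CI. The
other tracks, planted at no enrichment, stay near OR 1. The joint model
(`out/model.tsv`) selects `track03` alone among the candidates:

```
term                 estimate   std_error  beta_coefficient  pvalue
const                -5.01986   0.0892673  -56.2341          0
platform_affymetrix  0.0231124  0.0827379  0.279344          0.779981
platform_illumina    -0.0952421 0.083321   -1.14307          0.253008
track03              1.23728    0.0823251  15.0292           4.72621e-51
```

with exp(1.237) ≈ 3.45 matching the planted effect, deviance 217.6 against
the platforms-only model, and pseudo-r² 0.03 (McFadden) / 0.08 (M&Z).

The same stages are available as separate subcommands (`simulate`,
`annotate`, `enrich-perm`, `enrich-sample`, `model`) over plain BED/TSV
files; see `circenrich --help`.

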