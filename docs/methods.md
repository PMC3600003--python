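# Methods

## Problem and data model

The package tests whether trait-associated SNPs co-occur with annotated
genomic regions beyond chance. Its inputs are (a) a SNP catalog — id,
chromosome, 1-based position, platform-group memberships, optional
association P-value; (b) an LD-pair table (snpA, snpB, r²); (c) one BED
track per annotation (0-based half-open intervals); optionally (d) a
stranded TSS BED. A 1-based position p lies in an interval [start, end)
iff start < p ≤ end; `chr1` and `1` are reconciled before matching.

Status assignment: P < 5 × 10⁻⁸ → significant; 5 × 10⁻⁸ ≤ P < 5 × 10⁻⁵ →
suggestive; SNPs on the Y or unassigned chromosomes are removed. A
suggestive SNP in direct LD with any significant SNP tags the same signal
and is demoted to background rather than deleted — the catalog keeps its
positional slot so rotation nulls remain well defined. No transitive LD
closure is applied. LD partnership itself requires r² strictly above the
threshold (0.9 by default, 0.7 as the liberal alternative) and a
positional distance of at most 250 kb per side, intra-chromosomal only.

The unit all inference runs on is the LD-expanded overlap matrix: SNP ×
annotation booleans, true when the SNP or ≥ 1 of its LD partners sits
inside the track. Incidence is binary — several partners or intervals
still count once. The matrix is precomputed once; every null afterwards is
a relabelling, never a re-overlap, which is what makes 20,000 permutations
a counting exercise.

## Circular permutation null

For each permutation, one offset per chromosome is drawn uniformly on
[1, n] (n = SNPs on that chromosome; offset n is the identity, occurring
with probability 1/n) and the association labels rotate by that offset
along the positional order, wrapping at the chromosome end. Rotation
preserves per-chromosome label counts and label clustering exactly, and
leaves annotations and LD untouched. Offsets come from one seeded
generator consumed permutation-major, chromosome-minor; oracle tests
replay the identical stream against a from-scratch recount.

Summaries per annotation, from observed count `obs`, null counts
`c_1..c_B`, associated-set size `m`:

- point OR from the 2×2 table (obs, m−obs, mean(c), m−mean(c)); null cells
  may be non-integer;
- CI by re-evaluating the OR with the null cell replaced by null-count
  quantiles: the upper quantile gives the lower bound and vice versa, so
  the interval brackets the point estimate. The default
  (`percentile_2.5_97.5`) is a conventional 95% interval. A literal
  order-statistic mode keeps the historical convention of using the 5th
  count from each end of the sorted null — at 20,000 permutations a
  ≈ 99.95% interval — for fidelity experiments only; the phrase "5th and
  95th largest" that convention is sometimes stated with cannot be taken
  at face value, since two upper-tail references cannot bracket the point
  estimate;
- empirical P as the proportion of permutations at least as extreme as the
  observation, on the side of the observed departure from the null mean
  (one-sided directional, non-strict). When no permutation is as extreme
  the value is reported as a bound, < 1/B (< 5 × 10⁻⁵ at 20,000);
- fold enrichment obs/mean(c), ≈ OR whenever both hit fractions are below
  5% (the difference is the factor (m−mean(c))/(m−obs), within 5% of 1 in
  that regime).

### P-value modes and calibration

The reporting default (directional, non-strict) is deliberately
conservative per direction but, being a smaller-tail selection, its
two-direction exceedance rate on null data is ≈ 2α. Conversely, doubling
the non-strict smaller tail over-corrects under a discrete null because
the tie mass P(X = obs) is charged to both tails. Calibration statements
at level α are therefore made on the strict doubled scale
(`tail_mode="two_sided_doubled"`, `strict=True`), where the two effects
cancel: on null data at toy scale the measured rate at α = 0.05 sits
within the exact binomial 99% band, and the null P-values pass a KS
uniformity check once the null has enough distinct count values (an
associated set of ~500 on a 20,000-SNP toy; with much rarer associated
sets the count distribution is too coarse for fine-grained uniformity,
which is a property of the toy's discreteness, not of the method).

## Platform-sampling null

The comparison method draws background SNP sets of the same size as the
associated set, allocating per platform group by largest-remainder
apportionment of the group proportions observed among the associated SNPs
(a multi-platform SNP counts once per group; groups are sampled in sorted
order without replacement, and SNPs taken by an earlier group leave the
later pools). Background SNPs may include trait-associated ones unless
excluded by flag. Their LD-expanded incidence reuses the precomputed
matrix rows, exactly as for real SNPs. Inference is theoretical on
purpose — Wald CI and two-sided normal P on ln OR against the mean sample
hit count — mirroring the asymptotic shortcut the sampling approach
historically used; contrasting it with the empirical permutation
inference is part of what the package demonstrates. Zero cells make
bounds infinite (reported literally as `Infinity`); a Haldane–Anscombe
+0.5 correction is available behind a flag and is used internally only to
produce the finite bound of a one-sided-unbounded interval and the Wald P
when a cell is zero.

Whether permutation or sampling CIs are wider depends on how strongly the
annotation and the associated set cluster: at default toy scale the
permutation intervals are the narrower ones; under strongly clustered
labels the sampling null's variance is badly underestimated (see the
false-positive comparison below). The acceptance script reports both mean
widths rather than asserting a direction.

## Joint logistic model

Status (1/0) on annotation incidences, intercept and platform indicators
forced (being genotyped at all predicts catalog membership; the "empty"
model contains exactly those terms). Bidirectional stepwise AIC from the
base: each step scans all single additions and removals of candidate
annotations, takes the move with the largest AIC reduction (ties broken
lexicographically for determinism), and halts when no move reduces AIC —
so the final AIC never exceeds the base AIC, and the step log is strictly
decreasing. Tautological annotations (e.g. gene lists defined by trait
association) are excluded from candidacy via a blacklist. Per-term
inference is Wald (β-coefficient = estimate/SE = z; its square is the Wald
χ²); nested-model comparison is the deviance test 2Δloglik ~ χ²(Δdf),
with negative numerical deviances clipped to zero with a warning.
Pseudo-r²: McFadden 1 − ℓ_full/ℓ_empty; McKelvey–Zavoina
Var(η̂)/(Var(η̂) + π²/3) with the sample variance (ddof = 1) of the full
model's linear predictor. Complete or quasi-complete separation is
detected (perfect prediction or exploding coefficients) and flagged on
the fit rather than silently accepted; the flagged fit comes from a
BFGS maximization without the separation guard.

Distance to TSS: per SNP, the minimum over its LD expansion of the
strand-aware upstream distance to the nearest TSS (5′ side: TSS at t, +
strand counts SNPs at p ≤ t with distance t − p; − strand counts p ≥ t
with p − t). SNPs with no upstream TSS on their chromosome get a missing
value, replaced by a configurable cap when the covariate enters a model
(flagged in output); a SNP-only mode ignores partners. The covariate
enters untransformed in base pairs; log1p is config-gated.

## Synthetic genomes

The generator reproduces the structure that makes the inference hard, not
population-genetic realism:

- SNP positions: Poisson cluster process — uniform cluster centers,
  geometric cluster sizes (mean 8), geometric offsets (mean 5 kb) —
  deduplicated, sorted, subsampled to the requested count. Gaps are
  overdispersed relative to a uniform arrangement (index of dispersion ≫ 1).
- LD: chromosomes tiled into exponential-length blocks (mean 20 kb);
  every intra-block pair receives an r² from a uniform range (default
  0.5–1.0); only pairs passing the r²/distance filters enter the map; no
  cross-block partners. A cartoon, but sufficient for the overlap
  semantics the nulls exercise.
- Annotations: clustered intervals (geometric cluster sizes, exponential
  lengths, mean 2 kb) accumulated until each track's merged coverage is
  within ±10% relative of its target; defaults span 2%–40% coverage
  across 10 tracks.
- Platform groups: independent Bernoulli membership per group
  (defaults 0.55/0.60/1.0 for two array vendors plus an
  imputation-panel group), with a fallback so every SNP keeps ≥ 1 group.
- Association labels: weighted sampling without replacement
  (Efraimidis–Spirakis exponential tilting) with per-SNP weight
  ∏ OR_t^incidence(t), so the realized conditional odds ratio approaches
  the target while the associated fraction stays rare. The realized 2×2
  table is returned as ground truth, and tests compare estimates against
  the realized, not nominal, OR — removing Monte-Carlo ambiguity. A
  second planting mode lays labels in positional runs (geometric cluster
  length) independent of every annotation, emulating the LD-clustering of
  real GWAS hits for null-behaviour studies.

Default toy scale is 3 chromosomes × 20,000 SNPs × 60 Mb, 10 tracks,
2,000 permutations — minutes on one CPU. What passing tests on these
toys do **not** show: behaviour under real LD (no allele frequencies, no
decay with distance within blocks), real annotation length distributions,
or catalog-scale multiple-testing families.

## Problem sizes used in the validation suite

- Rotation-vs-recount oracle: 1,002 SNPs, 3 chromosomes, 5 tracks, 200
  shared-offset permutations, exact equality in all 1,000 cells.
- Null calibration: 500 replicates (10 genomes × 50 label redraws) of a
  20,100-SNP toy, 500 associated, 2,000 permutations each.
- Planted-OR recovery: OR ∈ {1.5, 2, 4}, 69 replicates each over three
  shared 100,000-SNP genomes (5 chromosomes), 1,000 associated, 2,000
  permutations: median point OR within 15% of the realized truth, 95% CI
  coverage ≥ 90%.
- Joint-model recovery: 100 replicates at n = 100,000 from known
  coefficients (intercept −4, platform 0.5, annotation ln 4, two null
  annotations): all coefficients within 3 SE ≥ 95% of the time; stepwise
  selects the planted annotation ≥ 95% and each pure-noise annotation at
  most 20% of the time (the AIC add-threshold corresponds to a χ²₁ > 2
  event, ≈ 16% by construction).

## Known limitations

- The sampling null treats the mean of the background samples as a single
  pseudo-sample in the Wald formula, inheriting the anti-conservativeness
  the empirical method exists to fix; this is faithful to the method being
  benchmarked, not a recommendation.
- Stepwise AIC is a greedy search; with strongly collinear annotations the
  selected set is one of several near-equivalent models (deterministic
  here only because ties break lexicographically).
- The permutation CI takes null-count quantiles through the OR formula;
  for annotations so sparse that null counts are mostly zero the upper
  bound degenerates to +Infinity, matching the convention of reporting
  unbounded intervals literally.
- Strand-agnostic overlap; no partial-overlap fractions; no
  cross-chromosome rotation (chromosome-bound by design).
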