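# Methods

## The model

`mantelqtl` implements a distance-based multi-locus association method for
populations with dense genotypes and many correlated phenotype measures
(the P >> N regime), in the spirit of multivariate distance matrix
regression. Both data modalities are reduced to N x N pairwise sample
dissimilarity matrices:

* **Genotype distance** over a marker set S:
  d_G(i, j) = sum_{m in S} |g_i(m) - g_j(m)|, with g the 0/1/2 minor-allele
  dosage — the Manhattan distance with equal weight per marker, no
  standardization. An identity-by-state variant
  d(i, j) = #{m : g_i(m) != g_j(m)} is available (`metric="ibs_mismatch"`).
* **Phenotype distance** per category: the Manhattan distance over the
  category's measure vector. Measures are centered and scaled to unit
  variance first by default, because equal weight per measure is only
  meaningful on a common scale; a raw mode exists for same-unit categories.
  This standardization choice is ours — whether the original analysis
  standardized is not documented — and both modes are tested.

The **Mantel statistic** r is the Pearson correlation over the N(N-1)/2
upper off-diagonal entries of the two matrices; its p-value comes from B
joint row/column permutations of one matrix with the add-one estimator
p = (b + 1)/(B + 1), one-sided by default (genotype similarity predicting
phenotype similarity). p is never zero; the smallest attainable value with
B = 1000 is 1/1001 < 0.001.

The analysis proceeds in three stages:

1. **Scan**: every polymorphic marker is Mantel-correlated with the
   phenotype distance; markers are ranked by r (ties broken by p, then map
   order).
2. **Forward selection**: markers individually significant at p < 0.01
   enter in rank order; the cumulative correlation c_k of the first-k-marker
   distance is tracked. Manhattan additivity makes the update incremental
   and exactly equal to recomputation. The selected set is the earliest k
   with c_k >= (1 - plateau_tol) * max_k c_k (plateau_tol default 0.02;
   the plateau is otherwise an eyeball judgment, so the tolerance is a
   package decision).
3. **Calibration**: the whole procedure — re-scan, re-gate, re-select — is
   repeated on R phenotype-label shuffles, and the observed curve is
   expressed as Z_k = (c_k - mu_k)/sigma_k against the null mean and
   (R-1)-divisor SD per set size. Because each null curve is itself a
   best-of-scan selection, the Z-score accounts for selection bias. Z > 3
   corresponds to a one-sided normal tail of 0.00135.

Downstream, marker sets detected independently in two strata (cohorts, or
sham vs. all irradiated animals pooled) are cross-tabulated over the shared
post-MAF marker universe and tested with the two-sided Fisher exact test;
the odds ratio (Haldane-Anscombe +0.5 when a cell is zero) and its Woolf
log-OR 95% CI carry the directional claim. Genes whose bodies lie within
1 Mb (inclusive; a TSS-distance mode is non-default) of markers common to
both strata are tested for gene-set overrepresentation with the
hypergeometric upper tail and Benjamini-Hochberg adjustment per collection.
The default universe is all annotated genes on chromosomes carrying at
least one tested marker; it is configurable because this choice moves every
p-value and no single convention is canonical.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `maf_threshold` | 0.05 | markers kept if MAF strictly above this |
| `p_gate` | 0.01 | per-marker permutation gate for forward selection |
| `B` | 999 | permutations per Mantel test/scan |
| `R` | 25 | label shuffles in the null ensemble |
| `plateau_tol` | 0.02 | relative tolerance for entering the curve plateau |
| `window_bp` | 1,000,000 | gene-collection window around common markers |
| `stratum_floor` | 30 | minimum samples per stratum in comparisons |

The gate interacts with B: p < 0.01 is attainable only if B >= 199, and the
attainable gate level is floor(p_gate (B+1))/(B+1) — 0.005 at B = 199,
0.009 at B = 999. Tests of null gate rates use the attainable level, not
the nominal one.

## The synthetic generator

No raw data from the motivating study are available, so the package ships a
generator that emulates its structure with known ground truth:

* **Founders and mosaics.** Eight founder strains carry binary alleles; per
  marker the carrier count is chosen so the equal-mixing MAF lands in
  [0.05, 0.5] (granularity 1/8; `target_maf` records the realized value).
  Each animal is two chromosome-wise founder mosaics whose founder of
  origin switches with probability 1/`mean_block_markers` per marker step —
  geometric block lengths, the first-order behavior of an advanced
  intercross, without pedigree simulation. Markers sit on 19 autosomes with
  20-200 kb spacing, matching a 10^2-kb-scale mapping resolution.
* **Phenotypes.** A per-condition additive genetic score (standardized
  within condition, so heritability is a variance fraction and irradiation
  arms differ in architecture, not mean — the study reports no direct mean
  effect of irradiation, and we follow that reading), a latent factor
  shared within each of six categories (four measures each), and iid noise:
  y = sqrt(h2) G + sqrt(1-h2)(sqrt(lam) L + sqrt(1-lam) eps), with lam
  solved so the realized within-category correlation hits its target
  (default 0.7; between-category correlation is then h2). Cohort mean
  offsets and variance multipliers are applied last.
* **Architecture knob.** Each condition has its own causal-marker list;
  `overlap` in [0, 1] sets the shared fraction (1 = identical lists sharing
  effect values, 0 = disjoint loci). Effect magnitudes are uniform in
  [0.5, 1.5] with random signs; shared loci keep one effect across
  conditions, so the knob shifts *which* loci act, not how common loci act.

What the generator does **not** emulate: linkage maps with recombination
hotspots, sex chromosomes and sex effects, selection, genotyping error and
missingness, non-Gaussian phenotype scales, and family structure from
circular breeding. Passing tests therefore show the statistical machinery
behaves as designed under a clean HS-like architecture — not that any
particular biological finding replicates.

## Numerical and algorithmic choices

* The scan exploits the fact that a biallelic marker partitions samples
  into at most three dosage classes: the permutation-dependent part of the
  statistic reduces to cross-sums between phenotype-distance blocks and
  class indicators, computed for all markers at once with two matrix
  products per permutation (float32; observed statistics are computed in
  float64 column-at-a-time so the same marker yields bit-identical values
  in the scan and the cumulative curve). Permutation exceedances are
  compared in the same float32 pathway as the permuted values, so
  comparisons are internally consistent; near-ties at relative 1e-7 may
  resolve either way, which perturbs b by at most the number of exact ties.
* Each marker draws permutations from its own `SeedSequence`-spawned
  stream, so scan results are independent of execution order and of which
  other markers are scanned. When only the gate decision is needed (null
  ensembles, stratified comparisons) a marker's stream is truncated once
  its exceedance count can no longer pass the gate; the eligible set is
  provably identical to the full-B scan, and truncated markers report the
  add-one p over the permutations actually drawn (always on the ineligible
  side of the gate).
* Distances are stored dense (N <= ~2000 at desk scale). Degenerate inputs
  are errors, not silent zeros: constant off-diagonal distances raise, a
  zero sigma_k flags the Z undefined, an empty margin flags the odds ratio
  undefined. A null shuffle with no eligible markers contributes a flat
  zero curve. Curves of differing lengths are right-padded by carrying the
  last value.
* Greedy order is fixed by the initial scan ranking and not re-scored after
  each inclusion — the cheap, literal reading of forward selection by
  decreasing individual significance; adaptive re-scoring is out of scope.

## Operating characteristics at desk scale

The `validation` module measures the pipeline on generated data; the test
suite and `scripts/acceptance.py` run these experiments. Observations a
user should know (all reproducible from the suite):

* The permutation test is exactly calibrated (type-I error at the
  attainable alpha level, gate-passing fraction at floor(0.01(B+1))/(B+1)).
* Sensitivity is strongly sample-size limited. The null forward-selection
  curves themselves climb (best-of-M chance markers combine to sizable
  cumulative correlations), so the observed curve must beat that selection
  bias. With ~10 causal loci at total measure-level heritability 0.5,
  separation (peak Z > 3, most loci recovered) appears at roughly 300-400
  samples per analysis with ~10^3 markers; at 200 samples and 2,000 markers
  the true-set correlation ceiling (~0.17) sits below the null selection
  bias (~0.3) and the procedure — correctly — does not call the signal.
  This mirrors the original study's need for cohorts of 600-1,200 animals.
* The condition-shift contrast reproduces in silico: identical
  architectures across strata give overlap odds-ratio CIs well above 1;
  disjoint architectures give chance-level overlap, with the median OR
  rising monotonically in the architecture-overlap knob.
* Cohort mean/variance shifts leave within-stratum Mantel correlations
  unchanged up to sampling noise (the statistic is affine-invariant), so
  across-category rankings of peak correlations are preserved between
  cohorts when category signals are separated beyond the selection-noise
  floor (at 600 samples per cohort, adjacent heritability steps of ~0.12
  are resolvable).

## Limitations

* No analytic null for the cumulative correlation: the label-shuffled
  ensemble *is* the method, and the Z-to-p mapping assumes approximate
  normality of the null, checked only empirically.
* Allele-frequency-weighted distances, PLINK/VCF input, backward
  elimination, exhaustive subset search, genome-wide FWER thresholds for
  single markers, and live pathway-database queries are out of scope; gene
  sets are supplied as GMT files.
* The forward-selection peak set is one of two defensible definitions of
  "significant markers" for the overlap test; all gate-passing markers are
  the other, available via `set_definition="gate"` and reported in logs.
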