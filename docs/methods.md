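# Methods

## Statistical model

The analysis treats each variant site as a multinomial over pooled diploid
genotype classes (`0/0`, `0/1`, `1/1`, `0/2,etc.`, `1/2,etc.`, `2/2,etc.`)
within each cohort group.  Association between a genotype class and case
status is quantified by the cross-product odds ratio of a 2×2 table, with
the Woolf log-scale normal-approximation confidence interval
(SE = √(1/a + 1/b + 1/c + 1/d)) and a two-sided Wald p-value.  For a single
binary predictor on a 2×2 table these closed forms coincide with the Wald
statistics of a logistic-regression fit, so no iterative optimisation is
used or needed.

Assumptions: subjects are independent; genotype calls are correct (the
pipeline consumes a pre-extracted locus VCF and does not re-call variants);
group labels are fixed and known; no covariate adjustment (age, sex,
ancestry) is performed.  P-values are raw and two-sided; no multiplicity
correction is applied by default, matching the reporting convention of the
underlying analysis, with an optional Benjamini–Hochberg filter
(`significant_results(..., adjust="bh")`).

### Reference-genotype reassignment

The comparison baseline at a site is the genotype class most abundant among
healthy controls, not automatically `0/0`.  At sites where the genome
reference allele is the minority allele in healthy people, this reassigns
the baseline (e.g. to `1/1`) and every other class — including `0/0` — is
tested against it.  Ties are broken by the fixed class order
`0/0 < 0/1 < 1/1 < 0/2,etc. < 1/2,etc. < 2/2,etc.`; ties do not occur in
practice but the rule makes runs deterministic.  For group pairs not
involving HC (e.g. GPD vs GUN), the reference is still taken from HC
whenever HC subjects are present in the matrix, because the baseline is
defined by healthy people; only when no HC subjects exist does the control
group of the pair define it.

### Comparator modes

`complement` (default): the comparator rows c/d count all non-missing
subjects not carrying the tested class.  This mode reproduces the reported
OR/CI/p values exactly for every site we can check from the published
carrier counts.  `reference-class`: c/d count carriers of the reference
class only; it is provided because a small number of reported recalculated
rows are not consistent with complement counting and their exact
denominator composition is not recoverable — the package does not force
agreement for those rows (see Limitations).

### Numerical conventions

- Zero cells: Haldane–Anscombe, +0.5 added to all four cells, on by
  default; disabling it makes zero-cell tables an error rather than a
  number.
- Rounding for table comparison: OR and CI bounds to 2 decimals, p to 3,
  percentages to 1, all half-up (`decimal.ROUND_HALF_UP`); internal values
  are kept at full precision and exported alongside the rounded columns.
- OR-strength bins: OR<0.2, [0.2, 0.5], (0.5, 2.0), [2.0, 5.0], OR>5 —
  the closed bins include their endpoints.
- Significance is a strict inequality: p = α exactly is not significant.
- Coordinates: VCF positions are 1-based everywhere except inside the
  regulatory module, which converts once (`pos0 = pos − 1`) to the 0-based
  half-open BED convention.  "Within ±w bp" of a peak measures from the SNP
  point to the nearest covered base and is inclusive at exactly w; in-peak
  samples (distance 0) are included in the window count.  Samples with no
  peaks on the SNP's chromosome count as closed chromatin, not missing.
- Heatmap ordering: agglomerative clustering with Hamming distance and
  complete linkage on the binary carrier matrix, rows and columns
  independently; the linkage's deterministic merge order resolves ties, and
  an all-identical (zero-distance) input keeps its original order.  Metric
  and linkage are a package convention for binary incidence data.
- Cluster detection: greedy growth in original column order of same-gene
  column groups whose pairwise agreement ≥ `min_agreement` (default 1.0,
  where the groups are exactly the equal-column classes per gene).
- Methylation group comparison: Welch's unequal-variance t-test on beta
  values, declared exploratory; at least 2 samples per group are required.

## Burden and combination semantics

A subject is a *carrier* of a significant SNP when its class equals the
tested class, regardless of OR direction — protective-SNP carriers count
toward burden.  Multiallelic sites with several significant classes
contribute one column (class union), so burden counts SNPs, not classes.
Missing genotypes count as non-carriers, with a logged tally.  Cluster
collapsing replaces member columns by their element-wise maximum; the four
built-in clusters (3+2+2+4 members in CYP7B1 and CYP39A1) ship as
overridable defaults.  Gene-combination counts are derived from per-subject
gene-incidence sets; `pair_only` counts incidence sets that are non-empty
subsets of the pair, which guarantees the additive identity
`only_A + only_B + both_only = pair_only`.

## Synthetic cohort generator

The real cohort resources (PPMI genotypes, FOUNDIN-PD ATAC-seq, EPIC
methylation, bulk RNA-seq) are access-controlled.  The generator emulates
the features the analysis relies on:

- **Genotypes**: per group, each subject's class at each site is an
  independent draw from a configured class distribution.  The default
  configuration plants, at every one of the 24 SNPs, the tested-class
  carrier probability implied by the published per-group carrier counts
  (e.g. 19/362 for rs118111353 in IPD) with the remaining mass on the
  site's reference class.  Carrier probabilities are the primitives; the
  implied OR is available in closed form (`expected_or`) and is what the
  recovery tests target.
- **Clusters**: member SNPs copy the head member's carrier status with a
  configurable fidelity (default 1.0 = perfectly co-occurring).
- **Peaks**: per sample and configured SNP, a peak covering the position is
  emitted with probability baseline × class-multiplier; a multiplier of 0
  reproduces allele-dependent closed chromatin (the default closes
  rs118111353 for `0/1` carriers).  Decoy peaks ≥5 kb away keep peak files
  non-trivial.
- **Methylation / expression**: betas are group-wise normal clipped to
  [0, 1] (clipping, not re-drawing: bias is negligible at the configured
  sds); expression is log-normal per group with a zero-expression CYP3A7
  control gene.

What it does **not** emulate: linkage disequilibrium beyond the
cluster-copy mechanism, per-site class spectra richer than two classes in
the default configuration, population stratification, covariate structure,
genotype uncertainty or missingness patterns, and read-level data.  Passing
parameter-recovery tests therefore demonstrates correctness of the
estimators under the stated sampling model, not robustness to the
confounders of real cohort data.

## Problem sizes and calibration checks

- **CI coverage**: 200 replicates at the cohort's group sizes (362 IPD /
  193 HC) with a planted OR of 3.5 at a control carrier frequency of 0.10,
  checking 93–97% coverage of the Woolf 95% interval.  The 10% frequency is
  representative of the cohort's common intronic variants and puts the
  check in the asymptotic regime where the interval's nominal level
  applies; at rare-variant frequencies (≈1.5%) expected counts in controls
  drop to ~3 and the Haldane-corrected interval over-covers (~97%), which
  is a property of the estimator at small counts, not an implementation
  artefact.
- **Log-OR recovery**: one replicate at 10⁵ subjects per group for planted
  ORs of 3.5 and 0.5 (absolute log-OR error < 0.05; the sampling SE at this
  size is ≈0.013–0.018).
- **Overlap equivalence**: 1,000 randomized peak fixtures (< 10 kb spans)
  against an exhaustive per-base scan.
- **Wald/Woolf duality**: 10,000 random tables with all cells ≥ 1,
  p < 0.05 ⟺ the 95% CI excludes 1 (both derive from the same z).
- Unit tests run the full pipeline on a scaled-down synthetic cohort
  (120 IPD / 80 HC / 20 GPD / 20 GUN), a size at which several of the
  planted associations are detectable while the whole suite stays fast.

## Known limitations

- The CYP27A1 coordinates in the built-in table are approximate (the
  source table rounds them); they are placeholders with realistic spacing
  inside the locus, used only for interval bookkeeping and simulation.
- A few published recalculated rows (sites whose baseline was reassigned)
  are not reproducible from the published carrier counts under either
  comparator mode; their denominators are not recoverable and no fixture is
  drawn from them.
- The per-subject tables behind the published burden and combination
  figures are not public; those stages are validated against the synthetic
  generator's truth records and closed-form identities instead.
- No covariate-adjusted regression, haplotype phasing, Hardy–Weinberg
  testing, peak calling or methylation-array normalization: the package
  starts from classified genotypes, called peaks and beta values.
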