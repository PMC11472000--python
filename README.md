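# cypassoc

Case-control genotype-class association analysis of SNPs in the four
cytochrome P450 genes that degrade cholesterol in the brain — **CYP46A1**,
**CYP39A1**, **CYP27A1** and **CYP7B1** — in Parkinson's disease (PD)
cohorts, together with per-subject SNP-burden profiling and regulatory
annotation against open chromatin and CpG methylation.

## Who this is for

Researchers studying genetic risk factors of idiopathic Parkinson's disease
(IPD) in cohorts such as PPMI, where subjects fall into four groups: IPD
patients, healthy controls (HC), genetically predisposed patients with
symptoms (GPD) and genetically predisposed unaffected individuals (GUN).
The cohort resources themselves are access-controlled, so the package ships
a seeded synthetic-cohort generator that emulates their statistical
structure and doubles as the test oracle.

## The statistics at the core

Diploid VCF calls are pooled into genotype classes `0/0`, `0/1`, `1/1` and
the multiallelic pools `0/2,etc.`, `1/2,etc.`, `2/2,etc.`.  For a variant
and a pair of groups (case, control), each non-reference class is tested
with a 2×2 table — *a*/*b* = case/control carriers of the tested class,
*c*/*d* = the comparator counts — and

- odds ratio: OR = (a·d)/(b·c),
- Woolf 95% CI: exp(ln OR ± 1.96·SE), SE = √(1/a + 1/b + 1/c + 1/d),
- two-sided Wald p-value from z = ln OR / SE.

The comparison baseline (*reference class*) at each site is the genotype
class most abundant among healthy controls.  At a handful of sites this is
**not** `0/0` — the conventional reference allele is actually the minority
allele in healthy people — and the baseline is reassigned, which flips the
direction and magnitude of the reported ORs ("reference-genotype
reassignment").  Zero cells get the Haldane–Anscombe +0.5 correction;
p-values are raw and two-sided with significance at p < 0.05.

Downstream, significant SNPs become a binary subject × SNP carrier matrix
used for burden distributions (optionally collapsing co-occurring SNP
clusters to one unit), gene-combination counts, carrier-frequency tables
and hierarchically clustered binary heatmaps.  SNP positions are also
annotated against per-sample ATAC-seq peak sets (in-peak and within ±500
bp), stratified by genotype, and linked to the nearest CpG site with a
Welch comparison of methylation betas between groups.

## Worked example

The built-in carrier table (`cypassoc.datasets`) records, for each of the
24 PD-associated SNPs, how many subjects of each group carry the tested
genotype class.  For rs118111353 (CYP7B1), 19 of 362 IPD patients and 3 of
193 healthy controls carry the `0/1` class:

```python
from cypassoc import datasets
from cypassoc.association_stats import (
    ClassCounts, build_contingency, odds_ratio, woolf_ci, wald_p)

row = datasets.PD_SNP_INDEX["rs118111353"]
sizes = datasets.GROUP_SIZES
case = ClassCounts("rs118111353", "IPD",
                   {"0/1": row["carriers"]["IPD"],
                    "0/0": sizes["IPD"] - row["carriers"]["IPD"]})
control = ClassCounts("rs118111353", "HC",
                      {"0/1": row["carriers"]["HC"],
                       "0/0": sizes["HC"] - row["carriers"]["HC"]})
t = build_contingency(case, control, "0/1", "0/0", "complement")
print(f"table a={t.a} b={t.b} c={t.c} d={t.d}")
print(f"OR = {odds_ratio(t):.2f}")
lo, hi = woolf_ci(t)
print(f"95% CI = ({lo:.2f}, {hi:.2f})")
print(f"p = {wald_p(t):.3f}")
```

prints

```
table a=19 b=3 c=343 d=190
OR = 3.51
95% CI = (1.02, 12.01)
p = 0.046
```

i.e. carriers of the alternate allele are about 3.5× over-represented among
IPD patients relative to healthy controls, with a confidence interval that
barely excludes 1 — a significant but imprecisely estimated risk signal, as
expected at 22 carriers total.

## Command line

```sh
assoc simulate --seed 1 --out cohort/          # synthetic fixture bundle
assoc validate --config cohort/run_config.yaml
assoc run --config cohort/run_config.yaml      # full pipeline
```

`assoc run` writes TSV reports: `associations.tsv` (per-class OR/CI/p with
the exact 2×2 cells), `or_bins.tsv` (OR-strength bins per gene),
`burden.tsv` (raw and cluster-collapsed burden distributions),
`gene_combos.tsv`, `carrier_freq.tsv`, `regulatory.tsv` and `run.log`.

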