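"""Built-in reference tables for the four brain cholesterol-degrading P450 genes.

Holds the published per-group carrier counts of the 24 PD-associated SNPs
from the PPMI case-control analysis (groups IPD, GPD, GUN, HC), the cohort
group sizes, the default co-occurring SNP clusters, and approximate gene
loci used to assign variants to genes.

Positions for the CYP27A1 variants are approximate: the source table rounds
them to three significant figures, so synthetic placeholders with realistic
spacing inside the CYP27A1 locus are used.  Positions are only consumed by
interval bookkeeping and the synthetic-cohort generator, never for lookup
against a reference genome.
"""

from __future__ import annotations

from .cohort_io import VariantRecord, normalize_variant_id

#: Cohort group sizes: idiopathic PD, healthy controls, genetic-predisposition
#: PD (symptomatic), genetic-predisposition unaffected.
GROUP_SIZES: dict[str, int] = {"IPD": 362, "HC": 193, "GPD": 317, "GUN": 344}

#: Approximate spans of the four genes, used to assign variants to genes.
GENE_LOCI: tuple[tuple[str, int, int, str], ...] = (
    ("chr14", 99_600_000, 99_800_000, "CYP46A1"),
    ("chr8", 64_500_000, 64_800_000, "CYP7B1"),
    ("chr6", 46_550_000, 46_700_000, "CYP39A1"),
    ("chr2", 219_500_000, 219_800_000, "CYP27A1"),
)


def assign_gene(chrom: str, pos: int) -> str:
    """Gene symbol whose locus contains (chrom, pos), or "" when unmapped."""
    for c, start, end, gene in GENE_LOCI:
        if chrom == c and start <= pos <= end:
            return gene
    return ""


# One row per PD-associated SNP: the variant, the genotype class whose
# over/under-representation is tested, the genotype class that dominates in
# healthy controls (the comparison baseline after reference reassignment),
# and the number of carriers of the tested class in each group.
# Carrier counts are per-group tallies of the tested genotype class.
PD_SNPS: tuple[dict, ...] = (
    # CYP46A1
    dict(record=VariantRecord("chr14", 99_719_392, "rs4905883", "G", ("T",), "CYP46A1"),
         tested_class="0/0", reference_class="1/1",
         carriers={"IPD": 1, "GPD": 4, "GUN": 1, "HC": 5}),
    dict(record=VariantRecord("chr14", 99_722_645, None, "G", ("GTGTGTGTGTC",), "CYP46A1"),
         tested_class="1/1", reference_class="0/0",
         carriers={"IPD": 65, "GPD": 39, "GUN": 53, "HC": 20}),
    dict(record=VariantRecord("chr14", 99_713_865, None, "CAAAAA",
                              ("CAAAAAAA", "C", "CAAAACAAAAAA"), "CYP46A1"),
         tested_class="1/2,etc.", reference_class="0/0",
         carriers={"IPD": 74, "GPD": 47, "GUN": 54, "HC": 20}),
    # CYP7B1
    dict(record=VariantRecord("chr8", 64_701_869, "rs2356986", "C", ("T",), "CYP7B1"),
         tested_class="0/1", reference_class="0/0",
         carriers={"IPD": 152, "GPD": 126, "GUN": 125, "HC": 64}),
    dict(record=VariantRecord("chr8", 64_701_977, "rs2356985", "C", ("G",), "CYP7B1"),
         tested_class="0/1", reference_class="0/0",
         carriers={"IPD": 153, "GPD": 126, "GUN": 125, "HC": 64}),
    dict(record=VariantRecord("chr8", 64_702_184, "rs2884074", "G", ("T",), "CYP7B1"),
         tested_class="0/1", reference_class="0/0",
         carriers={"IPD": 153, "GPD": 126, "GUN": 125, "HC": 64}),
    dict(record=VariantRecord("chr8", 64_726_077, "rs118111353", "T", ("C",), "CYP7B1"),
         tested_class="0/1", reference_class="0/0",
         carriers={"IPD": 19, "GPD": 1, "GUN": 6, "HC": 3}),
    dict(record=VariantRecord("chr8", 64_591_473, "rs16931331", "A", ("G",), "CYP7B1"),
         tested_class="1/1", reference_class="0/0",
         carriers={"IPD": 16, "GPD": 18, "GUN": 15, "HC": 2}),
    dict(record=VariantRecord("chr8", 64_591_813, "rs16931334", "C", ("T", "A"), "CYP7B1"),
         tested_class="1/1", reference_class="0/0",
         carriers={"IPD": 16, "GPD": 18, "GUN": 15, "HC": 2}),
    dict(record=VariantRecord("chr8", 64_607_398, None, "TAAA",
                              ("TA", "TAA", "TAAAA", "T"), "CYP7B1"),
         tested_class="0/0", reference_class="1/1",
         carriers={"IPD": 20, "GPD": 21, "GUN": 20, "HC": 3}),
    dict(record=VariantRecord("chr8", 64_656_091, "rs117732106", "C", ("G",), "CYP7B1"),
         tested_class="0/1", reference_class="0/0",
         carriers={"IPD": 7, "GPD": 12, "GUN": 16, "HC": 10}),
    dict(record=VariantRecord("chr8", 64_670_875, "rs4477068", "T", ("G",), "CYP7B1"),
         tested_class="0/1", reference_class="0/0",
         carriers={"IPD": 7, "GPD": 12, "GUN": 16, "HC": 10}),
    # CYP39A1
    dict(record=VariantRecord("chr6", 46_609_103, "rs200377987", "G", ("GA",), "CYP39A1"),
         tested_class="0/1", reference_class="0/0",
         carriers={"IPD": 19, "GPD": 12, "GUN": 15, "HC": 3}),
    dict(record=VariantRecord("chr6", 46_611_705, "rs188027691", "C", ("A",), "CYP39A1"),
         tested_class="0/1", reference_class="0/0",
         carriers={"IPD": 19, "GPD": 11, "GUN": 14, "HC": 3}),
    dict(record=VariantRecord("chr6", 46_628_780, "rs115993944", "C", ("T",), "CYP39A1"),
         tested_class="0/1", reference_class="0/0",
         carriers={"IPD": 19, "GPD": 12, "GUN": 14, "HC": 3}),
    dict(record=VariantRecord("chr6", 46_629_771, "rs3799865", "T", ("C",), "CYP39A1"),
         tested_class="0/1", reference_class="0/0",
         carriers={"IPD": 19, "GPD": 12, "GUN": 14, "HC": 3}),
    dict(record=VariantRecord("chr6", 46_613_939, "rs34289054", "CA", ("C", "AA", "CAA"), "CYP39A1"),
         tested_class="0/2,etc.", reference_class="0/0",
         carriers={"IPD": 11, "GPD": 10, "GUN": 18, "HC": 13}),
    dict(record=VariantRecord("chr6", 46_650_484, None, "CTTTT", ("CTTTTTTT", "CT"), "CYP39A1"),
         tested_class="1/1", reference_class="0/0",
         carriers={"IPD": 13, "GPD": 19, "GUN": 25, "HC": 18}),
    dict(record=VariantRecord("chr6", 46_634_524, "rs55887439", "CT", ("TT", "C", "CTT"), "CYP39A1"),
         tested_class="0/0", reference_class="1/1",
         carriers={"IPD": 90, "GPD": 69, "GUN": 71, "HC": 31}),
    # CYP27A1 (positions approximate, see module docstring)
    dict(record=VariantRecord("chr2", 219_646_800, "rs692303", "C", ("T",), "CYP27A1"),
         tested_class="0/1", reference_class="0/0",
         carriers={"IPD": 3, "GPD": 4, "GUN": 2, "HC": 8}),
    dict(record=VariantRecord("chr2", 219_648_500, "rs73991002", "A", ("C",), "CYP27A1"),
         tested_class="0/1", reference_class="0/0",
         carriers={"IPD": 2, "GPD": 4, "GUN": 2, "HC": 8}),
    dict(record=VariantRecord("chr2", 219_652_300, "rs692258", "C", ("T",), "CYP27A1"),
         tested_class="0/1", reference_class="0/0",
         carriers={"IPD": 3, "GPD": 4, "GUN": 2, "HC": 7}),
    dict(record=VariantRecord("chr2", 219_655_900, "rs692290", "G", ("T",), "CYP27A1"),
         tested_class="0/1", reference_class="0/0",
         carriers={"IPD": 3, "GPD": 4, "GUN": 2, "HC": 7}),
    dict(record=VariantRecord("chr2", 219_670_200, "rs74446825", "G", ("A",), "CYP27A1"),
         tested_class="0/1", reference_class="0/0",
         carriers={"IPD": 29, "GPD": 22, "GUN": 20, "HC": 27}),
)

#: variant id -> row of :data:`PD_SNPS`
PD_SNP_INDEX: dict[str, dict] = {
    normalize_variant_id(row["record"]): row for row in PD_SNPS
}

#: Default co-occurring SNP clusters (same-gene SNPs whose carrier status
#: co-occurs across subjects); collapsed to one unit in burden tables.
DEFAULT_CLUSTERS: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("CYP7B1_cluster1", "CYP7B1", ("rs2356986", "rs2356985", "rs2884074")),
    ("CYP7B1_cluster2", "CYP7B1", ("rs16931331", "rs16931334")),
    ("CYP7B1_cluster3", "CYP7B1", ("rs117732106", "rs4477068")),
    ("CYP39A1_cluster1", "CYP39A1",
     ("rs200377987", "rs188027691", "rs115993944", "rs3799865")),
)
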