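"""Seeded synthetic-cohort generator with closed-form oracles.

The real cohort data (PPMI whole-genome VCFs, FOUNDIN-PD ATAC-seq peaks,
EPIC methylation arrays and bulk RNA-seq) are access-controlled, so this
module generates inputs with the statistical structure the analysis
assumes: per-group genotype-class frequencies with known odds ratios,
co-occurring SNP clusters that copy a head SNP's carrier status with a
configurable fidelity, per-sample open-chromatin peak sets whose openness
may depend on the subject's genotype class, CpG sites at fixed offsets
from SNPs with group-structured beta values, and log-normal per-group
expression.  Every output is a pure function of (config, seed), and a
truth record of all sampled values accompanies each simulation.

Carrier probabilities (not odds ratios) are the generator's primitives;
:func:`expected_or` derives the implied odds ratio in closed form.

The default configuration mirrors the published IPD/GPD/GUN/HC carrier
frequencies of the 24 PD-associated SNPs, so desk-scale runs resemble the
real cohort's sparsity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import (
    CLASS_CODE,
    CLASS_LABELS,
    CLASS_ORDER,
    GROUPS,
    GenotypeMatrix,
    SubjectRecord,
    VariantRecord,
    normalize_variant_id,
)
from .regulatory_context import CpGSite, GenomicInterval, PeakSet

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


#: Representative diploid call written to the VCF for each pooled class.
CLASS_TO_GT: dict[str, str] = {
    "0/0": "0/0", "0/1": "0/1", "1/1": "1/1",
    "0/2,etc.": "0/2", "1/2,etc.": "1/2", "2/2,etc.": "2/2",
    "missing": "./.",
}


@dataclass
class VariantSpec:
    """One planted variant: per-group genotype-class probabilities."""

    record: VariantRecord
    tested_class: str
    reference_class: str
    class_probs: dict[str, dict[str, float]]  # group -> class -> probability

    @property
    def variant_id(self) -> str:
        return normalize_variant_id(self.record)

    def validate(self, groups: list[str]) -> None:
        vid = self.variant_id
        for g in groups:
            probs = self.class_probs.get(g)
            if probs is None:
                raise ConfigError(f"variant {vid}: no class probabilities for group {g}")
            if any(not 0 <= p <= 1 for p in probs.values()):
                raise ConfigError(f"variant {vid}: probability outside [0, 1] for {g}")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigError(
                    f"variant {vid}: class probabilities for {g} sum to "
                    f"{sum(probs.values())}, not 1"
                )
        max_index = 1 + len(self.record.alts)
        for cls in {self.tested_class, self.reference_class}:
            pair = CLASS_TO_GT[cls]
            if max(int(x) for x in pair.split("/")) >= max_index:
                raise ConfigError(
                    f"variant {vid}: class {cls} needs more alternate alleles"
                )


@dataclass
class ClusterSpec:
    """SNPs copying the head member's carrier status with given fidelity."""

    name: str
    gene: str
    members: tuple[str, ...]  # variant ids; members[0] is the head
    fidelity: float = 1.0

    def validate(self) -> None:
        if len(self.members) < 2:
            raise ConfigError(f"cluster {self.name}: needs >= 2 members")
        if not 0 <= self.fidelity <= 1:
            raise ConfigError(f"cluster {self.name}: fidelity outside [0, 1]")


@dataclass
class PeakSpec:
    """Openness model for one variant: P(open) = baseline * class multiplier."""

    baseline: float
    class_multiplier: dict[str, float] = field(default_factory=dict)
    half_width: int = 250


@dataclass
class CpGSpec:
    """One CpG site at a fixed offset from a variant, with per-group betas."""

    variant_id: str
    offset_bp: int
    group_beta: dict[str, tuple[float, float]]  # group -> (mean, sd)
    site_id: str | None = None


@dataclass
class SyntheticConfig:
    """Full description of a synthetic cohort (see module docstring)."""

    seed: int = 0
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"IPD": 362, "HC": 193, "GPD": 317, "GUN": 344}
    )
    variants: list[VariantSpec] = field(default_factory=list)
    clusters: list[ClusterSpec] = field(default_factory=list)
    peaks: dict[str, PeakSpec] = field(default_factory=dict)
    cpg: list[CpGSpec] = field(default_factory=list)
    # gene -> group -> (log_mean, log_sd); None plants a zero-expression gene
    expression: dict[str, dict[str, tuple[float, float]] | None] = field(
        default_factory=dict
    )

    def groups(self) -> list[str]:
        return [g for g in GROUPS if self.group_sizes.get(g, 0) > 0]

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ConfigError(f"unknown group '{g}'")
            if n < 0:
                raise ConfigError(f"negative size for group '{g}'")
        if not self.groups():
            raise ConfigError("no group with size >= 1")
        vids = set()
        for spec in self.variants:
            spec.validate(self.groups())
            if spec.variant_id in vids:
                raise ConfigError(f"duplicate planted variant {spec.variant_id}")
            vids.add(spec.variant_id)
        for cl in self.clusters:
            cl.validate()
            absent = [mbr for mbr in cl.members if mbr not in vids]
            if absent:
                raise ConfigError(f"cluster {cl.name}: unknown members {absent}")
        for vid in self.peaks:
            if vid not in vids:
                raise ConfigError(f"peak spec for unknown variant {vid}")
        for c in self.cpg:
            if c.variant_id not in vids:
                raise ConfigError(f"CpG spec for unknown variant {c.variant_id}")

    def variant_spec(self, variant_id: str) -> VariantSpec:
        for spec in self.variants:
            if spec.variant_id == variant_id:
                return spec
        raise ConfigError(f"unknown variant '{variant_id}'")


def two_class_probs(
    tested: str, reference: str, p_tested: dict[str, float]
) -> dict[str, dict[str, float]]:
    """Class probabilities concentrating all mass on tested vs reference."""
    return {
        g: {tested: p, reference: 1.0 - p} for g, p in p_tested.items()
    }


def planted_or_variant(
    or_value: float,
    p_control: float,
    record: VariantRecord | None = None,
    tested: str = "0/1",
    reference: str = "0/0",
) -> VariantSpec:
    """A biallelic IPD/HC variant whose tested-class odds ratio is exactly
    ``or_value`` given the control carrier probability."""
    odds = or_value * p_control / (1 - p_control)
    p_case = odds / (1 + odds)
    if record is None:
        record = VariantRecord("chr8", 64_700_000, "rs_planted", "A", ("G",), "CYP7B1")
    return VariantSpec(
        record, tested, reference,
        two_class_probs(tested, reference, {"IPD": p_case, "HC": p_control}),
    )


def default_config(seed: int = 0) -> SyntheticConfig:
    """Configuration mirroring the published cohort structure.

    Genotype-class frequencies reproduce the per-group carrier counts of
    the 24 PD-associated SNPs; the four co-occurring clusters copy their
    head SNP perfectly; rs118111353 openness excludes alternate-allele
    carriers (the allele-dependent openness seen in the iPSC lines);
    methylation betas do not differ between groups; expression is strongest
    for CYP46A1 and CYP27A1 with a zero-expression CYP3A7 control.
    """
    from . import datasets

    variants, clusters, peaks, cpg = [], [], {}, []
    for row in datasets.PD_SNPS:
        rec: VariantRecord = row["record"]
        p_tested = {
            g: row["carriers"][g] / datasets.GROUP_SIZES[g] for g in GROUPS
        }
        variants.append(
            VariantSpec(
                rec, row["tested_class"], row["reference_class"],
                two_class_probs(row["tested_class"], row["reference_class"], p_tested),
            )
        )
    for name, gene, members in datasets.DEFAULT_CLUSTERS:
        clusters.append(ClusterSpec(name, gene, members, fidelity=1.0))
    peaks["rs118111353"] = PeakSpec(
        baseline=0.35, class_multiplier={"0/1": 0.0}, half_width=250
    )
    peaks["rs74446825"] = PeakSpec(baseline=0.05, half_width=250)
    flat_beta = {g: (0.85, 0.05) for g in GROUPS}
    cpg = [
        CpGSpec("rs74446825", 175, flat_beta, site_id="cg02930667"),
        CpGSpec("rs4905883", -120, flat_beta),
        CpGSpec("rs692303", 340, flat_beta),
        CpGSpec("rs692290", -480, flat_beta),
    ]
    expression = {
        "CYP46A1": {g: (2.5, 0.4) for g in GROUPS},
        "CYP27A1": {g: (2.2, 0.4) for g in GROUPS},
        "CYP7B1": {g: (0.7, 0.5) for g in GROUPS},
        "CYP39A1": {g: (0.3, 0.5) for g in GROUPS},
        "CYP3A7": None,
    }
    return SyntheticConfig(
        seed=seed,
        group_sizes=dict(datasets.GROUP_SIZES),
        variants=variants,
        clusters=clusters,
        peaks=peaks,
        cpg=cpg,
        expression=expression,
    )


def _rng(cfg: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stage])


def simulate_cohort(
    cfg: SyntheticConfig,
) -> tuple[list[SubjectRecord], GenotypeMatrix, dict]:
    """Draw the cohort: subjects, classified genotypes and the truth record."""
    cfg.validate()
    rng = _rng(cfg, 0)
    subjects = [
        SubjectRecord(f"{g}_{i:05d}", g)
        for g in cfg.groups()
        for i in range(cfg.group_sizes[g])
    ]
    n = len(subjects)
    group_rows = {
        g: np.array([i for i, s in enumerate(subjects) if s.group == g]) for g in cfg.groups()
    }
    codes = np.empty((n, len(cfg.variants)), dtype=np.int8)
    for j, spec in enumerate(cfg.variants):
        for g in cfg.groups():
            probs = np.array(
                [spec.class_probs[g].get(cls, 0.0) for cls in CLASS_ORDER]
            )
            draw = rng.choice(len(CLASS_ORDER), size=len(group_rows[g]), p=probs)
            codes[group_rows[g], j] = draw
    col_of = {spec.variant_id: j for j, spec in enumerate(cfg.variants)}
    # cluster members copy the head's carrier status with the given fidelity
    for cl in cfg.clusters:
        head_spec = cfg.variant_spec(cl.members[0])
        head_carrier = codes[:, col_of[cl.members[0]]] == CLASS_CODE[head_spec.tested_class]
        for mbr in cl.members[1:]:
            spec = cfg.variant_spec(mbr)
            copy_mask = rng.random(n) < cl.fidelity
            j = col_of[mbr]
            codes[copy_mask & head_carrier, j] = CLASS_CODE[spec.tested_class]
            codes[copy_mask & ~head_carrier, j] = CLASS_CODE[spec.reference_class]
    matrix = GenotypeMatrix(subjects, [s.record for s in cfg.variants], codes)
    truth = {
        "seed": int(cfg.seed),
        "group_sizes": {g: cfg.group_sizes[g] for g in cfg.groups()},
        "classes": matrix.classes_frame(),
        "tested_class": {s.variant_id: s.tested_class for s in cfg.variants},
        "class_counts": {
            s.variant_id: {
                g: {
                    cls: int(
                        np.count_nonzero(
                            codes[group_rows[g], col_of[s.variant_id]] == CLASS_CODE[cls]
                        )
                    )
                    for cls in CLASS_ORDER
                }
                for g in cfg.groups()
            }
            for s in cfg.variants
        },
    }
    return subjects, matrix, truth


def expected_or(
    cfg: SyntheticConfig,
    variant_id: str,
    tested: str,
    group_pair: tuple[str, str],
) -> float:
    """Closed-form odds ratio implied by the planted class probabilities."""
    spec = cfg.variant_spec(variant_id)
    case, control = group_pair
    p_case = spec.class_probs[case].get(tested, 0.0)
    p_ctrl = spec.class_probs[control].get(tested, 0.0)
    if not 0 < p_case < 1 or not 0 < p_ctrl < 1:
        raise ConfigError(
            f"degenerate tested-class probability for {variant_id} ({p_case}, {p_ctrl})"
        )
    return (p_case / (1 - p_case)) / (p_ctrl / (1 - p_ctrl))


def simulate_peaks(
    cfg: SyntheticConfig, matrix: GenotypeMatrix
) -> tuple[list[PeakSet], dict]:
    """Per-sample open-chromatin peak sets over the planted variants.

    Each configured variant emits, per sample, a peak covering the SNP with
    probability baseline * class multiplier (clipped to [0, 1]); decoy
    peaks far from every SNP are added so peak files are never trivially
    informative.  Truth records the open/closed call per sample and variant.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    peak_sets: list[PeakSet] = []
    truth: dict[str, dict[str, bool]] = {}
    for subj in matrix.subjects:
        sid = subj.subject_id
        intervals: list[GenomicInterval] = []
        truth[sid] = {}
        for vid, pspec in cfg.peaks.items():
            rec = matrix.variant_record(vid)
            pos0 = rec.pos - 1
            cls = matrix.class_label(sid, vid)
            p = float(
                np.clip(pspec.baseline * pspec.class_multiplier.get(cls, 1.0), 0, 1)
            )
            is_open = bool(rng.random() < p)
            truth[sid][vid] = is_open
            if is_open:
                intervals.append(
                    GenomicInterval(
                        rec.chrom,
                        max(0, pos0 - pspec.half_width),
                        pos0 + pspec.half_width,
                    )
                )
            # decoy peak well outside the +/-500 bp window of the SNP
            if rng.random() < 0.5:
                start = pos0 + 5_000 + int(rng.integers(0, 2_000))
                intervals.append(GenomicInterval(rec.chrom, start, start + 300))
        peak_sets.append(PeakSet(sid, intervals))
    return peak_sets, truth


def simulate_methylation(
    cfg: SyntheticConfig, subjects: list[SubjectRecord]
) -> tuple[list[CpGSite], dict]:
    """CpG sites near planted variants with per-group beta values.

    Betas are normal per group, clipped to [0, 1]; truth records the
    configured group means.
    """
    cfg.validate()
    rng = _rng(cfg, 2)
    vrec = {s.variant_id: s.record for s in cfg.variants}
    sites: list[CpGSite] = []
    truth: dict[str, dict] = {}
    for i, cspec in enumerate(cfg.cpg):
        rec = vrec[cspec.variant_id]
        site_id = cspec.site_id or f"cgSIM{i:05d}"
        beta: dict[str, float] = {}
        for subj in subjects:
            params = cspec.group_beta.get(subj.group)
            if params is None:
                continue
            mean, sd = params
            beta[subj.subject_id] = float(np.clip(rng.normal(mean, sd), 0.0, 1.0))
        sites.append(CpGSite(site_id, rec.chrom, rec.pos + cspec.offset_bp, beta))
        truth[site_id] = {
            "variant": cspec.variant_id,
            "offset_bp": cspec.offset_bp,
            "group_means": {g: m for g, (m, _) in cspec.group_beta.items()},
        }
    return sites, truth


def simulate_expression(
    cfg: SyntheticConfig, subjects: list[SubjectRecord]
) -> pd.DataFrame:
    """Log-normal per-group RPKM table (genes x samples); None plants zeros."""
    cfg.validate()
    rng = _rng(cfg, 3)
    data = {}
    for gene, spec in cfg.expression.items():
        vals = np.zeros(len(subjects))
        if spec is not None:
            for i, subj in enumerate(subjects):
                log_mean, log_sd = spec[subj.group]
                vals[i] = np.exp(rng.normal(log_mean, log_sd))
        data[gene] = vals
    return pd.DataFrame(
        data, index=[s.subject_id for s in subjects]
    ).T.rename_axis("gene")


def _write_vcf(
    path: Path, subjects: list[SubjectRecord], matrix: GenotypeMatrix
) -> None:
    order = sorted(
        range(len(matrix.variants)),
        key=lambda j: (matrix.variants[j].chrom, matrix.variants[j].pos),
    )
    chroms = sorted({v.chrom for v in matrix.variants})
    sids = [s.subject_id for s in matrix.subjects]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cypassoc-synthetic\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sids) + "\n"
        )
        for j in order:
            v = matrix.variants[j]
            gts = "\t".join(
                CLASS_TO_GT[CLASS_LABELS[code]] for code in matrix.codes[:, j]
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.rsid or '.'}\t{v.ref}\t"
                f"{','.join(v.alts)}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_fixture_bundle(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate everything and write a pipeline-ready bundle of files.

    Emits a VCF, a sample sheet, per-sample BED peak files, CpG site and
    beta tables, an expression table, a truth record (JSON) and a run
    configuration (YAML) pointing at them all.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects, matrix, truth_cohort = simulate_cohort(cfg)
    peak_sets, truth_peaks = simulate_peaks(cfg, matrix)
    sites, truth_cpg = simulate_methylation(cfg, subjects)
    rpkm = simulate_expression(cfg, subjects)

    paths = {
        "vcf": outdir / "cohort.vcf",
        "sample_sheet": outdir / "samples.csv",
        "bed_dir": outdir / "peaks",
        "cpg_sites": outdir / "cpg_sites.tsv",
        "cpg_betas": outdir / "cpg_betas.tsv",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "truth.json",
        "run_config": outdir / "run_config.yaml",
    }
    _write_vcf(paths["vcf"], subjects, matrix)
    pd.DataFrame(
        [(s.subject_id, s.group) for s in subjects], columns=["subject_id", "group"]
    ).to_csv(paths["sample_sheet"], index=False)
    paths["bed_dir"].mkdir(exist_ok=True)
    for ps in peak_sets:
        with open(paths["bed_dir"] / f"{ps.sample_id}.bed", "w") as fh:
            for iv in ps.intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    pd.DataFrame(
        [(s.site_id, s.chrom, s.pos) for s in sites],
        columns=["site_id", "chrom", "pos"],
    ).to_csv(paths["cpg_sites"], sep="\t", index=False)
    beta_df = pd.DataFrame(
        {s.site_id: s.beta for s in sites}
    ).T.rename_axis("site_id")
    beta_df.to_csv(paths["cpg_betas"], sep="\t")
    rpkm.to_csv(paths["expression"], sep="\t")
    truth = {
        "cohort": {
            k: (v.to_dict(orient="index") if isinstance(v, pd.DataFrame) else v)
            for k, v in truth_cohort.items()
        },
        "peaks": truth_peaks,
        "cpg": truth_cpg,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    run_cfg = {
        "vcf": str(paths["vcf"]),
        "sample_sheet": str(paths["sample_sheet"]),
        "bed_dir": str(paths["bed_dir"]),
        "cpg_sites": str(paths["cpg_sites"]),
        "cpg_betas": str(paths["cpg_betas"]),
        "expression": str(paths["expression"]),
        "group_pairs": [["IPD", "HC"]],
        "alpha": 0.05,
        "mode": "complement",
        "window_bp": 500,
        "zero_cell": True,
        "out_dir": str(outdir / "results"),
        "seed": int(cfg.seed),
    }
    paths["run_config"].write_text(yaml.safe_dump(run_cfg))
    logger.info("fixture bundle written to %s", outdir)
    return paths
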