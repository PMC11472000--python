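"""Cohort input handling: sample sheets, VCF genotypes and pooled genotype classes.

Diploid VCF calls are mapped into the pooled genotype classes used by the
case-control analysis: "0/0", "0/1", "1/1" for biallelic calls and the
multiallelic pools "0/2,etc." (reference plus any higher alternate),
"1/2,etc." (two distinct alternates) and "2/2,etc." (homozygous for a
higher alternate).  Calls with any unknown allele become "missing", a
first-class category that is excluded from contingency counts downstream.

Coordinates are 1-based throughout this module (the VCF convention);
conversion to 0-based half-open intervals happens only in
:mod:`cypassoc.regulatory_context`.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: The four cohort groups: idiopathic PD, healthy controls, genetically
#: predisposed with symptoms, genetically predisposed unaffected.
GROUPS: tuple[str, ...] = ("IPD", "HC", "GPD", "GUN")

#: Fixed ordering of the non-missing genotype classes (also the tie-break
#: order for reference-class assignment).
CLASS_ORDER: tuple[str, ...] = ("0/0", "0/1", "1/1", "0/2,etc.", "1/2,etc.", "2/2,etc.")
MISSING: str = "missing"
CLASS_LABELS: tuple[str, ...] = CLASS_ORDER + (MISSING,)
CLASS_CODE: dict[str, int] = {label: i for i, label in enumerate(CLASS_LABELS)}
MISSING_CODE: int = CLASS_CODE[MISSING]


class CohortError(ValueError):
    """Validation failure in cohort inputs."""


@dataclass(frozen=True)
class SubjectRecord:
    """One cohort subject with its group assignment."""

    subject_id: str
    group: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortError(
                f"unknown group label '{self.group}' for subject '{self.subject_id}'"
            )


@dataclass(frozen=True)
class VariantRecord:
    """One variant site: 1-based position, reference and alternate alleles."""

    chrom: str
    pos: int
    rsid: str | None
    ref: str
    alts: tuple[str, ...]
    gene: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CohortError(f"variant position must be >= 1, got {self.pos}")
        if not self.alts:
            raise CohortError(f"variant at {self.chrom}:{self.pos} has no alternate allele")
        if any(alt == self.ref for alt in self.alts):
            raise CohortError(
                f"variant at {self.chrom}:{self.pos} lists REF among its ALTs"
            )


def normalize_variant_id(v: VariantRecord) -> str:
    """Stable variant identifier: rsid when present, else chrom:pos_REF/firstALT."""
    if v.rsid:
        return v.rsid
    return f"{v.chrom}:{v.pos}_{v.ref}/{v.alts[0]}"


def classify_genotype(alleles) -> str:
    """Map an unordered diploid allele-index pair to its pooled genotype class.

    ``alleles`` is a length-2 sequence of non-negative allele indices;
    ``None`` or ``"."`` mark an unknown allele and force "missing".
    Phasing is irrelevant: the pair is sorted before mapping.
    """
    alleles = tuple(alleles)
    if len(alleles) != 2:
        raise CohortError(f"diploid calls only: expected 2 allele slots, got {len(alleles)}")
    norm = []
    for a in alleles:
        if a is None or a == ".":
            return MISSING
        a = int(a)
        if a < 0:
            return MISSING
        norm.append(a)
    i, j = sorted(norm)
    if j == 0:
        return "0/0"
    if (i, j) == (0, 1):
        return "0/1"
    if (i, j) == (1, 1):
        return "1/1"
    if i == 0:  # j >= 2
        return "0/2,etc."
    if i == j:  # i >= 2
        return "2/2,etc."
    return "1/2,etc."  # 1 <= i < j, j >= 2


def read_sample_sheet(path: str | Path) -> list[SubjectRecord]:
    """Read a delimited sample sheet with header columns subject_id, group."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"subject_id", "group"}
    if not required.issubset(df.columns):
        raise CohortError(
            f"sample sheet {path} must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    records: list[SubjectRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        sid, group = str(row["subject_id"]), str(row["group"])
        if group not in GROUPS:
            raise CohortError(f"unknown group label '{group}' in row {idx + 1}")
        if sid in seen:
            raise CohortError(f"duplicate subject_id '{sid}' in row {idx + 1}")
        seen.add(sid)
        records.append(SubjectRecord(sid, group))
    tally = Counter(r.group for r in records)
    logger.info("sample sheet %s: %s", path, dict(tally))
    return records


def group_tally(subjects: list[SubjectRecord]) -> dict[str, int]:
    """Number of subjects per group."""
    return dict(Counter(s.group for s in subjects))


@dataclass
class GenotypeMatrix:
    """Subjects x variants grid of pooled genotype classes.

    Classes are stored as small integer codes (see :data:`CLASS_CODE`);
    label accessors are provided for readability at the edges.
    """

    subjects: list[SubjectRecord]
    variants: list[VariantRecord]
    codes: np.ndarray  # int8, shape (n_subjects, n_variants)
    _vid_index: dict[str, int] = field(init=False, repr=False)
    _sid_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.subjects), len(self.variants)):
            raise CohortError(
                f"genotype grid shape {self.codes.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.variants)} variants"
            )
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() > MISSING_CODE):
            raise CohortError("genotype grid contains invalid class codes")
        vids = [normalize_variant_id(v) for v in self.variants]
        if len(set(vids)) != len(vids):
            dupes = [v for v, n in Counter(vids).items() if n > 1]
            raise CohortError(f"variant id collision: {dupes}")
        sids = [s.subject_id for s in self.subjects]
        if len(set(sids)) != len(sids):
            raise CohortError("duplicate subject ids in genotype matrix")
        self._vid_index = {v: i for i, v in enumerate(vids)}
        self._sid_index = {s: i for i, s in enumerate(sids)}

    @property
    def variant_ids(self) -> list[str]:
        return list(self._vid_index)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._vid_index[variant_id]
        except KeyError:
            raise CohortError(f"unknown variant '{variant_id}'") from None

    def variant_record(self, variant_id: str) -> VariantRecord:
        return self.variants[self.variant_index(variant_id)]

    def subject_index(self, subject_id: str) -> int:
        try:
            return self._sid_index[subject_id]
        except KeyError:
            raise CohortError(f"unknown subject '{subject_id}'") from None

    def group_mask(self, group: str) -> np.ndarray:
        if group not in GROUPS:
            raise CohortError(f"unknown group label '{group}'")
        return np.array([s.group == group for s in self.subjects], dtype=bool)

    def groups_present(self) -> set[str]:
        return {s.group for s in self.subjects}

    def class_label(self, subject_id: str, variant_id: str) -> str:
        return CLASS_LABELS[
            self.codes[self.subject_index(subject_id), self.variant_index(variant_id)]
        ]

    def classes_frame(self) -> pd.DataFrame:
        """Class labels as a subjects x variants DataFrame."""
        labels = np.array(CLASS_LABELS, dtype=object)[self.codes]
        return pd.DataFrame(
            labels,
            index=[s.subject_id for s in self.subjects],
            columns=self.variant_ids,
        )


def read_target_variants(path: str | Path) -> list[str]:
    """Plain-text target list, one variant id per line; blank lines ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def read_genotypes(
    vcf_path: str | Path,
    subjects: list[SubjectRecord],
    target_variants: list[str] | None = None,
    gene_map: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Read per-sample GT fields from a VCF and classify them.

    Only the GT field is consulted.  Phase separators are ignored.  Subjects
    absent from the VCF raise; explicitly requested variants absent from the
    VCF raise, listing them.  Malformed or absent GT entries become
    "missing" with a logged warning.  ``gene_map`` optionally maps variant
    ids to gene symbols; otherwise genes are assigned from the built-in
    P450 loci.
    """
    from . import datasets

    wanted = set(target_variants) if target_variants is not None else None
    sids = [s.subject_id for s in subjects]
    with pysam.VariantFile(str(vcf_path)) as vf:
        vcf_samples = set(vf.header.samples)
        absent = [s for s in sids if s not in vcf_samples]
        if absent:
            raise CohortError(f"subjects missing from VCF {vcf_path}: {absent}")
        variants: list[VariantRecord] = []
        columns: list[np.ndarray] = []
        n_malformed = 0
        for rec in vf:
            if not rec.alts:
                logger.warning("skipping ALT-less record at %s:%s", rec.chrom, rec.pos)
                continue
            rsid = rec.id if rec.id not in (None, ".") else None
            vr = VariantRecord(rec.chrom, rec.pos, rsid, rec.ref, tuple(rec.alts))
            vid = normalize_variant_id(vr)
            if wanted is not None and vid not in wanted:
                continue
            gene = (
                gene_map.get(vid, "")
                if gene_map is not None
                else datasets.assign_gene(rec.chrom, rec.pos)
            )
            vr = VariantRecord(rec.chrom, rec.pos, rsid, rec.ref, tuple(rec.alts), gene)
            col = np.empty(len(sids), dtype=np.int8)
            for i, sid in enumerate(sids):
                gt = rec.samples[sid].get("GT")
                if gt is None:
                    n_malformed += 1
                    col[i] = MISSING_CODE
                    continue
                col[i] = CLASS_CODE[classify_genotype(gt)]
            variants.append(vr)
            columns.append(col)
    if n_malformed:
        logger.warning("%d absent/malformed GT entries set to 'missing'", n_malformed)
    if wanted is not None:
        found = {normalize_variant_id(v) for v in variants}
        missing = sorted(wanted - found)
        if missing:
            raise CohortError(f"requested variants absent from VCF: {missing}")
    codes = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(sids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(list(subjects), variants, codes)
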