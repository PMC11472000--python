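"""SNP annotation against open-chromatin peaks, CpG sites and expression.

Peaks are 0-based half-open intervals (the BED convention); SNP positions
arrive 1-based from the VCF side and are converted with ``pos0 = pos - 1``
exactly once, here.  A SNP is *in* open chromatin for a sample when some
peak interval of that sample covers pos0; it is *within the window* when
the distance from pos0 to the nearest peak edge is <= the half-width
(inclusive at exactly the boundary; in-peak samples have distance 0 and are
included).  Samples with no peaks on the SNP's chromosome count as closed
chromatin.  Strand is ignored throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .cohort_io import CohortError, GenotypeMatrix, SubjectRecord, VariantRecord, normalize_variant_id

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")


@dataclass
class PeakSet:
    """Open-chromatin intervals of one sample, sorted by (chrom, start)."""

    sample_id: str
    intervals: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start))

    def by_chrom(self, chrom: str) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.chrom == chrom]


@dataclass
class CpGSite:
    """A methylation site with per-sample beta values in [0, 1]."""

    site_id: str
    chrom: str
    pos: int  # 1-based
    beta: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.beta.items() if not 0 <= v <= 1}
        if bad:
            raise ValueError(f"beta values outside [0, 1] at {self.site_id}: {bad}")


@dataclass
class RegulatoryAnnotation:
    """Open-chromatin summary of one SNP over a set of samples."""

    variant: str
    n_in_peak: int
    n_within_window: int
    window_bp: int
    in_peak_samples: list[str] = field(default_factory=list)
    within_samples: list[str] = field(default_factory=list)
    allele_breakdown: dict[str, int] = field(default_factory=dict)
    nearest_cpg: tuple[str, int] | None = None


def read_peaks(path: str | Path, sample_id: str) -> PeakSet:
    """Read a BED3+ file into a PeakSet (extra columns ignored)."""
    path = Path(path)
    if path.stat().st_size == 0:
        return PeakSet(sample_id, [])
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={"chrom": str},
    )
    try:
        starts = df["start"].astype(int)
        ends = df["end"].astype(int)
    except (ValueError, TypeError) as exc:
        raise CohortError(f"malformed BED coordinates in {path}: {exc}") from exc
    if (starts < 0).any():
        line = int(np.argmax(starts.to_numpy() < 0)) + 1
        raise CohortError(f"negative coordinate in {path} line {line}")
    intervals = [
        GenomicInterval(c, s, e) for c, s, e in zip(df["chrom"], starts, ends)
    ]
    if intervals != sorted(intervals, key=lambda iv: (iv.chrom, iv.start)):
        logger.info("peaks in %s were unsorted; sorting", path)
    return PeakSet(sample_id, intervals)


def _distance_to_peaks(pos0: int, intervals: list[GenomicInterval]) -> int | None:
    """bp from a 0-based point to the nearest covered base; None without peaks."""
    if not intervals:
        return None
    starts = np.array([iv.start for iv in intervals])
    ends = np.array([iv.end for iv in intervals])
    # distance to interval [s, e): 0 inside, else gap to nearest covered base
    d = np.maximum.reduce([starts - pos0, pos0 - (ends - 1), np.zeros(len(starts), dtype=int)])
    return int(d.min())


def snp_peak_overlap(
    v: VariantRecord, peaks: list[PeakSet], window_bp: int = 500
) -> RegulatoryAnnotation:
    """Count samples whose open chromatin covers the SNP or lies within the window."""
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    pos0 = v.pos - 1
    in_peak, within = [], []
    for ps in peaks:
        ivs = ps.by_chrom(v.chrom)
        if ivs:
            tree = IntervalTree.from_tuples((iv.start, iv.end) for iv in ivs)
            if tree[pos0]:
                in_peak.append(ps.sample_id)
        dist = _distance_to_peaks(pos0, ivs)
        if dist is not None and dist <= window_bp:
            within.append(ps.sample_id)
    return RegulatoryAnnotation(
        variant=normalize_variant_id(v),
        n_in_peak=len(in_peak),
        n_within_window=len(within),
        window_bp=window_bp,
        in_peak_samples=in_peak,
        within_samples=within,
    )


def allele_stratify(
    ann: RegulatoryAnnotation, m: GenotypeMatrix
) -> RegulatoryAnnotation:
    """Genotype-class breakdown of the in-peak samples at the SNP.

    Sample ids must map to subject ids of the genotype matrix.
    """
    unmapped = [s for s in ann.in_peak_samples if s not in {x.subject_id for x in m.subjects}]
    if unmapped:
        raise CohortError(f"in-peak samples without a subject: {unmapped}")
    breakdown: dict[str, int] = {}
    for sid in ann.in_peak_samples:
        cls = m.class_label(sid, ann.variant)
        breakdown[cls] = breakdown.get(cls, 0) + 1
    return replace(ann, allele_breakdown=breakdown)


def nearest_cpg(
    v: VariantRecord, sites: list[CpGSite], max_bp: int = 500
) -> tuple[str, int] | None:
    """Same-chromosome CpG site minimizing |site pos - SNP pos|, within max_bp.

    Returns (site_id, signed distance site-minus-SNP); ties go to the
    smaller coordinate; None when no site lies within the window.
    """
    if max_bp < 0:
        raise ValueError("max_bp must be >= 0")
    best: tuple[int, int, str] | None = None  # (|d|, pos, site_id)
    for s in sites:
        if s.chrom != v.chrom:
            continue
        d = s.pos - v.pos
        key = (abs(d), s.pos, s.site_id)
        if abs(d) <= max_bp and (best is None or key < best):
            best = key
    if best is None:
        return None
    _, pos, site_id = best
    return site_id, pos - v.pos


def methylation_group_compare(
    site: CpGSite,
    subjects: list[SubjectRecord],
    pair: tuple[str, str] = ("IPD", "HC"),
) -> dict | None:
    """Welch two-sample comparison of beta values between the pair's groups.

    Exploratory, no multiplicity correction.  Returns None (with a logged
    notice) when either group has fewer than 2 measured samples.
    """
    group_of = {s.subject_id: s.group for s in subjects}
    vals: dict[str, list[float]] = {g: [] for g in pair}
    for sid, beta in site.beta.items():
        g = group_of.get(sid)
        if g in vals:
            vals[g].append(beta)
    if any(len(v) < 2 for v in vals.values()):
        logger.info(
            "site %s: fewer than 2 samples in a group of %s; no test", site.site_id, pair
        )
        return None
    x, y = (np.array(vals[g]) for g in pair)
    t = stats.ttest_ind(x, y, equal_var=False)
    return dict(
        site_id=site.site_id,
        groups=pair,
        n=(len(x), len(y)),
        means=(float(x.mean()), float(y.mean())),
        difference=float(x.mean() - y.mean()),
        p_value=float(t.pvalue),
    )


def expression_group_summary(
    rpkm: pd.DataFrame,
    subjects: list[SubjectRecord],
    genes: list[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene per-group expression summaries (median, quartiles, n).

    ``rpkm`` is genes x samples.  Genes absent from the table are returned
    in the second element; genes with zero expression in every sample are
    flagged (negative-control behaviour).
    """
    missing = [g for g in genes if g not in rpkm.index]
    if missing:
        logger.warning("genes absent from expression table: %s", missing)
    group_of = {s.subject_id: s.group for s in subjects}
    rows = []
    for gene in genes:
        if gene in missing:
            continue
        series = rpkm.loc[gene]
        all_zero = bool((series == 0).all())
        by_group: dict[str, list[float]] = {}
        for sid, val in series.items():
            g = group_of.get(str(sid))
            if g is not None:
                by_group.setdefault(g, []).append(float(val))
        for g, vals in sorted(by_group.items()):
            arr = np.array(vals)
            rows.append(
                dict(
                    gene=gene,
                    group=g,
                    n=len(arr),
                    median=float(np.median(arr)),
                    q1=float(np.percentile(arr, 25)),
                    q3=float(np.percentile(arr, 75)),
                    zero_expression=all_zero,
                )
            )
    return pd.DataFrame(rows), missing
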