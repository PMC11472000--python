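"""Genotype-class odds-ratio testing with reference-genotype reassignment.

For each variant and group pair (case, control) the analysis:

1. tallies subjects of each group into pooled genotype classes
   (missing calls excluded but reported),
2. declares the class most abundant among healthy controls the *reference*
   class — at a handful of sites the conventional "0/0" is not the majority
   genotype in healthy people, and the comparison baseline is reassigned,
3. for every other class with at least one carrier, builds a 2x2 table and
   computes the cross-product odds ratio, the Woolf (log-scale normal
   approximation) confidence interval, and a two-sided Wald p-value.

For a single binary predictor on a 2x2 table these closed forms coincide
with the Wald statistics of a logistic regression, so no iterative fitting
is involved.  Zero cells are handled with the Haldane–Anscombe +0.5
correction (all four cells), enabled by default.

P-values are raw and two-sided; no multiplicity adjustment is applied by
default (an optional Benjamini–Hochberg filter is available).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up
from .cohort_io import (
    CLASS_CODE,
    CLASS_ORDER,
    CohortError,
    GenotypeMatrix,
    MISSING_CODE,
)

logger = logging.getLogger(__name__)

#: Odds-ratio strength bins; the closed bins [0.2, 0.5] and [2.0, 5.0]
#: include their endpoints, the outer bins are strict.
OR_BIN_LABELS: tuple[str, ...] = (
    "OR<0.2", "0.2<=OR<=0.5", "0.5<OR<2.0", "2.0<=OR<=5.0", "OR>5",
)

#: Group pairs (case, control) the analysis is defined for.
GROUP_PAIRS: tuple[tuple[str, str], ...] = (
    ("IPD", "HC"), ("GPD", "HC"), ("GPD", "GUN"), ("IPD", "GPD"), ("IPD", "GUN"),
)


class ZeroCellError(ValueError):
    """A 2x2 cell is zero and the zero-cell correction is disabled."""


@dataclass
class ClassCounts:
    """Genotype-class tallies for one variant within one group."""

    variant: str
    group: str
    counts: dict[str, int]
    missing: int = 0

    @property
    def total_informative(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a/b = case/control carriers of the tested class,
    c/d = case/control comparator counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")


@dataclass
class AssociationResult:
    """One tested genotype class of one variant for one (case, control) pair."""

    variant: str
    gene: str
    pos: int
    tested_class: str
    reference_class: str
    case_group: str
    control_group: str
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    table: ContingencyTable


@dataclass
class ORBinSummary:
    """Per-gene counts of significant results in the five OR-strength bins."""

    group_pair: tuple[str, str]
    bins: dict[str, list[int]] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(
            self.bins, orient="index", columns=list(OR_BIN_LABELS)
        ).rename_axis("gene")


def count_genotype_classes(
    m: GenotypeMatrix, group: str, variant: str
) -> ClassCounts:
    """Tally the genotype classes of one variant over the subjects of one group."""
    col = m.codes[m.group_mask(group), m.variant_index(variant)]
    counts = {
        label: int(np.count_nonzero(col == CLASS_CODE[label])) for label in CLASS_ORDER
    }
    missing = int(np.count_nonzero(col == MISSING_CODE))
    return ClassCounts(variant, group, counts, missing)


def assign_reference_class(hc_counts: ClassCounts) -> str:
    """The non-missing class with the maximal healthy-control count.

    Ties break by the fixed class order "0/0" < "0/1" < "1/1" < "0/2,etc."
    < "1/2,etc." < "2/2,etc.".
    """
    if hc_counts.total_informative == 0:
        raise CohortError(
            f"no informative healthy-control genotypes for {hc_counts.variant}"
        )
    return max(CLASS_ORDER, key=lambda cls: (hc_counts.counts.get(cls, 0), ))


def build_contingency(
    case_counts: ClassCounts,
    control_counts: ClassCounts,
    tested: str,
    reference: str,
    mode: str = "complement",
) -> ContingencyTable:
    """2x2 table for one tested class.

    ``mode="complement"``: the comparator rows c, d are all non-missing
    subjects not carrying the tested class (the convention that reproduces
    the published OR/CI/p values).  ``mode="reference-class"``: c, d count
    carriers of the reference class only.
    """
    if tested == reference:
        raise CohortError(
            f"tested class '{tested}' equals the reference class for "
            f"{case_counts.variant}"
        )
    if mode not in ("complement", "reference-class"):
        raise ValueError(f"unknown comparator mode '{mode}'")
    a = case_counts.counts.get(tested, 0)
    b = control_counts.counts.get(tested, 0)
    if mode == "complement":
        c = case_counts.total_informative - a
        d = control_counts.total_informative - b
    else:
        c = case_counts.counts.get(reference, 0)
        d = control_counts.counts.get(reference, 0)
    return ContingencyTable(a, b, c, d)


def _cells(t: ContingencyTable, zero_cell: bool) -> tuple[float, float, float, float]:
    cells = (t.a, t.b, t.c, t.d)
    if min(cells) == 0:
        if not zero_cell:
            raise ZeroCellError(f"zero cell in table {cells} with correction disabled")
        return tuple(x + 0.5 for x in cells)  # Haldane–Anscombe
    return tuple(float(x) for x in cells)


def odds_ratio(t: ContingencyTable, zero_cell: bool = True) -> float:
    """Cross-product odds ratio (a*d)/(b*c), Haldane-corrected on zero cells."""
    a, b, c, d = _cells(t, zero_cell)
    return (a * d) / (b * c)


def _log_or_se(t: ContingencyTable, zero_cell: bool) -> tuple[float, float]:
    a, b, c, d = _cells(t, zero_cell)
    return math.log((a * d) / (b * c)), math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def woolf_ci(
    t: ContingencyTable, level: float = 0.95, zero_cell: bool = True
) -> tuple[float, float]:
    """Woolf confidence interval exp(ln OR +/- z * sqrt(1/a+1/b+1/c+1/d))."""
    log_or, se = _log_or_se(t, zero_cell)
    z = stats.norm.ppf(0.5 + level / 2)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def wald_p(t: ContingencyTable, zero_cell: bool = True) -> float:
    """Two-sided normal tail probability of z = ln(OR) / SE."""
    log_or, se = _log_or_se(t, zero_cell)
    return 2 * stats.norm.sf(abs(log_or / se))


def associate_variant(
    m: GenotypeMatrix,
    variant: str,
    group_pair: tuple[str, str],
    mode: str = "complement",
    zero_cell: bool = True,
) -> list[AssociationResult]:
    """Association results for every non-reference class of one variant.

    The reference class is determined from healthy-control counts whenever
    HC subjects are present in the matrix (the baseline is defined by
    healthy people even for pairs not involving HC); otherwise from the
    control group of the pair.  A class is tested when it has at least one
    carrier in either group of the pair.
    """
    case_group, control_group = group_pair
    case_counts = count_genotype_classes(m, case_group, variant)
    control_counts = count_genotype_classes(m, control_group, variant)
    if "HC" in m.groups_present():
        ref_counts = (
            control_counts
            if control_group == "HC"
            else count_genotype_classes(m, "HC", variant)
        )
    else:
        ref_counts = control_counts
    reference = assign_reference_class(ref_counts)
    vr = m.variant_record(variant)
    results = []
    for cls in CLASS_ORDER:
        if cls == reference:
            continue
        if case_counts.counts.get(cls, 0) == 0 and control_counts.counts.get(cls, 0) == 0:
            continue
        table = build_contingency(case_counts, control_counts, cls, reference, mode)
        or_value = odds_ratio(table, zero_cell)
        ci_low, ci_high = woolf_ci(table, zero_cell=zero_cell)
        p = wald_p(table, zero_cell)
        results.append(
            AssociationResult(
                variant, vr.gene, vr.pos, cls, reference,
                case_group, control_group, or_value, ci_low, ci_high, p, table,
            )
        )
    return results


def associate_all(
    m: GenotypeMatrix,
    group_pair: tuple[str, str],
    mode: str = "complement",
    zero_cell: bool = True,
) -> list[AssociationResult]:
    """Run :func:`associate_variant` over every variant of the matrix."""
    out: list[AssociationResult] = []
    for vid in m.variant_ids:
        out.extend(associate_variant(m, vid, group_pair, mode, zero_cell))
    return out


def significant_results(
    results: list[AssociationResult],
    alpha: float = 0.05,
    adjust: str | None = None,
) -> list[AssociationResult]:
    """Results with p < alpha (strict), sorted by gene then position.

    ``adjust="bh"`` filters on Benjamini–Hochberg adjusted p-values instead
    of raw ones; the default is raw, unadjusted p-values.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not results:
        return []
    if adjust == "bh":
        adj = stats.false_discovery_control([r.p_value for r in results], method="bh")
        kept = [r for r, q in zip(results, adj) if q < alpha]
    elif adjust is None:
        kept = [r for r in results if r.p_value < alpha]
    else:
        raise ValueError(f"unknown adjustment '{adjust}'")
    return sorted(kept, key=lambda r: (r.gene, r.pos, r.variant, r.tested_class))


def or_bin(or_value: float) -> int:
    """Index of the OR-strength bin (see :data:`OR_BIN_LABELS`)."""
    if or_value < 0.2:
        return 0
    if or_value <= 0.5:
        return 1
    if or_value < 2.0:
        return 2
    if or_value <= 5.0:
        return 3
    return 4


def bin_or_summary(results: list[AssociationResult]) -> ORBinSummary:
    """Per-gene counts of (already significance-filtered) results per OR bin."""
    pair = (
        (results[0].case_group, results[0].control_group) if results else ("", "")
    )
    summary = ORBinSummary(pair)
    for r in results:
        summary.bins.setdefault(r.gene, [0] * len(OR_BIN_LABELS))
        summary.bins[r.gene][or_bin(r.or_value)] += 1
    return summary


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabular form of association results; OR/CI rounded to 2 decimals and
    p to 3 (half-up) as in the reported tables, with full-precision mirrors."""
    rows = []
    for r in results:
        rows.append(
            dict(
                gene=r.gene,
                variant_id=r.variant,
                tested_class=r.tested_class,
                reference_class=r.reference_class,
                case_group=r.case_group,
                control_group=r.control_group,
                a=r.table.a, b=r.table.b, c=r.table.c, d=r.table.d,
                OR=round_half_up(r.or_value, 2),
                CI_low=round_half_up(r.ci_low, 2),
                CI_high=round_half_up(r.ci_high, 2),
                p=round_half_up(r.p_value, 3),
                OR_full=r.or_value,
                CI_low_full=r.ci_low,
                CI_high_full=r.ci_high,
                p_full=r.p_value,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "variant_id", "tested_class", "reference_class",
            "case_group", "control_group", "a", "b", "c", "d",
            "OR", "CI_low", "CI_high", "p",
            "OR_full", "CI_low_full", "CI_high_full", "p_full",
        ],
    )


def write_results(
    results: list[AssociationResult], tsv_path: str | Path, json_path: str | Path | None = None
) -> None:
    """Write results as TSV and an optional JSON mirror of the same records."""
    df = results_frame(results)
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(df.to_dict(orient="records"), indent=1))
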