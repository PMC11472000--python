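"""Odds ratios, Woolf intervals, Wald p-values and reference reassignment."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cypassoc._util import round_half_up
from cypassoc.association_stats import (
    AssociationResult,
    ClassCounts,
    ContingencyTable,
    ZeroCellError,
    assign_reference_class,
    bin_or_summary,
    build_contingency,
    odds_ratio,
    or_bin,
    significant_results,
    associate_variant,
    wald_p,
    woolf_ci,
)
from cypassoc.cohort_io import CohortError, VariantRecord

from conftest import simple_matrix

cells = st.integers(min_value=1, max_value=1000)


@pytest.mark.parametrize(
    "table,or2,lo2,hi2,p3",
    [
        # published 2x2 tables rebuilt from per-group carrier counts
        ((19, 3, 343, 190), 3.51, 1.02, 12.01, 0.046),
        ((3, 7, 359, 186), 0.22, 0.06, 0.87, 0.031),
        ((2, 8, 360, 185), 0.13, 0.03, 0.61, 0.010),
        ((3, 8, 359, 185), 0.19, 0.05, 0.74, 0.016),
        ((10, 10, 90, 90), 1.00, 0.40, 2.52, 1.0),
    ],
)
def test_or_ci_p_reproduce_reported_values(table, or2, lo2, hi2, p3):
    t = ContingencyTable(*table)
    assert round_half_up(odds_ratio(t), 2) == or2
    lo, hi = woolf_ci(t)
    assert (round_half_up(lo, 2), round_half_up(hi, 2)) == (lo2, hi2)
    assert round_half_up(wald_p(t), 3) == p3


def test_zero_cell_haldane_correction():
    t = ContingencyTable(0, 5, 100, 95)
    assert odds_ratio(t) == pytest.approx((0.5 * 95.5) / (5.5 * 100.5))
    with pytest.raises(ZeroCellError):
        odds_ratio(t, zero_cell=False)


@given(a=cells, b=cells, c=cells, d=cells)
@settings(derandomize=True, max_examples=200)
def test_or_inversion_property(a, b, c, d):
    """Swapping tested and comparator rows inverts the OR exactly."""
    t1, t2 = ContingencyTable(a, b, c, d), ContingencyTable(c, d, a, b)
    assert odds_ratio(t1) * odds_ratio(t2) == pytest.approx(1.0, rel=1e-12)


@given(a=cells, b=cells, c=cells, d=cells, k=st.integers(2, 20))
@settings(derandomize=True, max_examples=100)
def test_or_scale_invariance_and_ci_shrinkage(a, b, c, d, k):
    t, tk = ContingencyTable(a, b, c, d), ContingencyTable(k * a, k * b, k * c, k * d)
    assert odds_ratio(t) == pytest.approx(odds_ratio(tk), rel=1e-12)
    lo1, hi1 = woolf_ci(t)
    lo2, hi2 = woolf_ci(tk)
    assert math.log(hi2) - math.log(lo2) < math.log(hi1) - math.log(lo1)


def test_wald_woolf_duality_random_tables():
    """p < 0.05 if and only if the 95% CI excludes 1 (all cells >= 1)."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        t = ContingencyTable(*(int(x) for x in rng.integers(1, 500, size=4)))
        lo, hi = woolf_ci(t)
        assert (wald_p(t) < 0.05) == (hi < 1 or lo > 1)


def _or_by_pair_enumeration(t: ContingencyTable) -> float:
    """Independent oracle: odds ratio as the ratio of concordant to
    discordant (case, control) pairs in the exhaustive 2x2 cross-product."""
    concordant = discordant = 0
    case = [1] * t.a + [0] * t.c  # 1 = carries tested class
    control = [1] * t.b + [0] * t.d
    for x in case:
        for y in control:
            if x == 1 and y == 0:
                concordant += 1
            elif x == 0 and y == 1:
                discordant += 1
    return concordant / discordant


def test_or_matches_pair_enumeration_oracle():
    rng = np.random.default_rng(7)
    for _ in range(25):
        t = ContingencyTable(*(int(x) for x in rng.integers(1, 30, size=4)))
        assert odds_ratio(t) == pytest.approx(_or_by_pair_enumeration(t), rel=1e-12)


def test_woolf_ci_matches_statsmodels():
    from statsmodels.stats.contingency_tables import Table2x2

    rng = np.random.default_rng(3)
    for _ in range(25):
        a, b, c, d = (int(x) for x in rng.integers(1, 200, size=4))
        lo, hi = woolf_ci(ContingencyTable(a, b, c, d))
        sm_lo, sm_hi = Table2x2(np.array([[a, b], [c, d]])).oddsratio_confint()
        assert lo == pytest.approx(sm_lo, rel=1e-12)
        assert hi == pytest.approx(sm_hi, rel=1e-12)


def test_symmetric_table_ci_symmetric_about_one():
    lo, hi = woolf_ci(ContingencyTable(12, 12, 70, 70))
    assert math.log(lo) == pytest.approx(-math.log(hi), rel=1e-12)


@pytest.mark.parametrize(
    "counts,expected",
    [
        ({"0/0": 150, "0/1": 30, "1/1": 13}, "0/0"),
        ({"0/0": 10, "0/1": 30, "1/1": 120}, "1/1"),
        ({"0/0": 50, "0/1": 50}, "0/0"),  # tie broken by fixed class order
    ],
)
def test_assign_reference_class(counts, expected):
    assert assign_reference_class(ClassCounts("v", "HC", counts)) == expected


def test_assign_reference_class_no_informative():
    with pytest.raises(CohortError, match="no informative"):
        assign_reference_class(ClassCounts("v", "HC", {}, missing=5))


def test_build_contingency_modes():
    case = ClassCounts("v", "IPD", {"0/0": 343, "0/1": 19})
    control = ClassCounts("v", "HC", {"0/0": 190, "0/1": 3})
    t = build_contingency(case, control, "0/1", "0/0", "complement")
    assert (t.a, t.b, t.c, t.d) == (19, 3, 343, 190)
    toy_case = ClassCounts("v", "IPD", {"0/0": 5, "0/1": 3, "1/1": 2})
    toy_ctrl = ClassCounts("v", "HC", {"0/0": 4, "0/1": 1, "1/1": 1})
    t2 = build_contingency(toy_case, toy_ctrl, "0/1", "0/0", "reference-class")
    assert (t2.a, t2.c) == (3, 5)  # comparator counts reference class only
    assert (t2.b, t2.d) == (1, 4)
    with pytest.raises(CohortError, match="equals the reference"):
        build_contingency(case, control, "0/0", "0/0")


def test_test_variant_class_enumeration():
    v = VariantRecord("chr8", 100, "rsX", "A", ("G", "T"), gene="CYP7B1")
    biallelic = simple_matrix(
        v, {"IPD": ["0/1"] * 3 + ["0/0"] * 7, "HC": ["0/1"] * 1 + ["0/0"] * 9}
    )
    results = associate_variant(biallelic, "rsX", ("IPD", "HC"))
    assert [r.tested_class for r in results] == ["0/1"]
    multi = simple_matrix(
        v,
        {
            "IPD": ["0/1"] * 3 + ["1/1"] * 2 + ["0/2,etc."] * 2 + ["0/0"] * 5,
            "HC": ["0/1"] * 2 + ["0/0"] * 8,
        },
    )
    results = associate_variant(multi, "rsX", ("IPD", "HC"))
    assert [r.tested_class for r in results] == ["0/1", "1/1", "0/2,etc."]


def test_test_variant_reassigns_reference_from_hc_majority():
    """When healthy controls are mostly 1/1, "0/0" becomes a tested class."""
    v = VariantRecord("chr14", 200, "rsY", "G", ("T",), gene="CYP46A1")
    m = simple_matrix(
        v, {"IPD": ["0/0"] * 1 + ["1/1"] * 9, "HC": ["0/0"] * 3 + ["1/1"] * 7}
    )
    results = associate_variant(m, "rsY", ("IPD", "HC"))
    assert [r.tested_class for r in results] == ["0/0"]
    assert results[0].reference_class == "1/1"


def _mk_result(gene, pos, or_value, p, case="IPD", control="HC"):
    return AssociationResult(
        f"v{pos}", gene, pos, "0/1", "0/0", case, control,
        or_value, or_value / 2, or_value * 2, p, ContingencyTable(1, 1, 1, 1),
    )


def test_significant_results_strict_threshold_and_order():
    results = [
        _mk_result("CYP7B1", 5, 2.0, 0.046),
        _mk_result("CYP27A1", 9, 0.5, 0.05),   # boundary: dropped
        _mk_result("CYP27A1", 1, 0.5, 0.010),
    ]
    kept = significant_results(results)
    assert [(r.gene, r.pos) for r in kept] == [("CYP27A1", 1), ("CYP7B1", 5)]
    assert significant_results([]) == []
    with pytest.raises(ValueError):
        significant_results(results, alpha=1.5)


@pytest.mark.parametrize(
    "value,bin_index",
    [(0.19, 0), (0.2, 1), (0.5, 1), (0.54, 2), (1.99, 2), (2.0, 3), (5.0, 3), (5.01, 4)],
)
def test_or_bin_boundaries(value, bin_index):
    assert or_bin(value) == bin_index


def test_bin_or_summary_counts_per_gene():
    results = [
        _mk_result("CYP27A1", i, o, 0.01)
        for i, o in enumerate([0.19, 0.13, 0.22, 0.22, 0.54])
    ]
    summary = bin_or_summary(results)
    assert summary.bins["CYP27A1"] == [2, 2, 1, 0, 0]
    assert bin_or_summary([]).bins == {}
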