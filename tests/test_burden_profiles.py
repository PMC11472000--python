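"""Carrier matrices, cluster collapsing, burden and gene combinations."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cypassoc.association_stats import significant_results, associate_all
from cypassoc.burden_profiles import (
    CarrierMatrix,
    ClusterDef,
    burden_distribution,
    carrier_frequency_table,
    carrier_matrix,
    collapse_clusters,
    detect_clusters,
    gene_combinations,
    heatmap_order,
)
from cypassoc.cohort_io import CohortError, read_genotypes, read_sample_sheet
from cypassoc.synthetic_cohort import simulate_cohort


def _cm(values, genes=None, columns=None):
    values = np.asarray(values, dtype=np.uint8)
    columns = columns or [f"snp{j}" for j in range(values.shape[1])]
    genes = genes or ["CYP7B1"] * values.shape[1]
    return CarrierMatrix(
        [f"S{i}" for i in range(values.shape[0])],
        columns,
        dict(zip(columns, genes)),
        values,
    )


def test_carrier_matrix_matches_generator_truth(small_bundle, small_cfg):
    """Planted carriers are recovered exactly from the written bundle."""
    subjects = read_sample_sheet(small_bundle["sample_sheet"])
    matrix = read_genotypes(small_bundle["vcf"], subjects)
    results = associate_all(matrix, ("IPD", "HC"))
    sig = significant_results(results, alpha=0.9999)  # keep all SNPs testable
    cm = carrier_matrix(matrix, sig, "IPD")
    _, _, truth = simulate_cohort(small_cfg)
    classes = truth["classes"]
    tested = truth["tested_class"]
    for j, vid in enumerate(cm.columns):
        want_cls = {r.tested_class for r in sig if r.variant == vid}
        for i, sid in enumerate(cm.subject_ids):
            assert cm.values[i, j] == (classes.loc[sid, vid] in want_cls)
    # tested-class carriers, where tested, match the planted class
    for vid in cm.columns:
        if {r.tested_class for r in sig if r.variant == vid} == {tested[vid]}:
            col = cm.values[:, cm.columns.index(vid)]
            planted = np.array(
                [classes.loc[sid, vid] == tested[vid] for sid in cm.subject_ids]
            )
            assert (col == planted).all()


def test_collapse_clusters_rules():
    cm = _cm(
        [[1, 1, 1, 0], [0, 0, 0, 1], [1, 1, 0, 0]],
        columns=["a", "b", "c", "x"],
    )
    cluster = ClusterDef("cl", ("a", "b", "c"), "CYP7B1")
    out = collapse_clusters(cm, [cluster])
    assert out.columns == ["cl", "x"]
    # element-wise maximum: carrying 2 of 3 members still counts once
    assert out.values[:, 0].tolist() == [1, 0, 1]
    assert out.values[:, 1].tolist() == cm.values[:, 3].tolist()
    with pytest.raises(CohortError, match="not in carrier matrix"):
        collapse_clusters(cm, [ClusterDef("bad", ("a", "zz"), "CYP7B1")])


def test_collapse_24_columns_with_default_cluster_sizes():
    """24 SNPs with clusters of 3+2+2+4 members collapse to 17 columns."""
    rng = np.random.default_rng(0)
    cols = [f"s{j}" for j in range(24)]
    cm = _cm(rng.integers(0, 2, size=(10, 24)), columns=cols)
    clusters = [
        ClusterDef("c1", tuple(cols[0:3]), "CYP7B1"),
        ClusterDef("c2", tuple(cols[3:5]), "CYP7B1"),
        ClusterDef("c3", tuple(cols[5:7]), "CYP7B1"),
        ClusterDef("c4", tuple(cols[7:11]), "CYP7B1"),
    ]
    assert len(collapse_clusters(cm, clusters).columns) == 17


def test_collapse_never_increases_burden():
    rng = np.random.default_rng(5)
    cm = _cm(rng.integers(0, 2, size=(30, 8)))
    clusters = [ClusterDef("c", tuple(cm.columns[:4]), "CYP7B1")]
    before = cm.values.sum(axis=1)
    after = collapse_clusters(cm, clusters).values.sum(axis=1)
    assert (after <= before).all()
    assert ((after >= 1) == (before >= 1)).all()


def test_burden_distribution_counts_and_percentages():
    rng = np.random.default_rng(2)
    cm = _cm(rng.integers(0, 2, size=(50, 6)))
    summary = burden_distribution(cm, "IPD")
    sums = cm.values.sum(axis=1)
    for _, row in summary.table.iterrows():
        assert row["n_subjects"] == int((sums == row["n_snps"]).sum())
    assert summary.table["n_subjects"].sum() == 50
    assert summary.table["pct"].sum() == pytest.approx(100, abs=0.2)
    assert summary.pct_at_least_one == pytest.approx(100 * (sums >= 1).mean())


def test_burden_distribution_all_zero():
    cm = _cm(np.zeros((10, 3), dtype=int))
    summary = burden_distribution(cm)
    assert summary.table.loc[0, "n_subjects"] == 10
    assert summary.pct_at_least_one == 0.0


def _combo_oracle(cm):
    """Brute-force enumeration over per-subject gene incidence sets."""
    genes = sorted(set(cm.gene_of.values()))
    incs = [
        {cm.gene_of[c] for c, v in zip(cm.columns, row) if v} for row in cm.values
    ]
    only = {g: sum(inc == {g} for inc in incs) for g in genes}
    pair_only = {
        (a, b): sum(bool(i) and i <= {a, b} for i in incs)
        for a, b in itertools.combinations(genes, 2)
    }
    both = {
        (a, b): sum(i == {a, b} for i in incs)
        for a, b in itertools.combinations(genes, 2)
    }
    return only, pair_only, both


def test_gene_combinations_match_bruteforce():
    rng = np.random.default_rng(9)
    for _ in range(10):
        cm = _cm(
            rng.integers(0, 2, size=(25, 6)),
            genes=["CYP46A1", "CYP46A1", "CYP7B1", "CYP7B1", "CYP39A1", "CYP27A1"],
        )
        combos = gene_combinations(cm)
        only, pair_only, both = _combo_oracle(cm)
        assert combos.only == only
        assert combos.pair_only == pair_only
        assert combos.both_only == both
        for pair in combos.pair_only:
            a, b = pair
            assert (
                combos.only[a] + combos.only[b] + combos.both_only[pair]
                == combos.pair_only[pair]
            )
        assert sum(combos.gene_count_hist.values()) == 25


def test_gene_combinations_empty_and_unmapped():
    cm = _cm(np.zeros((5, 2), dtype=int), genes=["CYP7B1", "CYP39A1"])
    combos = gene_combinations(cm)
    assert all(v == 0 for v in combos.only.values())
    assert combos.gene_count_hist[0] == 5
    bad = _cm(np.zeros((5, 2), dtype=int), genes=["CYP7B1", ""])
    with pytest.raises(CohortError, match="without a gene"):
        gene_combinations(bad)


def test_carrier_frequency_table(small_bundle):
    subjects = read_sample_sheet(small_bundle["sample_sheet"])
    matrix = read_genotypes(small_bundle["vcf"], subjects)
    sig = significant_results(associate_all(matrix, ("IPD", "HC")), alpha=0.9999)
    freq = carrier_frequency_table(matrix, sig)
    for _, row in freq.iterrows():
        assert row["pct_full"] == pytest.approx(
            100 * row["n_carriers"] / row["group_size"]
        )
        assert 0 <= row["n_carriers"] <= row["group_size"]


def test_heatmap_order_groups_identical_columns():
    cm = _cm(
        np.array([[1, 1, 0], [0, 0, 1], [1, 1, 0], [1, 1, 1], [0, 0, 0]]),
        columns=["a", "a2", "z"],
    )
    _, col_order = heatmap_order(cm)
    ia, ia2 = list(col_order).index(0), list(col_order).index(1)
    assert abs(ia - ia2) == 1  # identical columns end up adjacent


def test_heatmap_order_permutation_invariance():
    rng = np.random.default_rng(4)
    values = rng.integers(0, 2, size=(12, 5))
    cm = _cm(values)
    rows1, _ = heatmap_order(cm)
    perm = rng.permutation(12)
    cm2 = _cm(values[perm])
    rows2, _ = heatmap_order(cm2)
    ordered1 = [tuple(values[i]) for i in rows1]
    ordered2 = [tuple(values[perm][i]) for i in rows2]
    assert sorted(ordered1) == sorted(ordered2)


def test_heatmap_order_planted_blocks_contiguous():
    block_a = np.tile([1, 1, 1, 0, 0, 0], (8, 1)).T  # 6 subjects x 8 SNPs
    block_b = np.tile([0, 0, 0, 1, 1, 1], (8, 1)).T
    values = np.concatenate([block_a, block_b], axis=1)  # 6 x 16
    cm = _cm(values)
    rows, cols = heatmap_order(cm)
    first_half = {int(j < 8) for j in list(cols)[:8]}
    assert len(first_half) == 1  # one block occupies the first 8 leaves
    assert len(rows) == 6


def test_heatmap_order_degenerate_and_small():
    cm = _cm(np.ones((4, 3), dtype=int))
    rows, cols = heatmap_order(cm)
    assert rows.tolist() == [0, 1, 2, 3] and cols.tolist() == [0, 1, 2]
    with pytest.raises(ValueError, match="at least 2"):
        heatmap_order(_cm(np.ones((1, 3), dtype=int)))


def test_detect_clusters_equality_and_gene_constraint():
    values = np.array(
        [[1, 1, 1, 0, 1], [0, 0, 0, 1, 0], [1, 1, 1, 0, 1], [0, 0, 0, 0, 0]]
    )
    same_gene = _cm(values, genes=["CYP7B1"] * 3 + ["CYP7B1", "CYP39A1"])
    clusters = detect_clusters(same_gene)
    assert len(clusters) == 1
    assert set(clusters[0].members) == {"snp0", "snp1", "snp2"}
    cross_gene = _cm(values[:, [0, 4]], genes=["CYP7B1", "CYP39A1"])
    assert detect_clusters(cross_gene) == []  # identical but different genes


def test_detect_clusters_agreement_threshold():
    rng = np.random.default_rng(13)
    base = rng.integers(0, 2, size=100)
    noisy = base.copy()
    noisy[:5] = 1 - noisy[:5]  # 95% agreement
    cm = _cm(np.stack([base, noisy], axis=1))
    assert len(detect_clusters(cm, min_agreement=0.9)) == 1
    assert detect_clusters(cm, min_agreement=1.0) == []
    with pytest.raises(ValueError):
        detect_clusters(cm, min_agreement=0.4)
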