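"""Shared fixtures: small synthetic cohorts and deterministic matrices."""

from __future__ import annotations

import numpy as np
import pytest

from cypassoc import synthetic_cohort as sc
from cypassoc.cohort_io import (
    CLASS_CODE,
    GenotypeMatrix,
    SubjectRecord,
    VariantRecord,
    normalize_variant_id,
)


@pytest.fixture(scope="session")
def small_cfg():
    """Default cohort structure scaled down to a desk-size test cohort."""
    cfg = sc.default_config(seed=11)
    cfg.group_sizes = {"IPD": 120, "HC": 80, "GPD": 20, "GUN": 20}
    return cfg


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_cfg):
    """A written fixture bundle (VCF, sheet, BEDs, tables, truth) on disk."""
    out = tmp_path_factory.mktemp("bundle")
    return sc.write_fixture_bundle(small_cfg, out)


def matrix_from_carrier_counts(
    rows: list[dict], group_sizes: dict[str, int]
) -> GenotypeMatrix:
    """Deterministic genotype matrix reproducing per-group carrier counts.

    For each variant the first ``carriers[group]`` subjects of a group get
    the tested class, the rest the reference class — exactly the marginal
    tallies of the published carrier table, with no randomness.
    """
    subjects = [
        SubjectRecord(f"{g}_{i:04d}", g)
        for g, n in group_sizes.items()
        for i in range(n)
    ]
    codes = np.empty((len(subjects), len(rows)), dtype=np.int8)
    for j, row in enumerate(rows):
        tested = CLASS_CODE[row["tested_class"]]
        reference = CLASS_CODE[row["reference_class"]]
        i = 0
        for g, n in group_sizes.items():
            k = row["carriers"][g]
            codes[i:i + k, j] = tested
            codes[i + k:i + n, j] = reference
            i += n
    return GenotypeMatrix(subjects, [r["record"] for r in rows], codes)


def simple_matrix(
    variant: VariantRecord, calls_by_group: dict[str, list[str]]
) -> GenotypeMatrix:
    """One-variant matrix from explicit per-group class labels."""
    subjects, labels = [], []
    for g, calls in calls_by_group.items():
        for i, cls in enumerate(calls):
            subjects.append(SubjectRecord(f"{g}_{i:03d}", g))
            labels.append(cls)
    codes = np.array([[CLASS_CODE[cls]] for cls in labels], dtype=np.int8)
    return GenotypeMatrix(subjects, [variant], codes)


def variant_id_of(row: dict) -> str:
    return normalize_variant_id(row["record"])
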