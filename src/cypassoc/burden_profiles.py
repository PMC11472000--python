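"""Per-subject SNP-burden and gene-combination profiling.

Significant associations are turned into a binary subject x SNP carrier
matrix (1 = the subject carries the tested genotype class, whether the SNP
is over- or under-represented in cases).  From it the module derives burden
distributions (raw and with co-occurring SNP clusters collapsed to one
unit), counts of subjects whose associated SNPs fall only in a given gene
or gene pair, per-SNP per-group carrier-frequency tables, and a
hierarchically clustered ordering for binary heatmaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from ._util import round_half_up
from .association_stats import AssociationResult, count_genotype_classes
from .cohort_io import CLASS_CODE, CohortError, GenotypeMatrix, group_tally

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterDef:
    """A set of same-gene SNPs whose carrier status co-occurs across subjects."""

    name: str
    members: tuple[str, ...]
    gene: str

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"cluster '{self.name}' needs >= 2 members")


@dataclass
class CarrierMatrix:
    """Binary subjects x associated-SNPs incidence grid."""

    subject_ids: list[str]
    columns: list[str]
    gene_of: dict[str, str]
    values: np.ndarray  # uint8, shape (n_subjects, n_columns)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.subject_ids), len(self.columns)):
            raise ValueError("carrier grid shape mismatch")
        if self.values.size and self.values.max() > 1:
            raise ValueError("carrier grid must be binary")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.columns)


@dataclass
class BurdenSummary:
    """Per-k counts of subjects carrying exactly k associated SNPs."""

    group: str
    group_size: int
    table: pd.DataFrame  # columns: n_snps, n_subjects, pct
    pct_at_least_one: float


@dataclass
class GeneComboCounts:
    """Subjects with associated SNPs only in a gene / gene pair.

    ``pair_only`` counts subjects whose gene incidence is a non-empty subset
    of the pair (either member or both, nothing elsewhere); ``both_only``
    counts incidence exactly equal to the pair, so
    only_A + only_B + both_only == pair_only.
    """

    only: dict[str, int]
    pair_only: dict[tuple[str, str], int]
    both_only: dict[tuple[str, str], int]
    gene_count_hist: dict[int, int]


def carrier_matrix(
    m: GenotypeMatrix, sig: list[AssociationResult], group: str
) -> CarrierMatrix:
    """Binary incidence of the tested genotype class(es) per significant SNP.

    When a variant carries several significant classes (multiallelic sites)
    the subject counts as a carrier of that SNP if its class is any of
    them, so each SNP contributes one column.  Missing genotypes count 0.
    """
    if not sig:
        raise ValueError("no significant results to profile")
    tested: dict[str, set[str]] = {}
    gene_of: dict[str, str] = {}
    for r in sig:
        tested.setdefault(r.variant, set()).add(r.tested_class)
        gene_of[r.variant] = r.gene
    multi = [v for v, cls in tested.items() if len(cls) > 1]
    if multi:
        logger.info("variants with several tested classes pooled per SNP: %s", multi)
    mask = m.group_mask(group)
    subject_ids = [s.subject_id for s, keep in zip(m.subjects, mask) if keep]
    columns = list(tested)
    values = np.zeros((len(subject_ids), len(columns)), dtype=np.uint8)
    n_missing = 0
    for j, vid in enumerate(columns):
        col = m.codes[mask, m.variant_index(vid)]
        hit = np.zeros(col.shape, dtype=bool)
        for cls in tested[vid]:
            hit |= col == CLASS_CODE[cls]
        values[:, j] = hit
        n_missing += int(np.count_nonzero(col == CLASS_CODE["missing"]))
    if n_missing:
        logger.info("%d missing genotypes counted as non-carriers", n_missing)
    return CarrierMatrix(subject_ids, columns, gene_of, values)


def collapse_clusters(cm: CarrierMatrix, clusters: list[ClusterDef]) -> CarrierMatrix:
    """Replace each cluster's columns by their element-wise maximum.

    The collapsed column takes the cluster's name and sits at the position
    of the first member; non-cluster columns are unchanged.
    """
    member_to_cluster: dict[str, ClusterDef] = {}
    for cl in clusters:
        for mbr in cl.members:
            if mbr not in cm.columns:
                raise CohortError(f"cluster member '{mbr}' not in carrier matrix")
            if mbr in member_to_cluster:
                raise CohortError(f"'{mbr}' belongs to more than one cluster")
            member_to_cluster[mbr] = cl
    new_cols: list[str] = []
    new_vals: list[np.ndarray] = []
    gene_of: dict[str, str] = {}
    done: set[str] = set()
    for j, col in enumerate(cm.columns):
        cl = member_to_cluster.get(col)
        if cl is None:
            new_cols.append(col)
            new_vals.append(cm.values[:, j])
            gene_of[col] = cm.gene_of[col]
        elif cl.name not in done:
            done.add(cl.name)
            idx = [cm.columns.index(mbr) for mbr in cl.members]
            new_cols.append(cl.name)
            new_vals.append(cm.values[:, idx].max(axis=1))
            gene_of[cl.name] = cl.gene
    return CarrierMatrix(
        list(cm.subject_ids), new_cols, gene_of, np.stack(new_vals, axis=1)
    )


def burden_distribution(cm: CarrierMatrix, group: str = "", group_size: int | None = None) -> BurdenSummary:
    """Per-k subject counts and percentages, plus the share with >= 1 SNP."""
    n = len(cm.subject_ids) if group_size is None else group_size
    sums = cm.values.sum(axis=1)
    ks = np.arange(int(sums.max()) + 1 if sums.size else 1)
    counts = np.array([int(np.count_nonzero(sums == k)) for k in ks])
    table = pd.DataFrame(
        dict(
            n_snps=ks,
            n_subjects=counts,
            pct=[round_half_up(100 * c / n, 1) for c in counts],
        )
    )
    pct_ge1 = 100 * int(np.count_nonzero(sums >= 1)) / n
    return BurdenSummary(group, n, table, pct_ge1)


def gene_combinations(cm: CarrierMatrix) -> GeneComboCounts:
    """Counts of subjects by the set of genes their associated SNPs fall in."""
    unmapped = [c for c in cm.columns if c not in cm.gene_of or not cm.gene_of[c]]
    if unmapped:
        raise CohortError(f"columns without a gene assignment: {unmapped}")
    genes = sorted(set(cm.gene_of.values()))
    incidences: list[frozenset[str]] = []
    for row in cm.values:
        incidences.append(
            frozenset(cm.gene_of[c] for c, v in zip(cm.columns, row) if v)
        )
    only = {g: sum(inc == {g} for inc in incidences) for g in genes}
    pair_only: dict[tuple[str, str], int] = {}
    both_only: dict[tuple[str, str], int] = {}
    for i, g1 in enumerate(genes):
        for g2 in genes[i + 1:]:
            pair = frozenset((g1, g2))
            pair_only[(g1, g2)] = sum(bool(inc) and inc <= pair for inc in incidences)
            both_only[(g1, g2)] = sum(inc == pair for inc in incidences)
    hist = {k: sum(len(inc) == k for inc in incidences) for k in range(len(genes) + 1)}
    return GeneComboCounts(only, pair_only, both_only, hist)


def carrier_frequency_table(
    m: GenotypeMatrix,
    sig: list[AssociationResult],
    group_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-SNP, per-group carrier counts and percentages of the tested class.

    Percentages are 100 * count / group size, stored full precision with a
    1-decimal half-up rounding column for table comparison.
    """
    sizes = group_sizes or group_tally(m.subjects)
    tested: dict[str, set[str]] = {}
    meta: dict[str, AssociationResult] = {}
    for r in sig:
        tested.setdefault(r.variant, set()).add(r.tested_class)
        meta[r.variant] = r
    rows = []
    for vid, classes in tested.items():
        for group, size in sizes.items():
            counts = count_genotype_classes(m, group, vid)
            n = sum(counts.counts.get(cls, 0) for cls in classes)
            rows.append(
                dict(
                    gene=meta[vid].gene,
                    variant_id=vid,
                    tested_classes=",".join(sorted(classes)),
                    group=group,
                    n_carriers=n,
                    group_size=size,
                    pct=round_half_up(100 * n / size, 1),
                    pct_full=100 * n / size,
                )
            )
    return pd.DataFrame(rows)


def _cluster_order(x: np.ndarray) -> np.ndarray:
    """Complete-linkage leaf order on Hamming distance; original order when
    fewer than 2 items or when all items are identical."""
    if x.shape[0] < 2 or (x == x[0]).all():
        return np.arange(x.shape[0])
    return leaves_list(linkage(pdist(x, metric="hamming"), method="complete"))


def heatmap_order(cm: CarrierMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Row and column permutations from hierarchical clustering.

    Agglomerative clustering with Hamming distance and complete linkage on
    the binary incidence grid, applied to rows (subjects) and columns
    (SNPs) independently; scipy's deterministic merge order fixes ties.
    """
    if len(cm.subject_ids) < 2 or len(cm.columns) < 2:
        raise ValueError("heatmap ordering needs at least 2 rows and 2 columns")
    return _cluster_order(cm.values), _cluster_order(cm.values.T)


def detect_clusters(cm: CarrierMatrix, min_agreement: float = 1.0) -> list[ClusterDef]:
    """Greedy maximal groups of same-gene columns with pairwise carrier
    agreement >= ``min_agreement`` (fraction of subjects with equal status).

    At ``min_agreement = 1.0`` agreement is transitive and the groups are
    exactly the equal-column classes within each gene; below 1.0 columns are
    assigned greedily in original column order to the first group whose
    every member agrees sufficiently.
    """
    if not 0.5 < min_agreement <= 1.0:
        raise ValueError("min_agreement must be in (0.5, 1]")
    clusters: list[ClusterDef] = []
    by_gene: dict[str, list[int]] = {}
    for j, col in enumerate(cm.columns):
        by_gene.setdefault(cm.gene_of.get(col, ""), []).append(j)

    def agreement(i: int, j: int) -> float:
        return float(np.mean(cm.values[:, i] == cm.values[:, j]))

    for gene, idxs in by_gene.items():
        groups: list[list[int]] = []
        for j in idxs:
            for grp in groups:
                if all(agreement(j, k) >= min_agreement for k in grp):
                    grp.append(j)
                    break
            else:
                groups.append([j])
        for gi, grp in enumerate(g for g in groups if len(g) >= 2):
            clusters.append(
                ClusterDef(
                    name=f"{gene}_cluster{gi + 1}",
                    members=tuple(cm.columns[j] for j in grp),
                    gene=gene,
                )
            )
    return clusters


def render_heatmap(cm: CarrierMatrix, path: str) -> None:
    """Optional PNG render of the clustered binary heatmap (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows, cols = heatmap_order(cm)
    fig, ax = plt.subplots(figsize=(8, 6))
    ax.imshow(cm.values[np.ix_(rows, cols)].T, aspect="auto", cmap="Greys")
    ax.set_yticks(range(len(cols)))
    ax.set_yticklabels([cm.columns[j] for j in cols], fontsize=6)
    ax.set_xlabel("subjects (clustered)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
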