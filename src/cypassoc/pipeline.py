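"""End-to-end orchestration: genotypes -> associations -> burden -> regulation.

Runs the full analysis from a YAML configuration and writes diffable TSV
reports: association results per group pair, odds-ratio strength bins,
burden distributions (raw and cluster-collapsed), gene-combination counts,
per-group carrier frequencies, and the open-chromatin/CpG annotation when
peak and methylation inputs are provided.  Outputs are deterministic for a
fixed configuration and input set; a run log records versions, the echoed
configuration and the exact contingency cells behind every odds ratio so
any reported value can be audited by hand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, datasets
from .association_stats import (
    bin_or_summary,
    results_frame,
    significant_results,
    associate_all,
    write_results,
)
from .burden_profiles import (
    ClusterDef,
    burden_distribution,
    carrier_frequency_table,
    carrier_matrix,
    collapse_clusters,
    gene_combinations,
)
from .cohort_io import GROUPS, read_genotypes, read_sample_sheet
from .regulatory_context import (
    CpGSite,
    allele_stratify,
    methylation_group_compare,
    nearest_cpg,
    read_peaks,
    snp_peak_overlap,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""


@dataclass
class RunConfig:
    """Validated run configuration."""

    vcf: str
    sample_sheet: str
    out_dir: str
    bed_dir: str | None = None
    cpg_sites: str | None = None
    cpg_betas: str | None = None
    expression: str | None = None
    clusters_file: str | None = None
    group_pairs: list[tuple[str, str]] = field(default_factory=lambda: [("IPD", "HC")])
    alpha: float = 0.05
    mode: str = "complement"
    window_bp: int = 500
    zero_cell: bool = True
    seed: int = 0


def validate_config(path: str | Path) -> tuple[RunConfig | None, list[str]]:
    """Parse and validate a YAML run configuration.

    All problems are collected (not fail-fast) and returned as a list of
    messages naming the offending keys; the config is None if any were found.
    """
    errors: list[str] = []
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        return None, [f"cannot read config {path}: {exc}"]
    if not isinstance(raw, dict):
        return None, [f"config {path} is not a mapping"]
    for key in ("vcf", "sample_sheet", "out_dir"):
        if key not in raw:
            errors.append(f"missing required key '{key}'")
    for key in ("vcf", "sample_sheet", "bed_dir", "cpg_sites", "cpg_betas",
                "expression", "clusters_file"):
        val = raw.get(key)
        if val is not None and not Path(val).exists():
            errors.append(f"'{key}': path does not exist: {val}")
    alpha = raw.get("alpha", 0.05)
    if not isinstance(alpha, (int, float)) or not 0 < alpha < 1:
        errors.append(f"'alpha': must be in (0, 1), got {alpha}")
    mode = raw.get("mode", "complement")
    if mode not in ("complement", "reference-class"):
        errors.append(f"'mode': unknown comparator mode '{mode}'")
    window_bp = raw.get("window_bp", 500)
    if not isinstance(window_bp, int) or window_bp < 0:
        errors.append(f"'window_bp': must be a non-negative integer, got {window_bp}")
    pairs = []
    for pair in raw.get("group_pairs", [["IPD", "HC"]]):
        if (
            not isinstance(pair, (list, tuple))
            or len(pair) != 2
            or any(g not in GROUPS for g in pair)
        ):
            errors.append(f"'group_pairs': invalid pair {pair}")
        else:
            pairs.append((pair[0], pair[1]))
    if errors:
        return None, errors
    return (
        RunConfig(
            vcf=raw["vcf"],
            sample_sheet=raw["sample_sheet"],
            out_dir=raw["out_dir"],
            bed_dir=raw.get("bed_dir"),
            cpg_sites=raw.get("cpg_sites"),
            cpg_betas=raw.get("cpg_betas"),
            expression=raw.get("expression"),
            clusters_file=raw.get("clusters_file"),
            group_pairs=pairs,
            alpha=float(alpha),
            mode=mode,
            window_bp=window_bp,
            zero_cell=bool(raw.get("zero_cell", True)),
            seed=int(raw.get("seed", 0)),
        ),
        [],
    )


def load_clusters(path: str | Path) -> list[ClusterDef]:
    """Cluster definitions from a TSV with columns name, gene, member."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    clusters = []
    for (name, gene), grp in df.groupby(["name", "gene"], sort=False):
        clusters.append(ClusterDef(name, tuple(grp["member"]), gene))
    return clusters


def default_clusters(columns: list[str]) -> list[ClusterDef]:
    """Built-in clusters restricted to members present among ``columns``."""
    out = []
    for name, gene, members in datasets.DEFAULT_CLUSTERS:
        present = tuple(m for m in members if m in columns)
        if len(present) >= 2:
            out.append(ClusterDef(name, present, gene))
    return out


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run all stages and write the report bundle; see module docstring.

    Any stage failure removes partial outputs and raises
    :class:`PipelineError` naming the stage.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = [f"cypassoc {__version__}", f"config: {cfg}"]
    stage = "setup"

    def emit(name: str, df: pd.DataFrame) -> Path:
        path = out_dir / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
        return path

    try:
        stage = "cohort_io"
        subjects = read_sample_sheet(cfg.sample_sheet)
        matrix = read_genotypes(cfg.vcf, subjects)
        log_lines.append(
            f"cohort: {len(subjects)} subjects, {len(matrix.variants)} variants"
        )

        stage = "association_stats"
        all_results, sig_by_pair = [], {}
        for pair in cfg.group_pairs:
            res = associate_all(matrix, pair, cfg.mode, cfg.zero_cell)
            sig = significant_results(res, cfg.alpha)
            all_results.extend(res)
            sig_by_pair[pair] = sig
            log_lines.append(
                f"pair {pair}: {len(res)} tested classes, {len(sig)} significant"
            )
        sig_all = [r for sig in sig_by_pair.values() for r in sig]
        write_results(sig_all, out_dir / "associations.tsv", out_dir / "associations.json")
        written += [out_dir / "associations.tsv", out_dir / "associations.json"]
        for r in sig_all:
            log_lines.append(
                f"table {r.case_group}/{r.control_group} {r.variant} "
                f"{r.tested_class}: a={r.table.a} b={r.table.b} "
                f"c={r.table.c} d={r.table.d} OR={r.or_value:.6g}"
            )

        stage = "or_bins"
        bin_frames = []
        for pair, sig in sig_by_pair.items():
            frame = bin_or_summary(sig).as_frame().reset_index()
            frame.insert(0, "group_pair", f"{pair[0]}/{pair[1]}")
            bin_frames.append(frame)
        from .association_stats import OR_BIN_LABELS

        emit("or_bins.tsv", pd.concat(bin_frames, ignore_index=True)
             if bin_frames
             else pd.DataFrame(columns=["group_pair", "gene", *OR_BIN_LABELS]))

        stage = "burden_profiles"
        burden_rows, combo_frames, freq_frames = [], [], []
        for pair, sig in sig_by_pair.items():
            if not sig:
                log_lines.append(f"pair {pair}: no significant SNPs; burden skipped")
                continue
            clusters = (
                load_clusters(cfg.clusters_file)
                if cfg.clusters_file
                else default_clusters([r.variant for r in sig])
            )
            for group in pair:
                cm = carrier_matrix(matrix, sig, group)
                for label, mat in (("raw", cm), ("collapsed", collapse_clusters(cm, clusters))):
                    summary = burden_distribution(mat, group)
                    t = summary.table.copy()
                    t.insert(0, "collapsed", label)
                    t.insert(0, "group", group)
                    t.insert(0, "group_pair", f"{pair[0]}/{pair[1]}")
                    burden_rows.append(t)
            cm_case = carrier_matrix(matrix, sig, pair[0])
            combos = gene_combinations(cm_case)
            combo_rows = [
                dict(group_pair=f"{pair[0]}/{pair[1]}", combination=g, kind="only", n=n)
                for g, n in combos.only.items()
            ]
            combo_rows += [
                dict(group_pair=f"{pair[0]}/{pair[1]}",
                     combination=f"{a}/{b}", kind="pair_only", n=n)
                for (a, b), n in combos.pair_only.items()
            ]
            combo_rows += [
                dict(group_pair=f"{pair[0]}/{pair[1]}",
                     combination=f"{a} and {b}", kind="both_only", n=n)
                for (a, b), n in combos.both_only.items()
            ]
            combo_rows += [
                dict(group_pair=f"{pair[0]}/{pair[1]}",
                     combination=f"{k} genes", kind="gene_count", n=n)
                for k, n in combos.gene_count_hist.items()
            ]
            combo_frames.append(pd.DataFrame(combo_rows))
            freq_frames.append(carrier_frequency_table(matrix, sig))
        emit("burden.tsv", pd.concat(burden_rows, ignore_index=True)
             if burden_rows
             else pd.DataFrame(columns=["group_pair", "group", "collapsed",
                                        "n_snps", "n_subjects", "pct"]))
        emit("gene_combos.tsv", pd.concat(combo_frames, ignore_index=True)
             if combo_frames
             else pd.DataFrame(columns=["group_pair", "combination", "kind", "n"]))
        emit("carrier_freq.tsv",
             pd.concat(freq_frames, ignore_index=True).drop_duplicates()
             if freq_frames
             else pd.DataFrame(columns=["gene", "variant_id", "tested_classes",
                                        "group", "n_carriers", "group_size",
                                        "pct", "pct_full"]))

        stage = "regulatory_context"
        reg_rows = []
        sig_variants = sorted({r.variant for r in sig_all})
        if cfg.bed_dir and sig_variants:
            peaks = [
                read_peaks(p, p.stem) for p in sorted(Path(cfg.bed_dir).glob("*.bed"))
            ]
            sites: list[CpGSite] = []
            if cfg.cpg_sites:
                site_df = pd.read_csv(cfg.cpg_sites, sep="\t", dtype={"chrom": str})
                betas = (
                    pd.read_csv(cfg.cpg_betas, sep="\t", index_col="site_id")
                    if cfg.cpg_betas
                    else None
                )
                for _, row in site_df.iterrows():
                    beta = (
                        betas.loc[row["site_id"]].dropna().to_dict()
                        if betas is not None and row["site_id"] in betas.index
                        else {}
                    )
                    sites.append(
                        CpGSite(row["site_id"], row["chrom"], int(row["pos"]), beta)
                    )
            for vid in sig_variants:
                vr = matrix.variant_record(vid)
                ann = snp_peak_overlap(vr, peaks, cfg.window_bp)
                ann = allele_stratify(ann, matrix)
                ann.nearest_cpg = nearest_cpg(vr, sites, cfg.window_bp)
                cpg_p = None
                if ann.nearest_cpg is not None:
                    site = next(s for s in sites if s.site_id == ann.nearest_cpg[0])
                    cmp_res = methylation_group_compare(site, subjects)
                    cpg_p = cmp_res["p_value"] if cmp_res else None
                reg_rows.append(
                    dict(
                        gene=vr.gene, variant_id=vid, chrom=vr.chrom, pos=vr.pos,
                        ref=vr.ref, alt=",".join(vr.alts),
                        n_in_peak=ann.n_in_peak,
                        n_within_window=ann.n_within_window,
                        window_bp=ann.window_bp,
                        allele_breakdown=";".join(
                            f"{k}:{v}" for k, v in sorted(ann.allele_breakdown.items())
                        ),
                        nearest_cpg=ann.nearest_cpg[0] if ann.nearest_cpg else "",
                        cpg_distance_bp=ann.nearest_cpg[1] if ann.nearest_cpg else "",
                        cpg_group_p=cpg_p if cpg_p is not None else "",
                    )
                )
        emit("regulatory.tsv", pd.DataFrame(
            reg_rows,
            columns=["gene", "variant_id", "chrom", "pos", "ref", "alt",
                     "n_in_peak", "n_within_window", "window_bp",
                     "allele_breakdown", "nearest_cpg", "cpg_distance_bp",
                     "cpg_group_p"],
        ))

        stage = "report"
        log_path = out_dir / "run.log"
        log_path.write_text("\n".join(log_lines) + "\n")
        written.append(log_path)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    return {p.name: p for p in written}
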