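"""End-to-end scan: windows → statistics → models → tests → report.

`run_scan` reproduces the per-data-set analysis: windowed F_ST/pi/
Tajima's D at each window size, ROH calling and length models,
Cook's-distance outlier excess, dN/dS comparison, Patterson's D, and
Fisher combinations across comparisons.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dnds as dnds_mod
from . import genome_io, introgression, roh_hmm, selection_inference as si
from .genome_io import GenotypeMatrix, PipelineConfig
from .windowing import classify, gene_bearing, tile_windows

log = logging.getLogger("mitoscan")


@dataclass
class ScanInputs:
    matrix: GenotypeMatrix
    genes: list
    cds_alignments: dict[str, dict[str, str]] | None = None
    cds_n_interact: dict[str, bool] | None = None
    four_taxon_matrix: GenotypeMatrix | None = None
    four_taxa: tuple[str, str, str, str] = ("P1", "P2", "P3", "O")

    @classmethod
    def from_bundle(cls, bundle_dir: str) -> "ScanInputs":
        """Load the inputs written by
        :func:`mitoscan.synthetic_data.write_fixture_bundle` (or any
        directory with the same layout)."""
        from .synthetic_data import read_cds_dir

        groups = genome_io.read_group_map(os.path.join(bundle_dir, "groups.tsv"))
        matrix = genome_io.read_vcf(os.path.join(bundle_dir, "cohort.vcf"), groups)
        n_interact = genome_io.read_n_interact_list(
            os.path.join(bundle_dir, "n_interact_genes.tsv")
        )
        genes = genome_io.read_annotations(
            os.path.join(bundle_dir, "genes.gff3"), n_interact
        )
        cds_dir = os.path.join(bundle_dir, "cds")
        cds = read_cds_dir(cds_dir) if os.path.isdir(cds_dir) else None
        cds_flags = {g: g in n_interact for g in cds} if cds else None
        ft_vcf = os.path.join(bundle_dir, "four_taxon.vcf")
        ft = None
        if os.path.exists(ft_vcf):
            ft_groups = genome_io.read_group_map(
                os.path.join(bundle_dir, "four_taxon_groups.tsv")
            )
            ft = genome_io.read_vcf(ft_vcf, ft_groups)
        return cls(
            matrix=matrix, genes=genes, cds_alignments=cds,
            cds_n_interact=cds_flags, four_taxon_matrix=ft,
        )


@dataclass
class ScanReport:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir: str) -> None:
        genome_io.write_results(self.tables, out_dir)
        with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
            json.dump(self.provenance, fh, indent=1, sort_keys=True)

    def fisher_rows(self) -> pd.DataFrame:
        return self.tables.get("fisher_combined", pd.DataFrame())


def _chrom_lengths(matrix: GenotypeMatrix, override=None) -> dict[str, int]:
    if override:
        return dict(override)
    return {
        str(c): int(matrix.pos[matrix.chrom == c].max()) + 1
        for c in dict.fromkeys(matrix.chrom)
    }


def combine_across_comparisons(perm_table: pd.DataFrame) -> pd.DataFrame:
    """One Fisher combination per (metric, window size) across all
    groups/pairs; df = 2k is recorded. F_ST rows carry the caveat that
    pairwise comparisons within a data set are not independent."""
    rows = []
    if len(perm_table) == 0:
        return pd.DataFrame(
            columns=["metric", "window_size", "k", "df", "x2", "p", "caveat"]
        )
    for (metric, wsize), sub in perm_table.groupby(["metric", "window_size"]):
        p_vals = sub["p"].dropna()
        if len(p_vals) == 0:
            continue
        x2, df, p = si.fisher_combine(p_vals)
        rows.append(
            {
                "metric": metric, "window_size": wsize, "k": len(p_vals),
                "df": df, "x2": x2, "p": p,
                "caveat": (
                    "pairwise comparisons share samples; independence assumption "
                    "of Fisher's method is violated" if metric == "fst" else ""
                ),
            }
        )
    return pd.DataFrame(rows)


def run_scan(
    inputs: ScanInputs,
    config: PipelineConfig | None = None,
    chromosome_lengths: dict[str, int] | None = None,
) -> ScanReport:
    """Run the full scan. Deterministic given ``config.seed``."""
    from .popgen_stats import compute_window_stats

    config = config or PipelineConfig()
    seeds = np.random.SeedSequence(config.seed).spawn(8)
    seed_ints = [int(s.generate_state(1)[0] % 2**31) for s in seeds]

    matrix, genes = inputs.matrix, inputs.genes
    groups = sorted(set(matrix.groups.values()))
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    lengths = _chrom_lengths(matrix, chromosome_lengths)

    report = ScanReport()
    perm_rows = []
    fit_rows = []
    mm_rows = []
    outlier_rows = []
    tajima_rows = []
    all_windows = {}

    for wsize in config.window_sizes:
        windows = classify(tile_windows(lengths, wsize), genes)
        table = compute_window_stats(matrix, windows, groups, pairs, config)
        all_windows[wsize] = windows
        report.tables[f"windows_{wsize}"] = table
        gb = gene_bearing(windows)

        stats = [(f"fst[{a}:{b}]", "fst", "upper") for a, b in pairs]
        stats += [(f"pi[{g}]", "pi", "lower") for g in groups]
        for stat, metric, tail in stats:
            frame = si.intervals_frame(gb, stat)
            if len(frame) and frame["n_interact"].nunique() == 2:
                try:
                    res = si.InteractionModel(frame, label=stat).fit(
                        cov_type="block-bootstrap",
                        block_size=config.block_size,
                        n_boot=config.n_bootstrap,
                        seed=seed_ints[0],
                    )
                    fit = res.to_frame()
                    fit["window_size"] = wsize
                    fit_rows.append(fit)
                    mm = res.marginal_means(config.percentile_range)
                    mm["response"] = stat
                    mm["window_size"] = wsize
                    mm_rows.append(mm)
                except ValueError as err:
                    log.warning("model for %s at %d kb skipped: %s", stat, wsize, err)
                perm = si.permutation_test(
                    frame["response"], frame["n_interact"] == 1, tail=tail,
                    n_permutations=config.n_permutations, seed=seed_ints[1],
                    statistic=stat,
                )
                row = perm.to_row()
                row.update({"metric": metric, "window_size": wsize})
                perm_rows.append(row)

        for g in groups:
            t = si.tajima_class_comparison(
                windows, g, n_permutations=config.n_permutations, seed=seed_ints[2]
            )
            t["window_size"] = wsize
            tajima_rows.append(t)
            if math.isfinite(t["p"]):
                perm_rows.append(
                    {
                        "statistic": f"tajima_d[{g}]", "observed": t["observed_difference"],
                        "tail": "lower", "B": config.n_permutations, "p": t["p"],
                        "null_mean": math.nan, "null_sd": math.nan,
                        "metric": "tajima_d", "window_size": wsize,
                    }
                )

    # outlier excess at the smallest window size (the study's choice)
    wsize0 = min(config.window_sizes)
    outlier_reports = []
    for stat, direction in [(f"fst[{a}:{b}]", "upper") for a, b in pairs] + [
        (f"pi[{g}]", "lower") for g in groups
    ]:
        try:
            rep = si.cooks_outlier_excess(
                all_windows[wsize0], stat, direction,
                threshold_factor=config.cooks_threshold_factor,
            )
        except ValueError as err:
            log.warning("outlier analysis for %s skipped: %s", stat, err)
            continue
        outlier_reports.append(rep)
        outlier_rows.append(
            {
                "statistic": rep.statistic, "direction": rep.direction,
                "n_outliers": rep.n_outliers,
                "n_outliers_n_interact": rep.n_outliers_n_interact,
                "n_windows": rep.n_windows,
                "baseline_proportion": rep.baseline_proportion,
                "p": rep.p_value, "window_size": wsize0,
                "metric": f"{rep.statistic.split('[')[0]}_outliers",
            }
        )
        perm_rows.append(
            {
                "statistic": f"outliers[{rep.statistic}]", "observed": rep.n_outliers_n_interact,
                "tail": "upper", "B": 0, "p": rep.p_value,
                "null_mean": math.nan, "null_sd": math.nan,
                "metric": ("fst_outliers" if rep.direction == "upper" else "pi_outliers"),
                "window_size": wsize0,
            }
        )

    # ROHs
    rohs = roh_hmm.classify_roh(roh_hmm.call_roh_all(matrix), genes)
    report.tables["roh"] = roh_hmm.roh_table(rohs)
    roh_gb = [r for r in rohs if r.gene_number >= 1]
    roh_frame = si.intervals_frame(roh_gb, "log_roh_length")
    if len(roh_frame) and roh_frame["n_interact"].nunique() == 2:
        try:
            res = si.InteractionModel(roh_frame, label="log_roh_length").fit()
            fit = res.to_frame()
            fit["window_size"] = 0
            fit_rows.append(fit)
        except ValueError as err:
            log.warning("ROH length model skipped: %s", err)
        perm = si.permutation_test(
            roh_frame["response"], roh_frame["n_interact"] == 1, tail="upper",
            n_permutations=config.n_permutations, seed=seed_ints[3],
            statistic="log_roh_length",
        )
        row = perm.to_row()
        row.update({"metric": "roh_length", "window_size": 0})
        perm_rows.append(row)

    # dN/dS
    if inputs.cds_alignments:
        records = []
        flags = inputs.cds_n_interact or {}
        for gene_id, seqs in inputs.cds_alignments.items():
            records.append(
                dnds_mod.ng86_dnds(
                    gene_id, list(seqs.values()),
                    n_interact=bool(flags.get(gene_id, False)),
                    omega_cap=config.omega_cap,
                )
            )
        report.tables["dnds"] = dnds_mod.records_table(records)
        try:
            res = dnds_mod.dnds_comparison(
                records, background_n=config.background_genes,
                n_permutations=config.n_permutations, seed=seed_ints[4],
            )
            row = res.to_row()
            row.update({"metric": "dnds", "window_size": 0})
            perm_rows.append(row)
        except ValueError as err:
            log.warning("dN/dS comparison skipped: %s", err)

    # Patterson's D
    if inputs.four_taxon_matrix is not None:
        ft = inputs.four_taxon_matrix
        ft_lengths = _chrom_lengths(ft, chromosome_lengths)
        d_rows = []
        for wsize in config.window_sizes:
            ft_windows = classify(tile_windows(ft_lengths, wsize), genes)
            res = introgression.matrix_patterson_d(
                ft, inputs.four_taxa, windows=ft_windows
            )
            d_row = res.to_row()
            d_row["window_size"] = wsize
            d_rows.append(d_row)
            try:
                comp = introgression.windowed_d_comparison(
                    ft_windows, n_permutations=config.n_permutations,
                    seed=seed_ints[5],
                )
                row = comp.to_row()
                row.update({"metric": "d_stat", "window_size": wsize})
                perm_rows.append(row)
            except ValueError as err:
                log.warning("windowed D comparison at %d skipped: %s", wsize, err)
        report.tables["d_stat"] = pd.DataFrame(d_rows)

    report.tables["model_fits"] = (
        pd.concat(fit_rows, ignore_index=True) if fit_rows else pd.DataFrame()
    )
    report.tables["marginal_means"] = (
        pd.concat(mm_rows, ignore_index=True) if mm_rows else pd.DataFrame()
    )
    report.tables["permutation_tests"] = pd.DataFrame(perm_rows)
    report.tables["outlier_reports"] = pd.DataFrame(outlier_rows)
    report.tables["tajima_comparison"] = pd.DataFrame(tajima_rows)
    report.tables["fisher_combined"] = combine_across_comparisons(
        report.tables["permutation_tests"]
    )
    if outlier_reports:
        report.tables["cross_metric_overlap"] = si.cross_metric_overlap(
            outlier_reports, rohs, all_windows[wsize0]
        )

    cfg_repr = json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
        sort_keys=True,
    )
    report.provenance = {
        "config": json.loads(cfg_repr),
        "config_hash": hashlib.sha256(cfg_repr.encode()).hexdigest()[:16],
        "seed": config.seed,
        "n_samples": matrix.n_samples,
        "n_sites": matrix.n_sites,
        "groups": groups,
        "roh_params": roh_hmm.RohModelParams().metadata(),
        "dnds_estimator": "NG86 pairwise counting (not one-ratio ML)",
    }
    return report
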