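"""The generator: determinism, planted structure, and bundle round trips."""

import filecmp
import os

import numpy as np
import pytest

from mitoscan import genome_io
from mitoscan.popgen_stats import site_fst, window_fst
from mitoscan.synthetic_data import (
    ConfigError,
    SimulationConfig,
    TruthTable,
    simulate_cds,
    simulate_genes,
    simulate_genotypes,
    write_fixture_bundle,
)
from mitoscan.windowing import classify, tile_windows


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_sites": 0},
            {"samples_per_population": 0},
            {"baseline_fst": 0.0},
            {"baseline_fst": 0.5, "selected_fst": 0.2},
            {"omega_background": -1.0},
            {"planted_roh": [("s", -5, 100)]},
            {"planted_roh": [("s", 100, 100)]},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)


class TestDeterminism:
    def test_same_seed_identical_genotypes(self):
        cfg = SimulationConfig(seed=11, n_sites=500, n_genes=40)
        m1, t1 = simulate_genotypes(cfg)
        m2, t2 = simulate_genotypes(cfg)
        np.testing.assert_array_equal(m1.genotypes, m2.genotypes)
        np.testing.assert_array_equal(m1.pos, m2.pos)
        assert t1.selected_window_ids == t2.selected_window_ids

    def test_bundle_files_byte_identical_across_runs(self, tmp_path):
        cfg = SimulationConfig(
            seed=12, n_sites=400, n_genes=30, chromosome_length=600_000,
            samples_per_population=4,
        )
        a = tmp_path / "a"
        b = tmp_path / "b"
        write_fixture_bundle(cfg, a, codons_per_gene=32, cds_genes=10)
        write_fixture_bundle(cfg, b, codons_per_gene=32, cds_genes=10)
        for root, _, files in os.walk(a):
            rel = os.path.relpath(root, a)
            for f in files:
                assert filecmp.cmp(
                    os.path.join(a, rel, f), os.path.join(b, rel, f), shallow=False
                ), f


class TestPlantedStructure:
    def test_planted_roh_tract_is_homozygous(self):
        cfg = SimulationConfig(
            seed=13, n_sites=1000, chromosome_length=2_000_000,
            samples_per_population=4,
            planted_roh=[("pop1_s01", 1_000_000, 1_500_000)],
        )
        matrix, truth = simulate_genotypes(cfg)
        j = matrix.samples.index("pop1_s01")
        in_tract = (matrix.pos >= 1_000_000) & (matrix.pos < 1_500_000)
        assert in_tract.sum() > 0
        assert np.all(np.isin(matrix.genotypes[in_tract, j], [0, 2]))
        assert truth.planted_roh == [("pop1_s01", 1_000_000, 1_500_000)]

    def test_no_signal_when_selected_equals_baseline(self):
        """With selected_fst = baseline_fst and no SFS skew, mean window
        F_ST of 'selected' and unselected windows agree."""
        diffs = []
        for seed in range(15):
            cfg = SimulationConfig(
                seed=6000 + seed, baseline_fst=0.05, selected_fst=0.05,
                sfs_skew=0.0, selected_window_fraction=0.3, n_sites=4000,
            )
            matrix, truth = simulate_genotypes(cfg)
            diffs.append(_selected_minus_unselected_fst(cfg, matrix, truth))
        assert abs(float(np.mean(diffs))) < 0.01

    def test_strong_selection_elevates_window_fst(self):
        """selected_fst=0.4 vs baseline 0.05 on >= 200 windows: the mean
        F_ST of selected windows exceeds unselected in nearly all seeds."""
        n_seeds = 100
        hits = 0
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                seed=7000 + seed, baseline_fst=0.05, selected_fst=0.4,
                chromosome_length=3_000_000, window_size=15_000,  # 200 windows
                n_sites=4000, samples_per_population=8,
                selected_window_fraction=0.2,
            )
            matrix, truth = simulate_genotypes(cfg)
            hits += _selected_minus_unselected_fst(cfg, matrix, truth) > 0
        assert hits >= int(0.95 * n_seeds)

    def test_selected_windows_exist_in_window_set(self):
        cfg = SimulationConfig(seed=14, n_sites=1000)
        _, truth = simulate_genotypes(cfg)
        genes = simulate_genes(cfg, np.random.default_rng(cfg.seed))
        windows = classify(
            tile_windows({cfg.chrom: cfg.chromosome_length}, cfg.window_size), genes
        )
        ids = {w.window_id for w in windows}
        assert set(truth.selected_window_ids) <= ids
        by_id = {w.window_id: w for w in windows}
        for wid in truth.selected_window_ids:
            assert by_id[wid].window_class == "N_INTERACT"


def _selected_minus_unselected_fst(cfg, matrix, truth):
    sel_ids = set(truth.selected_window_ids)
    d1 = matrix.group_dosages("pop1")
    d2 = matrix.group_dosages("pop2")
    sel, unsel = [], []
    for start in range(0, cfg.chromosome_length, cfg.window_size):
        end = min(start + cfg.window_size, cfg.chromosome_length)
        mask = (matrix.pos >= start) & (matrix.pos < end)
        if not mask.any():
            continue
        f = window_fst(d1[mask], d2[mask])
        wid = f"{cfg.chrom}:{start}-{end}"
        (sel if wid in sel_ids else unsel).append(f)
    return float(np.nanmean(sel) - np.nanmean(unsel))


class TestCds:
    def test_omega_zero_means_no_amino_acid_changes(self):
        from Bio.Seq import Seq

        cfg = SimulationConfig(seed=15, n_genes=5, omega_background=1e-9,
                               omega_selected=1e-9)
        aligns, _ = simulate_cds(cfg, n_taxa=4, codons_per_gene=50)
        for seqs in aligns.values():
            proteins = {str(Seq(s).translate()) for s in seqs.values()}
            assert len(proteins) == 1

    def test_structure_of_alignments(self):
        cfg = SimulationConfig(seed=16, n_genes=8)
        aligns, truth = simulate_cds(cfg, n_taxa=3, codons_per_gene=40)
        from mitoscan.dnds import QC_PASS, qc_gene

        for gene_id, seqs in aligns.items():
            for s in seqs.values():
                assert s.startswith("ATG")
                assert len(s) == 120
            assert qc_gene(list(seqs.values())) == QC_PASS
            assert gene_id in truth.per_gene_true_omega

    def test_short_genes_rejected(self):
        with pytest.raises(ConfigError):
            simulate_cds(SimulationConfig(), codons_per_gene=10)


class TestBundleRoundTrip:
    def test_vcf_round_trip_matches_memory(self, bundle_dir, small_config):
        matrix, _ = simulate_genotypes(small_config)
        groups = genome_io.read_group_map(os.path.join(bundle_dir, "groups.tsv"))
        back = genome_io.read_vcf(os.path.join(bundle_dir, "cohort.vcf"), groups)
        np.testing.assert_array_equal(matrix.genotypes, back.genotypes)
        np.testing.assert_array_equal(matrix.pos, back.pos)

    def test_annotations_round_trip(self, bundle_dir, small_config):
        genes = simulate_genes(small_config, np.random.default_rng(small_config.seed))
        back = genome_io.read_annotations(
            os.path.join(bundle_dir, "genes.gff3"),
            os.path.join(bundle_dir, "n_interact_genes.tsv"),
        )
        assert len(back) == len(genes)
        for g1, g2 in zip(genes, back):
            assert (g1.gene_id, g1.start, g1.end, g1.strand, g1.n_interact) == (
                g2.gene_id, g2.start, g2.end, g2.strand, g2.n_interact
            )

    def test_truth_table_round_trip(self, bundle_dir):
        truth = TruthTable.from_json(os.path.join(bundle_dir, "truth.json"))
        assert truth.planted_roh == [("pop1_s01", 400_000, 900_000)]
        assert truth.selected_window_ids
        assert truth.per_gene_true_omega
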