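# mitoscan

A genome scan for natural selection on **mitonuclear-interacting genes**
(*N_interact* genes): autosomal genes whose products work directly with
mitochondrial DNA, RNA or protein — OXPHOS subunits, mitochondrial
aminoacyl-tRNA synthetases (ARS2), mitoribosomal proteins (MRP) and
mtDNA replication factors (REP). In species with strong female
philopatry (such as macaques), mitochondrial lineages are anchored
geographically while autosomal variation mixes, creating recurring
selection on mitonuclear compatibility. This package tests whether
*N_interact* genes carry stronger signatures of that selection than
other genes, using diploid genotypes (VCF), a gene annotation (GFF3 or
BED) and a curated *N_interact* gene list as inputs.

It is aimed at population geneticists who want the full analysis as a
tested, reusable library: every statistic has an independent oracle in
the test suite, and a synthetic-data generator plants each signature
(elevated differentiation, reduced diversity, skewed frequency spectra,
homozygous tracts, accelerated protein evolution, gene flow) so the
whole pipeline is verifiable without external data.

## What it computes

Genomic windows (30 and 100 kb by default) are classified by the
transcription start sites they contain: *N_interact* windows (≥ 1
*N_interact* TSS), non-*N_interact* windows (≥ 1 TSS, none
*N_interact*) and nongenic windows. Per window and per group the scan
computes:

- **π** — mean pairwise diversity over polymorphic sites,
  `2·n_ref·n_alt / (n·(n−1))` per site;
- **F_ST** — Weir–Cockerham (1984) per-site estimates (Hudson-style
  optional), averaged over sites with pooled MAF ≥ 0.05;
- **Tajima's D** — `(k̂ − S/a₁) / √(e₁S + e₂S(S−1))` with the 1989
  constants;
- **ROHs** — runs of homozygosity per sample from a two-state
  (Hardy–Weinberg / autozygous) HMM decoded by Viterbi;
- **dN/dS (ω)** — Nei–Gojobori (1986) counting estimates per gene with
  Jukes–Cantor correction, after start-codon / stop-codon / length QC
  and an ω ≤ 5 cap;
- **Patterson's D** — frequency-based ABBA−BABA with a block-jackknife
  Z genome-wide, plus per-window D.

Inference follows four routes: an OLS interaction model
`response ~ N_interact + gene_number + N_interact:gene_number` with
standard errors from a block bootstrap (contiguous blocks of 30
intervals, 1000 replicates) and estimated marginal means over the
1st–90th percentile of gene counts; one-sided permutation tests on
class-mean differences (1000 label shuffles, add-one p-values);
Cook's-distance outlier-excess tests (directional outliers of
`statistic ~ gene_number` with an exact binomial enrichment test); and
Fisher's method (`−2Σln p ~ χ²_{2k}`) to combine p-values across
comparisons.

## Worked example

Generate a synthetic cohort with planted selection on *N_interact*
windows, then run the full scan:

```python
from mitoscan import (PipelineConfig, ScanInputs, SimulationConfig,
                      run_scan, write_fixture_bundle)

write_fixture_bundle(SimulationConfig(seed=7), "demo")
inputs = ScanInputs.from_bundle("demo")
report = run_scan(inputs, PipelineConfig(seed=7, n_permutations=500,
                                         n_bootstrap=300),
                  chromosome_lengths={"chr1": 3_000_000})
print(report.tables["fisher_combined"][
    ["metric", "window_size", "k", "df", "x2", "p"]].to_string(index=False))
```

```
      metric  window_size  k  df        x2        p
      d_stat        30000  1   2  7.463399 0.023952
      d_stat       100000  1   2  0.775321 0.678643
        dnds            0  1   2 12.433212 0.001996
         fst        30000  1   2  6.652469 0.035928
         fst       100000  1   2  4.492628 0.105788
fst_outliers        30000  1   2  5.381889 0.067817
          pi        30000  2   4 11.450256 0.021944
          pi       100000  2   4  2.197990 0.699397
 pi_outliers        30000  2   4  8.072834 0.088946
    tajima_d        30000  2   4 11.183193 0.024581
    tajima_d       100000  2   4  2.100358 0.717307
```

Each row is one Fisher combination of `k` one-sided permutation
p-values (df = 2k). The planted signals — higher F_ST, lower π and
Tajima's D, faster protein evolution and gene flow into *N_interact*
windows — are recovered at the 30 kb window size; the 100 kb windows
dilute the 30 kb-scale planted sweeps, as expected.

The interaction model is a statsmodels-style Model/Results pair:

```python
from mitoscan.popgen_stats import compute_window_stats
from mitoscan.selection_inference import InteractionModel, intervals_frame
from mitoscan.windowing import classify, gene_bearing, tile_windows

wins = classify(tile_windows({"chr1": 3_000_000}, 30_000), inputs.genes)
compute_window_stats(inputs.matrix, wins)
frame = intervals_frame(gene_bearing(wins), "fst[pop1:pop2]")
res = InteractionModel(frame, label="fst[pop1:pop2]").fit(
    cov_type="block-bootstrap", block_size=30, n_boot=500, seed=7)
print(res.summary())
```

```
Interaction model: fst[pop1:pop2]
  n obs: 96   R^2: 0.1113   cov: block-bootstrap
  term                            coef          SE           p
  const                        0.04422   0.0040976   3.766e-27
  n_interact                   0.09687    0.034847    0.005438
  gene_number                0.0012342  0.00097446      0.2053
  n_interact:gene_number     -0.017524    0.008112     0.03075
```

The positive `n_interact` coefficient with a negative interaction means
*N_interact* windows have elevated F_ST, most strongly at low gene
counts — the fitted class gap at gene count *g* is
`β₁ + β₃·g` (`res.class_gap_test(g)`), and
`res.marginal_means((1, 90))` tabulates both classes over the
biologically relevant gene-count range with bootstrap 95% bands.

The same pipeline is available from the shell:

```sh
mitoscan simulate --out-dir demo --seed 7
mitoscan run --bundle demo --out-dir scan_out --seed 7
mitoscan dstat --bundle demo --out dstat.tsv
```

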