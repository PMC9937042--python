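# Methods

## The question and the design

The scan asks whether autosomal genes that interact with the
mitochondrial genome or its products (*N_interact* genes: OXPHOS, ARS2,
MRP, REP categories) show stronger signatures of natural selection than
other genes. Because any single statistic is noisy at the scale of one
genomic window, the design is comparative and class-based throughout:
windows (or ROHs, or genes) are classified as *N_interact*,
non-*N_interact* or nongenic, and inference is about the difference
between classes, not about individual windows. Sex chromosomes are
excluded everywhere: their mutation rate, effective population size,
hemizygosity and exposure to selection all differ from the autosomes.

## Window and interval classification

Chromosomes are tiled into fixed, non-overlapping windows anchored at
position 0 (two sizes, 30 kb and 100 kb by default); a trailing partial
window is kept with its true length and flagged, since all window
statistics are per-site averages. Classification uses the transcription
start site (strand-aware: interval start on +, end − 1 on −), not
gene-body overlap, under a half-open containment test; a TSS on a
window boundary belongs to the window that starts there (deterministic
tie-break). Duplicate gene ids collapse to the first record; distinct
genes sharing a TSS each count. Nongenic intervals are excluded from
all linear models and enter only the three-class Tajima's D comparison.

## Statistics

**π** is the mean over sites *polymorphic within the group* of the
per-site pairwise diversity `2·n_ref·n_alt/(n(n−1))`, with `n` the
called alleles at the site. Averaging over polymorphic sites (rather
than dividing by window length) makes the statistic insensitive to
variant density and window truncation; a per-bp variant can be derived
from the emitted site counts.

**F_ST** defaults to the Weir–Cockerham (1984) two-population
variance-components estimator per site (negative estimates retained),
averaged arithmetically over the window's sites with pooled minor
allele frequency ≥ 0.05 — explicitly a mean of per-site values, not a
ratio of sums. A Hudson-style estimator (`1 − H_w/H_b` on expected
heterozygosities) is selectable by config flag. The Hudson variant
deliberately omits finite-sample correction terms so that two groups
with identical allele frequencies give exactly 0; the default WC
estimator is the finite-sample-corrected choice.

**Tajima's D** uses the 1989 formula with constants computed from the
number of sequences. With missing genotypes the per-site allele count
varies; D uses the window-median per-site called-allele count — a fixed
rule that keeps D well-defined without imputation. `k̂` is the sum over
usable sites of per-site mean pairwise differences; S counts
segregating sites within the group.

**ROHs** come from a two-state HMM per sample: state HW emits a
heterozygote at the Hardy–Weinberg rate 2p(1−p) from cohort allele
frequencies, state AZ (autozygous) at the genotyping-error rate ε.
Transition probability across a gap of d bp is `1 − exp(−rate·d)`, with
`rate_into_az = 6.7e-8`/bp, `rate_out_of_az = 5e-9`/bp and `ε = 1e-3`
by default (the published defaults of the standard genotype-based
caller; all three are config-exposed and stamped into output metadata).
Decoding is Viterbi from a uniform initial distribution; missing
genotypes are skipped and do not break runs; an ROH spans the first to
last site of a maximal AZ run (half-open). No minimum-length or
minimum-site filter is applied by default since none is prescribed;
both are available. Hard genotypes only — genotype likelihoods are not
modelled. Note that raising ε is *not* globally monotone in the amount
of AZ called: it makes heterozygotes cheaper inside runs (extending
them) while making homozygotes slightly less diagnostic; on
homozygous-only input the effect is monotone decreasing, and the test
suite asserts exactly that.

**dN/dS** is the Nei–Gojobori (1986) counting estimator: per codon,
each position's three possible changes are classified synonymous or
nonsynonymous (changes to stop codons count as nonsynonymous, so
site counts sum to exactly 3 per codon); for a differing codon pair all
minimal mutational pathways are enumerated, pathways through stop
codons dropped, and difference counts averaged equally over the rest;
proportions are Jukes–Cantor corrected. Gene-level dN and dS are means
over all sequence pairs; ω = dN/dS, undefined when dS = 0. QC excludes
genes lacking an ATG start, containing a premature stop, or with length
not a multiple of three; estimates with ω > 5 are discarded as
unreliable. This is a deliberate substitution of a counting estimator
for a one-ratio maximum-likelihood codon model: it is closed-form,
oracle-testable and adequate for a class-mean comparison, but it
ignores transition/transversion bias and codon frequencies, and
pairwise means over a star of taxa are not branch-length-aware. The
neighbor-joining tree built from p-distances is emitted for reporting
only (scikit-bio's NJ with lexicographically sorted taxa for
deterministic ties).

**Patterson's D** uses frequency-based site patterns for
(((P1,P2),P3),O): `ABBA = (1−p₁)p₂p₃(1−p₄)`,
`BABA = p₁(1−p₂)p₃(1−p₄)`, summed over sites;
`D = (ΣABBA − ΣBABA)/(ΣABBA + ΣBABA)`. Frequencies (not pseudohaploid
draws) are appropriate because each taxon has multiple individuals. The
genome-wide Z comes from a delete-one block jackknife over 100
equal-site blocks; the windowed analysis reuses the genomic windows and
feeds the class comparison.

## Inference

**Interaction model.** For each response (ln of ROH length in 100 kb
units — log-transformed because raw lengths are strongly right-skewed —
or raw window F_ST/π, untransformed) an OLS fit of
`response ~ N_interact + gene_number + N_interact:gene_number`. The
interaction term avoids assuming the class effect is constant across
gene densities; the quantity of interest is the class gap
`β₁ + β₃·g`, reported over the integer gene-count grid spanning the
1st–90th percentiles of the observed distribution (estimated marginal
means), with 95% bands from bootstrap replicate predictions.

**Block bootstrap.** Adjacent windows are autocorrelated, so analytic
OLS standard errors are anticonservative. Contiguous blocks of 30
intervals (moving blocks, within chromosome) are resampled with
replacement to the original length, the model refit per replicate
(1000 by default), the SE taken as the replicate standard deviation and
p-values from the normal approximation `2(1 − Φ(|β̂|/SE))`.
Rank-deficient replicates are redrawn and counted. The block size of 30
follows the observed decay of window autocorrelation in this kind of
data. SEs at floating-point noise level (constant response) are
reported with p = NA rather than a meaningless number.

**Permutation tests.** One-sided label-shuffling tests on the
difference of class means, with the add-one convention
`p = (#{null ≥ obs} + 1)/(B + 1)` (upper tail; ≤ for lower), so p is
never 0 and is exactly 1 for constant input. Directions are fixed a
priori: ROH length and F_ST and ω upper-tailed; π and Tajima's D
lower-tailed. The observed statistic is computed through the same
arithmetic path as the null replicates so that degenerate inputs tie
exactly.

**Outlier excess.** `statistic ~ gene_number` is fitted on all
gene-bearing windows; a window is an outlier when its Cook's distance
exceeds 4/n *and* its residual sign matches the direction of interest
(positive for upper-F_ST, negative for lower-π). Enrichment of
*N_interact* windows among outliers is tested with an exact upper-tail
binomial, baseline probability the overall *N_interact* share of
gene-bearing windows. Both the 4/n threshold and the direction rule are
configuration, recorded in output metadata. The outlier analysis runs
at the smallest window size, matching the study design the scan
mirrors.

**Fisher combination.** `X² = −2Σln pᵢ ~ χ²` with df = 2k, one
combination per metric × window size across groups/pairs. F_ST rows
carry an explicit caveat: pairwise comparisons within a data set share
samples, violating the independence assumption. Zero p-values (which
the add-one convention cannot produce) are clamped to 1/1001 with a
warning.

## The synthetic-data generator

The generator emulates a desk-scale analogue of a multi-population
primate cohort; its defaults define the study conditions for all tests.

- **Differentiation**: Balding–Nichols — per-population allele
  frequencies Beta-distributed around a shared ancestral frequency with
  dispersion F. Chosen over coalescent simulation for its closed-form
  F_ST expectation, which makes window F_ST directly testable.
  Ancestral frequencies follow a truncated neutral SFS (density ∝ 1/p
  on [0.001, 0.999]) so the unswept genome yields Tajima's D near 0.
- **Sweeps**: selected windows (a fraction of *N_interact* windows,
  default 10%) use `selected_fst` (default 0.35 vs baseline 0.05) and
  mix a Beta(0.5, 5) rare-allele component into the ancestral prior
  with weight `sfs_skew/(1 + sfs_skew)` (default skew 3). Within each
  population the same sites are additionally compressed toward the
  nearest frequency boundary (multiplying the minor side by a
  Beta(1, sfs_skew) factor) — post-sweep rarefaction: the swept
  haplotype is near fixation and residual variation is rare. This
  produces the three signatures jointly: elevated window F_ST, reduced
  π per polymorphic site, and negative Tajima's D.
- **ROHs** are planted by drawing one allele per site in the tract and
  doubling it, preserving allele frequencies.
- **CDS evolution**: star tree from an ATG-initiated stopless ancestor;
  proposed point mutations arrive at `cds_mutation_rate` (0.05/nt per
  branch), synonymous ones accepted with min(1, 1/ω) and nonsynonymous
  with min(1, ω), so the realised rate ratio is ω (0.2 background, 0.6
  for *N_interact* genes). Stops and the start codon never change.
- **Introgression**: four-taxon tree (((P1,P2),P3),O) with per-branch
  Balding–Nichols drift `tree_branch_fst = 0.2` (species-level
  divergence; with weaker drift, shared ancestral polymorphism caps the
  attainable window D well below what gene flow should show). In a
  fraction f (default 0.3) of *N_interact* windows, P2's frequencies
  are re-drawn around P3's with drift 0.02 (or copied exactly when
  drift is 0).
- Default cohort: 2 populations × 20 diploids, one 3 Mb chromosome,
  6000 SNPs, 300 genes of which 10% are *N_interact* with category
  proportions matching the real catalogue (101:77:17:4). Identical
  config + seed reproduces every output bit-for-bit, including written
  bundles.

What the generator does **not** emulate: linkage disequilibrium and
recombination maps (sites are exchangeable within a window), realistic
demography (no growth, bottlenecks or migration beyond the planted
scenarios), genotyping error outside the ROH HMM's ε, multi-nucleotide
variants, and selection modes other than sweeps (no balancing or
background selection). Passing tests therefore demonstrate that the
machinery recovers planted signals of the stated effect sizes under
idealised sampling — not that real data of a given size would yield the
same power.

## Numerical and scale choices

Internal coordinates are 0-based half-open (BED convention); VCF
positions convert on ingest. Only biallelic SNPs are analysed; sites
with fewer than two called alleles are skipped; windows with no
qualifying sites are missing for that statistic and drop out of the
models. MAF for F_ST is computed on the pooled pair of groups (matching
two-population estimator conventions); π and D use within-group counts.
Calibration and power checks in the tests and acceptance script run at
reduced sizes chosen for a single CPU — e.g. 40-window null pipelines
with 1200 SNPs for calibration (500 replicates), 200-window cohorts for
F_ST power (200 replicates), 20–30 seeds for the per-signal recovery
rates — with thresholds stated in each test.

## Known limitations

- The two F_ST estimators can disagree at low sample sizes; which one a
  given study used is a config choice, not something the scan infers.
- Tajima's D with heavy, non-random missingness leans on the
  window-median-n rule; extreme missingness patterns would bias it.
- The NG86 estimator saturates (Jukes–Cantor undefined) for proportions
  ≥ 3/4; such pairs are dropped from the gene mean.
- Cross-metric overlap counts comparisons per window but applies no
  multiplicity correction — the scan tests class-level contrasts, not
  per-window significance.
- The block bootstrap assumes stationarity within chromosomes and
  blocks longer than the autocorrelation range; block size is not
  estimated from the data.
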