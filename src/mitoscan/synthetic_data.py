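"""Synthetic inputs with planted, known selection structure.

Every downstream stage of the scan is exercised on data from this
module, so each generator plants the signature its consumer is meant to
detect and records the truth alongside:

* **Differentiation** follows the Balding–Nichols model: per-population
  allele frequencies are Beta-distributed around a shared ancestral
  frequency with dispersion set by F_ST (closed-form expectation, so
  window F_ST is directly testable). Selected windows use a higher F
  and draw ancestral frequencies with extra mass near 0 (a
  Beta(0.5, 5) mixture component weighted by ``sfs_skew``), which
  lowers pi and skews the site-frequency spectrum negative, as after a
  sweep.
* **ROHs** are planted by overwriting a sample's tract with homozygous
  genotypes (one allele drawn per site and doubled).
* **Coding sequences** evolve on a star tree with synonymous changes
  accepted at rate min(1, 1/omega) and nonsynonymous at min(1, omega),
  so the realised dN/dS ratio is omega.
* **Introgression** uses a four-taxon tree (((P1,P2),P3),O); in a
  fraction f of designated windows P2's frequencies are copied (with
  optional drift) from P3 instead of the (P1,P2) ancestor.

The same seed always yields bit-identical outputs.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from . import genome_io
from .genome_io import GeneAnnotation, GenotypeMatrix
from .windowing import classify, tile_windows

_STOPLESS_CODONS = None


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic scan (desk-scale analogue of
    a multi-population macaque data set)."""

    n_populations: int = 2
    samples_per_population: int = 20
    chromosome_length: int = 3_000_000
    chrom: str = "chr1"
    n_sites: int = 6000
    window_size: int = 30_000
    baseline_fst: float = 0.05
    selected_fst: float = 0.35
    selected_window_fraction: float = 0.10
    sfs_skew: float = 3.0
    n_genes: int = 300
    n_interact_fraction: float = 0.10
    planted_roh: list[tuple[str, int, int]] = field(default_factory=list)
    omega_background: float = 0.2
    omega_selected: float = 0.6
    introgression_fraction: float = 0.3
    introgression_drift: float = 0.02
    tree_branch_fst: float = 0.2  # per-branch drift of the 4-taxon species tree
    cds_mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if self.n_populations < 1 or self.samples_per_population < 1:
            raise ConfigError("populations and samples per population must be >= 1")
        if not 0 < self.baseline_fst < 1:
            raise ConfigError("baseline_fst must lie in (0, 1)")
        if self.selected_window_fraction > 0 and not (
            self.baseline_fst <= self.selected_fst < 1
        ):
            raise ConfigError(
                "need baseline_fst <= selected_fst < 1 when selection is planted"
            )
        if self.sfs_skew < 0:
            raise ConfigError("sfs_skew must be >= 0")
        if not 0 <= self.introgression_fraction < 1:
            raise ConfigError("introgression_fraction must lie in [0, 1)")
        if self.omega_background <= 0 or self.omega_selected <= 0:
            raise ConfigError("omega values must be positive")
        for sample, start, end in self.planted_roh:
            if not (0 <= start < end <= self.chromosome_length):
                raise ConfigError(
                    f"planted ROH ({sample}, {start}, {end}) outside chromosome"
                )


@dataclass
class TruthTable:
    """What was planted, for truth-based tests downstream."""

    selected_window_ids: list[str] = field(default_factory=list)
    planted_roh: list[tuple[str, int, int]] = field(default_factory=list)
    per_gene_true_omega: dict[str, float] = field(default_factory=dict)
    introgressed_window_ids: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            raw = json.load(fh)
        raw["planted_roh"] = [tuple(t) for t in raw.get("planted_roh", [])]
        return cls(**raw)


# ---------------------------------------------------------------------------
# genes
# ---------------------------------------------------------------------------

_CATEGORY_WEIGHTS = {"OXPHOS": 101, "ARS2": 77, "MRP": 17, "REP": 4}


def simulate_genes(config: SimulationConfig, rng: np.random.Generator) -> list[GeneAnnotation]:
    """Random gene annotations; a fraction are N_interact with category
    frequencies matching the real catalogue's proportions."""
    n = config.n_genes
    n_ni = int(round(n * config.n_interact_fraction))
    ni_idx = set(rng.choice(n, size=n_ni, replace=False).tolist())
    cats = list(_CATEGORY_WEIGHTS)
    probs = np.array(list(_CATEGORY_WEIGHTS.values()), dtype=float)
    probs /= probs.sum()
    genes = []
    starts = np.sort(rng.integers(0, max(config.chromosome_length - 60_000, 1), size=n))
    for i, start in enumerate(starts):
        length = int(rng.integers(5_000, 50_000))
        end = min(int(start) + length, config.chromosome_length)
        ni = i in ni_idx
        genes.append(
            GeneAnnotation(
                gene_id=f"gene{i:04d}",
                chrom=config.chrom,
                start=int(start),
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                n_interact=ni,
                category=str(rng.choice(cats, p=probs)) if ni else "OTHER",
            )
        )
    return genes


def _pick_selected_windows(windows, fraction, rng):
    """Selected windows are drawn among N_interact windows (falling
    back to all gene-bearing windows if the annotation has none)."""
    pool = [w for w in windows if w.window_class == "N_INTERACT"]
    if not pool:
        pool = [w for w in windows if w.gene_number >= 1] or list(windows)
    k = int(round(fraction * len(pool)))
    take = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
    return [pool[i] for i in sorted(take)]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _balding_nichols(anc: np.ndarray, fst: np.ndarray, rng) -> np.ndarray:
    """Population frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    lam = (1.0 - fst) / fst
    return rng.beta(np.maximum(anc * lam, 1e-6), np.maximum((1.0 - anc) * lam, 1e-6))


def _neutral_sfs_freqs(n_sites, rng, lo=0.001, hi=0.999):
    """Ancestral frequencies with density proportional to 1/p (the
    standing-variation SFS of a neutral equilibrium population), so the
    unswept genome yields Tajima's D near 0."""
    u = rng.random(n_sites)
    return lo * (hi / lo) ** u


def _ancestral_freqs(n_sites, swept_mask, sfs_skew, rng):
    """Ancestral frequencies plus the per-site mask of sites carrying
    the sweep signature (a Beta(0.5, 5) rare-allele component mixed in
    with weight sfs_skew / (1 + sfs_skew))."""
    anc = _neutral_sfs_freqs(n_sites, rng)
    use_skew = np.zeros(n_sites, dtype=bool)
    if sfs_skew > 0 and swept_mask.any():
        w = sfs_skew / (1.0 + sfs_skew)
        use_skew = swept_mask & (rng.random(n_sites) < w)
        skewed = np.clip(rng.beta(0.5, 5.0, size=n_sites), 0.01, 0.99)
        anc = np.where(use_skew, skewed, anc)
    return anc, use_skew


def _sweep_compress(p, mask, sfs_skew, rng):
    """Post-sweep rarefaction within one population: frequencies at
    swept sites are pushed toward the nearest boundary (the swept
    haplotype is near fixation; residual variation is rare), which
    lowers pi and skews Tajima's D negative."""
    if sfs_skew <= 0 or not mask.any():
        return p
    x = rng.beta(1.0, sfs_skew, size=len(p))
    compressed = np.where(p < 0.5, p * x, 1.0 - (1.0 - p) * x)
    return np.where(mask, compressed, p)


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """Multi-population genotypes with selection signatures planted in
    a subset of N_interact windows, plus homozygous tracts.

    Returns the matrix (samples named ``pop<k>_s<i>``, grouped by
    population) and the truth table. The gene annotation used to choose
    selected windows is regenerated deterministically by
    :func:`simulate_genes` with the same seed.
    """
    rng = np.random.default_rng(config.seed)
    genes = simulate_genes(config, rng)
    windows = classify(
        tile_windows({config.chrom: config.chromosome_length}, config.window_size),
        genes,
    )
    selected = (
        _pick_selected_windows(windows, config.selected_window_fraction, rng)
        if config.selected_window_fraction > 0
        else []
    )

    positions = np.sort(
        rng.choice(config.chromosome_length, size=config.n_sites, replace=False)
    )
    swept = np.zeros(config.n_sites, dtype=bool)
    for w in selected:
        swept |= (positions >= w.start) & (positions < w.end)

    anc, sweep_mask = _ancestral_freqs(config.n_sites, swept, config.sfs_skew, rng)
    fst = np.where(swept, config.selected_fst, config.baseline_fst)

    samples, groups = [], {}
    dosage_cols = []
    pop_freqs = {}
    for k in range(config.n_populations):
        pop = f"pop{k + 1}"
        p = _balding_nichols(anc, fst, rng)
        p = _sweep_compress(p, sweep_mask, config.sfs_skew, rng)
        pop_freqs[pop] = p
        for i in range(config.samples_per_population):
            name = f"{pop}_s{i + 1:02d}"
            samples.append(name)
            groups[name] = pop
            dosage_cols.append(rng.binomial(2, p).astype(np.int8))
    genotypes = np.column_stack(dosage_cols)

    for sample, start, end in config.planted_roh:
        if sample not in groups:
            raise ConfigError(f"planted ROH names unknown sample {sample!r}")
        j = samples.index(sample)
        mask = (positions >= start) & (positions < end)
        p = pop_freqs[groups[sample]][mask]
        genotypes[mask, j] = (2 * rng.binomial(1, p)).astype(np.int8)

    matrix = GenotypeMatrix(
        chrom=np.array([config.chrom] * config.n_sites, dtype=object),
        pos=positions.astype(np.int64),
        ref=np.array(["A"] * config.n_sites, dtype=object),
        alt=np.array([rng.choice(["C", "G", "T"]) for _ in range(config.n_sites)], dtype=object),
        genotypes=genotypes,
        samples=samples,
        groups=groups,
    )
    truth = TruthTable(
        selected_window_ids=[w.window_id for w in selected],
        planted_roh=list(config.planted_roh),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# four-taxon introgression scenario
# ---------------------------------------------------------------------------

FOUR_TAXA = ("P1", "P2", "P3", "O")


def simulate_four_taxon(
    config: SimulationConfig,
    target: str = "n_interact",
) -> tuple[GenotypeMatrix, TruthTable]:
    """Genotypes for (((P1,P2),P3),O) with P3→P2 gene flow in a
    fraction ``introgression_fraction`` of target windows.

    ``target`` is ``"n_interact"`` (introgression planted only in
    N_interact windows; default) or ``"all"``. With
    ``introgression_drift = 0`` the introgressed P2 frequencies equal
    P3's exactly.
    """
    if target not in ("n_interact", "all"):
        raise ConfigError("target must be 'n_interact' or 'all'")
    rng = np.random.default_rng(config.seed)
    genes = simulate_genes(config, rng)
    windows = classify(
        tile_windows({config.chrom: config.chromosome_length}, config.window_size),
        genes,
    )
    if target == "n_interact":
        pool = [w for w in windows if w.window_class == "N_INTERACT"]
    else:
        pool = list(windows)
    k = int(round(config.introgression_fraction * len(pool)))
    take = sorted(rng.choice(len(pool), size=min(k, len(pool)), replace=False))
    introgressed = [pool[i] for i in take]

    positions = np.sort(
        rng.choice(config.chromosome_length, size=config.n_sites, replace=False)
    )
    flow = np.zeros(config.n_sites, dtype=bool)
    for w in introgressed:
        flow |= (positions >= w.start) & (positions < w.end)

    anc = _neutral_sfs_freqs(config.n_sites, rng)
    fvec = np.full(config.n_sites, config.tree_branch_fst)
    p_o = _balding_nichols(anc, fvec, rng)
    p_123 = _balding_nichols(anc, fvec, rng)
    p_3 = _balding_nichols(p_123, fvec, rng)
    p_12 = _balding_nichols(p_123, fvec, rng)
    p_1 = _balding_nichols(p_12, fvec, rng)
    p_2 = _balding_nichols(p_12, fvec, rng)
    if config.introgression_drift > 0:
        p_2_flow = _balding_nichols(
            p_3, np.full(config.n_sites, config.introgression_drift), rng
        )
    else:
        p_2_flow = p_3
    p_2 = np.where(flow, p_2_flow, p_2)

    freq_by_taxon = dict(zip(FOUR_TAXA, (p_1, p_2, p_3, p_o)))
    samples, groups, cols = [], {}, []
    for taxon in FOUR_TAXA:
        p = freq_by_taxon[taxon]
        for i in range(config.samples_per_population):
            name = f"{taxon}_s{i + 1:02d}"
            samples.append(name)
            groups[name] = taxon
            cols.append(rng.binomial(2, p).astype(np.int8))
    matrix = GenotypeMatrix(
        chrom=np.array([config.chrom] * config.n_sites, dtype=object),
        pos=positions.astype(np.int64),
        ref=np.array(["A"] * config.n_sites, dtype=object),
        alt=np.array(["T"] * config.n_sites, dtype=object),
        genotypes=np.column_stack(cols),
        samples=samples,
        groups=groups,
    )
    truth = TruthTable(introgressed_window_ids=[w.window_id for w in introgressed])
    return matrix, truth


# ---------------------------------------------------------------------------
# coding sequences
# ---------------------------------------------------------------------------

def _stopless_codons():
    global _STOPLESS_CODONS
    if _STOPLESS_CODONS is None:
        from .dnds import BASES, STOP_CODONS

        _STOPLESS_CODONS = [
            a + b + c
            for a in BASES for b in BASES for c in BASES
            if a + b + c not in STOP_CODONS
        ]
    return _STOPLESS_CODONS


def _evolve_branch(seq: list[str], omega: float, rate: float, rng) -> list[str]:
    """Apply Poisson-many proposed point mutations; synonymous accepted
    with min(1, 1/omega), nonsynonymous with min(1, omega); stops and
    the start codon never change."""
    from .dnds import BASES, STOP_CODONS, translate_codon

    seq = list(seq)
    length = len(seq) * 3
    n_events = rng.poisson(rate * (length - 3))
    p_syn = min(1.0, 1.0 / omega)
    p_nonsyn = min(1.0, omega)
    for _ in range(n_events):
        pos = int(rng.integers(3, length))  # keep ATG intact
        ci, off = divmod(pos, 3)
        codon = seq[ci]
        alts = [b for b in BASES if b != codon[off]]
        new = codon[:off] + str(rng.choice(alts)) + codon[off + 1:]
        if new in STOP_CODONS:
            continue
        syn = translate_codon(new) == translate_codon(codon)
        accept = rng.random() < (p_syn if syn else p_nonsyn)
        if accept:
            seq[ci] = new
    return seq


def simulate_cds(
    config: SimulationConfig,
    n_taxa: int = 6,
    codons_per_gene: int = 200,
    genes: list[GeneAnnotation] | None = None,
) -> tuple[dict[str, dict[str, str]], TruthTable]:
    """Per-gene CDS alignments evolved on a star tree.

    N_interact genes evolve at ``omega_selected``, others at
    ``omega_background``. Returns {gene_id: {taxon: sequence}} and a
    truth table with the per-gene true omega. Alignments always start
    with ATG, have length 3 * codons_per_gene and contain no stop
    codon.
    """
    if codons_per_gene < 30:
        raise ConfigError("codons_per_gene must be >= 30")
    rng = np.random.default_rng(config.seed + 1)
    if genes is None:
        genes = simulate_genes(config, np.random.default_rng(config.seed))
    taxa = [f"taxon{i + 1}" for i in range(n_taxa)]
    alignments: dict[str, dict[str, str]] = {}
    truth = TruthTable()
    codon_pool = _stopless_codons()
    for gene in genes:
        omega = config.omega_selected if gene.n_interact else config.omega_background
        ancestor = ["ATG"] + [
            codon_pool[i] for i in rng.integers(0, len(codon_pool), size=codons_per_gene - 1)
        ]
        alignments[gene.gene_id] = {
            t: "".join(_evolve_branch(ancestor, omega, config.cds_mutation_rate, rng))
            for t in taxa
        }
        truth.per_gene_true_omega[gene.gene_id] = omega
    return alignments, truth


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    out_dir: str
    vcf: str
    gff3: str
    gene_bed: str
    n_interact_list: str
    group_map: str
    cds_dir: str
    truth_json: str
    dstat_vcf: str
    dstat_group_map: str


def write_fixture_bundle(
    config: SimulationConfig,
    out_dir: str | os.PathLike,
    n_taxa: int = 6,
    codons_per_gene: int = 60,
    cds_genes: int | None = 80,
) -> FixtureBundle:
    """Emit a complete input bundle (VCF, GFF3, BED, TSVs, FASTAs,
    truth JSON) that round-trips through :mod:`mitoscan.genome_io`.

    ``cds_genes`` caps how many genes get CDS alignments (all
    N_interact genes plus a background sample); None means all genes.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genes = simulate_genes(config, rng)

    matrix, truth = simulate_genotypes(config)
    dmatrix, dtruth = simulate_four_taxon(config)
    truth.introgressed_window_ids = dtruth.introgressed_window_ids

    if cds_genes is None or cds_genes >= len(genes):
        cds_gene_list = genes
    else:
        ni = [g for g in genes if g.n_interact]
        other = [g for g in genes if not g.n_interact]
        n_bg = max(cds_genes - len(ni), 1)
        take = np.random.default_rng(config.seed + 2).choice(
            len(other), size=min(n_bg, len(other)), replace=False
        )
        cds_gene_list = ni + [other[i] for i in sorted(take)]
    alignments, cds_truth = simulate_cds(
        config, n_taxa=n_taxa, codons_per_gene=codons_per_gene, genes=cds_gene_list
    )
    truth.per_gene_true_omega = cds_truth.per_gene_true_omega

    paths = FixtureBundle(
        out_dir=out_dir,
        vcf=os.path.join(out_dir, "cohort.vcf"),
        gff3=os.path.join(out_dir, "genes.gff3"),
        gene_bed=os.path.join(out_dir, "truth_selected_windows.bed"),
        n_interact_list=os.path.join(out_dir, "n_interact_genes.tsv"),
        group_map=os.path.join(out_dir, "groups.tsv"),
        cds_dir=os.path.join(out_dir, "cds"),
        truth_json=os.path.join(out_dir, "truth.json"),
        dstat_vcf=os.path.join(out_dir, "four_taxon.vcf"),
        dstat_group_map=os.path.join(out_dir, "four_taxon_groups.tsv"),
    )
    genome_io.write_vcf(matrix, paths.vcf)
    genome_io.write_gff3(genes, paths.gff3)
    with open(paths.n_interact_list, "w") as fh:
        for g in genes:
            if g.n_interact:
                fh.write(f"{g.gene_id}\t{g.category}\n")
    genome_io.write_group_map(matrix.groups, paths.group_map)
    with open(paths.gene_bed, "w") as fh:
        for wid in truth.selected_window_ids:
            chrom, span = wid.split(":")
            start, end = span.split("-")
            fh.write(f"{chrom}\t{start}\t{end}\tselected\n")
        for sample, start, end in truth.planted_roh:
            fh.write(f"{config.chrom}\t{start}\t{end}\troh:{sample}\n")
    os.makedirs(paths.cds_dir, exist_ok=True)
    for gene_id in sorted(alignments):
        with open(os.path.join(paths.cds_dir, f"{gene_id}.fasta"), "w") as fh:
            for taxon in sorted(alignments[gene_id]):
                fh.write(f">{taxon}\n{alignments[gene_id][taxon]}\n")
    truth.to_json(paths.truth_json)
    genome_io.write_vcf(dmatrix, paths.dstat_vcf)
    genome_io.write_group_map(dmatrix.groups, paths.dstat_group_map)
    return paths


def read_cds_dir(cds_dir: str) -> dict[str, dict[str, str]]:
    """Read per-gene FASTA alignments written by the bundle."""
    from Bio import SeqIO

    out = {}
    for name in sorted(os.listdir(cds_dir)):
        if not name.endswith((".fasta", ".fa")):
            continue
        gene_id = name.rsplit(".", 1)[0]
        out[gene_id] = {
            rec.id: str(rec.seq)
            for rec in SeqIO.parse(os.path.join(cds_dir, name), "fasta")
        }
    return out
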