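"""Readers, writers and core containers for the scan pipeline.

All genomic coordinates are handled internally as 0-based half-open
intervals (BED convention); point positions (variant sites, transcription
start sites) are 0-based. VCF positions are converted on ingest and
restored on export.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger("mitoscan")

MISSING = -1

#: chromosome names never analysed: sex chromosomes and the mitochondrion.
EXCLUDED_CHROMS = {"X", "Y", "MT", "M", "chrX", "chrY", "chrM", "chrMT"}

N_INTERACT_CATEGORIES = ("OXPHOS", "ARS2", "MRP", "REP")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Diploid genotypes at biallelic SNPs, as alt-allele dosages.

    Attributes
    ----------
    chrom : array of str, one per site
    pos : array of int, 0-based position per site, strictly increasing
        within each chromosome
    ref, alt : arrays of single-base alleles
    genotypes : int8 array (n_sites, n_samples); values 0/1/2 are alt
        dosages, -1 is missing
    samples : list of sample ids (column order)
    groups : dict sample id -> group label
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: list[str]
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        if self.genotypes.shape != (len(self.pos), len(self.samples)):
            raise ValueError("genotype matrix shape does not match sites/samples")
        for chrom in pd.unique(self.chrom):
            p = self.pos[self.chrom == chrom]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        for s in self.groups:
            if s not in self.samples:
                raise ValueError(f"group map names unknown sample {s!r}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, names) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.samples)}
        return np.array([idx[n] for n in names], dtype=int)

    def group_members(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups.get(s) == group]

    def group_dosages(self, group: str) -> np.ndarray:
        """Dosage sub-matrix (n_sites, n_members) for one group."""
        members = self.group_members(group)
        if not members:
            raise KeyError(f"no samples assigned to group {group!r}")
        return self.genotypes[:, self.sample_index(members)]

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            genotypes=self.genotypes[mask],
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: interval, strand, derived TSS and N_interact status."""

    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    strand: str
    n_interact: bool = False
    category: str = "OTHER"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end <= start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.n_interact and self.category != "OTHER":
            raise ValueError("category labels are reserved for N_interact genes")

    @property
    def tss(self) -> int:
        """Transcription start: `start` on +, `end - 1` on - strand."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class PipelineConfig:
    """Tuning knobs of the scan, with the study defaults."""

    window_sizes: tuple[int, ...] = (30_000, 100_000)
    maf_cutoff: float = 0.05
    n_permutations: int = 1000
    block_size: int = 30
    n_bootstrap: int = 1000
    percentile_range: tuple[float, float] = (1.0, 90.0)
    background_genes: int = 3000
    omega_cap: float = 5.0
    fst_estimator: str = "weir-cockerham"
    cooks_threshold_factor: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.maf_cutoff < 0.5:
            raise ValueError("maf_cutoff must be in [0, 0.5)")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        lo, hi = self.percentile_range
        if not (0 <= lo <= 100 and 0 <= hi <= 100):
            raise ValueError("percentile bounds must lie in [0, 100]")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_SNP_ALLELES = frozenset("ACGT")


def read_vcf(path: str | os.PathLike, group_map: dict[str, str]) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are dropped (count logged), as are
    records on sex chromosomes / the mitochondrion. Missing genotypes
    become dosage -1.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    missing = set(group_map) - set(samples)
    if missing:
        raise ValueError(f"group map names samples absent from VCF: {sorted(missing)}")

    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_dropped_nonsnp = n_dropped_sex = 0
    for rec in vcf:
        if rec.CHROM in EXCLUDED_CHROMS:
            n_dropped_sex += 1
            continue
        if (
            len(rec.ALT) != 1
            or rec.REF not in _SNP_ALLELES
            or rec.ALT[0] not in _SNP_ALLELES
        ):
            n_dropped_nonsnp += 1
            continue
        gts = rec.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gts[gts == 3] = MISSING
        chroms.append(rec.CHROM)
        poss.append(rec.POS - 1)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(gts)
    if n_dropped_nonsnp or n_dropped_sex:
        log.info(
            "read_vcf: dropped %d multiallelic/non-SNP and %d sex-chromosome records",
            n_dropped_nonsnp, n_dropped_sex,
        )
    genotypes = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        genotypes=genotypes,
        samples=samples,
        groups=dict(group_map),
    )


def write_vcf(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal VCFv4.2 (GT only) restoring 1-based positions."""
    dosage_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(matrix.chrom):
            length = int(matrix.pos[matrix.chrom == chrom].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i in range(matrix.n_sites):
            gts = "\t".join(dosage_to_gt[int(g)] for g in matrix.genotypes[i])
            fh.write(
                f"{matrix.chrom[i]}\t{matrix.pos[i] + 1}\t.\t{matrix.ref[i]}\t"
                f"{matrix.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _parse_gff3_genes(path) -> list[tuple[str, str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            chrom, _, _, start, end, _, strand = parts[:7]
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Name")
            if gene_id is None:
                continue
            # GFF3 is 1-based inclusive
            out.append((gene_id, chrom, int(start) - 1, int(end), strand))
    return out


def _parse_bed_genes(path) -> list[tuple[str, str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError("BED gene records need 6 columns (incl. name, strand)")
            chrom, start, end, name, _, strand = parts[:6]
            out.append((name, chrom, int(start), int(end), strand))
    return out


def read_n_interact_list(path) -> dict[str, str]:
    """Read the N_interact catalogue: TSV of gene id and category."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            gene_id = parts[0]
            category = parts[1] if len(parts) > 1 else "OXPHOS"
            if category not in N_INTERACT_CATEGORIES:
                raise ValueError(f"unknown N_interact category {category!r}")
            table[gene_id] = category
    return table


def read_annotations(
    path: str | os.PathLike,
    n_interact: dict[str, str] | str | os.PathLike | None = None,
) -> list[GeneAnnotation]:
    """Read gene annotations (GFF3 or BED) and flag N_interact genes.

    ``n_interact`` maps gene id -> category (or is a path to such a TSV).
    Catalogue entries with no matching annotation id are counted and
    warned about, then ignored. Duplicate gene ids collapse to the first
    record seen.
    """
    path = str(path)
    if n_interact is None:
        n_interact = {}
    elif not isinstance(n_interact, dict):
        n_interact = read_n_interact_list(n_interact)

    if path.endswith((".bed", ".bed.txt")):
        raw = _parse_bed_genes(path)
    else:
        raw = _parse_gff3_genes(path)

    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    for gene_id, chrom, start, end, strand in raw:
        if gene_id in seen:
            continue
        seen.add(gene_id)
        flag = gene_id in n_interact
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                n_interact=flag,
                category=n_interact[gene_id] if flag else "OTHER",
            )
        )
    unmatched = set(n_interact) - seen
    if unmatched:
        log.warning(
            "read_annotations: %d N_interact ids not found in annotation "
            "(e.g. %s)", len(unmatched), sorted(unmatched)[:3],
        )
    return genes


def write_gff3(genes: list[GeneAnnotation], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tmitoscan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_group_map(path) -> dict[str, str]:
    """TSV of sample id and group label."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sample, group = line.split()[:2]
            out[sample] = group
    return out


def write_group_map(groups: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def write_table(frame: pd.DataFrame, path) -> None:
    """TSV writer for result tables (empty tables keep their header)."""
    frame.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(intervals, path, name_col: str | None = None) -> None:
    """BED export. ``intervals`` is an iterable of objects with
    chrom/start/end attributes or a DataFrame with those columns."""
    with open(path, "w") as fh:
        if isinstance(intervals, pd.DataFrame):
            for _, row in intervals.iterrows():
                name = f"\t{row[name_col]}" if name_col else ""
                fh.write(f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}{name}\n")
        else:
            for iv in intervals:
                name = f"\t{getattr(iv, name_col)}" if name_col else ""
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}{name}\n")


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | os.PathLike) -> dict[str, str]:
    """Write a dict of named result tables as TSVs under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, frame in tables.items():
        p = os.path.join(out_dir, f"{name}.tsv")
        write_table(frame, p)
        paths[name] = p
    return paths
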