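"""Per-gene dN/dS by the Nei–Gojobori (1986) counting method.

For each codon position the three possible single-nucleotide changes
are classified as synonymous or nonsynonymous (changes creating a stop
codon count as nonsynonymous, so synonymous + nonsynonymous sites sum
to exactly 3 per codon). For a codon pair differing at k positions, all
k! single-step mutational pathways are enumerated; pathways passing
through a stop codon are excluded and the synonymous/nonsynonymous
difference counts are averaged with equal weight over the remaining
pathways. Proportions are Jukes–Cantor corrected per class,
d = -3/4 * ln(1 - 4p/3). A gene's dN and dS are means over all
sequence pairs of the alignment; omega = dN/dS.

Genes failing QC (no ATG start, premature stop, length not a multiple
of three) or with omega above the cap are excluded from the
N_interact/background comparison.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .selection_inference import ResamplingResult, permutation_test

BASES = "ACGT"

QC_PASS = "PASS"
QC_NO_ATG = "NO_ATG"
QC_PREMATURE_STOP = "PREMATURE_STOP"
QC_BAD_LENGTH = "LENGTH_NOT_MULTIPLE_OF_3"
QC_OMEGA_CAP = "OMEGA_GT_CAP"

# standard genetic code
_CODON_TABLE: dict[str, str] = {}


def _build_code() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    _CODON_TABLE.update(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        _CODON_TABLE[stop] = "*"


_build_code()

STOP_CODONS = frozenset(c for c, aa in _CODON_TABLE.items() if aa == "*")


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon]


@dataclass
class DnDsRecord:
    gene_id: str
    n_interact: bool
    dn: float
    ds: float
    omega: float  # NaN when dS = 0 or undefined
    qc_status: str

    @property
    def usable(self) -> bool:
        return self.qc_status == QC_PASS and math.isfinite(self.omega)

    def to_row(self) -> dict:
        return {
            "gene_id": self.gene_id, "n_interact": self.n_interact,
            "dn": self.dn, "ds": self.ds, "omega": self.omega,
            "qc_status": self.qc_status,
        }


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_gene(sequences: list[str]) -> str:
    """QC status of an aligned CDS set: PASS iff every sequence starts
    with ATG, the length is a multiple of 3 and there is no internal
    stop codon (a terminal stop is allowed)."""
    if not sequences:
        raise ValueError("empty alignment")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("aligned sequences must have equal length")
    if length % 3 != 0:
        return QC_BAD_LENGTH
    for seq in sequences:
        seq = seq.upper()
        if not seq.startswith("ATG"):
            return QC_NO_ATG
        codons = [seq[i:i + 3] for i in range(0, len(seq) - 3, 3)]
        if any(c in STOP_CODONS for c in codons):
            return QC_PREMATURE_STOP
    return QC_PASS


# ---------------------------------------------------------------------------
# NG86 machinery
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; sums to 3.
    Changes producing stop codons count as nonsynonymous."""
    aa = translate_codon(codon)
    syn = 0.0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if translate_codon(alt) == aa and alt not in STOP_CODONS:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts for a codon pair,
    averaged with equal weight over minimal mutational pathways that
    avoid stop codons. Falls back to all pathways if every one passes
    through a stop."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order):
        syn = nsyn = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != c2:
                return None
            if translate_codon(cur) == translate_codon(nxt):
                syn += 1.0
            else:
                nsyn += 1.0
            cur = nxt
        return syn, nsyn

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [
            w for order in itertools.permutations(diff_pos)
            for w in [_walk_through_stops(c1, c2, order)]
        ]
    s = float(np.mean([v[0] for v in valid]))
    n = float(np.mean([v[1] for v in valid]))
    return s, n


def _walk_through_stops(c1, c2, order):
    syn = nsyn = 0.0
    cur = c1
    for pos in order:
        nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
        if translate_codon(cur) == translate_codon(nxt):
            syn += 1.0
        else:
            nsyn += 1.0
        cur = nxt
    return syn, nsyn


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; NaN when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p == 0:
        return 0.0
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pairwise_dnds(seq1: str, seq2: str) -> tuple[float, float]:
    """(dN, dS) for one sequence pair (JC-corrected NG86)."""
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2) or len(seq1) % 3:
        raise ValueError("sequences must be aligned and codon-complete")
    s_sites = n_sites = sd = nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        s1, n1 = codon_site_counts(c1)
        s2, n2 = codon_site_counts(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites += (n1 + n2) / 2.0
        ds_, dn_ = codon_pair_differences(c1, c2)
        sd += ds_
        nd += dn_
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    return jukes_cantor(pn), jukes_cantor(ps)


def ng86_dnds(
    gene_id: str,
    sequences: list[str],
    n_interact: bool = False,
    omega_cap: float = 5.0,
) -> DnDsRecord:
    """Gene-level NG86 record: dN and dS averaged over all sequence
    pairs; omega missing when dS = 0; omega above the cap flags the
    record OMEGA_GT_CAP (excluded from comparisons, like failed QC)."""
    status = qc_gene(sequences)
    if status != QC_PASS:
        return DnDsRecord(gene_id, n_interact, math.nan, math.nan, math.nan, status)
    if len(sequences) < 2:
        raise ValueError("need >= 2 sequences")
    dns, dss = [], []
    for a, b in itertools.combinations(sequences, 2):
        dn, ds = pairwise_dnds(a, b)
        if math.isfinite(dn) and math.isfinite(ds):
            dns.append(dn)
            dss.append(ds)
    if not dns:
        return DnDsRecord(gene_id, n_interact, math.nan, math.nan, math.nan, QC_PASS)
    dn, ds = float(np.mean(dns)), float(np.mean(dss))
    omega = dn / ds if ds > 0 else math.nan
    status = QC_PASS
    if math.isfinite(omega) and omega > omega_cap:
        status = QC_OMEGA_CAP
    return DnDsRecord(gene_id, n_interact, dn, ds, omega, status)


# ---------------------------------------------------------------------------
# neighbor-joining tree (reporting)
# ---------------------------------------------------------------------------

def pairwise_p_distance(sequences: dict[str, str]) -> pd.DataFrame:
    """Hamming proportion distance matrix over aligned sequences."""
    names = sorted(sequences)
    n = len(names)
    mat = np.zeros((n, n))
    arrs = {k: np.frombuffer(sequences[k].upper().encode(), dtype="S1") for k in names}
    for i, a in enumerate(names):
        for j in range(i + 1, n):
            b = names[j]
            mat[i, j] = mat[j, i] = float(np.mean(arrs[a] != arrs[b]))
    return pd.DataFrame(mat, index=names, columns=names)


def nj_tree(distances: pd.DataFrame) -> str:
    """Neighbor-joining tree (newick) from a symmetric distance matrix.
    Taxa are sorted lexicographically first so ties resolve
    deterministically."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    names = sorted(distances.index)
    mat = distances.loc[names, names].to_numpy(dtype=float)
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be symmetric")
    if (mat < 0).any():
        raise ValueError("distances must be non-negative")
    if len(names) < 3:
        # trivial tree
        if len(names) == 1:
            return f"{names[0]};"
        d = mat[0, 1]
        return f"({names[0]}:{d / 2:g},{names[1]}:{d / 2:g});"
    tree = nj(DistanceMatrix(mat, ids=names))
    return str(tree).strip()


# ---------------------------------------------------------------------------
# the class comparison
# ---------------------------------------------------------------------------

def dnds_comparison(
    records: list[DnDsRecord],
    background_n: int = 3000,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> ResamplingResult:
    """Upper-tail permutation test: mean omega of N_interact genes vs a
    random background sample of non-N_interact genes.

    Only records with PASS QC and defined omega enter. If fewer than
    ``background_n`` background genes are available, all are used.
    """
    import logging

    rng = np.random.default_rng(seed)
    fg = [r for r in records if r.usable and r.n_interact]
    bg = [r for r in records if r.usable and not r.n_interact]
    if not fg or not bg:
        raise ValueError("need usable records in both classes")
    if len(bg) > background_n:
        take = rng.choice(len(bg), size=background_n, replace=False)
        bg = [bg[i] for i in take]
    else:
        if len(bg) < background_n:
            logging.getLogger("mitoscan").warning(
                "dnds_comparison: background pool (%d) smaller than requested %d",
                len(bg), background_n,
            )
    values = np.array([r.omega for r in fg] + [r.omega for r in bg])
    labels = np.array([True] * len(fg) + [False] * len(bg))
    return permutation_test(
        values, labels, tail="upper", n_permutations=n_permutations,
        seed=int(rng.integers(2**31)), statistic="omega",
    )


def records_table(records: list[DnDsRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [r.to_row() for r in records],
        columns=["gene_id", "n_interact", "dn", "ds", "omega", "qc_status"],
    )
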