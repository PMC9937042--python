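"""Runs of homozygosity from hard genotypes with a two-state HMM.

The model follows the classic autozygosity HMM: a hidden state per site,
either HW (Hardy–Weinberg, outbred) or AZ (autozygous). AZ emits a
heterozygote only through genotyping error (probability ``epsilon``); HW
emits heterozygotes at the Hardy–Weinberg rate 2p(1-p) given the cohort
allele frequency p. Transitions between adjacent sites d bp apart occur
with probability 1 - exp(-rate * d). Viterbi decoding yields the state
path; each maximal AZ run becomes one ROH spanning its first to last
site (half-open, end = last site + 1).

Default rates follow the published defaults of the standard
genotype-based ROH caller; they are exposed in :class:`RohModelParams`
and recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .genome_io import MISSING, GenotypeMatrix
from .windowing import ROHInterval

HW, AZ = 0, 1


@dataclass(frozen=True)
class RohModelParams:
    rate_into_az: float = 6.7e-8   # per bp, HW -> AZ
    rate_out_of_az: float = 5e-9   # per bp, AZ -> HW
    epsilon: float = 1e-3          # P(het | AZ)
    min_length: int = 0            # post-hoc filters, off by default
    min_sites: int = 0

    def __post_init__(self) -> None:
        if self.rate_into_az <= 0 or self.rate_out_of_az <= 0:
            raise ValueError("transition rates must be positive")
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must be in (0, 1)")

    def metadata(self) -> dict:
        return asdict(self)


def _emission_logs(het: np.ndarray, freqs: np.ndarray, eps: float):
    """Log emission probabilities (n_sites, 2 states)."""
    p_het_hw = np.clip(2.0 * freqs * (1.0 - freqs), 1e-12, 1 - 1e-12)
    log_e = np.empty((len(het), 2))
    log_e[:, HW] = np.where(het, np.log(p_het_hw), np.log1p(-p_het_hw))
    log_e[:, AZ] = np.where(het, np.log(eps), np.log1p(-eps))
    return log_e


def viterbi_path(
    het: np.ndarray, positions: np.ndarray, freqs: np.ndarray,
    params: RohModelParams,
) -> np.ndarray:
    """Most probable HW/AZ state sequence (uniform initial distribution)."""
    n = len(het)
    log_e = _emission_logs(het, freqs, params.epsilon)
    d = np.diff(positions).astype(float)
    p_hw_az = 1.0 - np.exp(-params.rate_into_az * d)
    p_az_hw = 1.0 - np.exp(-params.rate_out_of_az * d)
    with np.errstate(divide="ignore"):
        log_t = np.stack(
            [
                np.log1p(-p_hw_az), np.log(p_hw_az),
                np.log(p_az_hw), np.log1p(-p_az_hw),
            ],
            axis=1,
        ).reshape(-1, 2, 2)

    score = np.log(0.5) + log_e[0]
    back = np.zeros((n, 2), dtype=np.int8)
    for i in range(1, n):
        cand = score[:, None] + log_t[i - 1]  # cand[s_prev, s_cur]
        back[i] = np.argmax(cand, axis=0)
        score = cand[back[i], [0, 1]] + log_e[i]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(score))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def call_roh(
    dosages: np.ndarray,
    positions: np.ndarray,
    freqs: np.ndarray,
    params: RohModelParams | None = None,
    sample: str = "sample",
    chrom: str = "chr1",
) -> list[ROHInterval]:
    """Call ROHs for one sample on one chromosome.

    ``dosages`` are the sample's alt dosages at sorted ``positions``
    with cohort alt-allele ``freqs``. Missing genotypes are skipped —
    they neither support nor break a run.
    """
    params = params or RohModelParams()
    dosages = np.asarray(dosages)
    keep = dosages != MISSING
    if keep.sum() < 2:
        return []
    het = dosages[keep] == 1
    pos = np.asarray(positions)[keep]
    frq = np.clip(np.asarray(freqs, dtype=float)[keep], 1e-6, 1 - 1e-6)
    path = viterbi_path(het, pos, frq, params)

    rohs: list[ROHInterval] = []
    in_az = np.flatnonzero(path == AZ)
    if len(in_az) == 0:
        return rohs
    run_breaks = np.flatnonzero(np.diff(in_az) > 1)
    starts = np.r_[0, run_breaks + 1]
    ends = np.r_[run_breaks, len(in_az) - 1]
    for a, b in zip(starts, ends):
        first, last = in_az[a], in_az[b]
        iv = ROHInterval(
            sample=sample, chrom=chrom,
            start=int(pos[first]), end=int(pos[last]) + 1,
            n_sites=int(last - first + 1),
        )
        if iv.length >= params.min_length and iv.n_sites >= params.min_sites:
            rohs.append(iv)
    return rohs


def call_roh_all(
    matrix: GenotypeMatrix, params: RohModelParams | None = None
) -> list[ROHInterval]:
    """ROHs for every sample on every chromosome of a genotype matrix;
    allele frequencies come from the whole cohort."""
    from .popgen_stats import allele_counts

    params = params or RohModelParams()
    rohs: list[ROHInterval] = []
    for chrom in dict.fromkeys(matrix.chrom):
        mask = matrix.chrom == chrom
        pos = matrix.pos[mask]
        geno = matrix.genotypes[mask]
        n, alt = allele_counts(geno)
        with np.errstate(divide="ignore", invalid="ignore"):
            freqs = np.where(n > 0, alt / np.maximum(n, 1), 0.5)
        for j, sample in enumerate(matrix.samples):
            rohs.extend(
                call_roh(geno[:, j], pos, freqs, params, sample=sample, chrom=chrom)
            )
    return rohs


def classify_roh(rohs: list[ROHInterval], annotations) -> list[ROHInterval]:
    """Attach gene counts and class (same TSS rule as windows)."""
    from .windowing import classify

    return classify(rohs, annotations)


def roh_table(rohs: list[ROHInterval]) -> pd.DataFrame:
    rows = [
        {
            "sample": r.sample, "chrom": r.chrom, "start": r.start, "end": r.end,
            "length": r.length, "n_sites": r.n_sites,
            "gene_number": r.gene_number,
            "n_interact_gene_number": r.n_interact_gene_number,
            "window_class": r.window_class,
        }
        for r in rohs
    ]
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "start", "end", "length", "n_sites",
                 "gene_number", "n_interact_gene_number", "window_class"],
    )
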