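"""Fixed-width genomic windows and the three-way N_interact classification.

A window (or ROH) is classified by the transcription start sites (TSSs)
it contains, not by gene-body overlap:

* ``N_INTERACT``     — contains the TSS of >= 1 N_interact gene
* ``NON_N_INTERACT`` — contains >= 1 TSS, none of them N_interact
* ``NONGENIC``       — contains no TSS at all

NONGENIC intervals are excluded from the linear models downstream; they
participate only in the three-class Tajima's D comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import GeneAnnotation

N_INTERACT = "N_INTERACT"
NON_N_INTERACT = "NON_N_INTERACT"
NONGENIC = "NONGENIC"


@dataclass
class GenomicWindow:
    chrom: str
    start: int
    end: int
    is_partial: bool = False
    gene_number: int = 0
    n_interact_gene_number: int = 0
    window_class: str = NONGENIC
    stats: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def window_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class ROHInterval:
    sample: str
    chrom: str
    start: int
    end: int
    n_sites: int = 0
    gene_number: int = 0
    n_interact_gene_number: int = 0
    window_class: str = NONGENIC

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("ROH interval must have positive length")


def tile_windows(
    chromosome_lengths: dict[str, int], window_size: int
) -> list[GenomicWindow]:
    """Tile each chromosome into [0,w), [w,2w), ...; a trailing partial
    window is retained with its true length and flagged."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    windows = []
    for chrom, length in chromosome_lengths.items():
        for start in range(0, int(length), window_size):
            end = min(start + window_size, int(length))
            windows.append(
                GenomicWindow(
                    chrom=chrom, start=start, end=end,
                    is_partial=(end - start) != window_size,
                )
            )
    return windows


def _classify_one(iv, tss_by_chrom) -> None:
    pos, flags = tss_by_chrom.get(iv.chrom, (None, None))
    if pos is None:
        n_total = n_ni = 0
    else:
        lo = np.searchsorted(pos, iv.start, side="left")
        hi = np.searchsorted(pos, iv.end, side="left")
        n_total = int(hi - lo)
        n_ni = int(flags[lo:hi].sum())
    iv.gene_number = n_total
    iv.n_interact_gene_number = n_ni
    if n_ni >= 1:
        iv.window_class = N_INTERACT
    elif n_total >= 1:
        iv.window_class = NON_N_INTERACT
    else:
        iv.window_class = NONGENIC


def classify(intervals, annotations: list[GeneAnnotation]):
    """Attach gene_number / n_interact_gene_number / class to intervals.

    The TSS-in-interval test is half-open: a TSS equal to the interval
    end belongs to the next window. Duplicate gene ids are collapsed;
    distinct genes sharing a TSS all count.
    """
    seen: set[str] = set()
    by_chrom: dict[str, list[tuple[int, bool]]] = {}
    for g in annotations:
        if g.gene_id in seen:
            continue
        seen.add(g.gene_id)
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.n_interact))
    tss_by_chrom = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        tss_by_chrom[chrom] = (
            np.array([p for p, _ in pairs], dtype=np.int64),
            np.array([f for _, f in pairs], dtype=bool),
        )
    for iv in intervals:
        _classify_one(iv, tss_by_chrom)
    return intervals


def gene_bearing(intervals):
    """Intervals eligible for the linear models (>= 1 TSS)."""
    return [iv for iv in intervals if iv.gene_number >= 1]
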