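"""Patterson's D (ABBA-BABA) from population allele frequencies.

For a four-taxon tree (((P1,P2),P3),O) with per-site alt-allele
frequencies p1..p4, the frequency-based site patterns are

    ABBA_i = (1 - p1) * p2 * p3 * (1 - p4)
    BABA_i = p1 * (1 - p2) * p3 * (1 - p4)

and D = (sum ABBA - sum BABA) / (sum ABBA + sum BABA). Under
incomplete lineage sorting alone ABBA and BABA are equally frequent and
D ~ 0; gene flow between P3 and P2 (P1) pushes D positive (negative).
The genome-wide Z score comes from a delete-one block jackknife over
blocks of equal site count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import GenotypeMatrix
from .popgen_stats import allele_counts
from .selection_inference import ResamplingResult, permutation_test


@dataclass
class DStatResult:
    taxa: tuple[str, str, str, str]
    abba: float
    baba: float
    d: float              # NaN when ABBA + BABA = 0
    jackknife_se: float
    z: float
    n_sites: int
    n_blocks: int
    window_d: pd.DataFrame | None = None

    def to_row(self) -> dict:
        return {
            "p1": self.taxa[0], "p2": self.taxa[1], "p3": self.taxa[2],
            "outgroup": self.taxa[3], "abba": self.abba, "baba": self.baba,
            "d": self.d, "se": self.jackknife_se, "z": self.z,
            "n_sites": self.n_sites,
        }


def site_patterns(p1, p2, p3, p4) -> tuple[np.ndarray, np.ndarray]:
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba


def patterson_d(
    p1, p2, p3, p4,
    taxa: tuple[str, str, str, str] = ("P1", "P2", "P3", "O"),
    n_blocks: int = 100,
) -> DStatResult:
    """Genome-wide D from per-site frequencies with block-jackknife Z.

    Sites with any undefined frequency are skipped. Blocks hold equal
    numbers of consecutive sites; the jackknife variance is
    (m - 1)/m * sum((D_{-j} - mean)^2).
    """
    p = [np.asarray(x, dtype=float) for x in (p1, p2, p3, p4)]
    keep = np.isfinite(p[0]) & np.isfinite(p[1]) & np.isfinite(p[2]) & np.isfinite(p[3])
    p = [x[keep] for x in p]
    n = len(p[0])
    abba, baba = site_patterns(*p)
    a, b = float(abba.sum()), float(baba.sum())
    if a + b == 0:
        return DStatResult(taxa, a, b, math.nan, math.nan, math.nan, n, 0)
    d = (a - b) / (a + b)

    m = min(n_blocks, n)
    if m >= 2:
        bounds = np.linspace(0, n, m + 1).astype(int)
        d_del = []
        for j in range(m):
            sl = slice(bounds[j], bounds[j + 1])
            aj = a - abba[sl].sum()
            bj = b - baba[sl].sum()
            d_del.append((aj - bj) / (aj + bj) if (aj + bj) > 0 else d)
        d_del = np.array(d_del)
        var = (m - 1.0) / m * np.sum((d_del - d_del.mean()) ** 2)
        se = math.sqrt(var)
        z = d / se if se > 0 else math.nan
    else:
        se = z = math.nan
        m = 0
    return DStatResult(taxa, a, b, d, se, z, n, m)


def matrix_patterson_d(
    matrix: GenotypeMatrix,
    taxa: tuple[str, str, str, str],
    n_blocks: int = 100,
    windows=None,
) -> DStatResult:
    """D from a genotype matrix with groups named by ``taxa``; if
    ``windows`` is given, per-window D values are attached."""
    freqs = []
    for group in taxa:
        n, alt = allele_counts(matrix.group_dosages(group))
        with np.errstate(divide="ignore", invalid="ignore"):
            freqs.append(np.where(n > 0, alt / np.maximum(n, 1), np.nan))
    res = patterson_d(*freqs, taxa=taxa, n_blocks=n_blocks)
    if windows is not None:
        rows = []
        for w in windows:
            mask = (matrix.chrom == w.chrom) & (matrix.pos >= w.start) & (matrix.pos < w.end)
            if not mask.any():
                d = math.nan
            else:
                abba, baba = site_patterns(*(f[mask] for f in freqs))
                a, b = np.nansum(abba), np.nansum(baba)
                d = (a - b) / (a + b) if (a + b) > 0 else math.nan
            w.stats["d_stat"] = d
            rows.append(
                {"chrom": w.chrom, "start": w.start, "end": w.end,
                 "window_class": w.window_class, "d": d}
            )
        res.window_d = pd.DataFrame(rows)
    return res


def windowed_d_comparison(
    windows,
    n_permutations: int = 1000,
    seed: int | None = None,
    min_windows: int = 5,
) -> ResamplingResult:
    """Upper-tail permutation test of mean window D, N_interact vs
    non-N_interact windows. Windows with undefined D are dropped
    (count logged); nongenic windows are not compared."""
    import logging

    values, labels = [], []
    n_dropped = 0
    for w in windows:
        if w.window_class == "NONGENIC":
            continue
        d = w.stats.get("d_stat", math.nan)
        if not math.isfinite(d):
            n_dropped += 1
            continue
        values.append(d)
        labels.append(w.window_class == "N_INTERACT")
    if n_dropped:
        logging.getLogger("mitoscan").info(
            "windowed_d_comparison: dropped %d windows with undefined D", n_dropped
        )
    labels = np.array(labels)
    if labels.sum() < min_windows or (~labels).sum() < min_windows:
        raise ValueError(
            f"need >= {min_windows} windows with defined D in each class"
        )
    return permutation_test(
        np.array(values), labels, tail="upper",
        n_permutations=n_permutations, seed=seed, statistic="d_stat",
    )
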