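"""Per-site and per-window nucleotide diversity, F_ST and Tajima's D.

All functions take alt-allele dosage arrays (sites x samples, values
0/1/2, -1 missing) as produced by :mod:`mitoscan.genome_io`. Window
values are arithmetic means of per-site values — F_ST in particular is
the average of per-site estimates, not a ratio of sums.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .genome_io import MISSING, GenotypeMatrix, PipelineConfig

WEIR_COCKERHAM = "weir-cockerham"
HUDSON = "hudson"


# ---------------------------------------------------------------------------
# per-site building blocks
# ---------------------------------------------------------------------------

def allele_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Called-allele count and alt-allele count per site.

    ``dosages`` is (n_sites, n_samples) or (n_samples,).
    """
    d = np.atleast_2d(np.asarray(dosages))
    called = d != MISSING
    n = 2 * called.sum(axis=1)
    alt = np.where(called, d, 0).sum(axis=1)
    return n.astype(np.int64), alt.astype(np.int64)


def site_pi(dosages: np.ndarray) -> np.ndarray:
    """Per-site pairwise diversity 2*n_ref*n_alt / (n*(n-1)).

    The average proportion of differences over all pairs of called
    alleles at the site; NaN where fewer than 2 alleles are called.
    """
    n, alt = allele_counts(dosages)
    ref = n - alt
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * ref * alt / (n * (n - 1.0))
    return np.where(n >= 2, pi, np.nan)


def heterozygote_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n called genotypes, n heterozygotes) per site."""
    d = np.atleast_2d(np.asarray(dosages))
    called = d != MISSING
    return called.sum(axis=1).astype(np.int64), (d == 1).sum(axis=1).astype(np.int64)


def site_fst(
    dosages1: np.ndarray,
    dosages2: np.ndarray,
    estimator: str = WEIR_COCKERHAM,
) -> np.ndarray:
    """Per-site two-population F_ST.

    ``weir-cockerham`` is the Weir & Cockerham (1984) variance-components
    estimator theta-hat = a / (a + b + c) computed from sample sizes,
    allele frequencies and observed heterozygosity; negative values are
    retained. ``hudson`` is 1 - Hw/Hb with Hw the mean expected
    heterozygosity of the two groups and Hb the between-group expected
    heterozygosity, which is exactly 0 for identical frequencies.

    Sites where either group has no called genotype are NaN. MAF
    filtering is applied by :func:`window_fst`, not here.
    """
    if estimator == WEIR_COCKERHAM:
        return _wc_fst(dosages1, dosages2)
    if estimator == HUDSON:
        return _hudson_fst(dosages1, dosages2)
    raise ValueError(f"unknown F_ST estimator {estimator!r}")


def _freqs(dosages):
    n_alleles, alt = allele_counts(dosages)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / n_alleles
    return n_alleles, p


def _wc_fst(d1, d2):
    # Weir & Cockerham 1984, r = 2 populations, per-individual formulation
    n1, h1 = heterozygote_counts(d1)
    n2, h2 = heterozygote_counts(d2)
    _, p1 = _freqs(d1)
    _, p2 = _freqs(d2)
    n1 = n1.astype(float)
    n2 = n2.astype(float)
    valid = (n1 > 0) & (n2 > 0) & (n1 + n2 > 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = (n1 + n2) / 2.0
        nc = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (h1 + h2) / (n1 + n2)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 / 2.0 - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
        theta = a / (a + b + c)
    theta = np.where(valid & np.isfinite(theta), theta, np.nan)
    return theta


def _hudson_fst(d1, d2):
    _, p1 = _freqs(d1)
    _, p2 = _freqs(d2)
    hw = 0.5 * (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2))
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = 1.0 - hw / hb
    return np.where(np.isfinite(fst), fst, np.nan)


def pooled_maf(d1, d2) -> np.ndarray:
    n1, a1 = allele_counts(d1)
    n2, a2 = allele_counts(d2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (a1 + a2) / (n1 + n2)
    return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalising constants for n sequences."""
    if n < 2:
        raise ValueError("Tajima's D needs >= 2 sequences")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d_from_summaries(s: int, k_hat: float, n: int) -> float:
    """D = (k_hat - S/a1) / sqrt(e1*S + e2*S*(S-1)) for S segregating
    sites, mean pairwise differences k_hat, and n sequences."""
    if s < 1 or n < 2:
        return math.nan
    c = tajima_constants(n)
    var = c["e1"] * s + c["e2"] * s * (s - 1.0)
    if var <= 0:
        return math.nan
    return (k_hat - s / c["a1"]) / math.sqrt(var)


def window_tajima_d(dosages: np.ndarray) -> float:
    """Tajima's D for one window of dosages (sites x samples).

    With missing data the per-site allele count varies; the constants
    use the window-median per-site called-allele count, a fixed rule
    that keeps D well-defined.
    """
    n_alleles, alt = allele_counts(dosages)
    usable = n_alleles >= 2
    if not usable.any():
        return math.nan
    n_alleles = n_alleles[usable]
    alt = alt[usable]
    seg = (alt > 0) & (alt < n_alleles)
    s = int(seg.sum())
    if s < 1:
        return math.nan
    ref = n_alleles - alt
    k_hat = float(np.sum(2.0 * ref * alt / (n_alleles * (n_alleles - 1.0))))
    n = int(np.median(n_alleles))
    return tajima_d_from_summaries(s, k_hat, n)


# ---------------------------------------------------------------------------
# window aggregation
# ---------------------------------------------------------------------------

def window_pi(dosages: np.ndarray) -> float:
    """Mean site diversity over sites polymorphic within the group;
    NaN if the window has no polymorphic site."""
    n, alt = allele_counts(dosages)
    poly = (n >= 2) & (alt > 0) & (alt < n)
    if not poly.any():
        return math.nan
    pi = 2.0 * (n[poly] - alt[poly]) * alt[poly] / (n[poly] * (n[poly] - 1.0))
    return float(pi.mean())


def window_fst(
    dosages1: np.ndarray,
    dosages2: np.ndarray,
    maf_cutoff: float = 0.05,
    estimator: str = WEIR_COCKERHAM,
) -> float:
    """Mean per-site F_ST over sites with pooled MAF >= cutoff."""
    per_site = site_fst(dosages1, dosages2, estimator)
    keep = np.isfinite(per_site) & (pooled_maf(dosages1, dosages2) >= maf_cutoff)
    if not keep.any():
        return math.nan
    return float(per_site[keep].mean())


def _window_site_slices(matrix: GenotypeMatrix, windows):
    """Index ranges of sites per window (windows and sites sorted)."""
    slices = []
    for w in windows:
        on_chrom = matrix.chrom == w.chrom
        pos = matrix.pos[on_chrom]
        base = np.flatnonzero(on_chrom)
        lo = np.searchsorted(pos, w.start, side="left")
        hi = np.searchsorted(pos, w.end, side="left")
        slices.append(base[lo:hi])
    return slices


def compute_window_stats(
    matrix: GenotypeMatrix,
    windows,
    groups: list[str] | None = None,
    pairs: list[tuple[str, str]] | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Fill window.stats with pi/Tajima's D per group and F_ST per pair,
    and return the long-format window table."""
    config = config or PipelineConfig()
    groups = groups if groups is not None else sorted(set(matrix.groups.values()))
    if pairs is None:
        pairs = [
            (g1, g2) for i, g1 in enumerate(groups) for g2 in groups[i + 1:]
        ]
    group_dosages = {g: matrix.group_dosages(g) for g in groups}
    slices = _window_site_slices(matrix, windows)

    rows = []
    for w, idx in zip(windows, slices):
        w.stats["n_sites"] = len(idx)
        for g in groups:
            d = group_dosages[g][idx]
            w.stats[f"pi[{g}]"] = window_pi(d)
            w.stats[f"tajima_d[{g}]"] = window_tajima_d(d)
        for g1, g2 in pairs:
            w.stats[f"fst[{g1}:{g2}]"] = window_fst(
                group_dosages[g1][idx],
                group_dosages[g2][idx],
                maf_cutoff=config.maf_cutoff,
                estimator=config.fst_estimator,
            )
        row = {
            "chrom": w.chrom, "start": w.start, "end": w.end,
            "gene_number": w.gene_number,
            "n_interact_gene_number": w.n_interact_gene_number,
            "window_class": w.window_class,
        }
        row.update(w.stats)
        rows.append(row)
    return pd.DataFrame(rows)
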