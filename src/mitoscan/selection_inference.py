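"""Statistical core of the scan.

The central question — do intervals that carry N_interact genes show
stronger signatures of selection than intervals carrying only other
genes? — is asked four ways:

1. an OLS interaction model ``response ~ N_interact + gene_number +
   N_interact:gene_number`` with standard errors from a block bootstrap
   that respects local genomic autocorrelation
   (:class:`InteractionModel` / :class:`InteractionResults`);
2. one-sided permutation tests on the difference of class means
   (:func:`permutation_test`);
3. an outlier-excess test: Cook's-distance outliers of a
   statistic-on-gene-number regression, tested for N_interact
   enrichment with an exact binomial (:func:`cooks_outlier_excess`);
4. Fisher's method to combine p-values across comparisons
   (:func:`fisher_combine`).

Responses: natural log of ROH length in units of 100 kb for ROHs;
raw (untransformed) F_ST or pi for genomic windows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger("mitoscan")

ROH_LENGTH_UNIT = 1e5  # ROH length response is ln(length / 100 kb)

PARAM_NAMES = ["const", "n_interact", "gene_number", "n_interact:gene_number"]


def intervals_frame(intervals, response: str) -> pd.DataFrame:
    """Model frame from classified intervals.

    ``response`` is ``"log_roh_length"`` (uses interval.length) or the
    name of a window statistic stored in ``interval.stats``. NONGENIC
    intervals are excluded; so are intervals with undefined response.
    """
    rows = []
    for iv in intervals:
        if iv.gene_number < 1:
            continue
        if response == "log_roh_length":
            y = math.log(iv.length / ROH_LENGTH_UNIT)
        else:
            y = iv.stats.get(response, math.nan)
        if not math.isfinite(y):
            continue
        rows.append(
            {
                "chrom": iv.chrom, "start": iv.start,
                "response": y,
                "n_interact": int(iv.window_class == "N_INTERACT"),
                "gene_number": iv.gene_number,
            }
        )
    frame = pd.DataFrame(rows, columns=["chrom", "start", "response",
                                        "n_interact", "gene_number"])
    return frame.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _design(frame: pd.DataFrame) -> np.ndarray:
    n = frame["n_interact"].to_numpy(float)
    g = frame["gene_number"].to_numpy(float)
    return np.column_stack([np.ones(len(frame)), n, g, n * g])


def _ols(x: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    return beta, rank


class InteractionModel:
    """OLS interaction model of a selection statistic on N_interact status.

    Parameters
    ----------
    frame : DataFrame with columns ``response``, ``n_interact`` (0/1),
        ``gene_number`` and, for block bootstrapping, ``chrom`` and
        ``start`` in genome order.
    label : name of the response for reporting.
    """

    def __init__(self, frame: pd.DataFrame, label: str = "response"):
        if len(frame) == 0:
            raise ValueError("empty model frame")
        classes = frame["n_interact"].nunique()
        if classes < 2:
            raise ValueError(
                "both N_interact classes must be present to fit the model"
            )
        counts = frame["n_interact"].value_counts()
        if counts.min() < 10:
            log.warning(
                "interaction model: smallest class has only %d observations",
                counts.min(),
            )
        self.frame = frame.reset_index(drop=True)
        self.label = label
        self.exog = _design(self.frame)
        self.endog = self.frame["response"].to_numpy(float)
        if np.linalg.matrix_rank(self.exog) < self.exog.shape[1]:
            raise ValueError("design matrix is rank deficient; fit refused")

    @classmethod
    def from_intervals(cls, intervals, response: str) -> "InteractionModel":
        return cls(intervals_frame(intervals, response), label=response)

    def fit(
        self,
        cov_type: str = "analytic",
        block_size: int = 30,
        n_boot: int = 1000,
        seed: int | None = None,
    ) -> "InteractionResults":
        """Fit by OLS.

        ``cov_type="analytic"`` uses the classical OLS covariance;
        ``cov_type="block-bootstrap"`` resamples contiguous blocks of
        ``block_size`` intervals (within chromosome) with replacement,
        refits each replicate, and reports the replicate standard
        deviation of each coefficient; p-values are then two-sided
        normal, p = 2 * (1 - Phi(|beta| / SE)).
        """
        import statsmodels.api as sm

        sm_fit = sm.OLS(self.endog, self.exog).fit()
        params = pd.Series(sm_fit.params, index=PARAM_NAMES)
        if cov_type == "analytic":
            bse = pd.Series(sm_fit.bse, index=PARAM_NAMES)
            pvalues = pd.Series(sm_fit.pvalues, index=PARAM_NAMES)
            boot_params = None
        elif cov_type == "block-bootstrap":
            boot_params, n_redrawn = _bootstrap_params(
                self.frame, block_size=block_size, n_boot=n_boot, seed=seed
            )
            se = boot_params.std(axis=0, ddof=1)
            bse = pd.Series(se, index=PARAM_NAMES)
            # SE at floating-point noise level means a degenerate
            # (e.g. constant) response: p is undefined, reported NA
            defined = se > 1e-10
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.abs(params.to_numpy()) / se
            pvalues = pd.Series(
                np.where(defined, 2.0 * sps.norm.sf(z), np.nan), index=PARAM_NAMES
            )
            if n_redrawn:
                log.info("block bootstrap: %d degenerate replicates redrawn", n_redrawn)
        else:
            raise ValueError(f"unknown cov_type {cov_type!r}")
        return InteractionResults(
            model=self, params=params, bse=bse, pvalues=pvalues,
            cov_type=cov_type, boot_params=boot_params,
            nobs=len(self.frame), rsquared=float(sm_fit.rsquared),
        )


def _block_resample_index(n: int, block_size: int, rng: np.random.Generator):
    """Moving-blocks index resample of length n."""
    if n <= block_size:
        return rng.integers(0, n, size=n)
    idx = []
    n_blocks = math.ceil(n / block_size)
    starts = rng.integers(0, n - block_size + 1, size=n_blocks)
    for s in starts:
        idx.append(np.arange(s, s + block_size))
    return np.concatenate(idx)[:n]


def _bootstrap_params(frame, block_size, n_boot, seed):
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    x = _design(frame)
    y = frame["response"].to_numpy(float)
    chrom_index = [
        np.flatnonzero((frame["chrom"] == c).to_numpy())
        for c in frame["chrom"].unique()
    ]
    out = np.empty((n_boot, x.shape[1]))
    n_redrawn = 0
    b = 0
    while b < n_boot:
        take = np.concatenate(
            [ci[_block_resample_index(len(ci), block_size, rng)] for ci in chrom_index]
        )
        beta, rank = _ols(x[take], y[take])
        if rank < x.shape[1]:
            n_redrawn += 1
            if n_redrawn > 10 * n_boot:
                raise RuntimeError("bootstrap: too many rank-deficient replicates")
            continue
        out[b] = beta
        b += 1
    return out, n_redrawn


@dataclass
class InteractionResults:
    """Estimates, uncertainties and diagnostics of an interaction fit."""

    model: InteractionModel
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_type: str
    nobs: int
    rsquared: float
    boot_params: np.ndarray | None = None

    def class_gap(self, gene_number: float) -> float:
        """Fitted N_interact minus non-N_interact response at a gene
        count: beta1 + beta3 * gene_number."""
        return float(
            self.params["n_interact"]
            + self.params["n_interact:gene_number"] * gene_number
        )

    def class_gap_test(self, gene_number: float) -> tuple[float, float, float]:
        """(gap, SE, two-sided p) for beta1 + beta3 * gene_number.

        Uses the bootstrap replicate distribution of the linear
        combination when available, else the analytic covariance.
        """
        gap = self.class_gap(gene_number)
        if self.boot_params is not None:
            reps = self.boot_params[:, 1] + self.boot_params[:, 3] * gene_number
            se = float(reps.std(ddof=1))
        else:
            import statsmodels.api as sm

            res = sm.OLS(self.model.endog, self.model.exog).fit()
            c = np.array([0.0, 1.0, 0.0, gene_number])
            se = float(np.sqrt(c @ res.cov_params() @ c))
        if se <= 1e-10:
            return gap, se, math.nan
        return gap, se, float(2.0 * sps.norm.sf(abs(gap) / se))

    def marginal_means(
        self, percentile_range: tuple[float, float] = (1.0, 90.0)
    ) -> pd.DataFrame:
        """Estimated marginal means over the integer gene-number grid
        spanning the given percentiles of the observed distribution,
        for both classes, with 95% intervals.

        Intervals come from the bootstrap replicate predictions
        (2.5/97.5 percentiles) when the fit used the block bootstrap,
        else from the analytic prediction variance.
        """
        g = self.model.frame["gene_number"].to_numpy()
        lo = int(math.floor(np.percentile(g, percentile_range[0])))
        hi = int(math.ceil(np.percentile(g, percentile_range[1])))
        grid = np.arange(max(lo, 1), hi + 1)
        rows = []
        for n_flag, cls in ((1, "N_INTERACT"), (0, "NON_N_INTERACT")):
            x = np.column_stack(
                [np.ones_like(grid, dtype=float),
                 np.full(len(grid), float(n_flag)),
                 grid.astype(float),
                 n_flag * grid.astype(float)]
            )
            pred = x @ self.params.to_numpy()
            if self.boot_params is not None:
                reps = self.boot_params @ x.T  # (n_boot, n_grid)
                ci_lo = np.percentile(reps, 2.5, axis=0)
                ci_hi = np.percentile(reps, 97.5, axis=0)
            else:
                import statsmodels.api as sm

                res = sm.OLS(self.model.endog, self.model.exog).fit()
                pr = res.get_prediction(x)
                ci = pr.conf_int(alpha=0.05)
                ci_lo, ci_hi = ci[:, 0], ci[:, 1]
            for gi, p, l, h in zip(grid, pred, ci_lo, ci_hi):
                rows.append(
                    {"window_class": cls, "gene_number": int(gi),
                     "predicted": p, "ci_low": l, "ci_high": h}
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Interaction model: {self.model.label}",
            f"  n obs: {self.nobs}   R^2: {self.rsquared:.4f}   cov: {self.cov_type}",
            f"  {'term':<24}{'coef':>12}{'SE':>12}{'p':>12}",
        ]
        for name in PARAM_NAMES:
            p = self.pvalues[name]
            lines.append(
                f"  {name:<24}{self.params[name]:>12.5g}{self.bse[name]:>12.5g}"
                f"{p if math.isfinite(p) else float('nan'):>12.4g}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": PARAM_NAMES,
             "coef": self.params.to_numpy(),
             "se": self.bse.to_numpy(),
             "p": self.pvalues.to_numpy(),
             "response": self.model.label,
             "cov_type": self.cov_type,
             "nobs": self.nobs}
        )


def fit_interaction_model(
    intervals, response: str, **fit_kwargs
) -> InteractionResults:
    """Convenience wrapper: build the model frame from classified
    intervals and fit it."""
    return InteractionModel.from_intervals(intervals, response).fit(**fit_kwargs)


def block_bootstrap_se(
    frame: pd.DataFrame,
    block_size: int = 30,
    n_boot: int = 1000,
    seed: int | None = None,
) -> InteractionResults:
    """Fit the interaction model with block-bootstrap standard errors."""
    return InteractionModel(frame).fit(
        cov_type="block-bootstrap", block_size=block_size, n_boot=n_boot, seed=seed
    )


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

@dataclass
class ResamplingResult:
    """One-sided permutation (or resampling) test result."""

    statistic: str
    observed: float
    tail: str
    n_replicates: int
    p_value: float
    seed: int | None = None
    null_mean: float = math.nan
    null_sd: float = math.nan

    def to_row(self) -> dict:
        return {
            "statistic": self.statistic, "observed": self.observed,
            "tail": self.tail, "B": self.n_replicates, "p": self.p_value,
            "null_mean": self.null_mean, "null_sd": self.null_sd,
        }


def permutation_test(
    values,
    labels,
    tail: str = "upper",
    n_permutations: int = 1000,
    seed: int | None = None,
    statistic: str = "mean_difference",
) -> ResamplingResult:
    """One-sided permutation test on the difference of group means.

    ``labels`` is boolean (True = N_interact). The observed difference
    mean(values[True]) - mean(values[False]) is compared with the
    distribution obtained by shuffling labels; the p-value uses the
    add-one convention p = (#{null >= obs} + 1) / (B + 1) for the upper
    tail (<= for the lower), so p is never 0.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    n1 = int(labels.sum())
    if n1 == 0 or n1 == len(labels):
        raise ValueError("both label classes must be present")
    rng = np.random.default_rng(seed)
    total = values.sum()
    n0 = len(values) - n1
    # same arithmetic path as the null replicates, so a constant input
    # yields identical floating-point values and p = 1 exactly
    s_obs = values[labels].sum()
    observed = s_obs / n1 - (total - s_obs) / n0
    null = np.empty(n_permutations)
    # mean difference from the permuted in-group sum; one shuffle per rep
    for b in range(n_permutations):
        take = rng.choice(len(values), size=n1, replace=False)
        s1 = values[take].sum()
        null[b] = s1 / n1 - (total - s1) / n0
    if tail == "upper":
        p = (np.sum(null >= observed) + 1.0) / (n_permutations + 1.0)
    else:
        p = (np.sum(null <= observed) + 1.0) / (n_permutations + 1.0)
    return ResamplingResult(
        statistic=statistic, observed=float(observed), tail=tail,
        n_replicates=n_permutations, p_value=float(p), seed=seed,
        null_mean=float(null.mean()), null_sd=float(null.std(ddof=1)) if n_permutations > 1 else math.nan,
    )


# ---------------------------------------------------------------------------
# Cook's-distance outlier excess
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    """Excess of directional regression outliers among N_interact windows."""

    statistic: str
    direction: str  # "upper" (F_ST) or "lower" (pi)
    outlier_ids: list[str]
    n_outliers: int
    n_outliers_n_interact: int
    n_windows: int
    n_windows_n_interact: int
    p_value: float
    cooks_threshold: float

    @property
    def baseline_proportion(self) -> float:
        return self.n_windows_n_interact / self.n_windows


def binomial_excess_p(n_outliers: int, k_n_interact: int, p0: float) -> float:
    """One-sided P(X >= k) with X ~ Binomial(n_outliers, p0)."""
    if n_outliers == 0:
        return 1.0
    return float(sps.binom.sf(k_n_interact - 1, n_outliers, p0))


def cooks_outlier_excess(
    windows,
    statistic: str,
    direction: str,
    threshold_factor: float = 4.0,
) -> OutlierReport:
    """Directional Cook's-distance outliers of statistic ~ gene_number,
    tested for N_interact enrichment.

    The regression is fitted on ALL gene-bearing windows; window i is an
    outlier when its Cook's distance exceeds ``threshold_factor / n``
    AND its residual sign matches the direction of interest (positive
    for upper outliers, negative for lower). The excess test is an
    exact binomial on the number of outliers that are N_interact
    windows, with baseline probability the overall N_interact share.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import OLSInfluence

    if direction not in ("upper", "lower"):
        raise ValueError("direction must be 'upper' or 'lower'")
    usable = [
        w for w in windows
        if w.gene_number >= 1 and math.isfinite(w.stats.get(statistic, math.nan))
    ]
    if len(usable) < 3:
        raise ValueError("too few gene-bearing windows with a defined statistic")
    y = np.array([w.stats[statistic] for w in usable])
    g = np.array([w.gene_number for w in usable], dtype=float)
    x = sm.add_constant(g)
    fit = sm.OLS(y, x).fit()
    cooks = OLSInfluence(fit).cooks_distance[0]
    resid = fit.resid
    n = len(usable)
    threshold = threshold_factor / n
    if direction == "upper":
        is_outlier = (cooks > threshold) & (resid > 0)
    else:
        is_outlier = (cooks > threshold) & (resid < 0)
    flags = np.array([w.window_class == "N_INTERACT" for w in usable])
    n_out = int(is_outlier.sum())
    k = int((is_outlier & flags).sum())
    p0 = flags.mean()
    p = binomial_excess_p(n_out, k, p0)
    return OutlierReport(
        statistic=statistic, direction=direction,
        outlier_ids=[w.window_id for w, o in zip(usable, is_outlier) if o],
        n_outliers=n_out, n_outliers_n_interact=k,
        n_windows=n, n_windows_n_interact=int(flags.sum()),
        p_value=p, cooks_threshold=threshold,
    )


# ---------------------------------------------------------------------------
# combining and comparisons
# ---------------------------------------------------------------------------

def fisher_combine(p_values, clamp: float | None = None) -> tuple[float, int, float]:
    """Fisher's method: X2 = -2 * sum(ln p) ~ chi2 with df = 2k.

    Returns (X2, df, combined p). p = 0 inputs are clamped to ``clamp``
    (default 1/1001, the smallest add-one permutation p at B = 1000)
    with a warning — the permutation convention cannot produce 0.
    """
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        raise ValueError("no p-values to combine")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        clamp = clamp if clamp is not None else 1.0 / 1001.0
        log.warning("fisher_combine: clamping %d zero p-values to %g",
                    int((p == 0).sum()), clamp)
        p = np.maximum(p, clamp)
    x2 = float(-2.0 * np.sum(np.log(p)))
    df = 2 * len(p)
    return x2, df, float(sps.chi2.sf(x2, df))


def tajima_class_comparison(
    windows,
    group: str,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> dict:
    """Lower-tail permutation comparison of mean Tajima's D between
    N_interact and non-N_interact windows, with the nongenic
    distribution reported descriptively."""
    key = f"tajima_d[{group}]"
    vals = {"N_INTERACT": [], "NON_N_INTERACT": [], "NONGENIC": []}
    for w in windows:
        v = w.stats.get(key, math.nan)
        if math.isfinite(v):
            vals[w.window_class].append(v)
    out = {
        "group": group,
        "mean_n_interact": float(np.mean(vals["N_INTERACT"])) if vals["N_INTERACT"] else math.nan,
        "mean_non_n_interact": float(np.mean(vals["NON_N_INTERACT"])) if vals["NON_N_INTERACT"] else math.nan,
        "mean_nongenic": float(np.mean(vals["NONGENIC"])) if vals["NONGENIC"] else math.nan,
        "n_nongenic": len(vals["NONGENIC"]),
    }
    if vals["N_INTERACT"] and vals["NON_N_INTERACT"]:
        values = np.array(vals["N_INTERACT"] + vals["NON_N_INTERACT"])
        labels = np.array(
            [True] * len(vals["N_INTERACT"]) + [False] * len(vals["NON_N_INTERACT"])
        )
        res = permutation_test(
            values, labels, tail="lower", n_permutations=n_permutations,
            seed=seed, statistic=f"tajima_d[{group}]",
        )
        out["observed_difference"] = res.observed
        out["p"] = res.p_value
    else:
        out["observed_difference"] = math.nan
        out["p"] = math.nan
    return out


def cross_metric_overlap(reports: list[OutlierReport], rohs, windows) -> pd.DataFrame:
    """Per-window congruence table across outlier comparisons, with a
    flag for residence inside any same-class ROH."""
    by_id = {w.window_id: w for w in windows}
    frame_rows = {}
    for wid, w in by_id.items():
        frame_rows[wid] = {
            "window_id": wid, "chrom": w.chrom, "start": w.start, "end": w.end,
            "window_class": w.window_class, "n_comparisons_outlier": 0,
            "in_roh": False,
        }
    for rep in reports:
        col = f"outlier[{rep.statistic}:{rep.direction}]"
        for row in frame_rows.values():
            row[col] = False
        for wid in rep.outlier_ids:
            if wid in frame_rows:
                frame_rows[wid][col] = True
                frame_rows[wid]["n_comparisons_outlier"] += 1
    for roh in rohs:
        for row in frame_rows.values():
            if (
                row["chrom"] == roh.chrom
                and row["start"] < roh.end
                and roh.start < row["end"]
                and row["window_class"] == roh.window_class
            ):
                row["in_roh"] = True
    return pd.DataFrame(list(frame_rows.values()))
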