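"""Cross-modal statistics: per-bin group comparisons, pre/post and laterality
t-tests, and Spearman rank correlations between modalities.

Conventions: all tests two-sided; the ROI (not the mouse) is the statistical
unit for imaging comparisons; per-bin p-values are uncorrected by default with
Holm adjustment available by flag.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from calmdx.errors import ValidationError

logger = logging.getLogger(__name__)

EXACT_MW_MAX_PRODUCT = 400  # exact U distribution when n1*n2 <= this and no ties
EXACT_SPEARMAN_MAX_N = 10   # exact permutation p for Spearman when n <= this


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    test: str  # mann_whitney | t_unpaired | t_paired
    bin_min: float | None = None
    zero_variance: bool = False
    low_n: bool = False


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n_pairs: int
    x_kind: str = ""
    y_kind: str = ""
    undefined: bool = False


def mann_whitney(sample_a, sample_b) -> TestResult:
    """Two-sided Mann-Whitney U test (U statistic of the first sample).

    Exact null distribution when n1*n2 <= 400 and the pooled data are
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size * b.size <= EXACT_MW_MAX_PRODUCT and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      n1=int(a.size), n2=int(b.size), test="mann_whitney",
                      low_n=min(a.size, b.size) < 3)


def t_tests(pre, post, paired: bool = False, welch: bool = False) -> TestResult:
    """Two-sided Student's t-test; paired works on the differences.

    A degenerate comparison (zero variance of the differences, or zero pooled
    variance) is reported as p = 1 with the zero_variance flag instead of a
    division-by-zero failure.
    """
    x = np.asarray(pre, dtype=float)
    y = np.asarray(post, dtype=float)
    if paired and x.size != y.size:
        raise ValidationError("paired test requires equal-length samples")
    if x.size < 2 or y.size < 2:
        raise ValidationError("need at least 2 observations per sample")
    name = "t_paired" if paired else "t_unpaired"
    if paired:
        d = y - x
        if np.allclose(d.std(ddof=1), 0):
            return TestResult(0.0, 1.0, x.size, y.size, name, zero_variance=True)
        res = sps.ttest_rel(y, x)
    else:
        if np.allclose(x.std(ddof=1), 0) and np.allclose(y.std(ddof=1), 0):
            return TestResult(0.0, 1.0, x.size, y.size, name, zero_variance=True)
        res = sps.ttest_ind(y, x, equal_var=not welch)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      n1=int(x.size), n2=int(y.size), test=name)


def per_bin_group_comparison(
    pooled: pd.DataFrame,
    test: str = "mann_whitney",
    groups: tuple[str, str] = ("formalin", "pbs"),
    holm: bool = False,
) -> pd.DataFrame:
    """One two-sample test per time bin, group A ROIs vs group B ROIs.

    `pooled` is the long table from pool_roi_bins.  Returns a table of
    per-bin results; a bin missing a group is skipped with a warning.
    Uncorrected p by default; with holm=True a p_holm column is added.
    """
    if test not in ("mann_whitney", "t_unpaired"):
        raise ValidationError(f"unsupported test {test!r}")
    present = set(pooled["group"].unique())
    if not set(groups) <= present:
        raise ValidationError(f"groups {groups} not both present in table ({present})")
    rows = []
    for bin_start, chunk in pooled.groupby("bin_start_min", sort=True):
        a = chunk.loc[chunk["group"] == groups[0], "value"].dropna().to_numpy()
        b = chunk.loc[chunk["group"] == groups[1], "value"].dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            # gap bins (inside the removed artifact) or a missing group
            warnings.warn(f"bin {bin_start} min lacks one group; skipped", stacklevel=2)
            continue
        r = mann_whitney(a, b) if test == "mann_whitney" else t_tests(b, a)
        r.bin_min = float(bin_start)
        rows.append({"bin_start_min": float(bin_start), "test": r.test,
                     "statistic": r.statistic, "p": r.p_value,
                     "n1": r.n1, "n2": r.n2, "low_n": r.low_n})
    out = pd.DataFrame(rows)
    if holm and not out.empty:
        logger.info("Holm adjustment requested; per-bin p-values are otherwise uncorrected")
        out["p_holm"] = _holm(out["p"].to_numpy())
    return out


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def _rankdata_avg(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    return float(xc @ yc / denom)


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p over all orderings of one rank vector."""
    n = xr.size
    xc = xr - xr.mean()
    xnorm = math.sqrt(float(xc @ xc))
    total = math.factorial(n)
    count = 0
    chunk = 40320
    it = itertools.permutations(yr)
    while True:
        block = np.array(list(itertools.islice(it, chunk)))
        if block.size == 0:
            break
        yc = block - block.mean(axis=1, keepdims=True)
        ynorm = np.sqrt(np.einsum("ij,ij->i", yc, yc))
        rhos = (yc @ xc) / (ynorm * xnorm)
        count += int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12))
    return count / total


def spearman(x_bins, y_bins) -> CorrelationResult:
    """Spearman's rho with averaged ranks on ties.

    p-value: exact permutation enumeration for n <= 10, otherwise the
    t-distribution approximation t = rho * sqrt((n-2)/(1-rho^2)).  NaN pairs
    are dropped.  Zero variance in either series yields the
    undefined-correlation flag (rho NaN, p NaN).
    """
    x = np.asarray(getattr(x_bins, "values", x_bins), dtype=float)
    y = np.asarray(getattr(y_bins, "values", y_bins), dtype=float)
    if x.size != y.size:
        raise ValidationError("series must have the same number of bins")
    good = np.isfinite(x) & np.isfinite(y)
    x, y = x[good], y[good]
    n = x.size
    if n < 3:
        raise ValidationError(f"need >= 3 paired bins, got {n}")
    x_kind = getattr(x_bins, "kind", "")
    y_kind = getattr(y_bins, "kind", "")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(rho=float("nan"), p_value=float("nan"), n_pairs=n,
                                 x_kind=x_kind, y_kind=y_kind, undefined=True)
    xr, yr = _rankdata_avg(x), _rankdata_avg(y)
    rho = _pearson(xr, yr)
    if n <= EXACT_SPEARMAN_MAX_N:
        p = _exact_spearman_p(xr, yr, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho * rho))
            p = 2 * sps.t.sf(abs(t), df=n - 2)
    return CorrelationResult(rho=rho, p_value=float(p), n_pairs=n,
                             x_kind=x_kind, y_kind=y_kind)


def correlate_modalities(
    peak_rasters: list,
    other_series: list,
    bin_width_min: float,
) -> CorrelationResult:
    """Correlate per-bin peak counts with another modality across sessions.

    For each session, peak times are summed across ROIs (excluding the
    whole-frame pseudo-ROI "w") and counted per bin of the paired series'
    grid; (count, value) bin pairs are concatenated across the sessions of a
    group and passed to :func:`spearman`.  15-min bins pair with serotonin,
    5-min bins with licking.
    """
    if len(peak_rasters) != len(other_series):
        raise ValidationError("one paired series per peak raster required")
    counts_all, other_all = [], []
    for raster, series in zip(peak_rasters, other_series):
        edges = np.asarray(series.bin_edges_min, dtype=float)
        if not np.allclose(np.diff(edges), bin_width_min):
            raise ValidationError(
                f"paired series bin width differs from {bin_width_min} min"
            )
        peaks = raster.peaks if hasattr(raster, "peaks") else raster
        times = np.concatenate(
            [np.asarray(v, float) for k, v in peaks.items() if k != "w"]
            or [np.empty(0)]
        )
        t_min = times / 60.0
        counts = np.histogram(t_min, bins=edges)[0]
        # sessions must cover the paired series' analysis window
        span = getattr(raster, "span_min", None)
        if span is not None and (edges[0] < span[0] - 0.1 or edges[-1] > span[1] + 0.1):
            raise ValidationError(
                f"paired series window [{edges[0]}, {edges[-1]}] min exceeds "
                f"the session span [{span[0]:.1f}, {span[1]:.1f}] min"
            )
        counts_all.append(counts.astype(float))
        other_all.append(np.asarray(series.values, dtype=float))
    counts_cat = np.concatenate(counts_all)
    other_cat = np.concatenate(other_all)
    res = spearman(counts_cat, other_cat)
    res.x_kind = "peak_count"
    res.y_kind = getattr(other_series[0], "kind", "")
    return res
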