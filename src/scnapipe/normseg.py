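"""Normalization and segmentation of single-cell bin counts.

Normalization: counts are scaled to the cell mean (library size), log2
transformed with a pseudo-count of 1/(2 x mean count), and GC-corrected by
subtracting a LOWESS fit of log-ratio on bin GC content.

Segmentation offers two routes, mirroring standard practice for
single-cell CNV data:

* circular binary segmentation (CBS): recursively find the arc (i, j]
  maximizing the two-sample t statistic between bins inside and outside
  the arc, accept the split when a permutation test at level ``alpha``
  rejects, and recurse. This is the core max-t + permutation algorithm
  without speedup heuristics; ties break toward the leftmost arc.
* exact penalized least squares: shared breakpoints across cells minimizing
  sum of squared residuals + gamma x (number of breakpoints), solved by
  optimal-partitioning dynamic programming. With a single cell this reduces
  to single-sample optimal partitioning and is the pipeline's per-cell
  default (deterministic and fast).

Adjacent segments that are not statistically distinct (Wilcoxon rank-sum on
member-bin values) are merged iteratively, largest p first, until every
adjacent pair differs at ``merge_pvalue``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess


@dataclass
class RatioProfile:
    """Per-cell log2 ratio profile on retained bins."""

    log2: np.ndarray
    chrom: np.ndarray            # chromosome label per bin
    gc_corrected: bool = False

    def __post_init__(self):
        self.log2 = np.asarray(self.log2, dtype=float)
        self.chrom = np.asarray(self.chrom)
        if not np.all(np.isfinite(self.log2)):
            raise ValueError("log2 ratios must be finite")

    @property
    def linear(self) -> np.ndarray:
        return 2.0 ** self.log2


@dataclass
class CBSConfig:
    alpha: float = 0.01
    nperm: int = 10_000
    seed: int = 0
    min_width: int = 2

    def __post_init__(self):
        if self.nperm < 100:
            warnings.warn("nperm < 100 gives a very coarse permutation p-value")


@dataclass
class JointSegConfig:
    gamma: float = 40.0

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class MergeConfig:
    merge_pvalue: float = 0.01


SEGMENT_COLUMNS = ["chrom", "start_bin", "end_bin", "n_bins", "mean"]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(
    counts_row: np.ndarray,
    bins: pd.DataFrame,
    span: float = 0.3,
    robust_iters: int = 2,
    gc_correct: bool = True,
) -> RatioProfile:
    """Library-size + GC-LOWESS normalization of one cell's bin counts.

    When the bin table carries a mappability column, counts are first scaled
    to unit mappability; bins built for equal mappable mass have near-
    constant mappability and are unaffected.
    """
    counts_row = np.asarray(counts_row, dtype=float)
    if "mappability" in bins.columns:
        mapp = bins["mappability"].values.astype(float)
        if np.any(mapp <= 0):
            raise ValueError("mappability must be positive on retained bins")
        counts_row = counts_row / mapp
    m = counts_row.mean()
    if m == 0:
        raise ValueError("empty cell (all-zero counts row)")
    eps = 1.0 / (2.0 * m)
    log2r = np.log2(counts_row / m + eps)
    chrom = bins["chrom"].values
    if not gc_correct:
        return RatioProfile(log2=log2r, chrom=chrom, gc_corrected=False)
    gc = bins["gc"].values.astype(float)
    if np.allclose(gc, gc[0]):
        fit = np.full_like(log2r, log2r.mean())
    else:
        # fit the GC curve on bins near the modal level only, so copy-number
        # events do not drag the correction; apply it to every bin
        med = np.median(log2r)
        mad = 1.4826 * np.median(np.abs(log2r - med))
        keep = (np.abs(log2r - med) <= 2.5 * mad) if mad > 0 else slice(None)
        fit = lowess(log2r[keep], gc[keep], frac=span, it=robust_iters,
                     xvals=gc, return_sorted=False)
        if np.any(~np.isfinite(fit)):  # gc outside the trimmed range
            order = np.argsort(gc[keep])
            fit = np.interp(gc, gc[keep][order],
                            np.nan_to_num(lowess(log2r[keep], gc[keep],
                                                 frac=span, it=robust_iters,
                                                 xvals=np.sort(gc[keep]),
                                                 return_sorted=False)))
    corrected = log2r - fit
    return RatioProfile(log2=corrected, chrom=chrom, gc_corrected=True)


def winsorize(x: np.ndarray, k: int = 5, n_mad: float = 2.5) -> np.ndarray:
    """MAD-winsorization of a log-ratio profile before segmentation.

    Each value is clamped to within ``n_mad`` scaled MADs of a running
    median (window ``2k+1``), damping single-bin outliers that otherwise
    drag breakpoint estimates; the standard preprocessing for penalized
    least-squares segmentation of copy-number data.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n == 0:
        return x.copy()
    med = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - k), min(n, i + k + 1)
        med[i] = np.median(x[lo:hi])
    resid = x - med
    sigma = 1.4826 * np.median(np.abs(resid))
    if sigma == 0:
        return x.copy()
    return med + np.clip(resid, -n_mad * sigma, n_mad * sigma)


# ---------------------------------------------------------------------------
# CBS
# ---------------------------------------------------------------------------

def _arc_t_max(x: np.ndarray) -> tuple[int, int, float]:
    """Best arc (i, j], 0 <= i < j <= n, proper nonempty subset, maximizing
    |t| between bins inside and outside; ties toward the leftmost (smallest
    i, then smallest j). Returns (i, j, |t|); |t| = 0 when degenerate."""
    n = len(x)
    if n < 2:
        return 0, n, 0.0
    S = np.concatenate(([0.0], np.cumsum(x)))
    Q = np.concatenate(([0.0], np.cumsum(x * x)))
    tot, tot_sq = S[n], Q[n]
    best = (0, n, 0.0)
    i_idx, j_idx = np.triu_indices(n + 1, k=1)
    k = (j_idx - i_idx).astype(float)
    proper = k < n
    i_idx, j_idx, k = i_idx[proper], j_idx[proper], k[proper]
    sum_in = S[j_idx] - S[i_idx]
    sq_in = Q[j_idx] - Q[i_idx]
    m = n - k
    mean_in = sum_in / k
    mean_out = (tot - sum_in) / m
    ss = (sq_in - k * mean_in**2) + (tot_sq - sq_in - m * mean_out**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        sd = np.sqrt(np.clip(ss, 0, None) / max(n - 2, 1))
        t = np.abs(mean_in - mean_out) / (sd * np.sqrt(1.0 / k + 1.0 / m))
    bad = ~np.isfinite(t)
    # zero residual variance: infinite t when means differ, else no signal
    t[bad] = np.where(np.abs(mean_in - mean_out)[bad] > 1e-12, np.inf, 0.0)
    if not len(t):
        return best
    tmax = t.max()
    if tmax <= 0:
        return best
    hits = np.flatnonzero(t == tmax)
    # leftmost arc: triu_indices orders by i then j already
    h = hits[0]
    return int(i_idx[h]), int(j_idx[h]), float(tmax)


def _max_t_value(x: np.ndarray) -> float:
    return _arc_t_max(x)[2]


def _permutation_p(
    x: np.ndarray, t_obs: float, cfg: CBSConfig, rng: np.random.Generator,
) -> float:
    """Sequential permutation p-value of the max-|t| statistic.

    Permutations stop early once the decision at level alpha is settled:
    either the exceedance count already pushes p above alpha, or the
    Clopper-Pearson 99.9% upper bound on p drops below alpha.
    """
    limit = int(np.ceil(cfg.alpha * cfg.nperm))
    exceed = 0
    done = 0
    while done < cfg.nperm:
        batch = min(250, cfg.nperm - done)
        for _ in range(batch):
            perm = rng.permutation(x)
            if _max_t_value(perm) >= t_obs - 1e-12:
                exceed += 1
        done += batch
        if exceed > limit:
            break  # p-value certainly above alpha
        upper = stats.beta.ppf(0.999, exceed + 1, max(done - exceed, 1))
        if upper < cfg.alpha:
            break  # split certainly significant
    return (exceed + 1) / (done + 1)


def _cbs_chrom(
    x: np.ndarray, cfg: CBSConfig, rng: np.random.Generator,
) -> list[int]:
    """Breakpoints (bin indices where a new segment starts) within one
    chromosome by recursive CBS."""
    breaks: set[int] = set()

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = hi - lo
        if n < 2 * cfg.min_width:
            return
        if np.ptp(seg) < 1e-12:
            return
        i, j, t_obs = _arc_t_max(seg)
        if t_obs <= 0:
            return
        p = _permutation_p(seg, t_obs, cfg, rng)
        if p >= cfg.alpha:
            return
        cuts = []
        if i > 0:
            cuts.append(lo + i)
        if j < n:
            cuts.append(lo + j)
        if not cuts:
            return
        breaks.update(cuts)
        edges = [lo] + cuts + [hi]
        for a, b in zip(edges[:-1], edges[1:]):
            recurse(a, b)

    recurse(0, len(x))
    return sorted(breaks)


def _segments_from_breaks(
    values: np.ndarray, chrom: np.ndarray, breaks_per_chrom: dict,
) -> pd.DataFrame:
    rows = []
    offset = 0
    for ch, n in _chrom_runs(chrom):
        cuts = [0] + breaks_per_chrom.get(ch, []) + [n]
        for a, b in zip(cuts[:-1], cuts[1:]):
            seg = values[offset + a:offset + b]
            rows.append((ch, offset + a, offset + b - 1, b - a, seg.mean()))
        offset += n
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def _chrom_runs(chrom: np.ndarray) -> list[tuple[str, int]]:
    runs = []
    if len(chrom) == 0:
        return runs
    current = chrom[0]
    count = 0
    for c in chrom:
        if c == current:
            count += 1
        else:
            runs.append((current, count))
            current, count = c, 1
    runs.append((current, count))
    return runs


def segment_cbs(profile: RatioProfile, cfg: CBSConfig | None = None) -> pd.DataFrame:
    """Per-chromosome recursive circular binary segmentation.

    Returns segments (chrom, start_bin, end_bin inclusive, n_bins, mean)
    partitioning the profile's bins; reproducible under cfg.seed.
    """
    cfg = cfg or CBSConfig()
    x = profile.log2
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in profile")
    rng = np.random.default_rng(cfg.seed)
    breaks = {}
    offset = 0
    for ch, n in _chrom_runs(profile.chrom):
        breaks[ch] = _cbs_chrom(x[offset:offset + n], cfg, rng)
        offset += n
    return _segments_from_breaks(x, profile.chrom, breaks)


# ---------------------------------------------------------------------------
# exact penalized least-squares segmentation (multi-sample)
# ---------------------------------------------------------------------------

def _dp_chrom(X: np.ndarray, gamma: float) -> list[int]:
    """Optimal partitioning of cells x n values minimizing
    sum_c SSE + gamma * #breakpoints. Returns interior breakpoints."""
    n_cells, n = X.shape
    C = np.concatenate([np.zeros((n_cells, 1)), np.cumsum(X, axis=1)], axis=1)
    Q = np.concatenate([[0.0], np.cumsum((X * X).sum(axis=0))])
    G = (C * C).sum(axis=0)  # sum_c C[c,i]^2
    dp = np.empty(n + 1)
    back = np.zeros(n + 1, dtype=np.int64)
    dp[0] = 0.0
    for j in range(1, n + 1):
        i = np.arange(j)
        length = (j - i).astype(float)
        cross = C[:, :j].T @ C[:, j]
        seg_cost = (Q[j] - Q[i]) - (G[j] - 2.0 * cross + G[i]) / length
        cand = dp[:j] + seg_cost + np.where(i > 0, gamma, 0.0)
        best = int(np.argmin(cand))
        dp[j] = cand[best]
        back[j] = best
    cuts = []
    j = n
    while j > 0:
        i = int(back[j])
        if i > 0:
            cuts.append(i)
        j = i
    return sorted(cuts)


def suggest_gamma(X: np.ndarray, scale: float = 2.0) -> float:
    """BIC-style breakpoint penalty: scale x sigma^2 x ln(n_bins), with
    sigma estimated per cell from the MAD of lag-1 differences and summed
    over cells."""
    X = np.atleast_2d(X)
    n = X.shape[1]
    sig2 = 0.0
    for row in X:
        d = np.diff(row)
        mad = np.median(np.abs(d - np.median(d)))
        sig2 += (1.4826 * mad / np.sqrt(2.0)) ** 2
    return float(scale * sig2 * np.log(max(n, 2)))


def segment_joint(
    profiles: np.ndarray | list[RatioProfile],
    chrom: np.ndarray | None = None,
    cfg: JointSegConfig | None = None,
) -> list[pd.DataFrame]:
    """Joint segmentation with shared breakpoints across cells.

    ``profiles`` is a cells x bins array (or list of RatioProfile on
    identical bins). Breakpoints minimize the summed squared error plus
    gamma per breakpoint, solved exactly per chromosome by dynamic
    programming; means are cell-specific. Returns one segment table per
    cell, all sharing breakpoints.
    """
    cfg = cfg or JointSegConfig()
    if isinstance(profiles, list):
        chrom = profiles[0].chrom
        X = np.vstack([p.log2 for p in profiles])
    else:
        X = np.atleast_2d(np.asarray(profiles, dtype=float))
        if chrom is None:
            raise ValueError("chrom labels required with array input")
    breaks = {}
    offset = 0
    for ch, n in _chrom_runs(np.asarray(chrom)):
        breaks[ch] = _dp_chrom(X[:, offset:offset + n], cfg.gamma)
        offset += n
    return [_segments_from_breaks(X[c], np.asarray(chrom), breaks)
            for c in range(X.shape[0])]


# ---------------------------------------------------------------------------
# level merging
# ---------------------------------------------------------------------------

def merge_levels(
    segments: pd.DataFrame,
    profile: RatioProfile | np.ndarray,
    cfg: MergeConfig | None = None,
) -> pd.DataFrame:
    """Merge adjacent segments that are not significantly distinct.

    Iteratively merges the adjacent pair (within a chromosome) with the
    largest Wilcoxon rank-sum p-value on member-bin values while
    p >= merge_pvalue, recomputing means after each merge.
    """
    cfg = cfg or MergeConfig()
    values = profile.log2 if isinstance(profile, RatioProfile) else np.asarray(profile)
    segs = [tuple(r) for r in segments[SEGMENT_COLUMNS].itertuples(index=False)]

    def pval(a, b):
        xa = values[a[1]:a[2] + 1]
        xb = values[b[1]:b[2] + 1]
        if len(xa) == 0 or len(xb) == 0:
            return 0.0
        if np.ptp(np.concatenate([xa, xb])) < 1e-15:
            return 1.0
        try:
            return float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        except ValueError:
            return 1.0

    while len(segs) > 1:
        best_p, best_i = -1.0, -1
        for i in range(len(segs) - 1):
            if segs[i][0] != segs[i + 1][0]:
                continue
            p = pval(segs[i], segs[i + 1])
            if p > best_p:
                best_p, best_i = p, i
        if best_i < 0 or best_p < cfg.merge_pvalue:
            break
        a, b = segs[best_i], segs[best_i + 1]
        merged_vals = values[a[1]:b[2] + 1]
        segs[best_i:best_i + 2] = [
            (a[0], a[1], b[2], b[2] - a[1] + 1, merged_vals.mean())]
    return pd.DataFrame(segs, columns=SEGMENT_COLUMNS)


def segment_means_per_bin(segments: pd.DataFrame, n_bins: int) -> np.ndarray:
    """Expand a segment table to a per-bin vector of segment means."""
    out = np.empty(n_bins)
    for _, s in segments.iterrows():
        out[int(s.start_bin):int(s.end_bin) + 1] = s["mean"]
    return out
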