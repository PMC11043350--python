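"""Integer copy-number calling by ploidy/purity grid search.

Segmented linear ratios are scaled by each candidate ploidy on a grid
(1.7 to 6.0 in steps of 0.01; purity fixed at 1 for single cells) and the
candidate minimizing the length-weighted squared distance of scaled segment
means to the nearest integers is selected. Ties break toward ploidy 2 (flat
profiles are otherwise ill-posed across integer multiples), then toward the
smaller ploidy. Copy numbers are the rounded scaled means, floored at 0 and
capped (default 20) to guard against degenerate high-ploidy fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GridSearchConfig:
    ploidy_min: float = 1.7
    ploidy_max: float = 6.0
    ploidy_step: float = 0.01
    purity: float = 1.0
    tie_ploidy: float = 2.0
    cn_cap: int = 20

    def __post_init__(self):
        if not self.ploidy_min < self.ploidy_max:
            raise ValueError("ploidy_min must be < ploidy_max")
        if self.ploidy_step <= 0:
            raise ValueError("ploidy_step must be > 0")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")

    def grid(self) -> np.ndarray:
        n = int(round((self.ploidy_max - self.ploidy_min) / self.ploidy_step))
        return self.ploidy_min + self.ploidy_step * np.arange(n + 1)


@dataclass
class CNProfile:
    """Integer copy number per bin plus the chosen ploidy and fit error."""

    cn: np.ndarray
    chosen_ploidy: float
    fit_error: float
    segments: pd.DataFrame

    def __post_init__(self):
        if np.any(self.cn < 0):
            raise ValueError("copy numbers must be >= 0")
        if self.fit_error < 0:
            raise ValueError("fit_error must be >= 0")


def _expected_ratio(cn: np.ndarray, ploidy: float, purity: float) -> np.ndarray:
    """Expected observed ratio of a clone at integer CN under purity rho and
    candidate ploidy psi: (rho*c + 2(1-rho)) / (rho*psi + 2(1-rho))."""
    return (purity * cn + 2 * (1 - purity)) / (purity * ploidy + 2 * (1 - purity))


def grid_errors(
    seg_means: np.ndarray, seg_weights: np.ndarray, cfg: GridSearchConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized length-weighted rounding error for every grid ploidy."""
    grid = cfg.grid()
    w = seg_weights / seg_weights.sum()
    if cfg.purity >= 1.0 - 1e-12:
        scaled = seg_means[None, :] * grid[:, None]
    else:
        # invert the expected-ratio relation: c = (r*(rho*psi+2(1-rho)) - 2(1-rho))/rho
        denom = cfg.purity * grid[:, None] + 2 * (1 - cfg.purity)
        scaled = (seg_means[None, :] * denom - 2 * (1 - cfg.purity)) / cfg.purity
    err = ((scaled - np.round(scaled)) ** 2 * w[None, :]).sum(axis=1)
    return grid, err


def call_integer_cn(
    segments: pd.DataFrame,
    cfg: GridSearchConfig | None = None,
    renormalize: bool = True,
) -> CNProfile:
    """Choose the grid ploidy with the lowest rounding error and emit the
    integer profile.

    ``segments`` carries log2 means (column ``mean``) and widths
    (``n_bins``). Linear ratios are recentered to weighted mean 1 before the
    search (log-scale normalization does not guarantee it exactly).
    """
    cfg = cfg or GridSearchConfig()
    if len(segments) == 0:
        raise ValueError("empty segment table")
    w = segments["n_bins"].values.astype(float)
    r = 2.0 ** segments["mean"].values
    if renormalize:
        r = r / np.average(r, weights=w)
    grid, err = grid_errors(r, w, cfg)
    emin = err.min()
    candidates = np.flatnonzero(err <= emin + 1e-15)
    # ties: closest to tie_ploidy (default 2), then smallest ploidy
    order = np.lexsort((grid[candidates],
                        np.abs(grid[candidates] - cfg.tie_ploidy)))
    best = candidates[order[0]]
    p_star = float(grid[best])
    if cfg.purity >= 1.0 - 1e-12:
        seg_cn = np.round(r * p_star)
    else:
        denom = cfg.purity * p_star + 2 * (1 - cfg.purity)
        seg_cn = np.round((r * denom - 2 * (1 - cfg.purity)) / cfg.purity)
    seg_cn = np.clip(seg_cn, 0, cfg.cn_cap).astype(np.int64)
    n_bins = int(segments["end_bin"].max()) + 1
    cn = np.empty(n_bins, dtype=np.int64)
    for s_cn, (_, seg) in zip(seg_cn, segments.iterrows()):
        cn[int(seg.start_bin):int(seg.end_bin) + 1] = s_cn
    return CNProfile(cn=cn, chosen_ploidy=p_star, fit_error=float(err[best]),
                     segments=segments.assign(cn=seg_cn))
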