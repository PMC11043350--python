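"""Spatial spread of clones: QC-normalized Shannon entropy over regions.

Each clone's regional cell counts are normalized by the number of cells
passing QC in each region (so unevenly sampled regions do not distort the
picture), renormalized to a probability vector, and summarized by Shannon
entropy in bits: 0 for a fully localized clone, log2(R) for a clone spread
uniformly over R regions. Region groups (tumor-rich TRR, focally enriched
FER, normal NOR) are compared by the two-sided Wilcoxon rank-sum test on
per-region mean clone entropies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EntropyResult:
    H: float        # bits
    support: int    # regions with >= 1 cell

    def __post_init__(self):
        if self.H < -1e-12:
            raise ValueError("entropy must be >= 0")


def clone_entropy(
    clone_counts: np.ndarray | pd.Series,
    qc_totals: np.ndarray | pd.Series,
) -> EntropyResult:
    """Shannon entropy (bits) of one clone's QC-normalized regional
    distribution: p'_r = n_r / N_r, p = p' / sum(p'), H = -sum p log2 p."""
    n = np.asarray(clone_counts, dtype=float)
    N = np.asarray(qc_totals, dtype=float)
    if n.sum() == 0:
        raise ValueError("clone has zero cells")
    present = n > 0
    if np.any(N[present] <= 0):
        raise ValueError("QC total is zero in a region where the clone is present")
    p = np.zeros_like(n)
    p[present] = n[present] / N[present]
    p = p / p.sum()
    nz = p > 0
    H = float(-(p[nz] * np.log2(p[nz])).sum()) + 0.0  # never -0.0
    return EntropyResult(H=max(H, 0.0), support=int(present.sum()))


def all_clone_entropies(
    clone_counts: pd.DataFrame, regions: pd.DataFrame,
) -> pd.DataFrame:
    """Entropy per clone; ``clone_counts`` is clones x regions, ``regions``
    carries qc_total per region (clones with zero cells are skipped)."""
    rows = []
    qc = regions["qc_total"].reindex(clone_counts.columns).values
    for clone, counts in clone_counts.iterrows():
        if counts.sum() == 0:
            continue
        res = clone_entropy(counts.values, qc)
        rows.append({"clone": clone, "H": res.H, "support": res.support})
    return pd.DataFrame(rows).set_index("clone")


def region_mean_entropy(
    clone_counts: pd.DataFrame,
    regions: pd.DataFrame,
    entropies: pd.DataFrame | None = None,
) -> pd.Series:
    """Per region, the mean entropy of clones with >= 1 cell there (NaN for
    regions hosting no clone)."""
    if entropies is None:
        entropies = all_clone_entropies(clone_counts, regions)
    out = {}
    for region in clone_counts.columns:
        present = clone_counts.index[(clone_counts[region] > 0)
                                     & clone_counts.index.isin(entropies.index)]
        out[region] = (float(entropies.loc[present, "H"].mean())
                       if len(present) else float("nan"))
    return pd.Series(out, name="mean_entropy")


def region_group_entropy(
    clone_counts: pd.DataFrame,
    regions: pd.DataFrame,
    groups: tuple[str, str] = ("TRR", "NOR"),
) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of per-region mean clone
    entropy between two region groups (exact null when sample sizes allow)."""
    mean_h = region_mean_entropy(clone_counts, regions)
    values = {}
    for g in groups:
        sel = regions.index[regions["label"] == g]
        vals = mean_h.reindex(sel).dropna().values
        values[g] = vals
    a, b = values[groups[0]], values[groups[1]]
    result = {"groups": groups,
              "n": (len(a), len(b)),
              "mean": (float(np.mean(a)) if len(a) else float("nan"),
                       float(np.mean(b)) if len(b) else float("nan"))}
    if len(a) < 2 or len(b) < 2:
        warnings.warn("a group has fewer than 2 regions; p-value missing")
        result.update(statistic=float("nan"), pvalue=float("nan"))
        return result
    test = stats.mannwhitneyu(a, b, alternative="two-sided",
                              method="exact" if max(len(a), len(b)) < 20
                              else "auto")
    result.update(statistic=float(test.statistic), pvalue=float(test.pvalue))
    return result


def render_map(
    regions: pd.DataFrame,
    statistic: pd.Series,
    out_tsv=None,
    out_figure=None,
) -> pd.DataFrame:
    """Lay a per-region statistic onto the anatomical grid.

    Returns the grid as a row x col DataFrame (NaN = absent tissue, drawn
    white); optionally writes a TSV and a vector figure.
    """
    coords = regions[["row", "col"]]
    if coords.duplicated().any():
        raise ValueError("duplicate grid coordinates")
    n_rows = int(regions["row"].max()) + 1
    n_cols = int(regions["col"].max()) + 1
    grid = np.full((n_rows, n_cols), np.nan)
    for region, rc in coords.iterrows():
        grid[int(rc["row"]), int(rc["col"])] = statistic.get(region, np.nan)
    df = pd.DataFrame(grid,
                      index=pd.RangeIndex(n_rows, name="row"),
                      columns=pd.RangeIndex(n_cols, name="col"))
    if out_tsv is not None:
        df.to_csv(out_tsv, sep="\t")
    if out_figure is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1 + n_cols, 1 + n_rows))
        masked = np.ma.masked_invalid(grid)
        cmap = plt.get_cmap("viridis").copy()
        cmap.set_bad("white")
        im = ax.pcolormesh(masked, cmap=cmap, edgecolors="grey", linewidth=0.5)
        ax.invert_yaxis()
        ax.set_xlabel("column")
        ax.set_ylabel("row")
        fig.colorbar(im, ax=ax)
        fig.savefig(out_figure, bbox_inches="tight")
        plt.close(fig)
    return df
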