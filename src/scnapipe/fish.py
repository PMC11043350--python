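"""FISH dot-count quantification of a monoallelic deletion.

Three probes target the deleted interval plus flanking regions upstream and
downstream of it. Per field of view (FOV), dot counts of the deletion and
upstream probes are expressed relative to the downstream reference probe.
Because the deletion is monoallelic, a relative deletion-dot fraction
N_del_dots converts to the fraction of cells carrying the deletion as

    N_cells_with_del = (1 - N_del_dots) / 0.5

so e.g. a deletion probe yielding 75% of the downstream dot count implies
~50% of cells carry the deletion on one chr13 copy. The upstream probe
fraction (~1) serves as an internal control. The deleted-cell fraction is
finally correlated (Pearson) with the annotated tumor-area fraction of each
FOV.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def relative_fractions(fovs: pd.DataFrame) -> pd.DataFrame:
    """Deletion- and upstream-probe dot counts relative to the downstream
    reference. FOVs with zero downstream dots are flagged and excluded."""
    out = fovs.copy()
    down = out["dots_down"].astype(float)
    flagged = down <= 0
    if flagged.any():
        warnings.warn(f"{int(flagged.sum())} FOV(s) with zero downstream "
                      "dots flagged and excluded")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["N_del_dots"] = np.where(flagged, np.nan, out["dots_del"] / down)
        out["upstream_fraction"] = np.where(flagged, np.nan,
                                            out["dots_up"] / down)
    out["flagged"] = flagged
    return out


def deleted_fraction(n_del_dots):
    """Convert the relative deletion-dot fraction to the fraction of cells
    carrying the monoallelic deletion: (1 - N_del_dots) / 0.5, clipped to
    [0, 1] with a logged warning when detection noise pushes it outside."""
    x = np.asarray(n_del_dots, dtype=float)
    if np.any(x[~np.isnan(x)] < 0):
        raise ValueError("N_del_dots must be >= 0")
    raw = (1.0 - x) / 0.5
    clipped = np.clip(raw, 0.0, 1.0)
    n_clip = int(np.sum((raw != clipped) & ~np.isnan(raw)))
    if n_clip:
        logger.warning("deleted_fraction clipped %d value(s) into [0, 1]", n_clip)
        warnings.warn(f"deleted_fraction clipped {n_clip} value(s) into [0, 1]")
    if np.isscalar(n_del_dots) or np.ndim(n_del_dots) == 0:
        return float(clipped)
    return clipped


def flag_control_outliers(fovs: pd.DataFrame, n_sd: float = 3.0) -> pd.Series:
    """Internal control: upstream fraction should sit near 1; FOVs deviating
    by more than ``n_sd`` SDs are flagged."""
    up = fovs["upstream_fraction"].dropna()
    sd = up.std()
    if sd == 0:
        return pd.Series(False, index=fovs.index)
    z = (fovs["upstream_fraction"] - up.mean()).abs() / sd
    return z > n_sd


def tumor_correlation(
    del_fraction: np.ndarray | pd.Series,
    tumor_area_fraction: np.ndarray | pd.Series,
) -> dict:
    """Pearson correlation and least-squares line between the deleted-cell
    fraction and the annotated tumor-area fraction per FOV."""
    x = np.asarray(tumor_area_fraction, dtype=float)
    y = np.asarray(del_fraction, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 FOVs with finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: correlation undefined")
        return {"pcc": float("nan"), "slope": float("nan"),
                "intercept": float("nan"), "pvalue": float("nan"), "n": len(x)}
    pearson = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return {"pcc": float(pearson.statistic), "pvalue": float(pearson.pvalue),
            "slope": float(fit.slope), "intercept": float(fit.intercept),
            "n": int(len(x))}


def quantify(fovs: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Full FOV table workflow: relative fractions, Eq.-style deleted-cell
    conversion, control flags and the tumor-area correlation."""
    table = relative_fractions(fovs)
    table["N_cells_with_del"] = deleted_fraction(table["N_del_dots"].values)
    table["control_outlier"] = flag_control_outliers(table)
    usable = table[~table["flagged"]]
    corr = tumor_correlation(usable["N_cells_with_del"],
                             usable["tumor_area_fraction"])
    return table, corr
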