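"""Mappability-balanced genomic bins, read counting and coverage metrics.

Bins of variable width are built so each accumulates the same mappable
mass: bins in low-mappability regions are extended and bins in
high-mappability regions shortened, keeping the average length near the
target (~500 kb by default). Blacklisted intervals (telomeres, centromeres
and other artefact-prone regions) are flagged and excluded from count
matrices. Per-cell coverage metrics follow the standard single-cell CNV
definitions: overdispersion is var/mean of bin counts (population
variance) and breadth of coverage is the fraction of the genome covered by
at least one read.

All coordinates are 0-based half-open (BED dialect).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .simgen import CellMatrix

BIN_COLUMNS = ["chrom", "start", "end", "gc", "mappability", "blacklisted"]


class IntervalFormatError(ValueError):
    pass


def build_bins(track: pd.DataFrame, target_len: int) -> pd.DataFrame:
    """Assemble variable-width bins of equal mappable mass from a windowed
    mappability track.

    ``track`` has columns chrom, start, end, mappability (and optionally gc);
    windows must tile each chromosome. Each bin accumulates mappable mass
    M* = target_len x genome-mean mappability; the last bin per chromosome
    absorbs the remainder and is flagged ``tail``.
    """
    req = {"chrom", "start", "end", "mappability"}
    if not req.issubset(track.columns):
        raise IntervalFormatError(f"track needs columns {sorted(req)}")
    lengths = (track["end"] - track["start"]).values
    if np.any(lengths <= 0):
        raise IntervalFormatError("track windows must have end > start")
    genome_mean = float(np.average(track["mappability"], weights=lengths))
    if genome_mean <= 0:
        raise ValueError("mappability track is all zero")
    target_mass = target_len * genome_mean

    has_gc = "gc" in track.columns
    out = []
    for chrom, grp in track.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        wl = (grp["end"] - grp["start"]).values
        mass = grp["mappability"].values * wl
        if mass.sum() <= 0:
            raise ValueError(f"chromosome {chrom} has zero mappability")
        starts = grp["start"].values
        ends = grp["end"].values
        acc = 0.0
        bin_start = starts[0]
        acc_len = 0.0
        acc_map = 0.0
        acc_gc = 0.0
        for i in range(len(grp)):
            acc += mass[i]
            acc_len += wl[i]
            acc_map += mass[i]
            if has_gc:
                acc_gc += grp["gc"].values[i] * wl[i]
            if acc >= target_mass:
                out.append((chrom, bin_start, ends[i], acc_gc / acc_len,
                            acc_map / acc_len, False, False))
                bin_start = ends[i]
                acc = acc_len = acc_map = acc_gc = 0.0
        if acc_len > 0:  # short tail bin
            out.append((chrom, bin_start, ends[-1], acc_gc / acc_len,
                        acc_map / acc_len, False, True))
    bins = pd.DataFrame(out, columns=["chrom", "start", "end", "gc",
                                      "mappability", "blacklisted", "tail"])
    if not has_gc:
        bins["gc"] = np.nan
    return bins


def filter_blacklist(
    bins: pd.DataFrame,
    blacklist: pd.DataFrame,
    max_overlap: float = 0.5,
) -> pd.DataFrame:
    """Flag bins whose overlap with blacklisted intervals exceeds
    ``max_overlap`` of the bin length; flagged bins are excluded downstream."""
    if len(blacklist) and np.any(
            blacklist["end"].values <= blacklist["start"].values):
        bad = blacklist[blacklist["end"] <= blacklist["start"]]
        raise IntervalFormatError(
            f"malformed blacklist intervals (end <= start): {bad.to_dict('records')}")
    bins = bins.copy()
    overlap = np.zeros(len(bins))
    for chrom, grp in (blacklist.groupby("chrom", sort=False)
                       if len(blacklist) else ()):
        sel = bins["chrom"] == chrom
        if not sel.any():
            continue
        b_start = bins.loc[sel, "start"].values[:, None]
        b_end = bins.loc[sel, "end"].values[:, None]
        ov = (np.minimum(b_end, grp["end"].values[None, :])
              - np.maximum(b_start, grp["start"].values[None, :]))
        overlap[sel.values] += np.clip(ov, 0, None).sum(axis=1)
    frac = overlap / (bins["end"] - bins["start"]).values
    bins["blacklisted"] = bins.get("blacklisted", False) | (frac > max_overlap)
    return bins


def retained(bins: pd.DataFrame) -> pd.DataFrame:
    """Bins kept for analysis (non-blacklisted)."""
    if "blacklisted" not in bins.columns:
        return bins
    return bins[~bins["blacklisted"]].reset_index(drop=True)


def count_reads(
    positions: pd.DataFrame,
    bins: pd.DataFrame,
    cell_meta: pd.DataFrame | None = None,
) -> CellMatrix:
    """Count read positions into retained bins.

    ``positions`` has columns cell, chrom, pos. Positions landing in
    blacklisted bins (or in no bin) are dropped; a position equal to a bin
    start belongs to that bin (half-open convention).
    """
    known = set(bins["chrom"])
    offenders = sorted(set(positions["chrom"]) - known)
    if offenders:
        raise ValueError(f"unknown chromosomes in positions: {offenders}")
    keep = retained(bins)
    cells = pd.Index(pd.unique(positions["cell"]), name="cell")
    cell_of = {c: i for i, c in enumerate(cells)}
    counts = np.zeros((len(cells), len(keep)), dtype=np.int64)
    col_of = {}
    for chrom, grp in keep.groupby("chrom", sort=False):
        col_of[chrom] = (grp["start"].values, grp["end"].values,
                         grp.index.values)
    for chrom, grp in positions.groupby("chrom", sort=False):
        starts, ends, cols = col_of[chrom]
        pos = grp["pos"].values
        j = np.searchsorted(starts, pos, side="right") - 1
        jc = np.clip(j, 0, None)
        ok = (j >= 0) & (pos < ends[jc])
        rows = np.fromiter((cell_of[c] for c in grp["cell"].values),
                           dtype=np.int64, count=len(grp))
        np.add.at(counts, (rows[ok], cols[j[ok]]), 1)
    if cell_meta is None:
        cell_meta = pd.DataFrame(index=cells)
    else:
        cell_meta = cell_meta.loc[cells]
    return CellMatrix(counts=counts, cell_meta=cell_meta, bin_ref=keep)


def downsample(row: np.ndarray, n: int, seed: int | None = None) -> np.ndarray:
    """Subsample a counts row to exactly ``n`` reads without replacement
    (multivariate hypergeometric). If n >= total the row is returned
    unchanged with a warning."""
    if n < 0:
        raise ValueError("n must be >= 0")
    row = np.asarray(row, dtype=np.int64)
    total = int(row.sum())
    if n >= total:
        if n > total:
            warnings.warn(
                f"requested {n} reads but row has {total}; returning unchanged")
        return row.copy()
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(row, n)


def overdispersion(row: np.ndarray) -> float:
    """Index of dispersion var/mean of bin counts (population variance);
    NaN when the mean is zero."""
    row = np.asarray(row, dtype=float)
    if row.size < 2:
        raise ValueError("need >= 2 bins")
    m = row.mean()
    if m == 0:
        return float("nan")
    return float(row.var() / m)


def breadth_of_coverage(
    positions: Iterable[tuple[str, int]] | pd.DataFrame,
    read_len: int,
    genome_len: int,
) -> float:
    """Fraction of the genome covered by >= 1 read; each read covers
    [pos, pos + read_len)."""
    if isinstance(positions, pd.DataFrame):
        pairs = positions[["chrom", "pos"]].itertuples(index=False)
    else:
        pairs = positions
    covered = 0
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in pairs:
        by_chrom.setdefault(chrom, []).append(int(pos))
    for chrom, pos_list in by_chrom.items():
        pos_arr = np.sort(np.asarray(pos_list))
        starts = pos_arr
        ends = pos_arr + read_len
        # merge
        new_start = np.concatenate(([True], starts[1:] > np.maximum.accumulate(ends[:-1])))
        grp = np.cumsum(new_start) - 1
        seg_start = np.minimum.reduceat(starts, np.flatnonzero(new_start))
        seg_end = np.maximum.reduceat(ends, np.flatnonzero(new_start))
        covered += int((seg_end - seg_start).sum())
        del grp
    return covered / genome_len


def dispersion_and_breadth(
    row: np.ndarray,
    positions=None,
    read_len: int | None = None,
    genome_len: int | None = None,
) -> tuple[float, float | None]:
    """Overdispersion of a counts row plus, when read positions are given,
    breadth of coverage."""
    od = overdispersion(row)
    br = None
    if positions is not None:
        if read_len is None or genome_len is None:
            raise ValueError("breadth needs read_len and genome_len")
        br = breadth_of_coverage(positions, read_len, genome_len)
    return od, br


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_bins_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bins_tsv(bins: pd.DataFrame, path) -> None:
    bins.to_csv(path, sep="\t", index=False)


def write_matrix_tsv(matrix: CellMatrix, path) -> None:
    df = pd.DataFrame(matrix.counts, index=matrix.cell_meta.index)
    df.columns = [f"bin{j}" for j in range(matrix.counts.shape[1])]
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path, bins: pd.DataFrame,
                    cell_meta: pd.DataFrame | None = None) -> CellMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = cell_meta if cell_meta is not None else pd.DataFrame(index=df.index)
    return CellMatrix(counts=df.values.astype(np.int64), cell_meta=meta,
                      bin_ref=bins)
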