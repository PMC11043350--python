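"""Karyotype classification, copy-number event distances, trees and clones.

Cells are classified by the length-weighted fraction of the considered
genome (autosomes plus chrX) whose called copy number deviates from
expectation (2 for autosomes, 2/1 for chrX in female/male samples): no
alteration -> diploid; up to 25% altered -> pseudo-diploid; more ->
aneuploid ('hopeful monster').

The distance between two integer profiles is the minimum number of
segmental events — each adding or subtracting one copy over a contiguous
bin interval, computed per chromosome — needed to transform one profile
into the other, with copy number 0 unrecoverable (no event may touch a bin
currently at 0). This has a closed form: chromosomes split at zero bins
into independent blocks, and within a block the cost is the total positive
variation of the positive and negative parts of the difference profile.
Pairs where the target is non-zero over a zero bin are unreachable and
flagged as infinite.

Trees are neighbor-joining on the distance matrix; clones are
complete-linkage clusters cut so every within-clone pairwise distance is at
most ``t`` (the 'max' clustering rule), with small clusters labeled noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
from skbio.tree import nj


@dataclass
class KaryotypeConfig:
    pseudo_max_fraction: float = 0.25
    sex: str = "male"

    def __post_init__(self):
        if not 0 < self.pseudo_max_fraction < 1:
            raise ValueError("pseudo_max_fraction must be in (0, 1)")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex: {self.sex}")


@dataclass
class CloneConfig:
    """Max-distance clustering threshold ``t`` (in events) and minimum clone
    size. The reference analyses used t=3 and 4 for the two prostate samples
    and 30/22 for the breast samples; clones smaller than min_clone_size are
    treated as noise."""

    t: float = 3.0
    min_clone_size: int = 5

    def __post_init__(self):
        if self.t < 0:
            raise ValueError("t must be >= 0")
        if self.min_clone_size < 1:
            raise ValueError("min_clone_size must be >= 1")


# ---------------------------------------------------------------------------
# karyotype
# ---------------------------------------------------------------------------

def expected_cn(chrom: np.ndarray, sex: str) -> np.ndarray:
    """Expected copy number per bin: 2 on autosomes, 2 on chrX for females,
    1 on chrX for males. chrY bins (if any) are not considered."""
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex: {sex}")
    exp = np.full(len(chrom), 2, dtype=np.int64)
    is_x = np.isin(chrom, ("chrX", "X"))
    if sex == "male":
        exp[is_x] = 1
    return exp


def altered_fraction(cn: np.ndarray, bins: pd.DataFrame, sex: str = "male") -> float:
    """Length-weighted fraction of autosomes + chrX with CN different from
    expectation."""
    chrom = bins["chrom"].values
    lengths = (bins["end"] - bins["start"]).values.astype(float)
    consider = ~np.isin(chrom, ("chrY", "Y"))
    exp = expected_cn(chrom, sex)
    altered = (np.asarray(cn) != exp) & consider
    return float(lengths[altered].sum() / lengths[consider].sum())


def classify_karyotype(fraction: float, cfg: KaryotypeConfig | None = None) -> str:
    """0 -> diploid; (0, 0.25] -> pseudo-diploid; >0.25 -> aneuploid."""
    cfg = cfg or KaryotypeConfig()
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if fraction == 0:
        return "diploid"
    if fraction <= cfg.pseudo_max_fraction:
        return "pseudo-diploid"
    return "aneuploid"


# ---------------------------------------------------------------------------
# event distance
# ---------------------------------------------------------------------------

def _interval_event_count(d: np.ndarray) -> float:
    """Minimum number of +1 interval operations realizing a non-negative
    integer vector d: the sum of positive increments of d (with d[-1]=0)."""
    if len(d) == 0:
        return 0.0
    padded = np.concatenate(([0], d))
    return float(np.clip(np.diff(padded), 0, None).sum())


def event_distance(
    cn_a: np.ndarray,
    cn_b: np.ndarray,
    chrom: np.ndarray | None = None,
) -> float:
    """Minimum segmental-event count transforming profile A into B
    (math.inf when unreachable because B > 0 where A = 0)."""
    a = np.asarray(cn_a, dtype=np.int64)
    b = np.asarray(cn_b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    if chrom is None:
        chrom = np.zeros(len(a), dtype=np.int64)
    chrom = np.asarray(chrom)
    total = 0.0
    for ch in pd.unique(chrom):
        sel = chrom == ch
        aa, bb = a[sel], b[sel]
        zero = aa == 0
        if np.any(bb[zero] > 0):
            return math.inf
        # zero bins are absorbing walls: solve each block independently
        edges = np.flatnonzero(zero)
        blocks = np.split(np.arange(len(aa)), edges)
        for blk in blocks:
            blk = blk[aa[blk] > 0]
            if len(blk) == 0:
                continue
            d = bb[blk] - aa[blk]
            total += _interval_event_count(np.clip(d, 0, None))
            total += _interval_event_count(np.clip(-d, 0, None))
    return total


def distance_matrix(
    profiles: np.ndarray, chrom: np.ndarray | None = None,
) -> np.ndarray:
    """Pairwise event distances between cells x bins integer profiles.
    Unreachable pairs are inf; the matrix is symmetrized with
    max(d(a,b), d(b,a)) so zero-loss asymmetries stay conservative."""
    n = profiles.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij = event_distance(profiles[i], profiles[j], chrom)
            dji = event_distance(profiles[j], profiles[i], chrom)
            D[i, j] = D[j, i] = max(dij, dji)
    return D


# ---------------------------------------------------------------------------
# tree and clones
# ---------------------------------------------------------------------------

def build_tree(D: np.ndarray, ids: list[str]):
    """Neighbor-joining tree (scikit-bio); negative branch lengths clamped
    to zero. For n < 3 a trivial star tree is returned with a warning."""
    D = np.asarray(D, dtype=float)
    finite_max = np.nanmax(np.where(np.isfinite(D), D, np.nan))
    D = np.where(np.isfinite(D), D, 2 * finite_max + 1)
    if len(ids) < 3:
        warnings.warn("fewer than 3 leaves: returning trivial tree")
        from skbio import TreeNode
        if len(ids) == 1:
            return TreeNode.read([f"({ids[0]}:0.0);"])
        d = D[0, 1] / 2
        return TreeNode.read([f"({ids[0]}:{d},{ids[1]}:{d});"])
    dm = DistanceMatrix(D, ids)
    return nj(dm, neg_as_zero=True)


def cluster_clones(
    D: np.ndarray,
    ids: list[str] | pd.Index,
    cfg: CloneConfig | None = None,
) -> pd.Series:
    """Complete-linkage clustering cut so every within-cluster pairwise
    distance is <= t; clusters below min_clone_size get the noise label -1.

    Clone labels are integers 0..k-1 ordered by decreasing clone size.
    """
    cfg = cfg or CloneConfig()
    D = np.asarray(D, dtype=float)
    n = len(ids)
    if n == 0:
        return pd.Series(dtype=np.int64)
    if np.any(np.isinf(D)):
        finite_max = D[np.isfinite(D)].max() if np.isfinite(D).any() else 1.0
        D = np.where(np.isinf(D), finite_max + 2 * cfg.t + 1, D)
    if n == 1:
        labels = np.array([0])
    else:
        Z = linkage(squareform(D, checks=False), method="complete")
        labels = fcluster(Z, t=cfg.t, criterion="distance") - 1
    # enforce the max-distance guarantee
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if len(members) > 1:
            sub = D[np.ix_(members, members)]
            assert sub.max() <= cfg.t + 1e-9, "max-distance guarantee violated"
    out = np.full(n, -1, dtype=np.int64)
    sizes = pd.Series(labels).value_counts()
    keep = [lab for lab in sizes.index if sizes[lab] >= cfg.min_clone_size]
    for new, lab in enumerate(keep):
        out[labels == lab] = new
    return pd.Series(out, index=pd.Index(ids, name="cell"), name="clone")


def refine_clones(
    profiles: np.ndarray,
    labels: pd.Series,
    chrom: np.ndarray | None = None,
    cfg: CloneConfig | None = None,
    n_iter: int = 2,
) -> pd.Series:
    """Refine clone assignments against clone median profiles.

    Complete-linkage clustering requires every *pair* of cells to be within
    ``t``, so a cell with a couple of private miscalled segments can be
    ejected even though it is close to its clone's consensus. This pass
    recomputes each clone's median integer profile and reassigns every cell
    to the nearest median when that distance is at most ``t`` (noise
    otherwise), iterating a few times; clones falling below
    ``min_clone_size`` are dissolved. Labels keep the size-ordered 0..k-1
    convention with -1 for noise.
    """
    cfg = cfg or CloneConfig()
    labels = labels.copy()
    for _ in range(n_iter):
        clone_ids = sorted(set(labels.values) - {-1})
        if not clone_ids:
            break
        medians = {k: clone_profile(profiles[labels.values == k])
                   for k in clone_ids}
        new = np.full(len(labels), -1, dtype=np.int64)
        for i in range(len(labels)):
            best, best_d = -1, np.inf
            for k, med in medians.items():
                d = event_distance(profiles[i], med, chrom)
                dr = event_distance(med, profiles[i], chrom)
                d = max(d, dr)
                if d < best_d:
                    best, best_d = k, d
            if best_d <= cfg.t:
                new[i] = best
        labels = pd.Series(new, index=labels.index, name=labels.name)
        sizes = labels.value_counts()
        for k in sizes.index:
            if k != -1 and sizes[k] < cfg.min_clone_size:
                labels[labels == k] = -1
    # relabel by decreasing size
    out = np.full(len(labels), -1, dtype=np.int64)
    sizes = labels[labels >= 0].value_counts()
    for new_id, k in enumerate(sizes.index):
        out[labels.values == k] = new_id
    return pd.Series(out, index=labels.index, name=labels.name)


def clone_profile(cn_matrix: np.ndarray) -> np.ndarray:
    """Per-bin median integer profile of a clone (.5 ties rounded down)."""
    cn_matrix = np.atleast_2d(cn_matrix)
    if cn_matrix.shape[0] == 0:
        raise ValueError("empty clone")
    med = np.median(cn_matrix, axis=0)
    return np.floor(med).astype(np.int64)


def annotate_genes(
    profile: np.ndarray,
    bins: pd.DataFrame,
    genes: pd.DataFrame,
    sex: str = "male",
) -> pd.DataFrame:
    """Per-gene status from a clone median profile.

    A gene is deleted iff every overlapping bin is below its expected copy
    number, amplified iff every one is above; anything else (including genes
    straddling an event boundary) is neutral. Genes outside the binned
    genome are skipped with a warning. ``genes`` has columns gene, chrom,
    start, end and optionally role (e.g. TSG).
    """
    exp = expected_cn(bins["chrom"].values, sex)
    rows = []
    for _, g in genes.iterrows():
        sel = ((bins["chrom"] == g["chrom"])
               & (bins["end"] > g["start"])
               & (bins["start"] < g["end"])).values
        if not sel.any():
            warnings.warn(f"gene {g['gene']} outside binned genome; skipped")
            continue
        cn_g = profile[sel]
        exp_g = exp[sel]
        if np.all(cn_g < exp_g):
            status = "deleted"
        elif np.all(cn_g > exp_g):
            status = "amplified"
        else:
            status = "neutral"
        rows.append({"gene": g["gene"], "status": status,
                     "role": g.get("role", "")})
    return pd.DataFrame(rows, columns=["gene", "status", "role"])


def oncoprint_matrix(
    clone_profiles: dict[int, np.ndarray],
    bins: pd.DataFrame,
    genes: pd.DataFrame,
    sex: str = "male",
) -> pd.DataFrame:
    """Genes x clones status matrix for OncoPrint-style plotting."""
    cols = {}
    for clone, prof in clone_profiles.items():
        ann = annotate_genes(prof, bins, genes, sex=sex)
        cols[clone] = ann.set_index("gene")["status"]
    return pd.DataFrame(cols)
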