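"""Synthetic single-cell copy-number cohorts with machine-readable ground truth.

The generator emulates the statistical structure a MALBAC-style single-cell
CNV experiment produces: ~500 kb genomic bins with smoothly varying GC and
mappability, a cohort mixing flat diploid cells, pseudo-diploid cells
carrying a handful of clonal (sub-)arm deletions, highly aneuploid cells
with independent whole-chromosome gains/losses, and a fraction of noisy
low-quality profiles. Bin counts follow a negative-binomial model whose
expectation is library_size x (CN/2) x mappability x gc_bias(gc). Clones are
placed on a rectangular region grid with a tunable spatial spread spanning
fully-localized to uniform, so spatial-entropy recovery can be tested
against truth.

Also provides generators for barcoded FASTQ reads (UMI + cell barcode +
restriction-site anchor + insert) and for three-probe FISH field-of-view
dot counts with a known deleted-cell fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the reference study conditions: a 10-chromosome
    toy genome of 100 x 500 kb bins per chromosome, a 4x4 region grid,
    karyotype mix of 41% diploid / 25% pseudo-diploid / 14% aneuploid /
    20% low-quality, eight pseudo-diploid clones each carrying 1-7
    contiguous (sub-)arm events, and MALBAC-like overdispersed counts
    (var = mu + nb_dispersion * mu^2) at 800k reads per cell.
    """

    n_chrom: int = 10
    bins_per_chrom: int = 100
    bin_length_bp: int = 500_000
    n_regions_rows: int = 4
    n_regions_cols: int = 4
    n_cells_per_region: int = 40
    frac_diploid: float = 0.41
    frac_pseudo: float = 0.25
    frac_aneuploid: float = 0.14
    frac_lowquality: float = 0.20
    n_clones: int = 8
    clone_n_events: tuple[int, int] = (1, 7)
    clone_event_bins: tuple[int, int] = (6, 40)
    min_clone_separation: int = 6
    aneuploid_n_chrom_events: tuple[int, int] = (4, 10)
    amp_event_prob: float = 0.1
    gc_bias_strength: float = 0.6
    nb_dispersion: float = 0.08
    reads_per_cell_mean: int = 800_000
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_chrom": self.n_chrom,
            "bins_per_chrom": self.bins_per_chrom,
            "bin_length_bp": self.bin_length_bp,
            "n_regions_rows": self.n_regions_rows,
            "n_regions_cols": self.n_regions_cols,
            "n_cells_per_region": self.n_cells_per_region,
            "n_clones": self.n_clones,
            "reads_per_cell_mean": self.reads_per_cell_mean,
        }
        for name, value in counts.items():
            if int(value) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {value}")
        fracs = (self.frac_diploid, self.frac_pseudo, self.frac_aneuploid,
                 self.frac_lowquality)
        if any(f < 0 for f in fracs):
            raise ConfigurationError("karyotype fractions must be >= 0")
        if sum(fracs) > 1 + 1e-9:
            raise ConfigurationError("karyotype fractions must sum to <= 1")
        for name, rng in (("clone_n_events", self.clone_n_events),
                          ("clone_event_bins", self.clone_event_bins),
                          ("aneuploid_n_chrom_events", self.aneuploid_n_chrom_events)):
            lo, hi = rng
            if lo < 1 or hi < lo:
                raise ConfigurationError(f"invalid range for {name}: {rng}")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")

    @property
    def n_regions(self) -> int:
        return self.n_regions_rows * self.n_regions_cols

    @property
    def n_bins(self) -> int:
        return self.n_chrom * self.bins_per_chrom


@dataclass
class TruthSet:
    """Ground truth of a simulated cohort, one entry per cell in each map."""

    cell_clone: pd.Series          # cell id -> clone id (-1 for none)
    cell_karyotype: pd.Series      # cell id -> diploid|pseudo-diploid|aneuploid|lowquality
    clone_cn: dict[int, np.ndarray]
    cell_cn: pd.DataFrame          # cells x bins integer CN (pre-noise truth)
    cell_region: pd.Series         # cell id -> region id
    region_label: pd.Series        # region id -> TRR|FER|NOR
    clone_region_weights: pd.DataFrame  # clones x regions placement probabilities


@dataclass
class CellMatrix:
    """Cells x bins integer read counts plus cell metadata and bin reference."""

    counts: np.ndarray
    cell_meta: pd.DataFrame        # index cell id; columns sample, region
    bin_ref: pd.DataFrame

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index


@dataclass
class SpatialCohort:
    """Region grid with histopathology-style labels and per-clone counts."""

    regions: pd.DataFrame          # index region id; row, col, label, qc_total
    clone_counts: pd.DataFrame     # clones x regions cell counts


# ---------------------------------------------------------------------------
# reference genome / bins
# ---------------------------------------------------------------------------

def _smooth_series(rng: np.random.Generator, n: int, window: int = 15) -> np.ndarray:
    """Standardized moving-average-smoothed Gaussian noise (a cheap smooth
    spatial process)."""
    raw = rng.normal(size=n + window)
    kernel = np.ones(window) / window
    sm = np.convolve(raw, kernel, mode="valid")[:n]
    sd = sm.std()
    if sd == 0:
        return np.zeros(n)
    return (sm - sm.mean()) / sd


def generate_reference(cfg: SimConfig) -> pd.DataFrame:
    """Build the bin annotation table: ordered 0-based half-open bins with
    smooth GC (centered ~0.42, human-like) and high mappability."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        gc = 0.42 + 0.06 * _smooth_series(rng, cfg.bins_per_chrom)
        gc = np.clip(gc, 0.25, 0.65)
        mapp = 0.92 + 0.05 * _smooth_series(rng, cfg.bins_per_chrom)
        mapp = np.clip(mapp, 0.55, 1.0)
        starts = np.arange(cfg.bins_per_chrom, dtype=np.int64) * cfg.bin_length_bp
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": starts + cfg.bin_length_bp,
            "gc": gc,
            "mappability": mapp,
            "blacklisted": False,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def gc_bias_curve(gc: np.ndarray, strength: float) -> np.ndarray:
    """Multiplicative amplification-bias bump.

    g(gc) = 1 + beta*(gc - 0.5) - gamma*(gc - 0.5)^2 with gamma = 2*beta,
    clipped at 0.1: smooth and recoverable by LOWESS, mimicking WGA GC bias.
    """
    beta = strength
    gamma = 2.0 * strength
    d = gc - 0.5
    return np.clip(1.0 + beta * d - gamma * d * d, 0.1, None)


def _uniform_mixture_weights(home: int, n_regions: int, lam: float) -> np.ndarray:
    """Placement weights: (1-lam)*delta_home + lam*uniform."""
    w = np.full(n_regions, lam / n_regions)
    w[home] += 1.0 - lam
    return w


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _solve_lambda_for_entropy(target_h: float, home: int, n_regions: int) -> float:
    """Bisect the delta/uniform mixing weight so placement entropy hits
    target_h bits (entropy is monotone increasing in lam)."""
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        h = _entropy_bits(_uniform_mixture_weights(home, n_regions, mid))
        if h < target_h:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def clone_placement_weights(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-clone region placement probabilities spanning the entropy spectrum
    [0, log2(R)] evenly across clones."""
    n_r = cfg.n_regions
    max_h = math.log2(n_r)
    targets = (np.linspace(0.0, max_h, cfg.n_clones) if cfg.n_clones > 1
               else np.array([0.0]))
    homes = rng.integers(0, n_r, size=cfg.n_clones)
    weights = np.empty((cfg.n_clones, n_r))
    for k in range(cfg.n_clones):
        lam = _solve_lambda_for_entropy(targets[k], int(homes[k]), n_r)
        weights[k] = _uniform_mixture_weights(int(homes[k]), n_r, lam)
    return pd.DataFrame(weights,
                        index=[f"clone{k}" for k in range(cfg.n_clones)],
                        columns=np.arange(n_r))


def _draw_clone_profiles(cfg: SimConfig, rng: np.random.Generator) -> dict[int, np.ndarray]:
    """Pseudo-diploid clone profiles: 1-7 contiguous (sub-)arm events,
    monoallelic deletions (CN 1) with rare single-copy gains (CN 3).

    Clones are redrawn until every pair is at least
    ``min_clone_separation`` segmental events apart, so the ground-truth
    clone labels are identifiable by clustering at the default threshold.
    """
    from .clonal import event_distance

    chrom_labels = np.repeat(np.arange(cfg.n_chrom), cfg.bins_per_chrom)
    profiles: dict[int, np.ndarray] = {}
    for k in range(cfg.n_clones):
        for _ in range(200):
            cn = np.full(cfg.n_bins, 2, dtype=np.int64)
            n_ev = int(rng.integers(cfg.clone_n_events[0],
                                    cfg.clone_n_events[1] + 1))
            for _ in range(n_ev):
                chrom = int(rng.integers(cfg.n_chrom))
                length = int(rng.integers(
                    cfg.clone_event_bins[0],
                    min(cfg.clone_event_bins[1], cfg.bins_per_chrom) + 1))
                start = int(rng.integers(0, cfg.bins_per_chrom - length + 1))
                lo = chrom * cfg.bins_per_chrom + start
                state = 3 if rng.random() < cfg.amp_event_prob else 1
                cn[lo:lo + length] = state
            if all(event_distance(cn, other, chrom_labels)
                   >= cfg.min_clone_separation for other in profiles.values()):
                break
        profiles[k] = cn
    return profiles


def _draw_aneuploid_profile(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Whole-chromosome gains/losses ('hopeful monster' karyotype)."""
    cn = np.full(cfg.n_bins, 2, dtype=np.int64)
    lo, hi = cfg.aneuploid_n_chrom_events
    lo = min(lo, cfg.n_chrom)
    hi = min(hi, cfg.n_chrom)
    n_ev = int(rng.integers(lo, hi + 1))
    chroms = rng.choice(cfg.n_chrom, size=n_ev, replace=False)
    for chrom in chroms:
        state = int(rng.choice([1, 3, 4], p=[0.5, 0.35, 0.15]))
        sl = slice(chrom * cfg.bins_per_chrom, (chrom + 1) * cfg.bins_per_chrom)
        cn[sl] = state
    return cn


def _ar1(rng: np.random.Generator, n: int, rho: float, sigma: float) -> np.ndarray:
    innov = rng.normal(scale=sigma * math.sqrt(1 - rho * rho), size=n)
    out = np.empty(n)
    prev = rng.normal(scale=sigma)
    for i in range(n):
        prev = rho * prev + innov[i]
        out[i] = prev
    return out


def generate_cohort(
    cfg: SimConfig, bins: pd.DataFrame,
    clone_cn: dict[int, np.ndarray] | None = None,
) -> tuple[CellMatrix, TruthSet, SpatialCohort]:
    """Simulate the cell cohort on the given bins.

    ``clone_cn`` optionally fixes the pseudo-diploid clone profiles (clone
    index -> integer CN per bin) instead of drawing them at random, e.g. to
    plant one specific deletion.

    Expected per-cell counts are library_size x (CN/2) x mappability x
    gc_bias(gc), renormalized so each cell's expected total equals
    ``reads_per_cell_mean``; counts are negative-binomial with
    var = mu + nb_dispersion * mu^2. Low-quality cells receive multiplicative
    AR(1) (rho=0.8) noise plus 2-6 random level shifts, which defeats
    segmentation the way rejected cells do.
    """
    cfg.validate()
    if len(bins) != cfg.n_bins:
        raise ConfigurationError("bins do not match cfg dimensions")
    n_cells = cfg.n_regions * cfg.n_cells_per_region
    if n_cells < 1:
        raise ConfigurationError("zero cells requested")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    if clone_cn is None:
        clone_cn = _draw_clone_profiles(cfg, rng)
    else:
        if set(clone_cn) != set(range(cfg.n_clones)):
            raise ConfigurationError("clone_cn must cover clones 0..n_clones-1")
        clone_cn = {k: np.asarray(v, dtype=np.int64) for k, v in clone_cn.items()}
        for k, v in clone_cn.items():
            if len(v) != cfg.n_bins or np.any(v < 0):
                raise ConfigurationError("invalid clone_cn profile")
    weights = clone_placement_weights(cfg, rng)

    karyos = np.array(["diploid", "pseudo-diploid", "aneuploid", "lowquality"])
    probs = np.array([cfg.frac_diploid, cfg.frac_pseudo, cfg.frac_aneuploid,
                      cfg.frac_lowquality], dtype=float)
    leftover = 1.0 - probs.sum()
    if leftover > 1e-9:
        probs[3] += leftover  # remainder counts as low-quality
    probs = probs / probs.sum()
    cell_karyo = rng.choice(karyos, size=n_cells, p=probs)

    cell_ids = pd.Index([f"cell{i:05d}" for i in range(n_cells)], name="cell")
    cell_clone = np.full(n_cells, -1, dtype=np.int64)
    cell_region = np.empty(n_cells, dtype=np.int64)
    cn_matrix = np.tile(np.full(cfg.n_bins, 2, dtype=np.int64), (n_cells, 1))

    for i in range(n_cells):
        k = cell_karyo[i]
        if k == "pseudo-diploid":
            clone = int(rng.integers(cfg.n_clones))
            cell_clone[i] = clone
            cn_matrix[i] = clone_cn[clone]
            cell_region[i] = rng.choice(cfg.n_regions, p=weights.iloc[clone].values)
        else:
            if k == "aneuploid":
                cn_matrix[i] = _draw_aneuploid_profile(cfg, rng)
            cell_region[i] = rng.integers(cfg.n_regions)

    # expected counts and NB sampling
    gc_bias = gc_bias_curve(bins["gc"].values, cfg.gc_bias_strength)
    base = bins["mappability"].values * gc_bias
    counts = np.empty((n_cells, cfg.n_bins), dtype=np.int64)
    for i in range(n_cells):
        w = (cn_matrix[i] / 2.0) * base
        if cell_karyo[i] == "lowquality":
            w = w * np.exp(_ar1(rng, cfg.n_bins, rho=0.8, sigma=0.5))
            for _ in range(int(rng.integers(2, 7))):
                a = int(rng.integers(cfg.n_bins))
                b = min(cfg.n_bins, a + int(rng.integers(10, cfg.n_bins // 2)))
                w[a:b] *= float(rng.choice([0.5, 0.67, 1.5, 2.0]))
        mu = cfg.reads_per_cell_mean * w / w.sum()
        if cfg.nb_dispersion > 0:
            size = 1.0 / cfg.nb_dispersion
            counts[i] = rng.negative_binomial(size, size / (size + mu))
        else:
            counts[i] = rng.poisson(mu)

    cell_meta = pd.DataFrame({"sample": "sim", "region": cell_region},
                             index=cell_ids)
    matrix = CellMatrix(counts=counts, cell_meta=cell_meta, bin_ref=bins)

    # region bookkeeping: labels follow histopathology-style thresholds on the
    # fraction of clone-member (tumor) cells per region
    regions = pd.DataFrame({
        "row": np.repeat(np.arange(cfg.n_regions_rows), cfg.n_regions_cols),
        "col": np.tile(np.arange(cfg.n_regions_cols), cfg.n_regions_rows),
    }, index=pd.RangeIndex(cfg.n_regions, name="region"))
    tumor_frac = np.zeros(cfg.n_regions)
    qc_total = np.zeros(cfg.n_regions, dtype=np.int64)
    for r in range(cfg.n_regions):
        in_r = cell_region == r
        n_r = int(in_r.sum())
        if n_r:
            tumor_frac[r] = (cell_clone[in_r] >= 0).mean()
        qc_total[r] = int((in_r & (cell_karyo != "lowquality")).sum())
    label = np.where(tumor_frac > 0.5, "TRR",
                     np.where(tumor_frac >= 0.1, "FER", "NOR"))
    regions["label"] = label
    regions["qc_total"] = qc_total

    clone_counts = pd.DataFrame(
        0, index=weights.index, columns=np.arange(cfg.n_regions))
    for i in range(n_cells):
        if cell_clone[i] >= 0:
            clone_counts.iloc[cell_clone[i], cell_region[i]] += 1

    truth = TruthSet(
        cell_clone=pd.Series(cell_clone, index=cell_ids),
        cell_karyotype=pd.Series(cell_karyo, index=cell_ids),
        clone_cn=clone_cn,
        cell_cn=pd.DataFrame(cn_matrix, index=cell_ids),
        cell_region=pd.Series(cell_region, index=cell_ids),
        region_label=regions["label"].copy(),
        clone_region_weights=weights,
    )
    spatial = SpatialCohort(regions=regions, clone_counts=clone_counts)
    return matrix, truth, spatial


# ---------------------------------------------------------------------------
# FASTQ reads
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_fastq(
    barcodes: Sequence[str],
    layout: "object" = None,
    n_reads: int = 1000,
    error_rate: float = 0.0,
    seed: int = 0,
    umi_len: int = 8,
    anchor: str = "CATG",
    insert_len: int = 30,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate barcoded reads: UMI + cell barcode + anchor + random insert.

    Per-base substitution errors at ``error_rate`` are applied to the whole
    read. Returns FASTQ records as (name, sequence, quality) tuples plus a
    truth table recording each read's intended barcode.

    ``layout`` may be a :class:`scnapipe.demux.ReadLayout`; if given, its
    UMI/barcode lengths and anchor override the keyword defaults.
    """
    if len(set(barcodes)) != len(barcodes):
        raise ConfigurationError("duplicate barcodes")
    if not barcodes:
        raise ConfigurationError("empty barcode list")
    bc_len = len(barcodes[0])
    if any(len(b) != bc_len for b in barcodes):
        raise ConfigurationError("barcodes must have equal length")
    if layout is not None:
        umi_len = layout.umi_len
        anchor = layout.anchor_seq
        if layout.bc_len != bc_len:
            raise ConfigurationError("layout bc_len does not match barcodes")
    rng = np.random.default_rng(seed)

    bc_idx = rng.integers(len(barcodes), size=n_reads)
    read_len = umi_len + bc_len + len(anchor) + insert_len
    seqs = np.empty((n_reads, read_len), dtype=np.uint8)
    umis = _BASES[rng.integers(4, size=(n_reads, umi_len))]
    seqs[:, :umi_len] = umis
    bc_arr = np.frombuffer("".join(barcodes).encode(), dtype=np.uint8).reshape(
        len(barcodes), bc_len)
    seqs[:, umi_len:umi_len + bc_len] = bc_arr[bc_idx]
    if anchor:
        seqs[:, umi_len + bc_len:umi_len + bc_len + len(anchor)] = np.frombuffer(
            anchor.encode(), dtype=np.uint8)
    seqs[:, umi_len + bc_len + len(anchor):] = _BASES[
        rng.integers(4, size=(n_reads, insert_len))]

    if error_rate > 0:
        hit = rng.random((n_reads, read_len)) < error_rate
        # substitute with one of the three other bases
        shift = rng.integers(1, 4, size=hit.sum())
        base_i = np.searchsorted(_BASES, seqs[hit])
        seqs[hit] = _BASES[(base_i + shift) % 4]

    qual = "I" * read_len
    records = []
    for i in range(n_reads):
        records.append((f"read{i}", seqs[i].tobytes().decode(), qual))
    truth = pd.DataFrame({
        "read": [r[0] for r in records],
        "barcode": [barcodes[j] for j in bc_idx],
        "umi": ["".join(map(chr, umis[i])) for i in range(n_reads)],
    })
    return records, truth


def write_fastq(records: Sequence[tuple[str, str, str]], path) -> None:
    """Write (name, seq, qual) records as plain 4-line phred33 FASTQ."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# FISH fields of view
# ---------------------------------------------------------------------------

def generate_fish_fovs(
    n_fov: int,
    true_del_fraction: Sequence[float] | float,
    dots_per_fov: int = 2000,
    detection_eff: float = 0.9,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate three-probe FISH dot counts per field of view.

    Each FOV holds ``dots_per_fov / 2`` nuclei with two target copies each.
    Upstream/downstream probes see all 2n targets; the deletion probe misses
    one copy in each deleted cell, i.e. a fraction ``f/2`` of targets.
    Counts are binomial thinned by ``detection_eff``. The true deleted-cell
    fraction doubles as the annotated tumor-area fraction, emulating FOVs
    where deletion carriers are the tumor cells.
    """
    f = np.broadcast_to(np.asarray(true_del_fraction, dtype=float), (n_fov,)).copy()
    if np.any((f < 0) | (f > 1)):
        raise ConfigurationError("true_del_fraction must be in [0, 1]")
    if not 0 < detection_eff <= 1:
        raise ConfigurationError("detection_eff must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_nuclei = dots_per_fov // 2
    targets = 2 * n_nuclei
    del_targets = np.round(targets * (1 - f / 2)).astype(np.int64)
    df = pd.DataFrame({
        "fov": [f"fov{i:03d}" for i in range(n_fov)],
        "dots_up": rng.binomial(targets, detection_eff, size=n_fov),
        "dots_del": rng.binomial(del_targets, detection_eff),
        "dots_down": rng.binomial(targets, detection_eff, size=n_fov),
        "tumor_area_fraction": f,
        "true_del_fraction": f,
    })
    return df
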