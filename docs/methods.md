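# Methods

`scnapipe` implements a complete single-cell somatic copy-number (SCNA)
analysis chain of the kind used for multi-region tumor profiling with
barcoded, whole-genome-amplified single-nucleus libraries, together with a
synthetic-data generator that reproduces the statistical structure such
experiments produce. This note documents the models, the parameters that
matter, and the design decisions taken where more than one reasonable
choice existed.

## The synthetic cohort model (`simgen`)

The generator emulates a prostate-style multi-region experiment: a tissue
midsection cut into a rectangular grid of regions, each contributing a few
dozen nuclei, with four cell populations:

* **diploid** cells — flat CN 2 profiles;
* **pseudo-diploid** cells — members of one of `n_clones` clones, each
  clone carrying 1–7 contiguous (sub-)chromosome-arm events of 6–40 bins,
  monoallelic deletions (CN 1) with a 10% chance of a single-copy gain
  (CN 3);
* **aneuploid** cells ("hopeful monsters") — 4–10 independent
  whole-chromosome gains/losses, no clone membership;
* **low-quality** cells — diploid expectation distorted by multiplicative
  AR(1) noise (ρ = 0.8, σ = 0.5 on the log scale) plus 2–6 random level
  shifts. This is a stand-in: the mechanism behind real rejected profiles
  (many are S-phase cells) is not modeled, only their effect of defeating
  segmentation.

Default karyotype mix: 41% diploid, 25% pseudo-diploid, 14% aneuploid,
20% low-quality, matching the reported prevalence of pseudo-diploid
(~23–28%) and aneuploid (~13–16%) cells in early prostate tumors.

Counts follow a negative-binomial model per bin:
`E[c_j] = L · (CN_j / 2) · mappability_j · g(gc_j)`, renormalized so each
cell's expected total is `L = reads_per_cell_mean` (default 800 000, the
depth bulk metrics are computed at), with `Var[c] = μ + d·μ²` and
`d = nb_dispersion = 0.08` (per-bin CV ≈ 28% at default depth,
MALBAC-like overdispersion). The GC bias is a smooth multiplicative bump
`g(gc) = 1 + β(gc−0.5) − 2β(gc−0.5)²` clipped at 0.1 (β = 0.6), recoverable
by LOWESS.

The toy genome is 10 chromosomes × 100 bins × 500 kb. Chromosome-scale GC
and mappability are smoothed Gaussian processes (GC centered near 0.42,
mappability near 0.92), so bin-level biases are spatially correlated as in
real data. The generator does not simulate base-level sequence, realistic
chromosome sizes, or quality scores — its purpose is to give every
downstream stage inputs with the right statistical structure and a
machine-readable truth.

**Clone identifiability.** Clone profiles are rejection-sampled so every
pair of clones is at least `min_clone_separation = 6` segmental events
apart — twice the default clustering threshold. Without this the truth
labels can be unidentifiable in principle (two clones closer than the
threshold must merge under max-linkage), and clone-recovery scores would
measure luck rather than method quality.

**Spatial placement.** Each clone's regional distribution is a
`(1−λ)·δ(home) + λ·uniform` mixture, with λ solved by bisection so the
clones' placement entropies tile `[0, log2 R]` evenly. Region labels follow
histopathology-style thresholds on the simulated tumor-cell (clone-member)
fraction: >50% TRR, 10–50% FER, otherwise NOR.

What passing tests on this cohort do **not** show: robustness to real
amplification artifacts (chimeras, allelic dropout structure), to
mappability tracks estimated from alignment, or to doublets — none of
these are modeled.

## Demultiplexing (`demux`)

Inline barcodes are matched with a mismatch budget (2 for 384-adapter
sets, 1 for 96-adapter sets). A read is assigned to the unique barcode at
minimal Hamming distance within the budget; ties are left unassigned (the
conservative choice for cell purity), `N` counts as a mismatch against
everything, and the UMI is carried verbatim into the read name as
`_{barcode}_{umi}`. Assignment is verified read-for-read against an
exhaustive nearest-neighbor scan in the tests.

## Binning and metrics (`bins`)

Variable-width bins are built by greedy accumulation of mappable mass over
track windows until each bin holds `target_len × genome-mean mappability`;
the last bin per chromosome absorbs the remainder and is flagged.
Blacklisted intervals flag bins overlapping them by more than half the bin
length (`max_overlap = 0.5`). Coordinates are 0-based half-open
throughout. Downsampling is exact multivariate hypergeometric.
Overdispersion is the index of dispersion var/mean with population
variance — the plain reading of "variance normalized by the mean"; the
choice is documented because sample variance would differ at small n.

## Normalization and segmentation (`normseg`)

Per cell: counts are scaled to unit mappability (a no-op on true
equal-mappable-mass bins, required on fixed-length simulated bins), divided
by the cell mean, log2-transformed with pseudo-count `1/(2·mean)`, and
GC-corrected by subtracting a LOWESS fit (span 0.3, 2 robustness
iterations) of log-ratio on GC. The LOWESS is fit only on bins within
2.5 MAD of the modal level so copy-number events cannot drag the
correction — fitting on all bins measurably blurs event boundaries.

Two segmenters are provided:

* **CBS** — recursive max-|t| arc search with a sequential permutation
  test (α = 0.01, up to 10 000 permutations). Permutations stop early once
  the decision is settled in either direction (exceedances already push
  p above α, or the Clopper–Pearson 99.9% upper bound on p falls below α);
  decisions agree with the full permutation count with high probability.
  Ties in the arc scan break toward the leftmost arc. The first split is
  pinned to an exhaustive arc-scan oracle in the tests.
* **Exact penalized least squares** — optimal-partitioning dynamic
  programming minimizing `Σ_cells SSE + γ·(#breakpoints)` with shared
  breakpoints across cells; exact (verified against exhaustive partition
  search at ≤ 20 bins). With one cell this is single-sample optimal
  partitioning and is the pipeline's per-cell default: deterministic and
  two orders of magnitude faster than CBS.

The γ default of the joint API is 40; the pipeline instead derives a
per-cell γ = 2·σ̂²·ln(n_bins) with σ̂ from the MAD of lag-1 differences
(BIC-style). The constant 2 was calibrated on default synthetic cohorts as
the best trade-off between detecting 6-bin single-copy gains
(Δlog2 ≈ 0.58) and suppressing spurious breakpoints; values 3–4 miss a
fraction of small gains, values ≤ 1.5 fragment noisy cells. Breakpoints
are located on MAD-winsorized values (running-median window 11, clamp at
2.5 scaled MADs); segment means are always recomputed from the raw
profile, so the invariant "segment mean = arithmetic mean of member bins"
holds exactly.

Adjacent segments that are not significantly distinct are merged
iteratively (largest Wilcoxon rank-sum p first, while p ≥ 0.01). This is a
simplification of the aCGH `mergeLevels` ladder; its behavior is pinned by
tests rather than by equivalence to the R implementation.

## Integer copy numbers (`cncall`)

Segmented linear ratios (recentered to weighted mean 1) are scaled by each
candidate ploidy on the 1.7–6.0 grid in 0.01 steps (purity 1 for single
cells) and scored by the length-weighted squared distance of scaled means
to the nearest integers; the lowest-error ploidy wins. Exact ties break
toward ploidy 2, then the smaller value — a flat profile is otherwise
ill-posed across integer multiples. Copy numbers are floored at 0 and
capped at 20. The search is pinned to a plain-loop grid oracle.

Known limitation: a cell whose only events are small single-copy gains on
an otherwise flat genome can lock onto a doubled ploidy when segment-mean
noise happens to favor it (≈1–2% of diploid-rooted cells at default
dispersion). This is inherent to the exact argmin objective; a general
purity path (`purity < 1`) is implemented but not exercised by the
synthetic conditions.

## Profile QC (`qc`)

Sixteen features per cell (total reads; overdispersion; MAPD; lag-1
autocorrelation; residual SD around segment means; segment count; mean
segment length; fraction of genome altered; CN-state entropy; max and min
CN; fraction of zero-count bins; Gini of counts; within/between segment
variance ratio; grid-search fit error; fraction of bins >0.3 from their
segment mean). The feature list is this package's own frozen definition of
a profile-quality feature set; formulas live in `qc.compute_features` so
retraining is reproducible. A 500-tree random forest with class-balanced
bagging is trained on a stratified 80/20 split; the pass threshold is the
validation-ROC point maximizing Youden's J (closest-to-corner available by
option), and passing is inclusive at the threshold.

## Karyotypes, distances, clones (`clonal`)

The altered fraction is the length-weighted share of autosomes + chrX
where called CN differs from expectation (2 autosomes; chrX 2/1 for
female/male). Classes: 0 → diploid; ≤ 25% → pseudo-diploid (boundary
inclusive, configurable); > 25% → aneuploid.

The distance between integer profiles is the minimum number of segmental
events — ±1 over a contiguous bin interval, per chromosome, where no event
may touch a bin at CN 0 (zero is absorbing) — with a closed form: split
each chromosome at the source profile's zero bins; within each block the
cost is the total positive variation of the positive and negative parts of
the difference. Targets that are non-zero over a zero source bin are
unreachable (flagged infinite); matrices symmetrize unreachable asymmetry
with the max. The closed form is verified against a breadth-first-search
oracle (exhaustively for 3-bin profiles, randomized at 4–6 bins).

Trees are neighbor-joining (negative branch lengths clamped to 0). Clones
are complete-linkage clusters cut so every within-clone pairwise distance
is ≤ t (default 3 events, the threshold used for prostate samples;
min_clone_size = 5), followed by two refinement passes that reassign each
cell to the nearest clone *median profile* within t. The refinement exists
because the pairwise-max rule ejects a cell with a couple of private
miscalled segments even when it is one event from its clone's consensus.

Before distances, the pipeline re-segments all cells on
**consensus breakpoints**: per-cell breakpoints are pooled (±2 bins),
kept when supported by ≥ 4 cells, and thinned to a minimum 5-bin
separation; every cell is then re-called on the shared partition. Without
this, independent per-cell boundary wobble of ±1–2 bins inflates
within-clone distances past t. Equivalence with allele-aware event
distances (MEDICC-style tools) is *not* claimed; the acceptance standard
is truth recovery on synthetic cohorts (ARI ≥ 0.9 at defaults).

Clone median profiles round half-integer medians down; a gene is called
deleted/amplified only if **every** overlapping bin is below/above its
expected copy number — genes straddling an event boundary stay neutral.

## Spatial entropy (`spatial`)

For a clone with `n_r` cells in region r and `N_r` QC-passing cells there,
`p'_r = n_r/N_r`, normalized to `p`, and `H = −Σ p log2 p` (bits; 0·log 0
= 0). H is 0 for a fully localized clone, log2(R) for uniform spread, and
invariant to rescaling all QC totals. A region's mean entropy averages the
clones present in it (≥1 cell, no minimum — configurable); TRR/FER/NOR
groups are compared with the two-sided Wilcoxon rank-sum test, exact for
small groups.

## FISH quantification (`fish`)

Three probes (upstream, deletion, downstream) are counted per field of
view. The deletion probe's dot count relative to the downstream reference,
`N_del_dots`, converts to the deleted-cell fraction via the monoallelic
relation `N_cells = (1 − N_del_dots)/0.5`, clipped to [0, 1] with a logged
warning (detection noise can cross the bounds; clipping was chosen over
failure). The upstream fraction ≈ 1 is an internal control; FOVs deviating
by > 3 SD are flagged. The deleted fraction is correlated (Pearson) with
the annotated tumor-area fraction per FOV.

## Problem sizes and determinism

All randomness flows through explicit integer seeds; identical
configuration and seed give byte-identical outputs. The test suite runs
the full chain at these scales: 640 cells × 1000 bins for integer-CN and
clone recovery, 200 cells for the planted 14-bin deletion, 2000 cells
(300 bins) for QC training, 10⁵ reads for demultiplexing — sizes chosen so
each check completes in minutes on one CPU while keeping the statistical
structure of the full-scale analysis.
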