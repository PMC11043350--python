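# scnapipe

Single-cell somatic copy-number analysis for multi-region tumor profiling.

Shallow single-cell DNA sequencing of barcoded, whole-genome-amplified
nuclei yields a read-count matrix over ~500 kb genomic bins per cell.
`scnapipe` turns such data — or faithful synthetic stand-ins with known
ground truth — into integer copy-number profiles, karyotype classes,
QC-filtered cell sets, copy-number clones, spatial maps of clonal spread,
and FISH-based deletion quantification. It is aimed at method developers
and analysts who need a complete, testable reference chain for single-cell
SCNA calling in spatially sampled tissue (e.g., a prostate midsection cut
into a grid of regions).

## What it computes

* **Demultiplexing** — inline cell barcodes with a Hamming mismatch budget
  (2 for 384-adapter sets, 1 for 96-sets); UMIs carried in read names.
* **Binning** — variable-width bins of equal mappable mass, blacklist
  filtering, exact hypergeometric downsampling, breadth of coverage and
  overdispersion (var/mean).
* **Normalization** — library size, log2, LOWESS GC correction fit on
  modal-level bins; mappability scaling.
* **Segmentation** — circular binary segmentation (max-|t| arc +
  permutation test) and exact penalized-least-squares partitioning
  (`min Σ SSE + γ·#breakpoints`, single- or multi-sample, solved by
  dynamic programming).
* **Integer CN** — grid search over ploidy ψ ∈ [1.7, 6.0] (step 0.01,
  purity 1), minimizing the length-weighted rounding error
  `Σ_s w_s (ψ·r_s − round(ψ·r_s))²`; ties resolve toward ψ = 2.
* **QC** — 16 profile features and a 500-tree class-balanced random
  forest with a ROC-chosen pass threshold.
* **Karyotypes & clones** — altered-fraction classes (diploid /
  pseudo-diploid ≤ 25% / aneuploid > 25%), minimum-segmental-event
  distances between integer profiles (CN 0 unrecoverable),
  neighbor-joining trees, max-linkage clone cuts at distance t with
  median-profile refinement, and per-gene deletion/amplification calls.
* **Spatial entropy** — per clone, Shannon entropy (bits) of its
  QC-normalized regional distribution: `p'_r = n_r/N_r`,
  `H = −Σ p log2 p`; 0 = fully localized, log2(R) = uniform; region-group
  comparisons by two-sided Wilcoxon rank-sum.
* **FISH** — three-probe dot counts per field of view; the monoallelic
  conversion `N_cells,del = (1 − N_del,dots)/0.5` and the correlation of
  deleted-cell fraction with annotated tumor area.
* **Simulation** — cohorts with diploid / pseudo-diploid (clonal) /
  aneuploid / low-quality cells, negative-binomial counts with smooth GC
  bias, clones placed on a region grid across the full localization
  spectrum, barcoded FASTQ reads, and FISH dot counts — all with
  machine-readable truth.

See `docs/methods.md` for models, parameter defaults, and design
decisions.

## Worked example

Run the full synthetic pipeline from one config:

```sh
cat > example.yaml <<EOF
sim:
  n_chrom: 10
  bins_per_chrom: 100
  n_regions_rows: 2
  n_regions_cols: 3
  n_cells_per_region: 40
  n_clones: 3
clones:
  t: 3
  min_clone_size: 5
seed: 7
EOF
scna run --config example.yaml --out-dir demo/
```

This simulates 240 cells on a 10-chromosome × 100-bin (500 kb) genome over
a 2×3 region grid, calls copy numbers, trains and applies QC, clusters
pseudo-diploid cells into clones and scores their spatial spread. The
manifest reports, among others:

```
"qc": { "validation_auc": 1.0, "threshold": 0.91, "n_pass": 195 }
```

meaning the quality classifier separated good from low-quality profiles
perfectly on its validation split and passed 195/240 cells. The clone
table (`demo/clones.tsv`) classifies 89 cells diploid, 64 pseudo-diploid
and 87 aneuploid-or-noisy, and recovers three clones of 25, 24 and 15
cells; `demo/clone_entropy.tsv` reads

```
clone  H                   support
0      2.458954989819856   6
1      1.6564326776467622  6
2      0.0                 1
```

— clone 2 is fully localized to a single region (H = 0 bits) while clone 0
is spread nearly uniformly over all six regions (H close to
log2 6 ≈ 2.58 bits). Against the simulation's ground truth, the inferred
clone labels of pseudo-diploid cells reach an adjusted Rand index of 0.93.

Each stage is also available standalone (`scna sim|demux|bins|segment|
callcn|fish ...`), and everything in the CLI is importable:

```python
from scnapipe import fish
fish.deleted_fraction(0.75)   # -> 0.5
```

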