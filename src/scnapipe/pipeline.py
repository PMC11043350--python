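"""End-to-end orchestration of the single-cell copy-number workflow.

Stages (each writing a file-based artifact so it can be rerun standalone):
synthetic cohort generation -> per-cell normalization, segmentation and
level merging -> integer CN calling by ploidy grid search -> QC feature
computation and random-forest filtering -> karyotype classification ->
pseudo-diploid clone calling via event distances -> spatial clone entropy
-> optional FISH quantification. A JSON manifest records package version,
seeds and per-stage output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, clonal, cncall, fish, normseg, qc, simgen, spatial

logger = logging.getLogger(__name__)


def profile_cell(
    counts_row: np.ndarray,
    bins: pd.DataFrame,
    method: str = "dp",
    cbs_cfg: normseg.CBSConfig | None = None,
    gamma: float | None = None,
    merge_cfg: normseg.MergeConfig | None = None,
    grid_cfg: cncall.GridSearchConfig | None = None,
    gc_correct: bool = True,
):
    """Single-cell stage chain: normalize -> segment -> merge -> integer CN.

    ``method`` selects the segmenter: "dp" (per-cell exact penalized least
    squares, deterministic; gamma defaults to the BIC-style suggestion) or
    "cbs" (permutation-tested circular binary segmentation).
    Returns (RatioProfile, segments, CNProfile).
    """
    profile = normseg.normalize(counts_row, bins, gc_correct=gc_correct)
    if method == "cbs":
        segments = normseg.segment_cbs(profile, cbs_cfg)
    elif method == "dp":
        # breakpoints from MAD-winsorized values (outlier-robust), segment
        # means from the raw profile
        xw = normseg.winsorize(profile.log2)
        g = gamma if gamma is not None else normseg.suggest_gamma(xw)
        segments = normseg.segment_joint(
            xw[None, :], profile.chrom, normseg.JointSegConfig(gamma=g))[0]
        segments["mean"] = [
            profile.log2[int(s.start_bin):int(s.end_bin) + 1].mean()
            for s in segments.itertuples()]
    else:
        raise ValueError(f"unknown segmentation method: {method}")
    segments = normseg.merge_levels(segments, profile, merge_cfg)
    cn = cncall.call_integer_cn(segments, grid_cfg)
    return profile, segments, cn


def profile_cohort(
    matrix: simgen.CellMatrix,
    method: str = "dp",
    grid_cfg: cncall.GridSearchConfig | None = None,
    keep_intermediates: bool = False,
    **kwargs,
):
    """Run the per-cell stage chain over a whole cohort.

    Returns (features DataFrame, CN matrix cells x bins, per-cell summary
    DataFrame with ploidy/fit_error/n_segments); with
    ``keep_intermediates`` additionally a list of (RatioProfile, segments)
    per cell for downstream consensus re-segmentation.
    """
    feats, cns, summary, inter = [], [], [], []
    for i, cell in enumerate(matrix.cell_ids):
        row = matrix.counts[i]
        profile, segments, cnp = profile_cell(
            row, matrix.bin_ref, method=method, grid_cfg=grid_cfg, **kwargs)
        feats.append(qc.compute_features(row, profile, segments, cnp))
        cns.append(cnp.cn)
        summary.append({"cell": cell, "ploidy": cnp.chosen_ploidy,
                        "fit_error": cnp.fit_error,
                        "n_segments": len(segments)})
        if keep_intermediates:
            inter.append((profile, segments))
    features = pd.DataFrame(feats, index=matrix.cell_ids)
    cn_matrix = np.vstack(cns)
    out = (features, cn_matrix, pd.DataFrame(summary).set_index("cell"))
    return out + (inter,) if keep_intermediates else out


def consensus_breakpoints(
    seg_tables: list[pd.DataFrame],
    chrom: np.ndarray,
    min_support: int = 4,
    window: int = 2,
    min_gap: int = 5,
) -> list[int]:
    """Cohort-consensus breakpoints from per-cell segmentations.

    Per-cell breakpoint positions wobble by a bin or two around the true
    event boundary, which inflates pairwise event distances between cells of
    the same clone. Positions within ``window`` bins are pooled; pooled
    positions supported by at least ``min_support`` cells are kept (highest
    support first), each represented by its modal position. Breakpoints
    closer than ``min_gap`` bins to an already accepted one (or to a
    chromosome boundary) are dropped: the short segments they would create
    have noisy means whose copy-number rounding flips from cell to cell.
    Chromosome starts are implicit and never returned.
    """
    from collections import Counter

    votes: Counter = Counter()
    chrom = np.asarray(chrom)
    chrom_edges = {0, len(chrom)}
    for j in range(1, len(chrom)):
        if chrom[j] != chrom[j - 1]:
            chrom_edges.add(j)
    for seg in seg_tables:
        for start in seg["start_bin"].values:
            if int(start) not in chrom_edges:
                votes[int(start)] += 1
    candidates: list[tuple[int, int]] = []  # (support, position)
    remaining = dict(votes)
    while remaining:
        pos = max(remaining, key=lambda p: (remaining[p], -p))
        members = [p for p in remaining if abs(p - pos) <= window]
        support = sum(remaining[p] for p in members)
        for p in members:
            del remaining[p]
        if support >= min_support:
            candidates.append((support, pos))
    candidates.sort(key=lambda sp: (-sp[0], sp[1]))
    kept: list[int] = []
    for support, pos in candidates:
        near_edge = any(abs(pos - e) < min_gap for e in chrom_edges)
        near_kept = any(abs(pos - k) < min_gap for k in kept)
        if not near_edge and not near_kept:
            kept.append(pos)
    return sorted(kept)


def recall_on_breakpoints(
    profile: normseg.RatioProfile,
    breakpoints: list[int],
    grid_cfg: cncall.GridSearchConfig | None = None,
) -> cncall.CNProfile:
    """Re-segment one cell on a fixed shared breakpoint set and re-call CN.

    All cells re-called on the same set get identical segment boundaries, so
    event distances between clone mates reflect real differences only.
    """
    chrom = profile.chrom
    cuts = {0} | set(int(b) for b in breakpoints)
    for j in range(1, len(chrom)):
        if chrom[j] != chrom[j - 1]:
            cuts.add(j)
    edges = sorted(cuts) + [len(chrom)]
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        seg = profile.log2[a:b]
        rows.append((chrom[a], a, b - 1, b - a, seg.mean()))
    segments = pd.DataFrame(rows, columns=normseg.SEGMENT_COLUMNS)
    return cncall.call_integer_cn(segments, grid_cfg)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Run the synthetic end-to-end workflow from a nested config dict.

    Recognized sections (all optional): ``sim`` (SimConfig fields),
    ``segmentation`` {method}, ``grid`` (GridSearchConfig fields), ``qc``
    {enabled, split, threshold_rule}, ``clones`` (CloneConfig fields),
    ``karyotype`` (KaryotypeConfig fields), ``fish`` {enabled, n_fov,
    dots_per_fov, detection_eff}, ``seed``. Unknown keys are rejected.
    Returns the run manifest (also written to manifest.json).
    """
    known = {"sim", "segmentation", "grid", "qc", "clones", "karyotype",
             "fish", "seed"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {"version": __version__, "seed": seed, "stages": {}}

    def record(stage: str, **files) -> None:
        manifest["stages"][stage] = {
            name: {"path": str(p), "sha256": _checksum(Path(p))}
            for name, p in files.items()}

    # --- simulate -----------------------------------------------------
    sim_cfg = simgen.SimConfig(**{**cfg.get("sim", {}), "seed": seed})
    bins = simgen.generate_reference(sim_cfg)
    matrix, truth, cohort = simgen.generate_cohort(sim_cfg, bins)
    bins_path = out / "bins.tsv"
    bins.to_csv(bins_path, sep="\t", index=False)
    counts_path = out / "counts.tsv"
    pd.DataFrame(matrix.counts, index=matrix.cell_ids).to_csv(
        counts_path, sep="\t")
    truth_path = out / "truth_cells.tsv"
    pd.DataFrame({
        "clone": truth.cell_clone, "karyotype": truth.cell_karyotype,
        "region": truth.cell_region}).to_csv(truth_path, sep="\t")
    record("simgen", bins=bins_path, counts=counts_path, truth=truth_path)

    # --- per-cell calling ---------------------------------------------
    seg_cfg = cfg.get("segmentation", {})
    grid_cfg = cncall.GridSearchConfig(**cfg.get("grid", {}))
    features, cn_matrix, summary, intermediates = profile_cohort(
        matrix, method=seg_cfg.get("method", "dp"), grid_cfg=grid_cfg,
        keep_intermediates=True)
    cn_path = out / "cn_profiles.tsv"
    pd.DataFrame(cn_matrix, index=matrix.cell_ids).to_csv(cn_path, sep="\t")
    summary_path = out / "cell_summary.tsv"
    features_path = out / "qc_features.tsv"
    features.to_csv(features_path, sep="\t")
    record("cncall", cn_profiles=cn_path, features=features_path)

    # --- QC -----------------------------------------------------------
    qc_cfg = cfg.get("qc", {})
    if qc_cfg.get("enabled", True):
        labels = np.where(truth.cell_karyotype.values == "lowquality",
                          "bad", "good")
        model = qc.train_classifier(
            features, labels, split=qc_cfg.get("split", 0.8), seed=seed,
            threshold_rule=qc_cfg.get("threshold_rule", "youden"))
        scored = qc.apply_classifier(model, features)
        qc_pass = scored["pass"]
        manifest["stages"]["qc"] = {
            "validation_auc": model.train_auc,
            "threshold": model.threshold,
            "n_pass": int(qc_pass.sum()),
        }
    else:
        scored = pd.DataFrame({"probability": 1.0, "pass": True},
                              index=matrix.cell_ids)
        qc_pass = scored["pass"]
        manifest["stages"]["qc"] = {"skipped": True}
    summary = summary.join(scored)
    summary.to_csv(summary_path, sep="\t")

    # --- karyotype + clones -------------------------------------------
    kcfg = clonal.KaryotypeConfig(**cfg.get("karyotype", {}))
    fractions = np.array([
        clonal.altered_fraction(cn_matrix[i], matrix.bin_ref, kcfg.sex)
        for i in range(cn_matrix.shape[0])])
    karyo = pd.Series(
        [clonal.classify_karyotype(f, kcfg) for f in fractions],
        index=matrix.cell_ids, name="karyotype")
    pseudo = karyo.index[(karyo == "pseudo-diploid") & qc_pass]
    ccfg = clonal.CloneConfig(**cfg.get("clones", {}))
    chrom = matrix.bin_ref["chrom"].values
    idx = [matrix.cell_ids.get_loc(c) for c in pseudo]
    clones = pd.Series(-1, index=matrix.cell_ids, name="clone")
    if len(pseudo) >= 2:
        # consensus re-segmentation aligns event boundaries across cells
        # before distances are computed
        bks = consensus_breakpoints([intermediates[i][1] for i in idx],
                                    np.asarray(chrom))
        recalled = np.array([
            recall_on_breakpoints(intermediates[i][0], bks, grid_cfg).cn
            for i in idx])
        D = clonal.distance_matrix(recalled, chrom)
        initial = clonal.cluster_clones(D, list(pseudo), ccfg)
        refined = clonal.refine_clones(recalled, initial, chrom, ccfg)
        clones.loc[pseudo] = refined.values
        if len(pseudo) >= 3:
            tree = clonal.build_tree(D, list(pseudo))
            (out / "tree.nwk").write_text(str(tree))
    clone_path = out / "clones.tsv"
    pd.DataFrame({"karyotype": karyo, "clone": clones,
                  "altered_fraction": fractions}).to_csv(clone_path, sep="\t")
    record("clonal", clones=clone_path)

    # --- spatial entropy ----------------------------------------------
    regions = cohort.regions.copy()
    regions["qc_total"] = [
        int((matrix.cell_meta["region"].values == r)[qc_pass.values].sum())
        for r in regions.index]
    clone_counts = pd.DataFrame(
        0, index=sorted(set(clones) - {-1}), columns=regions.index)
    for cell, lab in clones.items():
        if lab >= 0:
            clone_counts.loc[lab, matrix.cell_meta.at[cell, "region"]] += 1
    if len(clone_counts) and (regions["qc_total"] > 0).all():
        entropies = spatial.all_clone_entropies(clone_counts, regions)
        entropy_path = out / "clone_entropy.tsv"
        entropies.to_csv(entropy_path, sep="\t")
        spatial.render_map(regions, spatial.region_mean_entropy(
            clone_counts, regions, entropies), out_tsv=out / "entropy_map.tsv")
        record("spatial", entropy=entropy_path)
    else:
        manifest["stages"]["spatial"] = {"skipped": True,
                                         "reason": "no clones or empty regions"}

    # --- FISH ----------------------------------------------------------
    fish_cfg = cfg.get("fish", {})
    if fish_cfg.get("enabled", False):
        rng = np.random.default_rng(seed + 7)
        n_fov = int(fish_cfg.get("n_fov", 51))
        fovs = simgen.generate_fish_fovs(
            n_fov, rng.uniform(0, 1, size=n_fov),
            dots_per_fov=int(fish_cfg.get("dots_per_fov", 2000)),
            detection_eff=float(fish_cfg.get("detection_eff", 0.9)),
            seed=seed + 8)
        table, corr = fish.quantify(fovs)
        fish_path = out / "fish_quant.tsv"
        table.to_csv(fish_path, sep="\t", index=False)
        manifest["stages"]["fish"] = {
            "pcc": corr["pcc"],
            "files": {"quant": {"path": str(fish_path),
                                "sha256": _checksum(fish_path)}}}
    else:
        manifest["stages"]["fish"] = {"skipped": True}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
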