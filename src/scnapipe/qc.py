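"""Profile-quality control with a random-forest classifier.

Sixteen per-cell features summarizing noise, segmentation complexity and
copy-number plausibility are computed from the count row, the normalized
ratio profile, the segment table and the called integer profile. A random
forest (500 trees, class-balanced bagging) is trained on annotated cells
with a stratified 80/20 split; the pass/fail probability threshold is the
ROC point maximizing Youden's J on the validation split (a
closest-to-corner rule is available). A cell passes when its probability of
being good is >= the threshold (inclusive).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split

from .cncall import CNProfile
from .normseg import RatioProfile, segment_means_per_bin

FEATURE_NAMES = [
    "total_reads",
    "overdispersion",
    "mapd",
    "lag1_autocorr",
    "residual_sd",
    "n_segments",
    "mean_segment_len",
    "frac_genome_altered",
    "cn_entropy",
    "cn_max",
    "cn_min",
    "frac_zero_bins",
    "gini",
    "var_ratio",
    "fit_error",
    "frac_outlier_bins",
]


def _gini(x: np.ndarray) -> float:
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n == 0 or x.sum() == 0:
        return 0.0
    cum = np.cumsum(x)
    return float((n + 1 - 2 * (cum / cum[-1]).sum()) / n)


def compute_features(
    counts_row: np.ndarray,
    profile: RatioProfile,
    segments: pd.DataFrame,
    cn_profile: CNProfile,
) -> pd.Series:
    """The 16 QC features for one cell (all finite)."""
    for name, obj in (("counts", counts_row), ("profile", profile),
                      ("segments", segments), ("cn_profile", cn_profile)):
        if obj is None:
            raise ValueError(f"missing upstream stage: {name}")
    counts_row = np.asarray(counts_row, dtype=float)
    ratios = profile.log2
    n = len(ratios)
    seg_mean = segment_means_per_bin(segments, n)
    resid = ratios - seg_mean
    cn = cn_profile.cn

    mean_c = counts_row.mean()
    diffs = np.abs(np.diff(ratios))
    centered = ratios - ratios.mean()
    denom = (centered ** 2).sum()
    lag1 = float((centered[:-1] * centered[1:]).sum() / denom) if denom > 0 else 0.0

    seg_var_within = float(np.mean(resid ** 2))
    between = float(np.var(seg_mean))
    var_ratio = seg_var_within / between if between > 0 else 0.0

    vals, freq = np.unique(cn, return_counts=True)
    p = freq / freq.sum()
    cn_entropy = float(-(p * np.log2(p)).sum())

    feats = pd.Series({
        "total_reads": float(counts_row.sum()),
        "overdispersion": float(counts_row.var() / mean_c) if mean_c > 0 else 0.0,
        "mapd": float(np.median(diffs)) if len(diffs) else 0.0,
        "lag1_autocorr": lag1,
        "residual_sd": float(resid.std()),
        "n_segments": float(len(segments)),
        "mean_segment_len": float(segments["n_bins"].mean()),
        "frac_genome_altered": float((cn != 2).mean()),
        "cn_entropy": cn_entropy,
        "cn_max": float(cn.max()),
        "cn_min": float(cn.min()),
        "frac_zero_bins": float((counts_row == 0).mean()),
        "gini": _gini(counts_row),
        "var_ratio": var_ratio,
        "fit_error": float(cn_profile.fit_error),
        "frac_outlier_bins": float((np.abs(resid) > 0.3).mean()),
    })[FEATURE_NAMES]
    if not np.all(np.isfinite(feats.values)):
        raise ValueError("non-finite QC feature")
    return feats


@dataclass
class QCModel:
    forest: RandomForestClassifier
    threshold: float
    train_auc: float
    feature_importances: pd.Series
    feature_names: list[str]
    version: str = "1"

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "QCModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def train_classifier(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    split: float = 0.8,
    seed: int = 0,
    n_trees: int = 500,
    threshold_rule: str = "youden",
) -> QCModel:
    """Train the pass/fail forest on annotated cells.

    ``labels`` are "good"/"bad" (or boolean good). Stratified 80/20 split;
    class balance via per-tree balanced subsampling; threshold chosen on the
    validation ROC. Reports validation AUC.
    """
    y = np.asarray(labels)
    if y.dtype != bool:
        y = y == "good"
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if len(y) < 50:
        raise ValueError("need >= 50 annotated cells")
    X = features[FEATURE_NAMES].values
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, train_size=split, stratify=y, random_state=seed)
    forest = RandomForestClassifier(
        n_estimators=n_trees, class_weight="balanced_subsample",
        random_state=seed, n_jobs=1)
    forest.fit(X_tr, y_tr)
    good_col = int(np.flatnonzero(forest.classes_)[0])
    p_val = forest.predict_proba(X_val)[:, good_col]
    auc = float(roc_auc_score(y_val, p_val))
    fpr, tpr, thr = roc_curve(y_val, p_val)
    if threshold_rule == "youden":
        best = int(np.argmax(tpr - fpr))
    elif threshold_rule == "closest":
        best = int(np.argmin(fpr ** 2 + (1 - tpr) ** 2))
    else:
        raise ValueError(f"unknown threshold rule: {threshold_rule}")
    threshold = float(np.clip(thr[best], 1e-9, 1 - 1e-9))
    return QCModel(
        forest=forest,
        threshold=threshold,
        train_auc=auc,
        feature_importances=pd.Series(forest.feature_importances_,
                                      index=FEATURE_NAMES),
        feature_names=list(FEATURE_NAMES),
    )


def apply_classifier(model: QCModel, features: pd.DataFrame) -> pd.DataFrame:
    """Score cells: probability of a good profile and pass/fail at the
    model threshold (pass iff probability >= threshold)."""
    if list(features.columns.intersection(model.feature_names)) != model.feature_names:
        missing = set(model.feature_names) - set(features.columns)
        raise ValueError(f"feature-name mismatch; missing {sorted(missing)}")
    X = features[model.feature_names].values
    good_col = int(np.flatnonzero(model.forest.classes_)[0])
    prob = model.forest.predict_proba(X)[:, good_col]
    return pd.DataFrame({
        "probability": prob,
        "pass": prob >= model.threshold,
    }, index=features.index)
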