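"""Radiomic feature extraction and mRMR feature selection.

Images are first normalized by the mean intensity of the white-matter
region contralateral to the tumor; features are then extracted per
(contrast, ROI) pair — first-order statistics, gray-level co-occurrence
(GLCM) textures and, once per ROI, shape descriptors.  Column names carry
the full ``contrast|roi|family|feature`` provenance so that a contrast
channel can be replaced or ablated downstream.

Feature selection is greedy maximum-relevance / minimum-redundancy with
mutual information estimated on equal-frequency discretized features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .physics import WeightedImage

__all__ = [
    "FeatureConfig",
    "normalize_by_reference",
    "extract_features",
    "build_feature_table",
    "parse_feature_name",
    "MRMRSelector",
    "select_features_mrmr",
    "label_subjects",
]

DEFAULT_ROIS = ("ET", "NET", "ED", "TC", "WT")
ROI_MEMBERS = {"ET": ("ET",), "NET": ("NET",), "ED": ("ED",),
               "TC": ("ET", "NET"), "WT": ("ET", "NET", "ED")}


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureConfig:
    contrasts: tuple[str, ...] = ("T1w", "T2w", "FLAIR", "T1w_c")
    rois: tuple[str, ...] = DEFAULT_ROIS
    glcm_bins: int = 16
    histogram_bins: int = 32


def normalize_by_reference(image: WeightedImage | np.ndarray,
                           wm_labels: np.ndarray,
                           tumor_hemisphere: str) -> WeightedImage:
    """Divide an image by the mean of contralateral white matter.

    The hemisphere split runs along axis 0; after normalization the
    contralateral-WM mean is 1 exactly.
    """
    if isinstance(image, WeightedImage):
        arr, contrast, params, mask = (image.intensities, image.contrast,
                                       image.params, image.mask)
    else:
        arr = np.asarray(image, float)
        contrast, params, mask = "unknown", None, arr != 0
    wm = np.asarray(wm_labels, bool)
    nx = arr.shape[0]
    contra = np.zeros_like(wm)
    if tumor_hemisphere == "left":
        contra[nx // 2:] = True
    elif tumor_hemisphere == "right":
        contra[: nx // 2] = True
    else:
        raise NormalizationError(f"unknown hemisphere {tumor_hemisphere!r}")
    ref = wm & contra
    if not ref.any():
        raise NormalizationError("contralateral white-matter region is empty")
    ref_mean = float(arr[ref].mean())
    if ref_mean == 0:
        raise NormalizationError("contralateral white-matter mean is zero")
    return WeightedImage(arr / ref_mean, contrast, params, mask)


# --------------------------------------------------------------------------
# feature families
# --------------------------------------------------------------------------

def _first_order(values: np.ndarray, n_hist_bins: int) -> dict[str, float]:
    v = values.astype(float)
    p = np.percentile(v, [10, 25, 50, 75, 90])
    hist, _ = np.histogram(v, bins=n_hist_bins)
    probs = hist / hist.sum()
    probs = probs[probs > 0]
    return {
        "mean": float(v.mean()),
        "std": float(v.std()),
        "skewness": float(stats.skew(v)) if v.std() > 0 else 0.0,
        "kurtosis": float(stats.kurtosis(v)) if v.std() > 0 else 0.0,
        "energy": float(np.mean(v**2)),
        "entropy": float(-(probs * np.log2(probs)).sum()),
        "p10": float(p[0]), "p25": float(p[1]), "p50": float(p[2]),
        "p75": float(p[3]), "p90": float(p[4]),
        "iqr": float(p[3] - p[1]),
    }


def _quantize(arr: np.ndarray, roi: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width binning over the robust (1st-99th percentile) intensity
    range; min/max bounds would let a handful of noise outliers stretch the
    bins and destabilize every co-occurrence feature."""
    vals = arr[roi]
    lo, hi = (float(x) for x in np.percentile(vals, [1, 99]))
    q = np.zeros(arr.shape, np.int64)
    if hi > lo:
        q[roi] = np.clip(((arr[roi] - lo) / (hi - lo) * n_bins).astype(np.int64),
                         0, n_bins - 1)
    return q


def _glcm(arr: np.ndarray, roi: np.ndarray, n_bins: int) -> dict[str, float]:
    """Symmetric co-occurrence over the three axis-aligned unit offsets."""
    q = _quantize(arr, roi, n_bins)
    counts = np.zeros((n_bins, n_bins), float)
    for ax in range(arr.ndim):
        sl_a = [slice(None)] * arr.ndim
        sl_b = [slice(None)] * arr.ndim
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        a, b = q[tuple(sl_a)], q[tuple(sl_b)]
        valid = roi[tuple(sl_a)] & roi[tuple(sl_b)]
        if valid.any():
            pairs = np.bincount(a[valid] * n_bins + b[valid],
                                minlength=n_bins * n_bins).reshape(n_bins, n_bins)
            counts += pairs + pairs.T
    total = counts.sum()
    if total == 0:  # ROI of a single voxel (or empty): degenerate texture
        counts[0, 0] = 1.0
        total = 1.0
    p = counts / total
    i = np.arange(n_bins)[:, None]
    j = np.arange(n_bins)[None, :]
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    nz = p[p > 0]
    if var_i > 0 and var_j > 0:
        corr = float((((i - mu_i) * (j - mu_j) * p).sum()) / np.sqrt(var_i * var_j))
    else:
        corr = 1.0
    return {
        "contrast": float(((i - j) ** 2 * p).sum()),
        "dissimilarity": float((np.abs(i - j) * p).sum()),
        "homogeneity": float((p / (1.0 + (i - j) ** 2)).sum()),
        "energy": float((p**2).sum()),
        "entropy": float(-(nz * np.log2(nz)).sum()),
        "correlation": corr,
    }


def _shape(roi: np.ndarray) -> dict[str, float]:
    """Voxel-count volume, exposed-face surface proxy and sphericity.

    The face-count surface overestimates a smooth surface by a factor of
    3/2 on average over orientations; dividing by it makes a voxelized
    sphere's sphericity come out near 1.
    """
    vol = float(roi.sum())
    if vol == 0:
        return {"volume": np.nan, "surface": np.nan, "sphericity": np.nan}
    faces = 0.0
    for ax in range(roi.ndim):
        pad = np.pad(roi, [(1, 1) if a == ax else (0, 0) for a in range(roi.ndim)])
        sl_a = [slice(None)] * roi.ndim
        sl_b = [slice(None)] * roi.ndim
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        faces += float((pad[tuple(sl_a)] != pad[tuple(sl_b)]).sum())
    surface = faces / 1.5
    sphericity = float(np.pi ** (1 / 3) * (6.0 * vol) ** (2 / 3) / surface)
    return {"volume": vol, "surface": surface, "sphericity": sphericity}


def feature_name(contrast: str, roi: str, family: str, feat: str) -> str:
    return f"{contrast}|{roi}|{family}|{feat}"


def parse_feature_name(name: str) -> tuple[str, str, str, str]:
    parts = name.split("|")
    if len(parts) != 4:
        raise ValueError(f"feature name {name!r} is not contrast|roi|family|feature")
    return tuple(parts)  # type: ignore[return-value]


def extract_features(record, contrast_set: Iterable[str] | None = None,
                     roi_set: Iterable[str] | None = None,
                     feature_config: FeatureConfig | None = None,
                     replaced_images: dict[str, WeightedImage] | None = None,
                     normalize: bool = True) -> pd.Series:
    """One feature row for one subject.

    ``replaced_images`` substitutes a synthesized volume for an acquired
    contrast before normalization and extraction (Experiment II plumbing);
    all other channels are untouched.  Empty ROIs yield NaN, to be imputed
    from the training fold downstream.
    """
    cfg = feature_config or FeatureConfig()
    contrasts = tuple(contrast_set) if contrast_set is not None else cfg.contrasts
    rois = tuple(roi_set) if roi_set is not None else cfg.rois
    wm = record.label_mask("WM")

    images = {}
    for c in contrasts:
        img = (replaced_images or {}).get(c, record.weighted[c])
        if normalize:
            img = normalize_by_reference(img, wm, record.hemisphere_of_tumor)
        images[c] = img.intensities

    roi_masks = {r: record.label_mask(*ROI_MEMBERS[r]) for r in rois}
    row: dict[str, float] = {}
    for c in contrasts:
        arr = images[c]
        for r in rois:
            m = roi_masks[r]
            if m.sum() == 0:
                for fam, feats in (("firstorder", _first_order(np.zeros(1), 2)),
                                   ("glcm", _glcm(np.zeros((2, 2, 2)), np.ones((2, 2, 2), bool), 2))):
                    for f in feats:
                        row[feature_name(c, r, fam, f)] = np.nan
                continue
            for f, val in _first_order(arr[m], cfg.histogram_bins).items():
                row[feature_name(c, r, "firstorder", f)] = val
            for f, val in _glcm(arr, m, cfg.glcm_bins).items():
                row[feature_name(c, r, "glcm", f)] = val
    for r in rois:
        for f, val in _shape(roi_masks[r]).items():
            row[feature_name("mask", r, "shape", f)] = val
    return pd.Series(row, name=record.subject_id)


def build_feature_table(records: Sequence, contrast_set=None, roi_set=None,
                        feature_config: FeatureConfig | None = None,
                        replaced_images: dict[str, dict[str, WeightedImage]] | None = None,
                        ) -> pd.DataFrame:
    """Subjects x features table; ``replaced_images`` maps subject_id ->
    {contrast: WeightedImage} for channel replacement."""
    rows = [
        extract_features(r, contrast_set, roi_set, feature_config,
                         replaced_images=(replaced_images or {}).get(r.subject_id))
        for r in records
    ]
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# mRMR selection
# --------------------------------------------------------------------------

def _discretize(col: np.ndarray, n_bins: int = 8) -> np.ndarray:
    """Equal-frequency binning; constant columns collapse to one bin."""
    edges = np.unique(np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, col, side="right")


def _mutual_info(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in MI (nats) between two small-alphabet integer arrays."""
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb).astype(float)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


class MRMRSelector(SelectorMixin, BaseEstimator):
    """Greedy maximum-relevance / minimum-redundancy feature selector.

    The first feature maximizes mutual information with the label; each
    subsequent pick maximizes relevance minus mean redundancy with the
    already-selected set.  Features are discretized by equal-frequency
    binning (default 8 bins); ties break lexicographically on the column
    name for determinism.
    """

    def __init__(self, k: int = 16, n_bins: int = 8):
        self.k = k
        self.n_bins = n_bins

    def fit(self, X: pd.DataFrame, y):
        if self.k <= 0:
            raise ValueError("k must be positive")
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(int)
        names = [str(c) for c in X.columns]
        disc = {n: _discretize(X[c].to_numpy(float), self.n_bins)
                for n, c in zip(names, X.columns)}
        relevance = {n: _mutual_info(disc[n], y) for n in names}

        selected: list[str] = []
        remaining = set(names)
        red_sum = {n: 0.0 for n in names}
        k = min(self.k, len(names))
        while len(selected) < k:
            best_name, best_score = None, -np.inf
            for n in sorted(remaining):
                score = relevance[n]
                if selected:
                    score -= red_sum[n] / len(selected)
                if score > best_score + 1e-12:
                    best_name, best_score = n, score
            selected.append(best_name)
            remaining.discard(best_name)
            for n in remaining:
                red_sum[n] += _mutual_info(disc[n], disc[best_name])
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.ranking_ = list(selected)
        self.n_features_in_ = len(names)
        return self

    def _get_support_mask(self):
        sel = set(self.ranking_)
        return np.asarray([n in sel for n in self.feature_names_in_])


def select_features_mrmr(table: pd.DataFrame, labels, k: int,
                         n_bins: int = 8) -> list[str]:
    """Ordered mRMR feature names (thin wrapper over :class:`MRMRSelector`)."""
    sel = MRMRSelector(k=k, n_bins=n_bins).fit(table, labels)
    return sel.ranking_


# --------------------------------------------------------------------------
# survival dichotomization
# --------------------------------------------------------------------------

def label_subjects(survival_table: pd.DataFrame, threshold_days: int = 480,
                   censor_policy: str = "exclude") -> tuple[pd.Series, pd.DataFrame]:
    """Binary labels: 1 iff survival > threshold (strict).

    Censored subjects whose follow-up is shorter than the threshold carry
    no label information; the default policy excludes them (they are
    returned in the report).  Censored subjects with follow-up past the
    threshold are known survivors and are labeled 1.
    """
    t = survival_table.set_index("subject_id") if "subject_id" in survival_table else survival_table
    labels = {}
    excluded = []
    for sid, row in t.iterrows():
        days, cens = int(row["survival_days"]), int(row["censored"])
        if days > threshold_days:
            labels[sid] = 1
        elif cens == 0:
            labels[sid] = 0
        else:
            if censor_policy == "exclude":
                excluded.append(sid)
            elif censor_policy == "short":
                labels[sid] = 0
            else:
                raise ValueError(f"unknown censor policy {censor_policy!r}")
    if not labels:
        raise ValueError("no labelable subjects")
    report = t.loc[excluded].reset_index() if excluded else t.iloc[0:0].reset_index()
    return pd.Series(labels, name="survival_gt_threshold"), report
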