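"""Preprocessing stack for high-dimensional omics matrices.

Pipeline order for expression-like modalities (gene/miRNA expression):
missing-feature removal -> log2(X+1) -> min-max to [0,1] -> either
top-k-variance selection (default k=1000) or PCA (default 100 components).
Every transform is fitted on training rows only and then applied
unchanged to validation/test rows, matching a leakage-free
cross-validation pipeline. Splitting is a stratified four-fold scheme
where the four test sets (25% each) partition the samples and the
remaining 75% is split 60/15 (of the total) into train/validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, train_test_split

from .containers import OmicsMatrix

__all__ = [
    "drop_missing_features", "log2_transform",
    "FittedTransform", "minmax_fit", "minmax_apply",
    "variance_select_fit", "variance_select_apply",
    "pca_fit", "pca_apply",
    "FoldAssignment", "stratified_folds",
]


def drop_missing_features(m: OmicsMatrix) -> OmicsMatrix:
    """Remove every feature column containing at least one missing value.

    Removal is strictly column-wise; the sample set is never touched.
    """
    keep = ~np.isnan(m.values).any(axis=0)
    if not keep.any():
        raise ValueError("all features contain missing values")
    return OmicsMatrix(m.values[:, keep],
                       list(m.sample_ids),
                       [f for f, k in zip(m.feature_ids, keep) if k],
                       m.modality_name)


def log2_transform(m: OmicsMatrix) -> OmicsMatrix:
    """Entry-wise log2(x + 1); reserved for nonnegative expression data."""
    if np.nanmin(m.values) < 0:
        raise ValueError("log2 transform requires nonnegative values")
    return OmicsMatrix(np.log2(m.values + 1.0), list(m.sample_ids),
                       list(m.feature_ids), m.modality_name)


@dataclass
class FittedTransform:
    """A train-fitted feature transform applicable to any matrix sharing
    the training feature space.

    kind:
      minmax           params: min, range (per feature; zero ranges -> 0)
      variance_select  params: indices of the selected features
      pca              params: mean vector and component loadings
    """

    kind: str
    params: dict = field(default_factory=dict)
    feature_ids: list[str] = field(default_factory=list)

    def apply(self, m: OmicsMatrix) -> OmicsMatrix:
        if list(m.feature_ids) != list(self.feature_ids):
            raise ValueError("matrix feature space differs from the fitted one")
        if self.kind == "minmax":
            return minmax_apply(self, m)
        if self.kind == "variance_select":
            return variance_select_apply(self, m)
        if self.kind == "pca":
            return pca_apply(self, m)
        raise ValueError(f"unknown transform kind {self.kind!r}")

    def save(self, path) -> None:
        payload = {"kind": self.kind, "feature_ids": self.feature_ids,
                   "params": {k: np.asarray(v).tolist()
                              for k, v in self.params.items()}}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "FittedTransform":
        with open(path) as fh:
            payload = json.load(fh)
        params = {k: np.asarray(v) for k, v in payload["params"].items()}
        return cls(payload["kind"], params, list(payload["feature_ids"]))


def minmax_fit(train: OmicsMatrix) -> FittedTransform:
    """Fit per-feature min/max on training rows only."""
    lo = train.values.min(axis=0)
    span = train.values.max(axis=0) - lo
    return FittedTransform("minmax", {"min": lo, "range": span},
                           list(train.feature_ids))


def minmax_apply(t: FittedTransform, m: OmicsMatrix, clip: bool = False) -> OmicsMatrix:
    """Scale with the training min/max; constant training features map to 0.

    Out-of-range test values are kept by default (``clip=False``).
    """
    span = np.where(t.params["range"] == 0, 1.0, t.params["range"])
    vals = (m.values - t.params["min"]) / span
    vals[:, t.params["range"] == 0] = 0.0
    if clip:
        vals = np.clip(vals, 0.0, 1.0)
    return OmicsMatrix(vals, list(m.sample_ids), list(m.feature_ids),
                       m.modality_name)


def variance_select_fit(train: OmicsMatrix, k: int = 1000) -> FittedTransform:
    """Select the k features of largest training variance.

    Ties are broken toward the lower feature index for determinism.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > train.n_features:
        raise ValueError("k exceeds the number of features")
    var = train.values.var(axis=0, ddof=1) if train.n_samples > 1 \
        else np.zeros(train.n_features)
    order = np.argsort(-var, kind="stable")  # stable: ties keep lower index
    idx = np.sort(order[:k])
    return FittedTransform("variance_select", {"indices": idx},
                           list(train.feature_ids))


def variance_select_apply(t: FittedTransform, m: OmicsMatrix) -> OmicsMatrix:
    idx = np.asarray(t.params["indices"], dtype=int)
    return OmicsMatrix(m.values[:, idx], list(m.sample_ids),
                       [m.feature_ids[i] for i in idx], m.modality_name)


def pca_fit(train: OmicsMatrix, n_components: int = 100) -> FittedTransform:
    """Fit PCA on training rows: center by the training mean, keep the top
    components by explained variance.

    Sign convention: each component's largest-magnitude loading is made
    positive so outputs are reproducible across library versions.
    """
    bound = min(train.n_samples - 1, train.n_features)
    if not (0 < n_components <= bound):
        raise ValueError(f"n_components must lie in [1, {bound}]")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(train.values)
    comps = pca.components_.copy()  # (n_components, n_features)
    flip = np.sign(comps[np.arange(comps.shape[0]),
                         np.abs(comps).argmax(axis=1)])
    comps *= flip[:, None]
    return FittedTransform(
        "pca",
        {"mean": pca.mean_, "components": comps,
         "explained_variance": pca.explained_variance_,
         "explained_variance_ratio": pca.explained_variance_ratio_},
        list(train.feature_ids))


def pca_apply(t: FittedTransform, m: OmicsMatrix) -> OmicsMatrix:
    comps = np.asarray(t.params["components"])
    scores = (m.values - np.asarray(t.params["mean"])) @ comps.T
    pc_ids = [f"PC{i + 1}" for i in range(comps.shape[0])]
    return OmicsMatrix(scores, list(m.sample_ids), pc_ids, m.modality_name)


@dataclass(frozen=True)
class FoldAssignment:
    """Disjoint train/validation/test sample indices for one fold."""

    fold_index: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self):
        sets = [set(np.asarray(s).tolist())
                for s in (self.train_idx, self.val_idx, self.test_idx)]
        if (sets[0] & sets[1]) or (sets[0] & sets[2]) or (sets[1] & sets[2]):
            raise ValueError("train/val/test sets must be pairwise disjoint")


def stratified_folds(strata_labels, fractions: tuple[float, float, float] = (0.60, 0.15, 0.25),
                     n_folds: int = 4, seed: int = 0) -> list[FoldAssignment]:
    """Stratified n-fold 60/15/25 splitting.

    The ``n_folds`` test sets partition the samples (each ~25% for the
    default four folds); within each fold the remaining samples are split
    into train/validation in the ratio ``fractions[0] : fractions[1]``
    (60/15 of the total by default), stratified by ``strata_labels``
    (class label for classification, event indicator for survival).
    Deterministic given ``seed``.
    """
    strata = np.asarray(strata_labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    _, counts = np.unique(strata, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError("every stratum needs at least n_folds samples")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    val_share = fractions[1] / (fractions[0] + fractions[1])
    for k, (rest_idx, test_idx) in enumerate(skf.split(strata, strata)):
        train_idx, val_idx = train_test_split(
            rest_idx, test_size=val_share, stratify=strata[rest_idx],
            random_state=seed + 1000 * (k + 1))
        folds.append(FoldAssignment(k, np.sort(train_idx), np.sort(val_idx),
                                    np.sort(test_idx)))
    return folds
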