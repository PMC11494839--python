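"""Stratified splitting and SMOTE oversampling of image samples.

The split assigns round(test_fraction * n) samples per class to the test
set via a seeded permutation.  SMOTE synthesizes new samples of a class by
linear interpolation between a random real sample and one of its k nearest
same-class neighbors (distances on flattened pixel vectors); paired masks
are interpolated with the same coefficient and re-thresholded to binary,
preserving spatial correspondence.  Both classes are raised to a common
per-class target, mirroring the balanced training set the method trains on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import DatasetManifest, SampleRecord


@dataclass
class SplitSpec:
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.test_fraction < 1:
            raise ValueError("test_fraction must lie in [0, 1)")


@dataclass
class SmoteSpec:
    """Oversampling parameters: k neighbors, per-class targets, distance metric."""

    per_class_target: dict = field(default_factory=dict)
    k_neighbors: int = 5
    metric: str = "euclidean"
    seed: int = 0

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.metric not in ("euclidean", "cosine"):
            raise ValueError("metric must be 'euclidean' or 'cosine'")


def stratified_split(manifest: DatasetManifest, spec: SplitSpec | None = None):
    """Per-class seeded split into (train, test) manifests.

    Test count per class is the nearest integer to test_fraction times the
    class total; train and test are disjoint and exhaustive.
    """
    spec = spec or SplitSpec()
    by_class = {}
    for i, rec in enumerate(manifest):
        by_class.setdefault(rec.label, []).append(i)
    for label, idxs in by_class.items():
        if not idxs:
            raise ValueError(f"class {label} has no records")
    rng = np.random.default_rng(spec.seed)
    train_idx, test_idx = [], []
    for label in sorted(by_class):
        idxs = np.asarray(by_class[label])
        n_test = int(np.rint(spec.test_fraction * len(idxs)))
        perm = rng.permutation(len(idxs))
        test_idx.extend(idxs[perm[:n_test]].tolist())
        train_idx.extend(idxs[perm[n_test:]].tolist())
    train = manifest.subset(sorted(train_idx), split_tag="train")
    test = manifest.subset(sorted(test_idx), split_tag="test")
    for r in train:
        r.split = "train"
    for r in test:
        r.split = "test"
    return train, test


def _pairwise_distances(vectors: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        sq = (vectors ** 2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * vectors @ vectors.T
        return np.sqrt(np.maximum(d2, 0.0))
    norms = np.linalg.norm(vectors, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    cos = (vectors @ vectors.T) / (norms[:, None] * norms[None, :])
    return 1.0 - cos


def nearest_neighbors(vectors, query_index: int, k: int, metric: str = "euclidean"):
    """Indices of the k nearest vectors to the query, excluding the query.

    Ties are broken toward the lower index (stable sort on distances).
    """
    vectors = np.asarray([np.ravel(v) for v in vectors], dtype=np.float64)
    n = len(vectors)
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of vectors ({n})")
    d = _pairwise_distances(vectors, metric)[query_index].copy()
    d[query_index] = np.inf
    return np.argsort(d, kind="stable")[:k].tolist()


def smote_oversample(train: DatasetManifest, spec: SmoteSpec) -> DatasetManifest:
    """Raise every class to its per-class target by SMOTE interpolation.

    Real records pass through unmodified; each synthetic record is
    x_i + u (x_nn - x_i) with u ~ Uniform(0,1), its mask interpolated with
    the same u and thresholded at 0.5, and its ``synthetic`` flag set.
    """
    by_class = {}
    for rec in train:
        by_class.setdefault(rec.label, []).append(rec)
    shapes = {r.image.shape for r in train}
    if len(shapes) > 1:
        raise ValueError(f"images must share one shape; found {sorted(shapes)}")

    out = list(train.records)
    rng = np.random.default_rng(spec.seed)
    for label in sorted(by_class):
        reals = by_class[label]
        target = spec.per_class_target.get(label, len(reals))
        if target < len(reals):
            raise ValueError(
                f"per_class_target[{label}]={target} below current count {len(reals)}")
        need = target - len(reals)
        if need == 0:
            continue
        if spec.k_neighbors >= len(reals):
            raise ValueError(
                f"k_neighbors={spec.k_neighbors} must be below class size {len(reals)}")
        vectors = [r.image.ravel() for r in reals]
        knn = [nearest_neighbors(vectors, i, spec.k_neighbors, spec.metric)
               for i in range(len(reals))]
        for j in range(need):
            i = int(rng.integers(len(reals)))
            nn = knn[i][int(rng.integers(spec.k_neighbors))]
            u = float(rng.random())
            a, b = reals[i], reals[nn]
            img = a.image + u * (b.image - a.image)
            mask = None
            if a.mask is not None and b.mask is not None:
                soft = a.mask.astype(np.float64) + u * (
                    b.mask.astype(np.float64) - a.mask.astype(np.float64))
                mask = (soft > 0.5).astype(np.uint8)
            out.append(SampleRecord(image=img.astype(a.image.dtype), mask=mask,
                                    label=label, id=f"{label.lower()}_syn_{j:04d}",
                                    synthetic=True, split=a.split))
    return DatasetManifest(out, split_tag=train.split_tag)
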