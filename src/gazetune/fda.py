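"""Fuzzy data augmentation (FDA).

Tabular augmentation works in four steps: (1) fuzzy C-means (FCM) clustering
assigns every record a fractional membership grade in each cluster; (2) for
each record a membership-weighted, descending-sorted matrix block is formed;
(3) an alpha-cut retains only records whose membership in their own cluster
is at least alpha; (4) the retained records' cluster-center rows are appended
to the original table, each labeled by the majority class of its cluster.

Image augmentation applies a small random rotation followed by one noise
type (Gaussian or salt-and-pepper) with parameters drawn from configurable
low-to-moderate ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import rotate as _sk_rotate
from sklearn.cluster import kmeans_plusplus

from .synthetic import SyntheticEyeImage

__all__ = [
    "FuzzyPartition",
    "AugmentedDataset",
    "ImageAugmentConfig",
    "fcm_fit",
    "build_membership_matrix",
    "alpha_cut_filter",
    "augment_table",
    "augment_image",
    "alpha_grid_search",
]


@dataclass
class FuzzyPartition:
    """A fitted fuzzy C-means partition.

    Attributes
    ----------
    U : (c, n) membership matrix; every column sums to 1.
    centers : (c, k) cluster centers.
    X : (n, k) the data the partition was fitted on.
    m : fuzzifier exponent (> 1).
    objective : per-iteration FCM objective values (non-increasing).
    """

    U: np.ndarray
    centers: np.ndarray
    X: np.ndarray
    m: float
    objective: list[float] = field(default_factory=list)
    n_iter: int = 0

    @property
    def c(self) -> int:
        return self.U.shape[0]

    @property
    def n(self) -> int:
        return self.U.shape[1]

    def hard_labels(self) -> np.ndarray:
        """Index of each record's highest-membership cluster."""
        return np.argmax(self.U, axis=0)

    def cl_rows(self) -> np.ndarray:
        """(n, k) cluster-center dataset: each record's nearest center row."""
        return self.centers[self.hard_labels()]


def _fcm_memberships(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Membership update: u_ci = 1 / sum_j (d_ci / d_ji)^(2/(m-1))."""
    d = np.linalg.norm(X[None, :, :] - centers[:, None, :], axis=2)  # (c, n)
    zero = d < 1e-12
    if zero.any():
        U = np.zeros_like(d)
        cols = zero.any(axis=0)
        U[:, cols] = zero[:, cols] / zero[:, cols].sum(axis=0)
        nz = ~cols
        if nz.any():
            r = d[:, nz] ** (-2.0 / (m - 1.0))
            U[:, nz] = r / r.sum(axis=0)
        return U
    r = d ** (-2.0 / (m - 1.0))
    return r / r.sum(axis=0)


def fcm_fit(
    X: np.ndarray,
    c: int = 3,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
) -> FuzzyPartition:
    """Fit fuzzy C-means by alternating optimization.

    Centers are seeded with k-means++ for reproducibility; iteration stops
    when the maximum center displacement drops below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D attribute table")
    if not np.isfinite(X).all():
        raise ValueError("X must contain only finite values")
    if c < 2:
        raise ValueError("need at least 2 clusters")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    n = X.shape[0]
    if n < c:
        raise ValueError(f"need at least c={c} records, got {n}")

    centers, _ = kmeans_plusplus(X, n_clusters=c, random_state=seed)
    objective: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        U = _fcm_memberships(X, centers, m)
        Um = U**m
        new_centers = (Um @ X) / Um.sum(axis=1, keepdims=True)
        d2 = np.linalg.norm(X[None, :, :] - new_centers[:, None, :], axis=2) ** 2
        objective.append(float((Um * d2).sum()))
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    U = _fcm_memberships(X, centers, m)
    return FuzzyPartition(U=U, centers=centers, X=X, m=m, objective=objective, n_iter=it)


def build_membership_matrix(partition: FuzzyPartition, record: int) -> np.ndarray:
    """Membership-weighted block for one record, sorted by descending grade.

    Row ``j`` of the result is ``mu_(j) * x_i`` where ``mu_(j)`` is the
    record's j-th largest cluster membership.
    """
    if not 0 <= record < partition.n:
        raise IndexError(f"record index {record} out of range [0, {partition.n})")
    mu = partition.U[:, record]
    order = np.argsort(-mu, kind="stable")
    return mu[order, None] * partition.X[record][None, :]


def alpha_cut_filter(
    partition: FuzzyPartition, alpha: float, criterion: str = "source"
) -> np.ndarray:
    """Indices of records retained by the alpha-cut.

    ``criterion='source'`` keeps record i when its membership in its own
    (highest-membership) cluster is >= alpha; ``'max'`` is the same quantity
    by construction for the argmax cluster, kept as an explicit alias for the
    row-max reading.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if criterion not in ("source", "max"):
        raise ValueError("criterion must be 'source' or 'max'")
    score = partition.U.max(axis=0)
    retained = np.flatnonzero(score >= alpha)
    if retained.size == 0:
        warnings.warn(
            f"alpha-cut {alpha} retains no records; augmentation is empty",
            stacklevel=2,
        )
    return retained


@dataclass
class AugmentedDataset:
    """Original rows plus retained cluster-center rows, with provenance."""

    rows: np.ndarray
    provenance: np.ndarray  # 'original' | 'augmented' per row
    labels: np.ndarray
    alpha: float
    n_original: int

    @property
    def n_augmented(self) -> int:
        return len(self.rows) - self.n_original

    @property
    def ratio(self) -> float:
        return self.n_augmented / self.n_original

    def report(self) -> dict:
        return {
            "n_in": self.n_original,
            "n_retained": self.n_augmented,
            "n_out": len(self.rows),
            "ratio": self.ratio,
            "alpha": self.alpha,
        }


def augment_table(
    X: np.ndarray,
    partition: FuzzyPartition,
    alpha: float,
    labels: np.ndarray,
) -> AugmentedDataset:
    """Append the alpha-cut-retained cluster-center rows to ``X``.

    Each augmented row is the retained record's nearest cluster center and is
    labeled by the majority label of that cluster's member records.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.shape != partition.X.shape or not np.array_equal(X, partition.X):
        raise ValueError("partition was not fitted on this X")
    if len(labels) != len(X):
        raise ValueError("labels length must match number of rows in X")

    retained = alpha_cut_filter(partition, alpha)
    assign = partition.hard_labels()
    cluster_label = {}
    for cl in range(partition.c):
        members = labels[assign == cl]
        if len(members):
            vals, counts = np.unique(members, return_counts=True)
            cluster_label[cl] = vals[np.argmax(counts)]
    aug_rows = partition.centers[assign[retained]]
    aug_labels = np.array([cluster_label[assign[i]] for i in retained], dtype=labels.dtype)

    rows = np.vstack([X, aug_rows]) if len(retained) else X.copy()
    out_labels = np.concatenate([labels, aug_labels]) if len(retained) else labels.copy()
    prov = np.array(["original"] * len(X) + ["augmented"] * len(retained))
    return AugmentedDataset(
        rows=rows, provenance=prov, labels=out_labels, alpha=alpha, n_original=len(X)
    )


def alpha_grid_search(
    alphas,
    score_fn,
) -> tuple[float, dict[float, float]]:
    """Pick the alpha-cut maximizing a downstream validation score.

    ``score_fn(alpha) -> float`` trains/validates with that alpha; ties break
    toward the larger alpha (fewer, higher-confidence augmented rows).
    """
    scores = {float(a): float(score_fn(a)) for a in alphas}
    best = max(sorted(scores), key=lambda a: (scores[a], a))
    return best, scores


@dataclass(frozen=True)
class ImageAugmentConfig:
    """Perturbation ranges for eye-image augmentation.

    Defaults are the low-to-moderate ranges suitable for subtle head motion:
    rotations within +/-15 degrees, Gaussian noise sigma in [0.01, 0.05],
    salt-and-pepper density in [0.001, 0.01].
    """

    rotation_range: tuple[float, float] = (-15.0, 15.0)
    gaussian_sd_range: tuple[float, float] = (0.01, 0.05)
    saltpepper_density_range: tuple[float, float] = (0.001, 0.01)
    noise: str = "both"  # 'gaussian' | 'saltpepper' | 'both' | 'none'
    bbox: tuple[float, float, float, float] | None = None
    landmarks: dict | None = None


def augment_image(
    img: SyntheticEyeImage, cfg: ImageAugmentConfig | None = None, seed: int = 0
) -> SyntheticEyeImage:
    """Rotate then add one noise type; output clipped to [0, 1], same shape."""
    cfg = cfg or ImageAugmentConfig()
    px = np.asarray(img.pixels, dtype=float)
    if px.size == 0:
        raise ValueError("empty image")
    rng = np.random.default_rng(seed)

    angle = rng.uniform(*cfg.rotation_range)
    out = px if angle == 0.0 else _sk_rotate(px, angle, mode="edge", preserve_range=True)

    if cfg.noise == "none":
        kind = None
    elif cfg.noise == "both":
        kind = "gaussian" if rng.random() < 0.5 else "saltpepper"
    elif cfg.noise in ("gaussian", "saltpepper"):
        kind = cfg.noise
    else:
        raise ValueError(f"unknown noise type {cfg.noise!r}")

    if kind == "gaussian":
        sd = rng.uniform(*cfg.gaussian_sd_range)
        out = out + rng.normal(0.0, sd, out.shape)
    elif kind == "saltpepper":
        density = rng.uniform(*cfg.saltpepper_density_range)
        flip = rng.random(out.shape) < density
        salt = rng.random(out.shape) < 0.5
        out = out.copy()
        out[flip & salt] = 1.0
        out[flip & ~salt] = 0.0

    out = np.clip(out, 0.0, 1.0)
    return SyntheticEyeImage(
        pixels=out, head_pose=img.head_pose.copy(), gaze_target=img.gaze_target
    )
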