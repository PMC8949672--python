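"""Clump-of-features (CoF) reduction: SFV -> bag-of-words histogram.

The spatial feature vector is reshaped back into its per-position channel
descriptors (one 128-vector per spatial cell of the final conv map at the
reference geometry).  A k-means vocabulary is fitted on the training
descriptors only — the inter-patient discipline: nothing from the test split
touches the vocabulary — and every beat is encoded as the normalised
histogram of nearest-centroid assignments (the reduced feature vector, RFV).

The cluster count k can be fixed (the elbow analysis on the original data
settles on 10) or chosen automatically: an SSE-vs-k elbow (largest
perpendicular distance to the chord between the curve's endpoints) validated
by mean silhouette.  Lloyd's iterations are run explicitly so the SSE trace
is observable and provably non-increasing; initialisation is k-means++.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

from .net import NetConfig

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorSet",
    "Vocabulary",
    "RFV",
    "SilhouetteReport",
    "sfv_to_descriptors",
    "kmeans_fit",
    "elbow_select",
    "silhouette",
    "encode_rfv",
    "fit_transform_split",
]

DEFAULT_K_GRID = tuple(range(2, 13))
DESCRIPTOR_CAP = 100_000  # seeded subsample cap for vocabulary fitting
SILHOUETTE_CAP = 2_000  # seeded subsample cap for silhouette validation


@dataclass
class DescriptorSet:
    descriptors: np.ndarray  # n x d
    owner: tuple[str, int] = ("", 0)


@dataclass
class Vocabulary:
    centroids: np.ndarray  # k x d
    k: int
    fit_seed: int
    sse: float
    sse_trace: list[float] = field(default_factory=list)


@dataclass
class RFV:
    histogram: np.ndarray  # length k, sums to 1
    label: str | None = None
    beat_ref: tuple[str, int] = ("", 0)


@dataclass
class SilhouetteReport:
    coefficients: np.ndarray  # per-sample, in [-1, 1]

    @property
    def mean(self) -> float:
        return float(self.coefficients.mean())


def sfv_to_descriptors(sfv: np.ndarray, cfg: NetConfig,
                       owner=("", 0)) -> DescriptorSet:
    """Reshape a flat SFV into one channel-vector per spatial position.

    The SFV is the row-major flatten of a (c3, side, side) map; descriptor i
    is the c3-vector at spatial position i, so the reshape inverts exactly.
    """
    sfv = np.asarray(sfv).ravel()
    d = cfg.conv_channels[2]
    n = cfg.pooled_side**2
    if sfv.size != n * d:
        raise ValueError(
            f"SFV length {sfv.size} does not factor as {n} positions x {d} "
            f"channels for this config"
        )
    return DescriptorSet(sfv.reshape(d, n).T.copy(), owner=owner)


def descriptors_to_sfv(desc: DescriptorSet) -> np.ndarray:
    """Exact inverse of sfv_to_descriptors."""
    return desc.descriptors.T.ravel().copy()


def kmeans_fit(
    descriptors: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> Vocabulary:
    """Lloyd's algorithm with k-means++ seeding.

    Stops when the relative SSE improvement drops below ``tol`` or
    assignments stabilise; the recorded SSE trace is non-increasing.  An
    emptied cluster is re-seeded on the point farthest from its centroid.
    """
    X = np.asarray(descriptors, dtype=float)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    centroids, _ = kmeans_plusplus(X, n_clusters=k, random_state=seed)
    trace: list[float] = []
    prev_sse = np.inf
    for _ in range(max_iter):
        D2 = cdist(X, centroids, "sqeuclidean")
        assign = D2.argmin(axis=1)
        sse = float(D2[np.arange(n), assign].sum())
        trace.append(sse)
        new = centroids.copy()
        for j in range(k):
            mask = assign == j
            if mask.any():
                new[j] = X[mask].mean(axis=0)
            else:  # re-seed an empty cluster on the worst-fit point
                far = D2[np.arange(n), assign].argmax()
                new[j] = X[far]
        if prev_sse - sse <= tol * max(sse, 1e-12):
            centroids = new
            break
        prev_sse = sse
        centroids = new
    # final SSE against the returned centroids
    D2 = cdist(X, centroids, "sqeuclidean")
    final_sse = float(D2.min(axis=1).sum())
    trace.append(final_sse)
    return Vocabulary(centroids=centroids, k=k, fit_seed=seed,
                      sse=final_sse, sse_trace=trace)


def elbow_select(
    descriptors: np.ndarray,
    k_grid=DEFAULT_K_GRID,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Knee of the SSE-vs-k curve (max perpendicular distance to the chord
    joining the endpoints); ties break toward smaller k.  A degenerate flat
    or linear curve falls back to the smallest k with a warning."""
    k_grid = list(k_grid)
    if len(k_grid) < 3 or any(b <= a for a, b in zip(k_grid, k_grid[1:])):
        raise ValueError("k_grid must be strictly increasing with length >= 3")
    sse = np.array([kmeans_fit(descriptors, k, seed=seed).sse for k in k_grid])
    ks = np.array(k_grid, dtype=float)
    # normalise both axes so the chord geometry is scale-free
    span = sse[0] - sse[-1]
    if span <= 0:
        warnings.warn("degenerate flat SSE curve; falling back to smallest k")
        return k_grid[0], sse
    xs = (ks - ks[0]) / (ks[-1] - ks[0])
    ys = (sse - sse[-1]) / span
    # distance from each point to the chord y = 1 - x
    dist = (1.0 - xs - ys) / np.sqrt(2.0)
    best = int(np.argmax(np.round(dist, 12)))  # ties -> smaller k via argmax
    if dist[best] <= 1e-9:
        warnings.warn("SSE curve is linear; falling back to smallest k")
        return k_grid[0], sse
    return k_grid[best], sse


def silhouette(descriptors: np.ndarray, assignments: np.ndarray) -> SilhouetteReport:
    """Per-sample silhouette coefficients.

    a_i = mean distance to the other members of its own cluster, b_i = the
    smallest mean distance to any other cluster, s_i = (b_i - a_i) /
    max(a_i, b_i).  A sample alone in its cluster scores 0.
    """
    X = np.asarray(descriptors, dtype=float)
    assign = np.asarray(assignments)
    labels = np.unique(assign)
    if labels.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    D = cdist(X, X)
    n = X.shape[0]
    s = np.zeros(n)
    members = {l: np.flatnonzero(assign == l) for l in labels}
    for i in range(n):
        own = members[assign[i]]
        if own.size == 1:
            s[i] = 0.0
            continue
        a_i = D[i, own].sum() / (own.size - 1)
        b_i = min(D[i, members[l]].mean() for l in labels if l != assign[i])
        denom = max(a_i, b_i)
        s[i] = 0.0 if denom == 0 else (b_i - a_i) / denom
    return SilhouetteReport(coefficients=s)


def encode_rfv(desc: DescriptorSet, vocab: Vocabulary,
               label: str | None = None) -> RFV:
    """Histogram of nearest-centroid assignments, normalised to sum 1.
    Distance ties go to the lowest centroid index."""
    X = desc.descriptors
    if X.shape[1] != vocab.centroids.shape[1]:
        raise ValueError(
            f"descriptor dim {X.shape[1]} != vocabulary dim "
            f"{vocab.centroids.shape[1]}"
        )
    assign = cdist(X, vocab.centroids, "sqeuclidean").argmin(axis=1)
    hist = np.bincount(assign, minlength=vocab.k).astype(float)
    hist /= hist.sum()
    return RFV(histogram=hist, label=label, beat_ref=desc.owner)


def fit_transform_split(
    train_sfvs: np.ndarray,
    test_sfvs: np.ndarray,
    cfg: NetConfig,
    k: int | str = "auto",
    seed: int = 0,
    train_labels=None,
    test_labels=None,
    k_grid=DEFAULT_K_GRID,
) -> tuple[list[RFV], list[RFV], Vocabulary]:
    """Fit the vocabulary on the training split only; encode both splits.

    ``k="auto"`` runs the elbow selection and logs a silhouette validation of
    the chosen clustering (on a seeded descriptor subsample).
    """
    train_sfvs = np.asarray(train_sfvs)
    if train_sfvs.size == 0:
        raise ValueError("training split must be non-empty")
    train_desc = [sfv_to_descriptors(v, cfg, owner=("train", i))
                  for i, v in enumerate(train_sfvs)]
    pool = np.concatenate([d.descriptors for d in train_desc], axis=0)
    rng = np.random.default_rng(seed)
    if pool.shape[0] > DESCRIPTOR_CAP:
        pool = pool[rng.choice(pool.shape[0], DESCRIPTOR_CAP, replace=False)]
    if k == "auto":
        k_chosen, sse_curve = elbow_select(pool, k_grid=k_grid, seed=seed)
        logger.info("elbow selected k=%d (SSE curve %s)", k_chosen,
                    np.array2string(sse_curve, precision=1))
    else:
        k_chosen = int(k)
    vocab = kmeans_fit(pool, k_chosen, seed=seed)
    if k == "auto":
        sub = pool
        if sub.shape[0] > SILHOUETTE_CAP:
            sub = sub[rng.choice(sub.shape[0], SILHOUETTE_CAP, replace=False)]
        assign = cdist(sub, vocab.centroids, "sqeuclidean").argmin(axis=1)
        if np.unique(assign).size >= 2:
            rep = silhouette(sub, assign)
            logger.info("silhouette validation: mean coefficient %.3f", rep.mean)
    lab_tr = list(train_labels) if train_labels is not None else [None] * len(train_desc)
    train_rfvs = [encode_rfv(d, vocab, label=l) for d, l in zip(train_desc, lab_tr)]
    test_sfvs = np.asarray(test_sfvs)
    if test_sfvs.size == 0:
        return train_rfvs, [], vocab
    test_desc = [sfv_to_descriptors(v, cfg, owner=("test", i))
                 for i, v in enumerate(test_sfvs)]
    lab_te = list(test_labels) if test_labels is not None else [None] * len(test_desc)
    test_rfvs = [encode_rfv(d, vocab, label=l) for d, l in zip(test_desc, lab_te)]
    return train_rfvs, test_rfvs, vocab
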