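"""Clump-of-features: reshape arithmetic, k-means vs exhaustive optimum,
elbow selection, silhouette vs brute force, histogram encoding, leakage."""

import itertools

import numpy as np
import pytest

from arrhythmianet.cof import (
    DescriptorSet,
    Vocabulary,
    descriptors_to_sfv,
    elbow_select,
    encode_rfv,
    fit_transform_split,
    kmeans_fit,
    sfv_to_descriptors,
    silhouette,
)
from arrhythmianet.net import NetConfig


def _cfg(side, c3):
    return NetConfig(input_side=side, conv_channels=(2, 3, c3), n_classes=2)


# -- reshape ----------------------------------------------------------------

def test_default_geometry_descriptor_factorisation():
    cfg = NetConfig()  # 2,097,152 = 16,384 positions x 128 channels
    sfv = np.arange(cfg.flatten_length, dtype=float)
    desc = sfv_to_descriptors(sfv, cfg)
    assert desc.descriptors.shape == (16_384, 128)


def test_small_geometry_descriptor_shape():
    cfg = NetConfig(input_side=64)
    desc = sfv_to_descriptors(np.zeros(cfg.flatten_length), cfg)
    assert desc.descriptors.shape == (1_024, 128)


def test_reshape_round_trip_is_exact(rng):
    cfg = _cfg(8, 5)
    sfv = rng.normal(size=cfg.flatten_length)
    back = descriptors_to_sfv(sfv_to_descriptors(sfv, cfg))
    np.testing.assert_array_equal(back, sfv)


def test_wrong_length_raises():
    with pytest.raises(ValueError, match="factor"):
        sfv_to_descriptors(np.zeros(7), _cfg(8, 5))


# -- k-means ----------------------------------------------------------------

def brute_force_best_partition(X, k):
    """Exhaustive search over all assignments of <=10 points into k clusters,
    minimising within-cluster sum of squares."""
    n = len(X)
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) < k:
            continue
        sse = 0.0
        for j in range(k):
            pts = X[[i for i in range(n) if assign[i] == j]]
            sse += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return best


def test_kmeans_equals_exhaustive_optimum_on_small_instances(rng):
    for trial in range(3):
        X = np.concatenate([
            rng.normal([0, 0], 0.1, size=(5, 2)),
            rng.normal([5, 5], 0.1, size=(5, 2)),
        ])
        vocab = kmeans_fit(X, k=2, seed=trial)
        assert vocab.sse == pytest.approx(brute_force_best_partition(X, 2),
                                          rel=1e-9)


def test_two_blob_partition_matches_membership(rng):
    X = np.concatenate([rng.normal([0, 0], 0.05, size=(6, 2)),
                        rng.normal([4, 4], 0.05, size=(6, 2))])
    vocab = kmeans_fit(X, k=2, seed=0)
    assign = np.linalg.norm(X[:, None] - vocab.centroids[None], axis=2).argmin(1)
    assert len(set(assign[:6])) == 1 and len(set(assign[6:])) == 1
    assert assign[0] != assign[6]


def test_k_equals_n_gives_zero_sse(rng):
    X = rng.normal(size=(6, 3))
    vocab = kmeans_fit(X, k=6, seed=0)
    assert vocab.sse == pytest.approx(0.0, abs=1e-18)


def test_kmeans_seeded_determinism(rng):
    X = rng.normal(size=(30, 4))
    v1 = kmeans_fit(X, k=3, seed=42)
    v2 = kmeans_fit(X, k=3, seed=42)
    np.testing.assert_array_equal(v1.centroids, v2.centroids)


def test_sse_trace_monotone_non_increasing(rng):
    X = rng.normal(size=(200, 5))
    vocab = kmeans_fit(X, k=4, seed=1)
    trace = np.asarray(vocab.sse_trace)
    assert np.all(np.diff(trace) <= 1e-9 * trace[0])


def test_too_few_points_raises(rng):
    with pytest.raises(ValueError, match="at least"):
        kmeans_fit(rng.normal(size=(2, 2)), k=3)


def test_sklearn_kmeans_cross_check(rng):
    """Independent implementation agreement on a well-separated instance."""
    from sklearn.cluster import KMeans

    X = np.concatenate([rng.normal([0, 0], 0.2, size=(20, 2)),
                        rng.normal([6, 0], 0.2, size=(20, 2)),
                        rng.normal([3, 5], 0.2, size=(20, 2))])
    ours = kmeans_fit(X, k=3, seed=0)
    ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
    assert ours.sse == pytest.approx(ref.inertia_, rel=1e-6)


# -- elbow ------------------------------------------------------------------

def test_elbow_finds_three_blobs(rng):
    X = np.concatenate([rng.normal([0, 0], 0.15, size=(30, 2)),
                        rng.normal([6, 0], 0.15, size=(30, 2)),
                        rng.normal([3, 5], 0.15, size=(30, 2))])
    k, curve = elbow_select(X, k_grid=range(2, 9), seed=0)
    assert k == 3
    assert np.all(np.diff(curve) <= 1e-9 * curve[0])  # non-increasing in k


def test_linear_sse_curve_falls_back_to_smallest_k(monkeypatch, rng):
    import arrhythmianet.cof as cof_mod

    def fake_fit(X, k, seed=0, **kw):
        return Vocabulary(centroids=np.zeros((k, 2)), k=k, fit_seed=seed,
                          sse=100.0 - 10.0 * k)

    monkeypatch.setattr(cof_mod, "kmeans_fit", fake_fit)
    with pytest.warns(UserWarning, match="linear"):
        k, _ = cof_mod.elbow_select(rng.normal(size=(20, 2)),
                                    k_grid=[2, 3, 4, 5], seed=0)
    assert k == 2


def test_degenerate_flat_curve_warns(monkeypatch, rng):
    import arrhythmianet.cof as cof_mod

    monkeypatch.setattr(
        cof_mod, "kmeans_fit",
        lambda X, k, seed=0, **kw: Vocabulary(np.zeros((k, 2)), k, seed, 5.0))
    with pytest.warns(UserWarning, match="flat"):
        k, _ = cof_mod.elbow_select(rng.normal(size=(20, 2)),
                                    k_grid=[2, 3, 4], seed=0)
    assert k == 2


def test_bad_k_grid_rejected(rng):
    with pytest.raises(ValueError):
        elbow_select(rng.normal(size=(20, 2)), k_grid=[2, 3], seed=0)
    with pytest.raises(ValueError):
        elbow_select(rng.normal(size=(20, 2)), k_grid=[4, 3, 2], seed=0)


# -- silhouette -------------------------------------------------------------

def brute_force_silhouette(X, assign):
    n = len(X)
    out = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if assign[j] == assign[i] and j != i]
        if not same:
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j])
                     for j in range(n) if assign[j] == c])
            for c in set(assign) if c != assign[i]
        )
        out[i] = (b - a) / max(a, b)
    return out


def test_silhouette_matches_brute_force(rng):
    X = rng.normal(size=(18, 3))
    assign = rng.integers(0, 3, size=18)
    while len(set(assign)) < 3:
        assign = rng.integers(0, 3, size=18)
    ours = silhouette(X, assign).coefficients
    np.testing.assert_allclose(ours, brute_force_silhouette(X, assign),
                               atol=1e-12)
    assert np.all(ours >= -1) and np.all(ours <= 1)


def test_silhouette_matches_sklearn(rng):
    from sklearn.metrics import silhouette_samples

    X = rng.normal(size=(20, 4))
    assign = np.array([0] * 7 + [1] * 7 + [2] * 6)
    np.testing.assert_allclose(silhouette(X, assign).coefficients,
                               silhouette_samples(X, assign), atol=1e-9)


def test_equidistant_sample_scores_zero():
    X = np.array([[0.0], [2.0], [4.0]])
    # sample 1 is equidistant from its own cluster-mate... construct exactly:
    X = np.array([[0.0], [1.0], [2.0]])
    assign = np.array([0, 0, 1])
    s = silhouette(X, assign).coefficients
    # sample 1: a = 1 (to sample 0), b = 1 (to sample 2) -> 0
    assert s[1] == pytest.approx(0.0, abs=1e-12)


def test_far_apart_tight_clusters_score_high(rng):
    X = np.concatenate([rng.normal(0, 0.01, size=(5, 2)),
                        rng.normal(10, 0.01, size=(5, 2))])
    assign = np.array([0] * 5 + [1] * 5)
    s = silhouette(X, assign).coefficients
    assert np.all(s >= 0.9) and np.all(s <= 1.0)


def test_misassigned_sample_scores_negative(rng):
    X = np.concatenate([rng.normal(0, 0.01, size=(5, 2)),
                        rng.normal(10, 0.01, size=(5, 2))])
    assign = np.array([0] * 5 + [1] * 5)
    assign[0] = 1  # wrong cluster
    s = silhouette(X, assign).coefficients
    assert s[0] < 0
    np.testing.assert_allclose(s, brute_force_silhouette(X, assign), atol=1e-12)


def test_single_cluster_rejected(rng):
    with pytest.raises(ValueError, match="2 clusters"):
        silhouette(rng.normal(size=(5, 2)), np.zeros(5, dtype=int))


def test_singleton_cluster_scores_zero():
    X = np.array([[0.0], [0.1], [5.0]])
    s = silhouette(X, np.array([0, 0, 1])).coefficients
    assert s[2] == 0.0


# -- RFV encoding -----------------------------------------------------------

def test_one_hot_histogram():
    vocab = Vocabulary(np.array([[0.0, 0.0], [10.0, 10.0]]), 2, 0, 0.0)
    desc = DescriptorSet(np.zeros((4, 2)))
    rfv = encode_rfv(desc, vocab)
    np.testing.assert_array_equal(rfv.histogram, [1.0, 0.0])


def test_histogram_sums_to_one(rng):
    vocab = Vocabulary(rng.normal(size=(5, 3)), 5, 0, 0.0)
    rfv = encode_rfv(DescriptorSet(rng.normal(size=(33, 3))), vocab)
    assert rfv.histogram.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(rfv.histogram >= 0)


def test_three_vs_one_split():
    vocab = Vocabulary(np.array([[0.0], [10.0]]), 2, 0, 0.0)
    desc = DescriptorSet(np.array([[0.1], [0.2], [-0.1], [9.8]]))
    rfv = encode_rfv(desc, vocab)
    np.testing.assert_allclose(rfv.histogram, [0.75, 0.25])


def test_dimension_mismatch_raises(rng):
    vocab = Vocabulary(rng.normal(size=(2, 3)), 2, 0, 0.0)
    with pytest.raises(ValueError, match="dim"):
        encode_rfv(DescriptorSet(rng.normal(size=(4, 2))), vocab)


# -- split-aware fit --------------------------------------------------------

def _blob_sfvs(rng, cfg, centers, n_each):
    """SFVs whose descriptors sit in given blobs (one blob per beat)."""
    d = cfg.conv_channels[2]
    n_pos = cfg.pooled_side**2
    out = []
    for c in centers:
        for _ in range(n_each):
            desc = rng.normal(c, 0.05, size=(n_pos, d))
            out.append(descriptors_to_sfv(DescriptorSet(desc)))
    return np.asarray(out)


def test_vocabulary_depends_only_on_training_split(rng):
    cfg = _cfg(8, 3)
    train_sfvs = _blob_sfvs(rng, cfg, [0.0, 4.0], 5)
    test_a = _blob_sfvs(rng, cfg, [1.0], 2)
    test_b = test_a + 100.0
    _, _, v1 = fit_transform_split(train_sfvs, test_a, cfg, k=2, seed=0)
    _, _, v2 = fit_transform_split(train_sfvs, test_b, cfg, k=2, seed=0)
    np.testing.assert_array_equal(v1.centroids, v2.centroids)


def test_auto_k_on_three_blob_fixture(rng):
    cfg = _cfg(8, 3)
    sfvs = _blob_sfvs(rng, cfg, [0.0, 5.0, -5.0], 6)
    train_rfvs, _, vocab = fit_transform_split(
        sfvs, np.empty((0,)), cfg, k="auto", seed=0, k_grid=range(2, 9))
    assert vocab.k == 3
    sub = np.concatenate(
        [sfv_to_descriptors(v, cfg).descriptors for v in sfvs])[:200]
    from scipy.spatial.distance import cdist

    assign = cdist(sub, vocab.centroids).argmin(axis=1)
    assert silhouette(sub, assign).mean > 0.5


def test_explicit_k_sets_rfv_length(rng):
    cfg = _cfg(8, 3)
    sfvs = _blob_sfvs(rng, cfg, [0.0, 5.0], 6)
    tr, te, vocab = fit_transform_split(sfvs[:8], sfvs[8:], cfg, k=10, seed=0)
    assert vocab.k == 10
    assert all(len(r.histogram) == 10 for r in tr + te)


def test_empty_test_split_allowed(rng):
    cfg = _cfg(8, 3)
    sfvs = _blob_sfvs(rng, cfg, [0.0, 5.0], 3)
    tr, te, _ = fit_transform_split(sfvs, np.empty((0,)), cfg, k=2, seed=0)
    assert te == [] and len(tr) == 6


def test_empty_train_split_rejected(rng):
    with pytest.raises(ValueError, match="non-empty"):
        fit_transform_split(np.empty((0,)), np.empty((0,)), _cfg(8, 3), k=2)
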