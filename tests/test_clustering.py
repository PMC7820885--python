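"""Soft assignment, target sharpening, KLD hardening gradients, and the
joint training loop."""

import numpy as np
import pytest

import deepclust as dc
from conftest import make_random_cluster_state

# ------------------------------------------------------------ soft assign


def test_soft_assign_worked_example():
    # z at the first centroid, second centroid 2 away, alpha=1:
    # kernels (1, 1/5) -> (5/6, 1/6)
    Q = dc.soft_assign(np.array([[0.0, 0.0]]),
                       np.array([[0.0, 0.0], [2.0, 0.0]]), alpha=1.0)
    assert Q[0] == pytest.approx([5 / 6, 1 / 6], abs=1e-12)


def test_soft_assign_equidistant_symmetry():
    Q = dc.soft_assign(np.array([[0.0, 1.0]]),
                       np.array([[-1.0, 0.0], [1.0, 0.0]]))
    assert Q[0] == pytest.approx([0.5, 0.5])


def test_soft_assign_translation_invariance(rng):
    Z = rng.normal(size=(6, 3))
    mu = rng.normal(size=(2, 3))
    shift = rng.normal(size=3)
    np.testing.assert_allclose(dc.soft_assign(Z, mu),
                               dc.soft_assign(Z + shift, mu + shift))


def test_soft_assign_rows_normalized(rng):
    Z, mu, Q, P = make_random_cluster_state(rng, 50, 4, 3)
    np.testing.assert_allclose(Q.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(Q > 0) and np.all(Q < 1)
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(Q.sum(axis=0) > 0)


def test_soft_assign_dimension_mismatch():
    with pytest.raises(ValueError):
        dc.soft_assign(np.zeros((3, 2)), np.zeros((2, 3)))


# ------------------------------------------------------ target distribution


def test_target_distribution_worked_example():
    Q = np.array([[0.9, 0.1], [0.6, 0.4], [0.3, 0.7]])
    P = dc.target_distribution(Q)
    expected = np.array([[0.9818, 0.0182], [0.6000, 0.4000], [0.1091, 0.8909]])
    np.testing.assert_allclose(P, expected, atol=1e-4)


def test_target_distribution_single_sample_identity():
    Q = np.array([[0.3, 0.7]])
    np.testing.assert_allclose(dc.target_distribution(Q), Q, atol=1e-15)


def test_target_distribution_uniform_fixed_point():
    Q = np.full((5, 4), 0.25)
    np.testing.assert_allclose(dc.target_distribution(Q), Q)


def test_target_distribution_sharpens_at_equal_frequencies():
    # balanced cluster frequencies: squaring can only lower row entropy
    Q = np.array([[0.7, 0.3], [0.3, 0.7], [0.6, 0.4], [0.4, 0.6]])
    P = dc.target_distribution(Q)

    def row_entropy(M):
        return -(M * np.log(M)).sum(axis=1)

    assert np.all(row_entropy(P) <= row_entropy(Q) + 1e-12)


def test_target_distribution_zero_frequency_error():
    with pytest.raises(ValueError):
        dc.target_distribution(np.array([[1.0, 0.0], [1.0, 0.0]]))


# ---------------------------------------------------------------- KLD loss


def test_kld_identity_and_ln2():
    Q = np.array([[0.4, 0.6], [0.2, 0.8]])
    assert dc.kld_loss(Q, Q) == 0.0
    assert dc.kld_loss(np.array([[1.0, 0.0]]),
                       np.array([[0.5, 0.5]])) == pytest.approx(np.log(2))


def test_kld_nonnegative_and_zero_iff_equal(rng):
    for _ in range(30):
        P = rng.dirichlet(np.ones(3), size=6)
        Q = rng.dirichlet(np.ones(3), size=6)
        v = dc.kld_loss(P, Q)
        assert v >= 0
        if not np.allclose(P, Q):
            assert v > 0


def test_kld_zero_support_handling():
    P = np.array([[1.0, 0.0]])
    Qz = np.array([[0.0, 1.0]])
    assert dc.kld_loss(P, Qz) == np.inf
    with pytest.raises(ValueError):
        dc.kld_loss(P, Qz, on_zero="raise")


def test_kld_is_pure_function(rng):
    _, _, Q, P = make_random_cluster_state(rng, 10, 3, 2)
    assert dc.kld_loss(P, Q) == dc.kld_loss(dc.target_distribution(Q), Q)


# ---------------------------------------------------------------- gradients


def fd_gradients(Z, mu, P, alpha=1.0, eps=1e-6):
    def L(Z_, mu_):
        return dc.kld_loss(P, dc.soft_assign(Z_, mu_, alpha))

    dZ = np.zeros_like(Z)
    for i in range(Z.shape[0]):
        for j in range(Z.shape[1]):
            zp, zm = Z.copy(), Z.copy()
            zp[i, j] += eps
            zm[i, j] -= eps
            dZ[i, j] = (L(zp, mu) - L(zm, mu)) / (2 * eps)
    dMu = np.zeros_like(mu)
    for i in range(mu.shape[0]):
        for j in range(mu.shape[1]):
            mp, mm = mu.copy(), mu.copy()
            mp[i, j] += eps
            mm[i, j] -= eps
            dMu[i, j] = (L(Z, mp) - L(Z, mm)) / (2 * eps)
    return dZ, dMu


def test_gradients_zero_when_p_equals_q(rng):
    Z, mu, Q, _ = make_random_cluster_state(rng, 5, 2, 2)
    dZ, dMu = dc.clustering_gradients(Z, mu, Q, Q)
    assert np.all(dZ == 0) and np.all(dMu == 0)


def test_gradients_match_finite_differences(rng):
    for _ in range(10):
        n = int(rng.integers(2, 9))
        K = int(rng.integers(2, 4))
        d = int(rng.integers(1, 5))
        Z, mu, Q, P = make_random_cluster_state(rng, n, K, d)
        dZ, dMu = dc.clustering_gradients(Z, mu, P, Q)
        fZ, fMu = fd_gradients(Z, mu, P)
        scale = max(np.abs(fZ).max(), np.abs(fMu).max(), 1e-12)
        assert np.abs(dZ - fZ).max() / scale < 1e-5
        assert np.abs(dMu - fMu).max() / scale < 1e-5


def test_gradient_translation_invariance(rng):
    Z, mu, Q, P = make_random_cluster_state(rng, 12, 3, 4)
    dZ, dMu = dc.clustering_gradients(Z, mu, P, Q)
    assert np.abs(dZ.sum(axis=0) + dMu.sum(axis=0)).max() < 1e-9


# ------------------------------------------------------------ combined loss


def test_combined_loss_endpoints_and_midpoint():
    assert dc.combined_loss(2.0, 4.0, 0.0) == 4.0
    assert dc.combined_loss(2.0, 4.0, 1.0) == 2.0
    assert dc.combined_loss(2.0, 4.0, 0.5) == 3.0
    with pytest.raises(ValueError):
        dc.combined_loss(1.0, 1.0, 1.5)


# ------------------------------------------------------------- init/pipeline


def test_init_centroids_degenerate_n_equals_k(rng):
    Z = rng.normal(size=(3, 2))
    for algo in ("kmeans", "agglomerative", "gmm"):
        mu = dc.init_centroids(Z, 3, algo, seed=0)
        # every point is its own centroid, in some order
        d = ((mu[:, None] - Z[None]) ** 2).sum(-1)
        assert d.min(axis=1).max() < 1e-12


def test_init_centroids_pair_midpoints():
    Z = np.array([[0.0, 0.0], [0.2, 0.0], [10.0, 0.0], [10.2, 0.0]])
    mu = dc.init_centroids(Z, 2, "kmeans", seed=0)
    mids = np.array([[0.1, 0.0], [10.1, 0.0]])
    d = ((np.sort(mu[:, 0])[:, None] - np.sort(mids[:, 0])[None]) ** 2)
    assert np.allclose(np.sort(mu[:, 0]), np.sort(mids[:, 0]))


def test_init_centroids_determinism_and_errors(rng):
    Z = rng.normal(size=(30, 2))
    a = dc.init_centroids(Z, 3, "kmeans", seed=5)
    b = dc.init_centroids(Z, 3, "kmeans", seed=5)
    np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError):
        dc.init_centroids(Z, 31, "kmeans")
    with pytest.raises(ValueError):
        dc.init_centroids(Z, 3, "dbscan")


def test_pipeline_cluster_separable_groups(rng):
    Z = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))])
    truth = np.repeat([0, 1], 20)
    for algo, kwargs in [("kmeans", {"n_clusters": 2}),
                         ("agglomerative", {"n_clusters": 2}),
                         ("gmm", {"n_clusters": 2}),
                         ("dbscan", {"eps": 0.5}),
                         ("optics", {"min_samples": 5,
                                     "cluster_method": "dbscan",
                                     "eps": 0.5})]:
        labels = dc.pipeline_cluster(Z, algo, seed=0, **kwargs)
        assert dc.unsupervised_accuracy(truth, labels) == 1.0


def test_dbscan_all_noise(rng):
    Z = np.arange(10, dtype=float)[:, None] * 100
    labels = dc.pipeline_cluster(Z, "dbscan", eps=1.0, min_samples=2)
    assert np.all(labels == -1)


def test_pipeline_cluster_unknown_algorithm():
    with pytest.raises(ValueError):
        dc.pipeline_cluster(np.zeros((3, 2)), "meanshift")


# ------------------------------------------------------------ joint training


def test_fixed_point_converges_within_two_refreshes():
    # samples exactly at K separated centroids, identity-like encoder:
    # assignments never change, so the tol rule fires at the 2nd refresh
    ds = dc.make_blob_dataset(n_per_class=20, n_clusters=2, latent_dim=2,
                              ambient_dim=2, separation=10, noise_sd=0.0,
                              seed=0, ambient_map="identity")
    spec = dc.BackboneSpec(family="dense", layer_sizes=[8], latent_dim=2)
    model = dc.build_backbone(spec, (2,), seed=0)
    dc.train_reconstruction(model, ds.values, epochs=40, seed=0)
    cfg = dc.TrainConfig(seed=0, max_iters=40, update_interval=20,
                         val_fraction=0.0)
    fitted = dc.fit_deep_clustering(model, ds.values, 2, cfg)
    assert fitted.converged
    assert fitted.iterations_run <= 2
    assert fitted.loss_history["pct_changed"].iloc[-1] == 0.0


def test_joint_mode_rejects_density_algorithms(blob600, dense_spec):
    model = dc.build_backbone(dense_spec, (50,), seed=0)
    cfg = dc.TrainConfig(base_algorithm="dbscan")
    with pytest.raises(ValueError, match="pipeline_cluster"):
        dc.fit_deep_clustering(model, blob600.values, 3, cfg)


def test_sigma_zero_leaves_centroids_untouched(blob600, dense_spec):
    model = dc.build_backbone(dense_spec, (50,), seed=0)
    dc.train_reconstruction(model, blob600.values, epochs=5, seed=0)
    cfg = dc.TrainConfig(sigma=0.0, max_iters=10, update_interval=5, seed=0,
                         tol=1e-9)
    fitted = dc.fit_deep_clustering(model.copy(), blob600.values, 3, cfg)
    # with the clustering loss disabled the centroids stay at their
    # k-means initialization
    train_idx = np.random.default_rng(0).permutation(600)[60:]
    init = dc.init_centroids(model.encode(blob600.values[train_idx]), 3,
                             "kmeans", seed=0)
    np.testing.assert_allclose(fitted.state.centroids, init, atol=1e-8)


def test_blob_recovery_and_history(blob600, dense_spec):
    model = dc.build_backbone(dense_spec, (50,), seed=1)
    dc.train_reconstruction(model, blob600.values, epochs=30, seed=1)
    cfg = dc.TrainConfig(seed=1, max_iters=1400, update_interval=140)
    fitted = dc.fit_deep_clustering(model, blob600.values, 3, cfg)
    assert dc.unsupervised_accuracy(blob600.labels, fitted.labels) >= 0.95
    h = fitted.loss_history
    assert h["L_KLD"].iloc[-1] <= h["L_KLD"].iloc[0]
    assert np.isfinite(h[["L_AE", "L_KLD", "combined"]].to_numpy()).all()
    assert fitted.G is not None and fitted.G > 0
    # state invariants after the run
    np.testing.assert_allclose(fitted.state.Q.sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_allclose(fitted.state.P.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(fitted.state.cluster_frequencies > 0)


def test_sweep_k_contract(blob600, dense_spec):
    model = dc.build_backbone(dense_spec, (50,), seed=1)
    dc.train_reconstruction(model, blob600.values, epochs=20, seed=1)
    cfg = dc.TrainConfig(seed=1, max_iters=280, update_interval=140)
    table = dc.sweep_k(model, blob600.values, range(2, 5), cfg,
                       labels=blob600.labels)
    assert list(table["K"]) == [2, 3, 4]
    assert table["NMI"].notna().all()
    t2 = dc.sweep_k(model, blob600.values, range(2, 5), cfg)
    assert t2["NMI"].isna().all()
    with pytest.raises(ValueError):
        dc.sweep_k(model, blob600.values, [], cfg)
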