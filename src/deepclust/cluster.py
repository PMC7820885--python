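"""Two-phase deep embedded clustering with cluster-assignment hardening.

Phase 1 trains an autoencoder backbone on the reconstruction objective
alone.  Phase 2 discards the decoder branch (or down-weights it),
initializes K centroids on the latent features with a conventional
algorithm, and then alternates between (a) soft-assigning samples to
centroids with a Student's-t kernel, (b) deriving a sharpened auxiliary
target distribution from the assignments, and (c) minimizing the KL
divergence between the two by backpropagating its analytic gradients
through the encoder while the centroids move as trainable parameters.
Training stops when fewer than ``tol`` percent of samples change their
hard assignment between consecutive target refreshes.

Density-based algorithms (DBSCAN, OPTICS) have no centroids, so they
participate only in pipeline mode: extract latent features, cluster them
conventionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN, OPTICS, AgglomerativeClustering, KMeans
from sklearn.mixture import GaussianMixture

from .autoencoders import BackboneModel, train_reconstruction
from .containers import as_values
from .nn import Adam, Tensor

__all__ = [
    "ClusterState",
    "TrainConfig",
    "FittedClustering",
    "init_centroids",
    "soft_assign",
    "target_distribution",
    "kld_loss",
    "clustering_gradients",
    "combined_loss",
    "fit_deep_clustering",
    "pipeline_cluster",
    "sweep_k",
]

CENTROID_ALGORITHMS = ("kmeans", "agglomerative", "gmm")
DENSITY_ALGORITHMS = ("dbscan", "optics")


@dataclass
class ClusterState:
    """Centroids, soft assignments Q, target distribution P, hard labels."""

    K: int
    centroids: np.ndarray
    Q: np.ndarray
    P: np.ndarray
    alpha: float = 1.0

    @property
    def cluster_frequencies(self) -> np.ndarray:
        return self.Q.sum(axis=0)

    @property
    def hard_labels(self) -> np.ndarray:
        return self.Q.argmax(axis=1)


@dataclass
class TrainConfig:
    """Settings for the hardening phase.

    ``sigma`` weights the combined loss sigma*L_KLD + (1-sigma)*L_AE.
    ``None`` selects the hard schedule (reconstruction only during
    pretraining, pure clustering loss afterwards, i.e. sigma=1 in phase
    2); a constant in (0, 1] keeps joint training.  ``tol`` is the
    stopping threshold in percent of samples changing assignment between
    target refreshes; ``update_interval`` counts optimizer steps between
    refreshes.
    """

    sigma: float | None = None
    tol: float = 0.1
    max_iters: int = 2000
    update_interval: int = 140
    base_algorithm: str = "kmeans"
    lr: float = 1e-3
    alpha: float = 1.0
    pretrain_epochs: int = 0
    pretrain_batch_size: int = 32
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma is not None and not 0 <= self.sigma <= 1:
            raise ValueError("sigma must lie in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class FittedClustering:
    labels: np.ndarray
    state: ClusterState
    loss_history: pd.DataFrame
    G: float | None
    iterations_run: int
    converged: bool
    optimizer_steps: int = 0


# -- the soft-assignment / hardening primitives -------------------------


def soft_assign(Z: np.ndarray, centroids: np.ndarray, alpha: float = 1.0
                ) -> np.ndarray:
    """Student's-t kernel soft assignment.

    q_ij = (1 + ||z_i - mu_j||^2 / alpha)^(-(alpha+1)/2), row-normalized.
    With alpha=1 this is the Cauchy kernel used throughout the deep
    embedded clustering literature.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    Z = np.asarray(Z, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    if Z.ndim != 2 or centroids.ndim != 2 or Z.shape[1] != centroids.shape[1]:
        raise ValueError("latent and centroid dimensions do not match")
    d2 = ((Z[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
    kernel = (1.0 + d2 / alpha) ** (-(alpha + 1.0) / 2.0)
    return kernel / kernel.sum(axis=1, keepdims=True)


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """Auxiliary target p_ij = (q_ij^2 / f_j) / sum_j' (q_ij'^2 / f_j').

    Squaring emphasizes confident assignments; dividing by the soft
    cluster frequencies f_j = sum_i q_ij counteracts large clusters.
    """
    Q = np.asarray(Q, dtype=float)
    f = Q.sum(axis=0)
    if np.any(f <= 0):
        raise ValueError("zero cluster frequency: target distribution undefined")
    weight = Q ** 2 / f
    return weight / weight.sum(axis=1, keepdims=True)


def kld_loss(P: np.ndarray, Q: np.ndarray, on_zero: str = "inf") -> float:
    """KL(P || Q) = sum_ij p_ij ln(p_ij / q_ij), natural log, 0*ln(0/q)=0."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("P and Q must have the same shape")
    mask = P > 0
    if np.any(Q[mask] <= 0):
        if on_zero == "raise":
            raise ValueError("q_ij = 0 where p_ij > 0: KL divergence infinite")
        return float("inf")
    return float((P[mask] * np.log(P[mask] / Q[mask])).sum())


def clustering_gradients(Z: np.ndarray, centroids: np.ndarray,
                         P: np.ndarray, Q: np.ndarray, alpha: float = 1.0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of KL(P||Q) w.r.t. latent points and centroids.

    dL/dz_i =  ((alpha+1)/alpha) sum_j (1 + ||z_i-mu_j||^2/alpha)^-1
               (p_ij - q_ij)(z_i - mu_j)
    dL/dmu_j = -((alpha+1)/alpha) sum_i (same factor).

    Their totals cancel (the loss is translation invariant).
    """
    Z = np.asarray(Z, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if Z.shape[1] != centroids.shape[1] or P.shape != Q.shape:
        raise ValueError("inconsistent shapes")
    diff = Z[:, None, :] - centroids[None, :, :]  # (n, K, d)
    d2 = (diff ** 2).sum(-1)
    factor = ((alpha + 1.0) / alpha) * (P - Q) / (1.0 + d2 / alpha)  # (n, K)
    contrib = factor[:, :, None] * diff
    dZ = contrib.sum(axis=1)
    dMu = -contrib.sum(axis=0)
    return dZ, dMu


def combined_loss(L_clustering: float, L_nonclustering: float,
                  sigma: float) -> float:
    """Convex combination sigma * L_KLD + (1 - sigma) * L_AE."""
    if not 0 <= sigma <= 1:
        raise ValueError("sigma must lie in [0, 1]")
    return sigma * L_clustering + (1 - sigma) * L_nonclustering


# -- centroid initialization and pipeline clustering --------------------


def init_centroids(Z: np.ndarray, K: int, algorithm: str = "kmeans",
                   seed: int = 0) -> np.ndarray:
    """K initial centroids on the latent features.

    k-means uses its own optimized centers; agglomerative (Ward) and
    Gaussian-mixture centroids are the mean of each found group /
    component.  Density-based algorithms have no centroids and are
    rejected here (use :func:`pipeline_cluster`).
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if K > n:
        raise ValueError("K cannot exceed the number of samples")
    if algorithm in DENSITY_ALGORITHMS:
        raise ValueError(
            f"{algorithm} produces no centroids; use pipeline_cluster instead")
    if algorithm not in CENTROID_ALGORITHMS:
        raise ValueError(f"unknown centroid algorithm {algorithm!r}")
    if n == K:
        return Z.copy()
    if algorithm == "kmeans":
        km = KMeans(n_clusters=K, n_init=10, random_state=seed).fit(Z)
        return km.cluster_centers_
    if algorithm == "agglomerative":
        labels = AgglomerativeClustering(n_clusters=K, linkage="ward").fit_predict(Z)
        return np.vstack([Z[labels == k].mean(axis=0) for k in range(K)])
    gm = GaussianMixture(n_components=K, covariance_type="full",
                         random_state=seed).fit(Z)
    return gm.means_


def pipeline_cluster(Z: np.ndarray, algorithm: str, seed: int = 0,
                     **params) -> np.ndarray:
    """Cluster latent features with a conventional algorithm.

    Supports kmeans, agglomerative (Ward), gmm (full covariance), dbscan
    and optics (xi extraction); density-based algorithms may label noise
    points -1.
    """
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("latent features must be finite")
    if algorithm == "kmeans":
        return KMeans(n_clusters=params.pop("n_clusters"), n_init=10,
                      random_state=seed, **params).fit_predict(Z)
    if algorithm == "agglomerative":
        return AgglomerativeClustering(
            n_clusters=params.pop("n_clusters"),
            linkage=params.pop("linkage", "ward"), **params).fit_predict(Z)
    if algorithm == "gmm":
        return GaussianMixture(n_components=params.pop("n_clusters"),
                               covariance_type=params.pop("covariance_type", "full"),
                               random_state=seed, **params).fit(Z).predict(Z)
    if algorithm == "dbscan":
        return DBSCAN(**params).fit_predict(Z)
    if algorithm == "optics":
        params.setdefault("min_samples", 5)
        return OPTICS(cluster_method=params.pop("cluster_method", "xi"),
                      **params).fit_predict(Z)
    raise ValueError(f"unknown clustering algorithm {algorithm!r}")


# -- the joint training loop --------------------------------------------


def _refresh_state(model: BackboneModel, values: np.ndarray,
                   centroids: np.ndarray, alpha: float
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    Z = model.encode(values)
    Q = soft_assign(Z, centroids, alpha)
    P = target_distribution(Q)
    return Z, Q, P


def fit_deep_clustering(model: BackboneModel, X, K: int,
                        config: TrainConfig | None = None) -> FittedClustering:
    """Run the two-phase procedure and return labels + diagnostics.

    Phase 1 (optional here; set ``config.pretrain_epochs`` or pass an
    already-pretrained backbone) minimizes the reconstruction loss
    alone.  Phase 2 initializes centroids with ``config.base_algorithm``
    on the encoded training samples and takes full-batch Adam steps on
    the combined loss, injecting the analytic hardening gradients into
    the encoder's backward pass; the auxiliary target P is refreshed
    every ``update_interval`` steps and the run stops once fewer than
    ``tol`` percent of training samples change hard assignment between
    refreshes.

    The generalizability ratio G = L_train / L_validation is computed on
    a seeded 90/10 split; only the training split drives the gradients.
    """
    config = config or TrainConfig()
    if config.base_algorithm in DENSITY_ALGORITHMS:
        raise ValueError(
            f"{config.base_algorithm} has no centroid update rule for joint "
            "training; use pipeline_cluster on encoded features instead")
    rng = np.random.default_rng(config.seed)
    values = as_values(X)
    n = values.shape[0]
    if K > n:
        raise ValueError("K cannot exceed the number of samples")

    perm = rng.permutation(n)
    n_val = int(round(config.val_fraction * n))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    train_values = values[train_idx]

    # Phase 1: representation learning with the non-clustering loss only
    if config.pretrain_epochs > 0:
        train_reconstruction(model, train_values, epochs=config.pretrain_epochs,
                             lr=config.lr, batch_size=config.pretrain_batch_size,
                             seed=config.seed)

    sigma = 1.0 if config.sigma is None else config.sigma
    alpha = config.alpha
    n_train = train_values.shape[0]

    Z = model.encode(train_values)
    centroids = init_centroids(Z, K, config.base_algorithm, seed=config.seed)
    centroid_t = Tensor(centroids.copy(), requires_grad=True)
    opt = Adam(model.parameters() + [centroid_t], lr=config.lr)

    history: list[dict] = []
    prev_labels: np.ndarray | None = None
    P = None
    converged = False
    refreshes = 0
    steps_done = 0

    for step in range(int(config.max_iters) + 1):
        if step % config.update_interval == 0:
            Z, Q, P = _refresh_state(model, train_values, centroid_t.data, alpha)
            hard = Q.argmax(axis=1)
            # keep K clusters alive: re-seed any empty centroid at the
            # least-confidently assigned sample
            counts = np.bincount(hard, minlength=K)
            if np.any(counts == 0):
                for j in np.flatnonzero(counts == 0):
                    centroid_t.data[j] = Z[np.argmin(Q.max(axis=1))]
                Z, Q, P = _refresh_state(model, train_values, centroid_t.data,
                                         alpha)
                hard = Q.argmax(axis=1)
            refreshes += 1
            _, recon_t = model.forward_t(train_values)
            l_ae = float(recon_t.item())
            l_kld = kld_loss(P, Q) / n_train
            changed = (np.nan if prev_labels is None
                       else float((hard != prev_labels).mean() * 100.0))
            history.append({
                "iteration": step,
                "L_AE": l_ae,
                "L_KLD": l_kld,
                "combined": combined_loss(l_kld, l_ae, sigma),
                "pct_changed": changed,
            })
            if prev_labels is not None and changed < config.tol:
                converged = True
                break
            prev_labels = hard
        if step == config.max_iters:
            break

        opt.zero_grad()
        z_t, recon_t = model.forward_t(train_values)
        seed_grad = np.zeros_like(z_t.data)
        if sigma > 0:
            Q_step = soft_assign(z_t.data, centroid_t.data, alpha)
            dZ, dMu = clustering_gradients(z_t.data, centroid_t.data,
                                           P, Q_step, alpha)
            seed_grad = (sigma / n_train) * dZ
            centroid_t.grad = (sigma / n_train) * dMu
        # single backward pass: (1-sigma)*recon plus a linear term whose
        # gradient w.r.t. the latent equals the analytic hardening gradient
        total = recon_t * (1.0 - sigma) + (z_t * Tensor(seed_grad)).sum()
        total.backward()
        opt.step()
        steps_done += 1

    # final state over the full dataset
    Z_all = model.encode(values)
    Q_all = soft_assign(Z_all, centroid_t.data, alpha)
    P_all = target_distribution(Q_all)
    state = ClusterState(K=K, centroids=centroid_t.data.copy(),
                         Q=Q_all, P=P_all, alpha=alpha)

    G = None
    if n_val > 0:
        _, recon_tr = model.forward_t(train_values)
        l_train = combined_loss(
            kld_loss(P_all[train_idx], Q_all[train_idx]) / max(n_train, 1),
            float(recon_tr.item()), sigma)
        _, recon_va = model.forward_t(values[val_idx])
        l_val = combined_loss(
            kld_loss(P_all[val_idx], Q_all[val_idx]) / n_val,
            float(recon_va.item()), sigma)
        if l_val > 0:
            G = l_train / l_val

    return FittedClustering(
        labels=Q_all.argmax(axis=1),
        state=state,
        loss_history=pd.DataFrame(history),
        G=G,
        iterations_run=refreshes,
        converged=converged,
        optimizer_steps=steps_done,
    )


def sweep_k(model: BackboneModel, X, k_range: Iterable[int],
            config: TrainConfig | None = None,
            labels: np.ndarray | None = None) -> pd.DataFrame:
    """One hardening run per K sharing the same pretrained backbone.

    Returns the Elbow table: K, WCSS, NMI (populated only when
    ground-truth labels are supplied) and G.  WCSS is computed on the
    *shared* pretrained embedding with per-run label means as centroids,
    so the curve is comparable across K.
    """
    config = config or TrainConfig()
    ks = sorted(int(k) for k in k_range)
    if not ks:
        raise ValueError("empty K range")
    values = as_values(X)
    Z_shared = model.encode(values)
    from .metrics import nmi as _nmi
    from .metrics import wcss as _wcss

    rows = []
    for K in ks:
        fitted = fit_deep_clustering(model.copy(), values, K,
                                     replace(config))
        centers = np.vstack([
            Z_shared[fitted.labels == k].mean(axis=0)
            if np.any(fitted.labels == k) else np.zeros(Z_shared.shape[1])
            for k in range(K)
        ])
        row = {
            "K": K,
            "WCSS": _wcss(Z_shared, fitted.labels, centers),
            "NMI": _nmi(labels, fitted.labels) if labels is not None else np.nan,
            "G": fitted.G,
        }
        rows.append(row)
    return pd.DataFrame(rows)
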