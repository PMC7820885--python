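"""Seeded synthetic datasets with known cluster structure.

Every downstream stage of the pipeline (preprocessing, representation
learning, cluster-assignment hardening, metrics) is exercised on these
generators, so no external download is needed.  Class-conditional
structure is always planted in *disjoint* feature blocks -- separated
Gaussian components, disjoint signature-gene blocks, distinct procedural
texture families, disjoint vocabulary ranges -- which makes ground truth
unambiguous and parameter-recovery tests deterministic up to sampling
noise.

All generators are pure functions of their parameters and a single
integer seed: regenerating with the same arguments reproduces the values
bit-identically.
"""

from __future__ import annotations

import numpy as np

from .containers import LabeledDataset, SequenceDataset

__all__ = [
    "make_blob_dataset",
    "make_expression_dataset",
    "make_image_dataset",
    "make_text_dataset",
]


def _check_positive(**kwargs: int) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")


def make_blob_dataset(
    n_per_class: int,
    n_clusters: int,
    latent_dim: int = 2,
    ambient_dim: int = 10,
    separation: float = 8.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    ambient_map: str = "random",
) -> LabeledDataset:
    """Gaussian clusters in a latent space, lifted to an ambient space.

    ``n_clusters`` isotropic Gaussian components with standard deviation
    ``noise_sd`` are placed in ``latent_dim`` dimensions so that every
    pair of centroids is at least ``separation * noise_sd`` apart (or
    ``separation`` when ``noise_sd == 0``), then pushed to
    ``ambient_dim`` through a fixed random linear map followed by an
    elementwise leaky-ReLU nonlinearity.  ``ambient_map="identity"``
    skips the lift (requires ``ambient_dim == latent_dim``) and returns
    the latent coordinates unchanged -- useful for closed-form checks.

    The latent coordinates, centroids and mixing map are recorded in
    ``generator_params``.
    """
    _check_positive(n_per_class=n_per_class, n_clusters=n_clusters,
                    latent_dim=latent_dim, ambient_dim=ambient_dim)
    if separation <= 0:
        raise ValueError("separation must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if ambient_dim < latent_dim:
        raise ValueError("ambient_dim must be >= latent_dim")
    if ambient_map not in {"random", "identity"}:
        raise ValueError("ambient_map must be 'random' or 'identity'")
    if ambient_map == "identity" and ambient_dim != latent_dim:
        raise ValueError("identity map requires ambient_dim == latent_dim")

    rng = np.random.default_rng(seed)
    # draw centroid directions, then scale so the min pairwise distance
    # equals the required margin
    if n_clusters == 1:
        centroids = np.zeros((1, latent_dim))
    else:
        while True:
            centroids = rng.normal(size=(n_clusters, latent_dim))
            diffs = centroids[:, None] - centroids[None, :]
            dists = np.sqrt((diffs ** 2).sum(-1))
            min_dist = dists[~np.eye(n_clusters, dtype=bool)].min()
            if min_dist > 1e-8:
                break
        margin = separation * (noise_sd if noise_sd > 0 else 1.0)
        centroids *= margin / min_dist

    labels = np.repeat(np.arange(n_clusters), n_per_class)
    latent = centroids[labels] + noise_sd * rng.normal(
        size=(labels.size, latent_dim)
    )

    if ambient_map == "identity":
        values = latent.copy()
        A = np.eye(latent_dim)
    else:
        A = rng.normal(size=(latent_dim, ambient_dim)) / np.sqrt(latent_dim)
        pre = latent @ A
        values = np.where(pre > 0, pre, 0.3 * pre)  # leaky-ReLU lift

    return LabeledDataset(
        values=values,
        labels=labels,
        modality="tabular",
        seed=seed,
        generator_params={
            "centroids": centroids,
            "latent": latent,
            "ambient_matrix": A,
            "noise_sd": noise_sd,
            "separation": separation,
            "ambient_map": ambient_map,
        },
    )


def make_expression_dataset(
    n_per_class: int,
    n_subtypes: int,
    n_genes: int = 200,
    n_signature: int = 10,
    n_low_info: int = 5,
    seed: int = 0,
    log2_fold: float = 5.0,
) -> LabeledDataset:
    """FPKM-like expression matrix with subtype-specific signature blocks.

    Each subtype up-regulates its own disjoint block of ``n_signature``
    genes by ``log2_fold`` doublings over a shared baseline.  Exactly
    ``n_low_info`` genes are constructed to fail the low-information
    filter after the log2(FPKM+1) transform: half have post-log mean
    below 0.4 and half have post-log standard deviation below 0.75.  All
    remaining genes are constructed to pass both thresholds.  The
    signature and low-information gene indices are recorded in
    ``generator_params``.
    """
    _check_positive(n_per_class=n_per_class, n_subtypes=n_subtypes,
                    n_genes=n_genes, n_signature=n_signature)
    if n_low_info < 0:
        raise ValueError("n_low_info must be >= 0")
    if n_signature * n_subtypes + n_low_info > n_genes:
        raise ValueError(
            "n_signature * n_subtypes + n_low_info must be <= n_genes"
        )

    rng = np.random.default_rng(seed)
    n = n_per_class * n_subtypes
    labels = np.repeat(np.arange(n_subtypes), n_per_class)

    # baseline expression on the log2 scale: mean 2, spread 1.2 -> passes
    # both filter thresholds comfortably
    log_values = rng.normal(2.0, 1.2, size=(n, n_genes))

    signature_genes = np.zeros(n_genes, dtype=bool)
    signature_of_subtype: dict[int, list[int]] = {}
    for k in range(n_subtypes):
        block = np.arange(k * n_signature, (k + 1) * n_signature)
        signature_of_subtype[k] = block.tolist()
        signature_genes[block] = True
        if n_subtypes > 1:
            log_values[np.ix_(labels == k, block)] += log2_fold

    # low-information genes occupy the tail block
    low_info = np.zeros(n_genes, dtype=bool)
    low_block = np.arange(n_genes - n_low_info, n_genes)
    low_info[low_block] = True
    for idx, g in enumerate(low_block):
        if idx % 2 == 0:
            # low post-log mean: FPKM uniform in [0, 0.2]
            log_values[:, g] = np.log2(rng.uniform(0.0, 0.2, size=n) + 1.0)
        else:
            # low post-log SD: nearly constant moderate expression
            log_values[:, g] = 1.5 + rng.normal(0.0, 0.01, size=n)

    fpkm = np.maximum(2.0 ** log_values - 1.0, 0.0)

    return LabeledDataset(
        values=fpkm,
        labels=labels,
        modality="expression",
        seed=seed,
        generator_params={
            "signature_genes": np.flatnonzero(signature_genes).tolist(),
            "signature_of_subtype": signature_of_subtype,
            "low_info_genes": np.flatnonzero(low_info).tolist(),
            "log2_fold": log2_fold,
            "filter_thresholds": {"mean_min": 0.4, "sd_min": 0.75},
        },
    )


def make_image_dataset(
    n_per_class: int,
    n_classes: int,
    height: int = 64,
    width: int = 64,
    seed: int = 0,
) -> LabeledDataset:
    """Small RGB images whose classes differ in texture and brightness.

    Each class combines a distinct base intensity with a sinusoidal
    stripe texture of class-specific frequency and orientation, plus
    pixel noise; classes are separable by local pixel statistics alone.
    The realized per-class mean-intensity margin is recorded in
    ``generator_params``.
    """
    _check_positive(n_per_class=n_per_class, n_classes=n_classes)
    if height < 16 or width < 16:
        raise ValueError("height and width must be >= 16")

    rng = np.random.default_rng(seed)
    n = n_per_class * n_classes
    labels = np.repeat(np.arange(n_classes), n_per_class)
    yy, xx = np.mgrid[0:height, 0:width].astype(float)

    images = np.empty((n, height, width, 3))
    for i, c in enumerate(labels):
        base = 0.15 + 0.7 * c / max(n_classes - 1, 1)
        freq = 2 * np.pi * (c + 2) / width
        angle = np.pi * c / max(n_classes, 1)
        phase = rng.uniform(0, 2 * np.pi)
        stripes = 0.15 * np.sin(freq * (xx * np.cos(angle) + yy * np.sin(angle))
                                + phase)
        tint = 0.05 * np.array([np.sin(c), np.cos(c), np.sin(2 * c)])
        img = base + stripes[..., None] + tint[None, None, :]
        img = img + rng.normal(0.0, 0.02, size=img.shape)
        images[i] = np.clip(img, 0.0, 1.0)

    class_means = np.array(
        [images[labels == c].mean() for c in range(n_classes)]
    )
    margin = (np.min(np.diff(np.sort(class_means)))
              if n_classes > 1 else 0.0)

    return LabeledDataset(
        values=images,
        labels=labels,
        modality="image",
        seed=seed,
        generator_params={
            "class_mean_intensity": class_means.tolist(),
            "class_mean_margin": float(margin),
        },
    )


# rating thresholds mirrored by preprocessing.rating_to_polarity:
# class 0 (negative) <-> ratings 1-4, class 1 (neutral) <-> 5-7,
# class 2 (positive) <-> 8-10
_RATING_RANGES = {0: (1, 4), 1: (5, 7), 2: (8, 10)}


def make_text_dataset(
    n_per_class: int,
    vocab_size: int = 60,
    max_length: int = 20,
    seed: int = 0,
    block_purity: float = 0.9,
) -> SequenceDataset:
    """Three-class token corpora with disjoint class vocabularies.

    Each of the three polarity classes draws a fraction ``block_purity``
    of its tokens from its own vocabulary block and the rest from a
    shared block; ratings are sampled inside the class's rating range so
    the polarity thresholds reproduce the class labels exactly.  Token
    id 0 is reserved for padding and never emitted.
    """
    _check_positive(n_per_class=n_per_class, vocab_size=vocab_size,
                    max_length=max_length)
    n_classes = 3
    if vocab_size < 3 * 10:
        raise ValueError("vocab_size must be >= 30 (10 tokens per class block)")

    rng = np.random.default_rng(seed)
    usable = vocab_size - 1  # id 0 reserved for padding
    block = usable // (n_classes + 1)  # 3 class blocks + 1 shared block
    class_blocks = {
        c: np.arange(1 + c * block, 1 + (c + 1) * block) for c in range(n_classes)
    }
    shared = np.arange(1 + n_classes * block, vocab_size)

    labels = np.repeat(np.arange(n_classes), n_per_class)
    token_ids: list[np.ndarray] = []
    ratings = np.empty(labels.size, dtype=int)
    min_len = max(1, max_length // 2)
    for i, c in enumerate(labels):
        L = int(rng.integers(min_len, max_length + 1))
        own = rng.random(L) < block_purity
        seq = np.where(
            own,
            rng.choice(class_blocks[c], size=L),
            rng.choice(shared, size=L) if shared.size else
            rng.choice(class_blocks[c], size=L),
        )
        token_ids.append(seq.astype(int))
        lo, hi = _RATING_RANGES[int(c)]
        ratings[i] = int(rng.integers(lo, hi + 1))

    return SequenceDataset(
        token_ids=token_ids,
        labels=labels,
        vocab_size=vocab_size,
        ratings=ratings,
        seed=seed,
        generator_params={
            "class_blocks": {c: b.tolist() for c, b in class_blocks.items()},
            "shared_block": shared.tolist(),
            "block_purity": block_purity,
            "max_length": max_length,
        },
    )
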