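"""Deterministic transforms applied before representation learning.

Expression matrices are log-transformed (log2(FPKM+1)) and stripped of
low-information genes (post-log mean < 0.4 or sample SD < 0.75 across
samples, both configurable); drug-review star ratings are collapsed to
three polarity classes; images are rescaled to a target size; token
sequences are embedded with a trainable lookup table.  The filter is
applied *after* the log transform -- the order is an interpretation
choice documented in the methods note.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize

from .containers import DataMatrix, FilterReport, SequenceDataset
from .nn import Embedding

__all__ = [
    "log_transform_expression",
    "filter_low_information_genes",
    "rating_to_polarity",
    "latent_norm_statistic",
    "rescale_image",
    "TokenVectorizer",
    "vectorize_tokens",
]

POLARITY_LEVELS = ("negative", "neutral", "positive")


def log_transform_expression(fpkm: DataMatrix | np.ndarray) -> DataMatrix | np.ndarray:
    """Replace each entry by log2(value + 1); shape preserved.

    Models proportional rather than additive expression changes.  Raises
    on negative input (FPKM values are non-negative by construction).
    """
    values = fpkm.values if isinstance(fpkm, DataMatrix) else np.asarray(fpkm, float)
    if np.any(values < 0):
        raise ValueError("expression values must be non-negative")
    logged = np.log2(values + 1.0)
    if isinstance(fpkm, DataMatrix):
        return DataMatrix(logged, sample_ids=list(fpkm.sample_ids),
                          feature_ids=list(fpkm.feature_ids),
                          labels=None if fpkm.labels is None else fpkm.labels.copy())
    return logged


def filter_low_information_genes(
    logged: DataMatrix | np.ndarray,
    mean_min: float = 0.4,
    sd_min: float = 0.75,
) -> tuple[DataMatrix | np.ndarray, FilterReport]:
    """Drop genes with low information burden across all samples.

    A gene is removed when its mean < ``mean_min`` OR its sample standard
    deviation (ddof=1) < ``sd_min``, computed on the log-transformed
    matrix.  Returns the restricted matrix plus a :class:`FilterReport`.
    Idempotent: filtering an already-filtered matrix removes nothing.
    """
    values = logged.values if isinstance(logged, DataMatrix) else np.asarray(logged, float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D samples x genes matrix")
    if values.shape[0] < 2:
        raise ValueError("need >= 2 samples for the SD to be defined")
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    kept = (means >= mean_min) & (sds >= sd_min)
    report = FilterReport(kept_mask=kept, per_feature_mean=means,
                          per_feature_sd=sds, mean_min=mean_min, sd_min=sd_min)
    if isinstance(logged, DataMatrix):
        filtered = DataMatrix(
            values[:, kept],
            sample_ids=list(logged.sample_ids),
            feature_ids=[f for f, k in zip(logged.feature_ids, kept) if k],
            labels=None if logged.labels is None else logged.labels.copy(),
        )
    else:
        filtered = values[:, kept]
    return filtered, report


def rating_to_polarity(rating: int) -> str:
    """Map a 10-star satisfaction rating to a polarity label.

    Ratings under and including 4 are negative, 5-7 neutral, 8 and above
    positive.
    """
    rating = int(rating)
    if not 1 <= rating <= 10:
        raise ValueError(f"rating must be in [1, 10], got {rating}")
    if rating <= 4:
        return "negative"
    if rating <= 7:
        return "neutral"
    return "positive"


def latent_norm_statistic(Z: np.ndarray) -> np.ndarray:
    """Per-sample (1/d) * ||z_i||^2 diagnostic.

    Embedded-clustering initialization expects inputs normalized so this
    statistic is approximately 1; this function only measures it.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.size == 0:
        raise ValueError("Z must be a non-empty 2-D matrix")
    d = Z.shape[1]
    return (Z ** 2).sum(axis=1) / d


def rescale_image(image: np.ndarray, target_hw: tuple[int, int]) -> np.ndarray:
    """Resize a channels-last image to (height, width), 3 channels, [0,1].

    Uses anti-aliased (bi)linear interpolation with a top-left origin;
    grayscale inputs are broadcast to 3 channels.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = np.repeat(image[..., None], 3, axis=-1)
    if image.ndim != 3 or image.shape[-1] not in (1, 3):
        raise ValueError("expected an (H, W) or (H, W, C) image with 1 or 3 channels")
    if image.shape[-1] == 1:
        image = np.repeat(image, 3, axis=-1)
    h, w = int(target_hw[0]), int(target_hw[1])
    if h <= 0 or w <= 0:
        raise ValueError("target size must be positive")
    if (h, w) == image.shape[:2]:
        out = image.copy()
    else:
        out = _sk_resize(image, (h, w, 3), anti_aliasing=True,
                         preserve_range=True)
    return np.clip(out, 0.0, 1.0)


class TokenVectorizer:
    """Trainable token embedding with a word2vec-text-format import hook.

    Each document of token ids becomes a length-L sequence of
    ``embed_dim`` real vectors.  The table is randomly initialized
    (seeded) and trainable; :meth:`load_word2vec_text` overwrites rows
    from a user-supplied text-format vector file whose words are integer
    token ids.
    """

    def __init__(self, vocab_size: int, embed_dim: int = 300, seed: int = 0):
        if vocab_size < 1 or embed_dim < 1:
            raise ValueError("vocab_size and embed_dim must be positive")
        self.embedding = Embedding(vocab_size, embed_dim,
                                   rng=np.random.default_rng(seed))
        self.vocab_size = vocab_size
        self.embed_dim = embed_dim

    def load_word2vec_text(self, path: str) -> int:
        """Load vectors from word2vec text format; returns rows replaced."""
        replaced = 0
        with open(path) as fh:
            first = fh.readline().split()
            if len(first) == 2:  # header line: n_vectors dim
                pass
            else:
                fh.seek(0)
            for line in fh:
                parts = line.rstrip().split()
                if not parts:
                    continue
                token = int(parts[0])
                vec = np.array(parts[1:], dtype=float)
                if vec.size != self.embed_dim:
                    raise ValueError("vector dimension mismatch")
                if 0 <= token < self.vocab_size:
                    self.embedding.table.data[token] = vec
                    replaced += 1
        return replaced

    def __call__(self, document: np.ndarray) -> np.ndarray:
        document = np.asarray(document, dtype=int)
        if document.size == 0:
            raise ValueError("cannot vectorize an empty document")
        return self.embedding(document).data.copy()


def vectorize_tokens(
    corpus: SequenceDataset,
    embed_dim: int = 300,
    max_length: int | None = None,
    seed: int = 0,
) -> tuple[list[np.ndarray], TokenVectorizer]:
    """Embed every document of ``corpus`` into ``embed_dim``-vectors.

    Documents longer than ``max_length`` are truncated (recorded via the
    returned vectorizer's table being position-independent; lengths are
    preserved otherwise).  Returns (list of (L, embed_dim) arrays, the
    vectorizer) so the same table can be reused and trained downstream.
    """
    vec = TokenVectorizer(corpus.vocab_size, embed_dim, seed=seed)
    out = []
    for doc in corpus.token_ids:
        if max_length is not None:
            doc = doc[:max_length]
        out.append(vec(doc))
    return out, vec
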