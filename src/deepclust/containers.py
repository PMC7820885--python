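"""Shared in-memory containers used across the pipeline.

The pipeline moves data through a small number of typed containers:
raw sample-by-feature matrices (:class:`DataMatrix`), generated fixtures
with known class structure (:class:`LabeledDataset`,
:class:`SequenceDataset`), and result records (:class:`FilterReport`,
:class:`ReconstructionReport`, :class:`MetricsReport`).  Keeping these as
plain dataclasses over numpy arrays makes every stage serializable to
delimited text and JSON.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

__all__ = [
    "DataMatrix",
    "LabeledDataset",
    "SequenceDataset",
    "FilterReport",
    "ReconstructionReport",
    "MetricsReport",
]


@dataclass
class DataMatrix:
    """n samples x D features with optional per-sample ground-truth labels."""

    values: np.ndarray
    sample_ids: list[str] | None = None
    feature_ids: list[str] | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DataMatrix.values must be 2-D (samples x features)")
        n, d = self.values.shape
        if self.sample_ids is None:
            self.sample_ids = [f"S{i}" for i in range(n)]
        if self.feature_ids is None:
            self.feature_ids = [f"F{j}" for j in range(d)]
        if len(self.sample_ids) != n or len(self.feature_ids) != d:
            raise ValueError("id lists inconsistent with values shape")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError("labels must have one entry per sample")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class LabeledDataset:
    """A generated dataset with known class structure.

    ``values`` is a real array: (n, D) for tabular/expression data,
    (n, H, W, 3) channels-last for images.  ``labels`` holds the generating
    class per sample in {0..K-1}.  ``generator_params`` records the
    distribution parameters the generator used (signature-gene masks,
    latent coordinates, class margins, ...) so that downstream recovery
    tests have unambiguous ground truth.
    """

    values: np.ndarray
    labels: np.ndarray
    modality: str
    seed: int
    generator_params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.modality not in {"tabular", "expression", "image", "sequence"}:
            raise ValueError(f"unknown modality: {self.modality!r}")
        if self.labels.ndim != 1 or self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("labels must be 1-D with one entry per sample")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class SequenceDataset:
    """Variable-length integer token sequences with optional ratings.

    Token id 0 is reserved for padding throughout the package.
    """

    token_ids: list[np.ndarray]
    labels: np.ndarray
    vocab_size: int
    ratings: np.ndarray | None = None
    seed: int = 0
    generator_params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.token_ids = [np.asarray(s, dtype=int) for s in self.token_ids]
        self.labels = np.asarray(self.labels, dtype=int)
        for s in self.token_ids:
            if s.size and (s.min() < 0 or s.max() >= self.vocab_size):
                raise ValueError("token id outside [0, vocab_size)")
        if self.ratings is not None:
            self.ratings = np.asarray(self.ratings, dtype=int)

    @property
    def n_samples(self) -> int:
        return len(self.token_ids)

    def lengths(self) -> np.ndarray:
        return np.array([len(s) for s in self.token_ids])


@dataclass
class FilterReport:
    """Outcome of the low-information gene filter.

    A feature is kept iff its post-log mean >= mean_min AND its sample
    standard deviation >= sd_min.
    """

    kept_mask: np.ndarray
    per_feature_mean: np.ndarray
    per_feature_sd: np.ndarray
    mean_min: float = 0.4
    sd_min: float = 0.75

    def __post_init__(self) -> None:
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        self.per_feature_mean = np.asarray(self.per_feature_mean, dtype=float)
        self.per_feature_sd = np.asarray(self.per_feature_sd, dtype=float)

    @property
    def n_removed(self) -> int:
        return int((~self.kept_mask).sum())

    def to_dict(self) -> dict[str, Any]:
        return {
            "kept_mask": self.kept_mask.tolist(),
            "per_feature_mean": self.per_feature_mean.tolist(),
            "per_feature_sd": self.per_feature_sd.tolist(),
            "thresholds": {"mean_min": self.mean_min, "sd_min": self.sd_min},
        }


@dataclass
class ReconstructionReport:
    """A reconstruction objective value together with its per-sample terms."""

    loss_value: float
    per_sample_losses: np.ndarray
    loss_kind: str  # squared_error | denoising | negative_elbo | sequence_reverse
    reduction: str = "mean"  # how per-sample terms combine into loss_value
    kl_term: float | None = None  # populated for negative_elbo

    def __post_init__(self) -> None:
        self.per_sample_losses = np.asarray(self.per_sample_losses, dtype=float)


@dataclass
class MetricsReport:
    """The clustering-quality metric suite for one run."""

    acc: float
    nmi: float
    ri: float
    ari: float
    homogeneity: float
    completeness: float
    wcss_by_k: dict[int, float] = field(default_factory=dict)
    G: float | None = None

    def to_dict(self) -> dict[str, Any]:
        d = {
            "acc": self.acc,
            "nmi": self.nmi,
            "ri": self.ri,
            "ari": self.ari,
            "homogeneity": self.homogeneity,
            "completeness": self.completeness,
        }
        if self.wcss_by_k:
            d["wcss_by_k"] = {str(k): v for k, v in self.wcss_by_k.items()}
        if self.G is not None:
            d["G"] = self.G
        return d


def as_values(X: "DataMatrix | LabeledDataset | np.ndarray") -> np.ndarray:
    """Extract the numeric array from any matrix-like container."""
    if isinstance(X, (DataMatrix, LabeledDataset)):
        return X.values
    return np.asarray(X, dtype=float)
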