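"""Delimited-matrix, image-directory and run-output readers/writers.

Matrices travel as delimited text with a header row of feature ids and a
first column of sample ids; an optional ``label`` column carries ground
truth.  Sample ordering is preserved end-to-end and every output file is
keyed by sample id so stages can be joined safely.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .containers import DataMatrix, LabeledDataset, MetricsReport

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_image_dir",
    "write_outputs",
]


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty file")
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_matrix(path: str | Path) -> DataMatrix:
    """Read a delimited numeric matrix (tab or comma, auto-detected).

    First column: sample ids; header row: feature ids; an optional
    ``label`` column is extracted into ``labels`` and excluded from the
    values.  Non-numeric cells raise with row/column coordinates.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"{path}: empty or missing file")
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no feature columns found")
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy()
        try:
            labels = labels.astype(int)
        except ValueError:
            pass
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric cell at row {df.index[i]!r}, "
                f"column {col!r}: {df[col].iloc[i]!r}")
        if converted.isna().any():
            i = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ValueError(
                f"{path}: missing value at row {df.index[i]!r}, column {col!r}")
        values[:, j] = converted.to_numpy()
    return DataMatrix(values, sample_ids=[str(s) for s in df.index],
                      feature_ids=[str(c) for c in df.columns], labels=labels)


def write_matrix(matrix: DataMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a DataMatrix as delimited text (inverse of read_matrix)."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, index=matrix.sample_ids,
                      columns=matrix.feature_ids)
    if matrix.labels is not None:
        df["label"] = matrix.labels
    df.to_csv(path, sep=sep, index_label="sample_id")


def read_image_dir(path: str | Path, manifest: str | Path | None = None,
                   rescale_to: tuple[int, int] | None = None) -> LabeledDataset:
    """Load PNG/TIFF images as a channels-last float stack in [0, 1].

    Ordering follows the manifest (TSV: filename, label) when given,
    otherwise lexicographic filename order.  Grayscale images broadcast
    to 3 channels; mixed sizes are an error unless ``rescale_to`` is set.
    """
    from .preprocessing import rescale_image

    path = Path(path)
    if manifest is not None:
        man = pd.read_csv(manifest, sep="\t")
        files = [path / f for f in man.iloc[:, 0]]
        labels = man.iloc[:, 1].to_numpy()
    else:
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".png", ".tif", ".tiff"})
        labels = np.zeros(len(files), dtype=int)
    if not files:
        raise ValueError(f"{path}: no images found")
    images = []
    for f in files:
        try:
            img = np.asarray(iio.imread(f), dtype=float)
        except Exception as exc:  # noqa: BLE001 - re-raise with filename
            raise ValueError(f"unreadable image: {f}") from exc
        if img.max() > 1.0:
            img = img / 255.0
        if img.ndim == 2:
            img = np.repeat(img[..., None], 3, axis=-1)
        if img.shape[-1] == 4:
            img = img[..., :3]
        if rescale_to is not None:
            img = rescale_image(img, rescale_to)
        images.append(img)
    shapes = {im.shape for im in images}
    if len(shapes) > 1:
        raise ValueError(
            "images have mixed sizes; pass a rescale target to unify them")
    return LabeledDataset(values=np.stack(images), labels=np.asarray(labels),
                          modality="image", seed=0,
                          generator_params={"source": str(path)})


def write_outputs(out_dir: str | Path, *, sample_ids: list[str],
                  labels: np.ndarray, Q: np.ndarray | None = None,
                  centroids: np.ndarray | None = None,
                  loss_history: pd.DataFrame | None = None,
                  metrics: MetricsReport | dict | None = None,
                  config: dict | None = None) -> dict[str, Path]:
    """Write the standard output bundle of a clustering run.

    labels TSV, Q TSV, centroids TSV, loss-history CSV, metrics JSON and
    the fully resolved config JSON; returns the mapping of artifact name
    to path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    p = out / "labels.tsv"
    pd.DataFrame({"sample_id": sample_ids, "label": labels}).to_csv(
        p, sep="\t", index=False)
    written["labels"] = p

    if Q is not None:
        p = out / "soft_assignments.tsv"
        qdf = pd.DataFrame(Q, index=sample_ids,
                           columns=[f"q_{j}" for j in range(Q.shape[1])])
        qdf.to_csv(p, sep="\t", index_label="sample_id")
        written["Q"] = p
    if centroids is not None:
        p = out / "centroids.tsv"
        pd.DataFrame(centroids).to_csv(p, sep="\t", index_label="cluster")
        written["centroids"] = p
    if loss_history is not None:
        p = out / "loss_history.csv"
        loss_history.to_csv(p, index=False)
        written["loss_history"] = p
    if metrics is not None:
        p = out / "metrics.json"
        payload = metrics.to_dict() if isinstance(metrics, MetricsReport) else metrics
        p.write_text(json.dumps(payload, indent=2))
        written["metrics"] = p
    if config is not None:
        p = out / "config.json"
        p.write_text(json.dumps(config, indent=2, default=str))
        written["config"] = p
    return written
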