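"""Read and validate labeled latent embeddings; write predictions.

The whole pipeline operates on cells in a shared low-dimensional latent
space (typically 10-30 dimensions) produced upstream by an integration
model; expression matrices are never touched here.  Two on-disk dialects
are supported: a TSV table (``cell_id``, ``dim_0`` .. ``dim_{d-1}``, and an
optional label column) and the h5ad HDF5 container (embedding under a named
``obsm`` slot, labels under a named ``obs`` column).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import NotFoundError, ValidationError

#: float format that round-trips IEEE doubles exactly through text
_FLOAT_FMT = "%.17g"


@dataclass
class LabeledEmbedding:
    """One dataset's latent coordinates plus per-cell annotations.

    ``labels`` is ``None`` for unlabeled query datasets, which can only be
    annotated, never used to update the hierarchy.
    """

    dataset_id: str
    X: np.ndarray
    cell_ids: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValidationError("X must be a cells x d matrix")
        if not np.isfinite(self.X).all():
            raise ValidationError(
                f"dataset {self.dataset_id!r}: X contains non-finite values"
            )
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.cell_ids.shape[0] != self.X.shape[0]:
            raise ValidationError("cell_ids length does not match X rows")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError(
                f"dataset {self.dataset_id!r}: cell_ids are not unique"
            )
        if self.labels is not None:
            # leading/trailing whitespace is stripped at ingest; labels are
            # otherwise compared exactly (case-sensitive)
            self.labels = np.asarray(
                [str(l).strip() for l in np.asarray(self.labels)], dtype=object
            )
            if self.labels.shape[0] != self.X.shape[0]:
                raise ValidationError("labels length does not match X rows")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def is_labeled(self) -> bool:
        return self.labels is not None

    def label_set(self) -> list[str]:
        """Unique labels in order of first appearance (deterministic)."""
        if self.labels is None:
            raise ValidationError(f"dataset {self.dataset_id!r} is unlabeled")
        return list(dict.fromkeys(self.labels))


def read_embedding(
    path,
    format: Optional[str] = None,
    latent_key: str = "X_latent",
    label_key: Optional[str] = "cell_type",
    dataset_id: Optional[str] = None,
) -> LabeledEmbedding:
    """Load a labeled (or unlabeled, ``label_key=None``) embedding.

    ``format`` is inferred from the filename extension when omitted.
    Row order is preserved from the file.
    """
    path = str(path)
    if format is None:
        format = "h5ad" if path.endswith(".h5ad") else "tsv"
    if dataset_id is None:
        dataset_id = path.rsplit("/", 1)[-1].split(".")[0]

    if format == "tsv":
        df = pd.read_csv(
            path, sep="\t", dtype={"cell_id": str}, float_precision="round_trip"
        )
        if "cell_id" not in df.columns:
            raise NotFoundError(f"{path}: no 'cell_id' column")
        dim_cols = [c for c in df.columns if c.startswith("dim_")]
        if not dim_cols:
            raise NotFoundError(f"{path}: no 'dim_*' coordinate columns")
        dim_cols = sorted(dim_cols, key=lambda c: int(c.split("_", 1)[1]))
        X = df[dim_cols].to_numpy(dtype=np.float64)
        labels = None
        if label_key is not None:
            if label_key not in df.columns:
                raise NotFoundError(f"{path}: no label column {label_key!r}")
            labels = df[label_key].to_numpy()
        return LabeledEmbedding(dataset_id, X, df["cell_id"].to_numpy(), labels)

    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        if latent_key not in adata.obsm:
            raise NotFoundError(
                f"{path}: obsm slot {latent_key!r} not found "
                f"(available: {list(adata.obsm.keys())})"
            )
        X = np.asarray(adata.obsm[latent_key], dtype=np.float64)
        labels = None
        if label_key is not None:
            if label_key not in adata.obs.columns:
                raise NotFoundError(
                    f"{path}: obs column {label_key!r} not found "
                    f"(available: {list(adata.obs.columns)})"
                )
            labels = adata.obs[label_key].to_numpy()
        return LabeledEmbedding(dataset_id, X, adata.obs_names.to_numpy(), labels)

    raise ValueError(f"unknown format {format!r}")


def write_embedding(emb: LabeledEmbedding, path) -> None:
    """Write the TSV dialect (floats at 17 significant digits)."""
    cols = {"cell_id": emb.cell_ids}
    for j in range(emb.d):
        cols[f"dim_{j}"] = [_FLOAT_FMT % v for v in emb.X[:, j]]
    if emb.labels is not None:
        cols["cell_type"] = emb.labels
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_predictions(result, path) -> None:
    """Write a PredictionResult as TSV.

    Columns: cell_id, predicted_label, path (root-to-label, '/'-joined),
    rejected, rejection_reason (posterior|reconstruction|distance|'').
    """
    rows = {
        "cell_id": result.cell_ids,
        "predicted_label": result.final_labels,
        "path": ["/".join(p) for p in result.paths],
        "rejected": [bool(r) for r in result.rejected],
        "rejection_reason": result.reasons,
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"cell_id": str}, keep_default_na=False
    )
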