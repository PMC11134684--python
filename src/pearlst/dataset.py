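"""The in-memory container shared by every pipeline stage.

A :class:`SpotDataset` holds a spot-by-gene count matrix, 2-D spatial
coordinates, and the optional per-spot histology image features (2048-dim,
produced upstream by a pluggable provider).  The processed expression matrix
(after normalization / log / HVG selection) and the augmented matrix (after
PDE denoising) are stored as separate layers so every stage sees exactly the
representation it expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

IMAGE_FEATURE_DIM = 2048


@dataclass
class SpotDataset:
    """Expression counts plus spatial coordinates for N spots.

    Parameters
    ----------
    counts
        N x G non-negative matrix of raw (or platform-emitted) counts.
    coords
        N x 2 spatial coordinates, Euclidean, arbitrary length units.
    spot_ids, gene_ids
        Row / column identifiers; generated if omitted.
    image_features
        Optional N x 2048 per-spot image feature rows.
    processed
        Optional N x d matrix after preprocessing (d = #HVGs).
    augmented
        Optional N x d matrix after PDE denoising + neighbor augmentation.
    labels
        Optional per-spot categorical labels (fixtures / evaluation only).
    """

    counts: np.ndarray
    coords: np.ndarray
    spot_ids: Optional[Sequence[str]] = None
    gene_ids: Optional[Sequence[str]] = None
    image_features: Optional[np.ndarray] = None
    processed: Optional[np.ndarray] = None
    processed_gene_ids: Optional[Sequence[str]] = None
    augmented: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        n = self.counts.shape[0]
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords must be {n} x 2 to match counts rows, got {self.coords.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts entries must be non-negative")
        if self.spot_ids is None:
            self.spot_ids = [f"spot_{i}" for i in range(n)]
        if self.gene_ids is None:
            self.gene_ids = [f"gene_{j}" for j in range(self.counts.shape[1])]
        self.spot_ids = list(self.spot_ids)
        self.gene_ids = list(self.gene_ids)
        if len(self.spot_ids) != n:
            raise ValueError("spot_ids length must match counts rows")
        if len(self.gene_ids) != self.counts.shape[1]:
            raise ValueError("gene_ids length must match counts columns")
        if self.image_features is not None:
            self.image_features = np.asarray(self.image_features, dtype=float)
            if self.image_features.shape[0] != n:
                raise ValueError(
                    "image_features row count must match the number of spots"
                )

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def X(self) -> np.ndarray:
        """The default expression matrix for downstream stages.

        Augmented if present, else processed, else raw counts.
        """
        if self.augmented is not None:
            return self.augmented
        if self.processed is not None:
            return self.processed
        return self.counts

    def with_(self, **kwargs) -> "SpotDataset":
        """Return a shallow copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_anndata(self):
        """Export as an AnnData container (processed X as the main matrix)."""
        import anndata as ad
        import pandas as pd

        X = self.processed if self.processed is not None else self.counts
        var_names = (
            self.processed_gene_ids
            if self.processed is not None and self.processed_gene_ids is not None
            else self.gene_ids
        )
        adata = ad.AnnData(
            X=np.asarray(X, dtype=np.float64),
            obs=pd.DataFrame(index=pd.Index(self.spot_ids, name="spot_id")),
            var=pd.DataFrame(index=pd.Index(var_names, name="gene_id")),
        )
        adata.obsm["spatial"] = self.coords.copy()
        if self.processed is not None:
            # raw counts live in uns because their gene axis is wider than X's
            adata.uns["raw_counts"] = self.counts.copy()
            adata.uns["raw_gene_ids"] = list(self.gene_ids)
        if self.augmented is not None:
            adata.layers["augmented"] = self.augmented.copy()
        if self.image_features is not None:
            adata.obsm["image_features"] = self.image_features.copy()
        if self.labels is not None:
            adata.obs["label"] = pd.Categorical(self.labels)
        return adata

    @classmethod
    def from_anndata(cls, adata, spatial_key: str = "spatial") -> "SpotDataset":
        """Build from an AnnData container; coordinates read from ``obsm``."""
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        if spatial_key not in adata.obsm:
            raise KeyError(f"coordinates not found under obsm[{spatial_key!r}]")
        labels = None
        if "label" in adata.obs:
            labels = np.asarray(adata.obs["label"])
        return cls(
            counts=np.asarray(X, dtype=float),
            coords=np.asarray(adata.obsm[spatial_key], dtype=float)[:, :2],
            spot_ids=list(adata.obs_names),
            gene_ids=list(adata.var_names),
            image_features=np.asarray(adata.obsm["image_features"], dtype=float)
            if "image_features" in adata.obsm
            else None,
            labels=labels,
        )
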