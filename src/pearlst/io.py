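"""Readers and writers for the standard spatial-omics interchange formats.

Counts: MTX triplet (features x barcodes, CellRanger orientation) with
barcodes.tsv / features.tsv, dense CSV/TSV (spots x genes, header row =
gene ids, first column = spot ids), or an h5ad container.  Coordinates:
TSV with a ``spot_id, x, y`` header, or embedded under ``obsm['spatial']``
in the container.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd

from pearlst.dataset import SpotDataset


def read_mtx_dir(path: str) -> tuple[np.ndarray, list, list]:
    """Read matrix.mtx + barcodes.tsv + features.tsv from a directory.

    Returns (counts as spots x genes, spot_ids, gene_ids).
    """
    from scipy.io import mmread

    mtx = mmread(os.path.join(path, "matrix.mtx"))
    barcodes = pd.read_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=None
    )[0].tolist()
    features = pd.read_csv(
        os.path.join(path, "features.tsv"), sep="\t", header=None
    )[0].tolist()
    M = np.asarray(mtx.todense() if hasattr(mtx, "todense") else mtx, dtype=float)
    if M.shape == (len(features), len(barcodes)):
        M = M.T  # CellRanger orientation: features x barcodes
    elif M.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix shape {M.shape} matches neither orientation of "
            f"{len(barcodes)} barcodes x {len(features)} features"
        )
    return M, barcodes, features


def write_mtx_dir(ds: SpotDataset, path: str) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    os.makedirs(path, exist_ok=True)
    mmwrite(os.path.join(path, "matrix.mtx"), csr_matrix(ds.counts.T))
    pd.Series(ds.spot_ids).to_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(ds.gene_ids).to_csv(
        os.path.join(path, "features.tsv"), sep="\t", index=False, header=False
    )


def read_counts_table(path: str) -> tuple[np.ndarray, list, list]:
    """Dense spots x genes CSV/TSV; header = gene ids, first column = spot ids."""
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.to_numpy(dtype=float), df.index.astype(str).tolist(), df.columns.astype(str).tolist()


def write_counts_table(ds: SpotDataset, path: str) -> None:
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    pd.DataFrame(ds.counts, index=ds.spot_ids, columns=ds.gene_ids).to_csv(
        path, sep=sep
    )


def read_coords(path: str, spot_ids: Optional[list] = None) -> np.ndarray:
    """Coordinates TSV/CSV with header ``spot_id, x, y``.

    If spot ids are given, rows are re-ordered to match them; otherwise
    0-based row alignment is assumed.
    """
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"spot_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"coordinates file must have header columns {sorted(required)}"
        )
    if spot_ids is not None:
        df = df.set_index("spot_id").loc[[str(s) for s in spot_ids]]
    return df[["x", "y"]].to_numpy(dtype=float)


def write_coords(ds: SpotDataset, path: str) -> None:
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    pd.DataFrame(
        {"spot_id": ds.spot_ids, "x": ds.coords[:, 0], "y": ds.coords[:, 1]}
    ).to_csv(path, sep=sep, index=False)


def read_image_features(path: str) -> np.ndarray:
    """Dense per-spot image-feature table (CSV/TSV keyed by spot id, or .npy)."""
    if path.endswith(".npy"):
        return np.load(path)
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.to_numpy(dtype=float)


def load_dataset(
    counts_path: str,
    coords_path: Optional[str] = None,
    image_features_path: Optional[str] = None,
    spatial_key: str = "spatial",
) -> SpotDataset:
    """Dispatch on file type and assemble a :class:`SpotDataset`."""
    if counts_path.endswith(".h5ad"):
        import anndata as ad

        ds = SpotDataset.from_anndata(ad.read_h5ad(counts_path), spatial_key)
    else:
        if os.path.isdir(counts_path):
            counts, spot_ids, gene_ids = read_mtx_dir(counts_path)
        else:
            counts, spot_ids, gene_ids = read_counts_table(counts_path)
        if coords_path is None:
            raise ValueError("coordinates file required for non-h5ad inputs")
        coords = read_coords(coords_path, spot_ids)
        ds = SpotDataset(counts=counts, coords=coords, spot_ids=spot_ids,
                         gene_ids=gene_ids)
    if image_features_path is not None:
        feats = read_image_features(image_features_path)
        ds = ds.with_(image_features=feats)
    return ds


def save_h5ad(ds: SpotDataset, path: str, extra_obs: Optional[dict] = None,
              extra_obsm: Optional[dict] = None, uns: Optional[dict] = None) -> None:
    """Write the dataset (plus any result columns / embeddings) to h5ad."""
    adata = ds.to_anndata()
    for key, values in (extra_obs or {}).items():
        adata.obs[key] = values
    for key, values in (extra_obsm or {}).items():
        adata.obsm[key] = np.asarray(values)
    for key, values in (uns or {}).items():
        adata.uns[key] = values
    adata.write_h5ad(path)
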