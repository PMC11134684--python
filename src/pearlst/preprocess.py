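"""Standard expression preprocessing: filter, normalize, log1p, HVG.

The pipeline order is fixed: gene filtering (expressed in >= ``min_cells``
spots), per-spot total normalization to a common scale (default 10,000),
log(1 + x), then restriction to the top highly variable genes (default
2,000) ranked by mean-binned normalized dispersion.
"""

from __future__ import annotations

import logging

import numpy as np

from pearlst.dataset import SpotDataset

logger = logging.getLogger(__name__)

DEFAULT_SCALE = 10_000.0
DEFAULT_MIN_CELLS = 4
DEFAULT_N_TOP = 2_000


def filter_genes(ds: SpotDataset, min_cells: int = DEFAULT_MIN_CELLS) -> SpotDataset:
    """Keep genes expressed (count > 0) in at least ``min_cells`` spots.

    The spot set and the original gene column order are preserved.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be a positive integer")
    n_expressing = np.count_nonzero(ds.counts > 0, axis=0)
    keep = n_expressing >= min_cells
    if not keep.any():
        raise ValueError(
            f"gene filtering with min_cells={min_cells} removed every gene; "
            "lower min_cells or check the input matrix"
        )
    if not np.allclose(ds.counts, np.round(ds.counts)):
        logger.warning("counts contain non-integer values; accepted as-is")
    return ds.with_(
        counts=ds.counts[:, keep],
        gene_ids=[g for g, k in zip(ds.gene_ids, keep) if k],
        processed=None,
        processed_gene_ids=None,
        augmented=None,
    )


def normalize_log(ds: SpotDataset, scale: float = DEFAULT_SCALE) -> SpotDataset:
    """Scale each spot to a common total, then apply log(1 + x).

    Zero-total spots pass through as all-zero rows (dropping them would
    desynchronize the coordinate table); a warning is emitted.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    counts = ds.counts
    if np.any(counts < 0):
        raise ValueError("negative entries in counts")
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning(
            "%d spot(s) with zero total counts retained as all-zero rows",
            int(zero.sum()),
        )
    factors = np.where(zero, 1.0, scale / np.where(zero, 1.0, totals))
    X = np.log1p(counts * factors[:, None])
    return ds.with_(processed=X, processed_gene_ids=list(ds.gene_ids))


def _dispersion_scores(X: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Mean-binned normalized dispersion (Seurat-v1 flavor) per gene.

    Computed on the expm1 scale of the logged matrix: dispersion =
    variance / mean, z-scored within bins of similar mean expression so
    highly expressed genes do not dominate the ranking.
    """
    E = np.expm1(X)
    mean = E.mean(axis=0)
    var = E.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    # bin genes by mean expression value; z-score dispersion within each bin
    n_genes = X.shape[1]
    n_bins = min(n_bins, max(1, n_genes // 2))
    quantiles = np.quantile(mean, np.linspace(0, 1, n_bins + 1)[1:-1])
    bin_of = np.digitize(mean, quantiles)
    score = disp.copy()  # singleton / zero-spread bins keep raw dispersion
    for b in np.unique(bin_of):
        idx = bin_of == b
        d = disp[idx]
        sd = d.std()
        if idx.sum() > 1 and sd > 0:
            score[idx] = (d - d.mean()) / sd
    return score, disp


def select_hvg(ds: SpotDataset, n_top: int = DEFAULT_N_TOP) -> SpotDataset:
    """Restrict the processed matrix to the ``n_top`` most variable genes.

    If fewer genes exist, all are kept.  Ties are broken by gene index so
    the selection is deterministic; the original column order is preserved
    in the output, and the ranking order is recorded in ``meta``.
    """
    if n_top < 1:
        raise ValueError("n_top must be a positive integer")
    if ds.processed is None:
        raise ValueError("select_hvg requires a normalized/logged matrix")
    X = ds.processed
    n_genes = X.shape[1]
    if n_genes <= n_top:
        selected = np.arange(n_genes)
    else:
        score, disp = _dispersion_scores(X)
        # rank by normalized score, raw dispersion breaking score ties,
        # gene index breaking exact ties (lexsort: last key is primary)
        ranking = np.lexsort((np.arange(X.shape[1]), -disp, -score))
        selected = np.sort(ranking[:n_top])
    gene_ids = list(ds.processed_gene_ids or ds.gene_ids)
    meta = dict(ds.meta)
    meta["hvg_selection_order"] = [gene_ids[i] for i in selected]
    return ds.with_(
        processed=X[:, selected],
        processed_gene_ids=[gene_ids[i] for i in selected],
        meta=meta,
    )


def preprocess(
    ds: SpotDataset,
    min_cells: int = DEFAULT_MIN_CELLS,
    scale: float = DEFAULT_SCALE,
    n_top: int = DEFAULT_N_TOP,
) -> SpotDataset:
    """Run the full fixed-order pipeline: filter -> normalize -> log1p -> HVG."""
    return select_hvg(normalize_log(filter_genes(ds, min_cells), scale), n_top)
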