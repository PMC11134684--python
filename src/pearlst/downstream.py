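"""Domain segmentation, pseudo-spatiotemporal mapping, and trajectory hooks.

Spatial domains are obtained by K-means on the learned embeddings (or
Louvain/Leiden community detection on a k-NN graph).  The pseudo-
spatiotemporal map (pSM) is the diffusion pseudotime from a root spot
chosen as the embedding-space point with the largest summed Euclidean
distance to all others; pseudotime is min-max scaled to [0, 1].  Cluster-
level trajectory abstraction is delegated to PAGA.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)

DEFAULT_DPT_KNN = 15
DEFAULT_DPT_COMPS = 10


def cluster_domains(
    Z: np.ndarray,
    n_clusters: int,
    seed: int = 0,
    method: str = "kmeans",
    resolution: float = 1.0,
) -> np.ndarray:
    """Segment spots into spatial domains from their embeddings.

    K-means (default) uses k-means++ initialization with ``n_init=10``
    and is deterministic under ``seed``.  ``method='louvain'`` runs
    community detection on a k-NN graph at the given resolution (the
    number of communities is then data-driven).
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if method == "kmeans":
        if not 1 <= n_clusters <= n:
            raise ValueError(f"n_clusters must be in [1, {n}]")
        km = KMeans(n_clusters=n_clusters, init="k-means++", n_init=10,
                    random_state=seed)
        return km.fit_predict(Z)
    if method == "louvain":
        import scanpy as sc

        adata = _anndata_from_embeddings(Z)
        sc.pp.neighbors(adata, n_neighbors=min(DEFAULT_DPT_KNN, n - 1),
                        use_rep="X", random_state=seed)
        sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                     key_added="domain", flavor="igraph", n_iterations=2,
                     directed=False)
        return adata.obs["domain"].astype(int).to_numpy()
    raise ValueError("method must be 'kmeans' or 'louvain'")


def select_root(Z: np.ndarray, root: Optional[int] = None) -> int:
    """Root spot for pseudotime: argmax of summed Euclidean distances.

    Ties break to the lowest index.  A user-supplied ``root`` (a priori
    knowledge) overrides the automatic rule.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n = Z.shape[0]
    if root is not None:
        if not 0 <= root < n:
            raise ValueError(f"root index {root} out of range")
        return int(root)
    if n == 1:
        return 0
    sums = squareform(pdist(Z)).sum(axis=1)
    return int(np.argmax(sums))  # argmax returns the first (lowest) index on ties


@dataclass
class PseudotimeResult:
    root_index: int
    psm: np.ndarray
    method_meta: dict = field(default_factory=dict)


def _anndata_from_embeddings(Z: np.ndarray):
    import anndata as ad
    import pandas as pd

    Z = np.asarray(Z, dtype=float)
    return ad.AnnData(
        X=Z, obs=pd.DataFrame(index=[str(i) for i in range(Z.shape[0])])
    )


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi > lo:
        return (x - lo) / (hi - lo)
    return np.zeros_like(x)


def compute_psm(
    Z: np.ndarray,
    root: Optional[int] = None,
    n_neighbors: int = DEFAULT_DPT_KNN,
    n_comps: int = DEFAULT_DPT_COMPS,
) -> PseudotimeResult:
    """Pseudo-spatiotemporal map via diffusion pseudotime (DPT).

    Delegates to the scanpy DPT implementation on a k-NN graph of the
    embeddings; results are min-max scaled to [0, 1] with psm[root] = 0.
    Disconnected k-NN graphs are handled per connected component (each
    component gets its own root and scaling) with a warning.
    """
    import scanpy as sc
    from scipy.sparse.csgraph import connected_components

    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n = Z.shape[0]
    root = select_root(Z, root)
    if n <= 2:
        psm = _minmax(np.linalg.norm(Z - Z[root], axis=1))
        return PseudotimeResult(root, psm, {"backend": "trivial"})

    k = int(min(n_neighbors, n - 1))
    comps = int(min(n_comps, n - 2))
    adata = _anndata_from_embeddings(Z)
    sc.pp.neighbors(adata, n_neighbors=k, use_rep="X", random_state=0)
    n_cc, cc_labels = connected_components(
        adata.obsp["connectivities"], directed=False
    )
    psm = np.zeros(n)
    if n_cc > 1:
        logger.warning(
            "embedding k-NN graph has %d components; pseudotime computed "
            "per component", n_cc,
        )
    for cc in range(n_cc):
        idx = np.flatnonzero(cc_labels == cc)
        if idx.size == 1:
            psm[idx] = 0.0
            continue
        Zc = Z[idx]
        if root in idx:
            local_root = int(np.flatnonzero(idx == root)[0])
        else:
            local_root = select_root(Zc)
        if idx.size <= 3:
            psm[idx] = _minmax(np.linalg.norm(Zc - Zc[local_root], axis=1))
            continue
        if not np.any(Zc.std(axis=0) > 0):
            psm[idx] = 0.0  # all embeddings identical: no ordering exists
            continue
        n_dcs = int(min(comps, idx.size - 2))
        sub = _anndata_from_embeddings(Zc)
        sc.pp.neighbors(sub, n_neighbors=min(k, idx.size - 1), use_rep="X",
                        random_state=0)
        sc.tl.diffmap(sub, n_comps=n_dcs)
        sub.uns["iroot"] = local_root
        sc.tl.dpt(sub, n_dcs=n_dcs)
        pt = np.asarray(sub.obs["dpt_pseudotime"], dtype=float)
        pt[~np.isfinite(pt)] = np.nanmax(pt[np.isfinite(pt)]) if np.isfinite(pt).any() else 0.0
        psm[idx] = _minmax(pt)
    psm[root] = 0.0
    return PseudotimeResult(
        root_index=root,
        psm=psm,
        method_meta={"backend": "scanpy.dpt", "n_neighbors": k, "n_comps": comps,
                     "n_components": int(n_cc)},
    )


def trajectory_hook(
    Z: np.ndarray, labels: Sequence, n_neighbors: int = DEFAULT_DPT_KNN
) -> dict:
    """Cluster-level trajectory abstraction, delegated to PAGA.

    Returns a JSON-serializable cluster graph: nodes are cluster names,
    edges carry PAGA connectivity weights.
    """
    try:
        import scanpy as sc
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "trajectory_hook requires the optional scanpy dependency"
        ) from exc
    import pandas as pd

    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != Z.shape[0]:
        raise ValueError("labels must have one entry per embedding row")
    names = [str(c) for c in pd.Categorical(labels).categories]
    if len(names) == 1:
        return {"nodes": names, "edges": []}
    adata = _anndata_from_embeddings(Z)
    adata.obs["cluster"] = pd.Categorical([str(l) for l in labels])
    sc.pp.neighbors(adata, n_neighbors=min(n_neighbors, Z.shape[0] - 1),
                    use_rep="X", random_state=0)
    # PAGA cannot build its coarse graph when no k-NN edge crosses clusters;
    # scientifically that simply means zero connectivity between all pairs.
    spot_conn = adata.obsp["connectivities"].tocoo()
    codes = adata.obs["cluster"].cat.codes.to_numpy()
    if not np.any(codes[spot_conn.row] != codes[spot_conn.col]):
        return {"nodes": names, "edges": []}
    sc.tl.paga(adata, groups="cluster")
    conn = adata.uns["paga"]["connectivities"].tocoo()
    edges = [
        {"source": names[i], "target": names[j], "weight": float(w)}
        for i, j, w in zip(conn.row, conn.col, conn.data)
        if i < j and w > 0
    ]
    return {"nodes": names, "edges": edges}


def write_cluster_graph(graph: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(graph, fh, indent=2, sort_keys=True)


def read_cluster_graph(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)


def ari(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted Rand index between two labelings (permutation model)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape[0] != labels_b.shape[0]:
        raise ValueError("labelings must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))


def low_coverage_mode(
    ds,
    nn_sets: Sequence[Sequence[int]],
    n_clusters: int,
    seed: int = 0,
) -> np.ndarray:
    """Segmentation path for imaging-based, low-gene-count platforms.

    Skips the PDE diffusion and the autoencoder entirely: each spot's
    profile is replaced by the mean of itself and its spatial nearest
    neighbors, then K-means runs directly on the augmented profiles.
    """
    X = np.asarray(ds.processed if ds.processed is not None else ds.counts,
                   dtype=float)
    out = np.empty_like(X)
    for i, nn in enumerate(nn_sets):
        members = [i] + [int(j) for j in nn]
        out[i] = X[members].mean(axis=0)
    return cluster_domains(out, n_clusters, seed=seed)
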