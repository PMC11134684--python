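"""Multi-modal spatial nearest neighbors.

Each pair of spots is scored by the product of three factors:

* **ES** -- expression similarity: Pearson correlation of the two spots'
  profiles across genes (cosine similarity of the mean-centered profiles).
* **MS** -- morphological similarity: cosine similarity of the 2048-dim
  image-feature rows.  Platforms without histology use the null provider
  (MS identically 1), so the gate reduces to expression x proximity.
* **PS** -- spatial proximity gate: 1 iff the Euclidean distance is
  strictly below a radius gamma estimated from the pooled distances to
  each spot's nearest neighbors.

The overall similarity OS = ES * MS * PS ranks, per spot, the up-to-k
spatial nearest neighbors used by the augmentation stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform

DEFAULT_K_NN = 4
DEFAULT_M = 30


def expression_similarity(X: np.ndarray) -> np.ndarray:
    """Pearson correlation of spot profiles across genes.

    Spots whose centered profile has zero norm (constant profiles,
    including all-zero rows) score 0 against every spot, themselves
    included.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("expression_similarity requires an N x d matrix with d >= 2")
    C = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(C, axis=1)
    ok = norms > 0
    Cn = np.zeros_like(C)
    Cn[ok] = C[ok] / norms[ok, None]
    ES = Cn @ Cn.T
    return np.clip(ES, -1.0, 1.0)


def morphological_similarity(M: np.ndarray, n_spots: Optional[int] = None) -> np.ndarray:
    """Cosine similarity of per-spot image-feature rows; zero-norm rows score 0."""
    M = np.asarray(M, dtype=float)
    if n_spots is not None and M.shape[0] != n_spots:
        raise ValueError(
            f"image feature rows ({M.shape[0]}) do not match spot count ({n_spots})"
        )
    norms = np.linalg.norm(M, axis=1)
    ok = norms > 0
    Mn = np.zeros_like(M)
    Mn[ok] = M[ok] / norms[ok, None]
    MS = Mn @ Mn.T
    return np.clip(MS, -1.0, 1.0)


def spatial_radius(
    coords: np.ndarray, m: int = DEFAULT_M, dispersion: str = "sd"
) -> float:
    """Radius gamma from pooled per-spot nearest-neighbor distances.

    For each spot its ``m`` smallest distances to other spots are pooled
    over all spots; gamma = pooled mean + pooled dispersion.  ``m`` is
    silently capped at N - 1.  ``dispersion`` selects standard deviation
    (default, dimensionally consistent) or variance.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("spatial_radius requires at least 2 spots")
    m = min(int(m), n - 1)
    if m < 1:
        raise ValueError("m must be positive")
    D = squareform(pdist(coords))
    np.fill_diagonal(D, np.inf)
    pooled = np.sort(D, axis=1)[:, :m].ravel()
    if dispersion == "sd":
        spread = pooled.std()
    elif dispersion == "variance":
        spread = pooled.var()
    else:
        raise ValueError("dispersion must be 'sd' or 'variance'")
    return float(pooled.mean() + spread)


def spatial_gate(coords: np.ndarray, gamma: float) -> np.ndarray:
    """Binary proximity gate: PS_ij = 1 iff 0 < ||r_i - r_j|| < gamma."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    coords = np.asarray(coords, dtype=float)
    D = squareform(pdist(coords))
    PS = ((D > 0) & (D < gamma)).astype(float)
    np.fill_diagonal(PS, 0.0)
    return PS


def overall_similarity(
    ES: np.ndarray, MS: np.ndarray, PS: np.ndarray, k_nn: int = DEFAULT_K_NN
) -> tuple[np.ndarray, List[List[int]]]:
    """OS = ES * MS * PS elementwise, plus per-spot ordered neighbor sets.

    NN_i lists the indices of the ``k_nn`` largest strictly positive
    OS_ij (j != i), in descending OS order, ties broken by lower index.
    Spots with fewer positive entries get shorter lists.
    """
    ES, MS, PS = (np.asarray(a, dtype=float) for a in (ES, MS, PS))
    if not (ES.shape == MS.shape == PS.shape):
        raise ValueError("ES, MS, PS must have identical shapes")
    OS = ES * MS * PS
    n = OS.shape[0]
    nn_sets: List[List[int]] = []
    idx = np.arange(n)
    for i in range(n):
        row = OS[i].copy()
        row[i] = 0.0
        pos = idx[row > 0]
        # stable sort on -OS => ties resolved by lower index
        order = pos[np.argsort(-row[pos], kind="stable")]
        nn_sets.append(order[:k_nn].tolist())
    return OS, nn_sets


@dataclass
class NeighborModel:
    """Pairwise similarities and per-spot nearest-neighbor sets."""

    ES: np.ndarray
    MS: np.ndarray
    PS: np.ndarray
    OS: np.ndarray
    gamma: float
    nn_sets: List[List[int]]


def compute_neighbors(
    X: np.ndarray,
    coords: np.ndarray,
    image_features: Optional[np.ndarray] = None,
    k_nn: int = DEFAULT_K_NN,
    m: int = DEFAULT_M,
    dispersion: str = "sd",
) -> NeighborModel:
    """Full neighbor computation: ES, MS (null provider if no image), PS, OS, NN sets."""
    n = np.asarray(X).shape[0]
    ES = expression_similarity(X)
    if image_features is None:
        MS = np.ones((n, n))
    else:
        MS = morphological_similarity(image_features, n_spots=n)
    gamma = spatial_radius(coords, m=m, dispersion=dispersion)
    PS = spatial_gate(coords, gamma)
    OS, nn_sets = overall_similarity(ES, MS, PS, k_nn=k_nn)
    return NeighborModel(ES=ES, MS=MS, PS=PS, OS=OS, gamma=gamma, nn_sets=nn_sets)
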