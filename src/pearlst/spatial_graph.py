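"""Spatial expression graph: alpha-complex 1-skeleton and normalized adjacency.

Spots become nodes; edges are the Delaunay edges whose alpha-complex
filtration radius is at most delta (for a Gabriel edge: half its length;
otherwise the smallest circumradius of an adjacent Delaunay triangle).
delta is estimated as the average distance to each spot's k nearest
neighbors.  The encoder consumes the symmetric-normalized, self-looped
adjacency A_bar = D~^{-1/2} (A + I) D~^{-1/2}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

DEFAULT_K_DELTA = 30
_JITTER_SEED = 20240901
_JITTER_EPS = 1e-9

Edge = Tuple[int, int]


def estimate_delta(coords: np.ndarray, k_delta: int = DEFAULT_K_DELTA) -> float:
    """Mean over spots of the mean distance to their k nearest neighbors."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("estimate_delta requires at least 2 spots")
    k = min(int(k_delta), n - 1)
    tree = cKDTree(coords)
    dist, _ = tree.query(coords, k=k + 1)
    return float(dist[:, 1:].mean())


def _circumradius(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Circumradius of triangle abc; inf for degenerate triangles."""
    la, lb, lc = (
        np.linalg.norm(b - c),
        np.linalg.norm(a - c),
        np.linalg.norm(a - b),
    )
    u, v = b - a, c - a
    area2 = abs(u[0] * v[1] - u[1] * v[0])  # 2 * area
    if area2 == 0:
        return float("inf")
    return float(la * lb * lc / (2.0 * area2))


def alpha_filtration_edges(coords: np.ndarray) -> dict[Edge, float]:
    """Filtration radius of every Delaunay edge.

    Gabriel edges (diametral ball empty of the opposite vertices of the
    adjacent triangles) enter at half their length; non-Gabriel edges at
    the smallest adjacent-triangle circumradius.
    """
    coords = np.asarray(coords, dtype=float)
    tri = Delaunay(coords)
    edge_tris: dict[Edge, List[int]] = {}
    for t, simplex in enumerate(tri.simplices):
        for u, v in ((0, 1), (0, 2), (1, 2)):
            e = tuple(sorted((int(simplex[u]), int(simplex[v]))))
            edge_tris.setdefault(e, []).append(t)
    filtration: dict[Edge, float] = {}
    for (i, j), tris in edge_tris.items():
        pi, pj = coords[i], coords[j]
        mid = (pi + pj) / 2.0
        half = np.linalg.norm(pj - pi) / 2.0
        gabriel = True
        radii = []
        for t in tris:
            simplex = tri.simplices[t]
            k = int([v for v in simplex if v not in (i, j)][0])
            radii.append(_circumradius(pi, pj, coords[k]))
            if np.linalg.norm(coords[k] - mid) < half:
                gabriel = False
        filtration[(i, j)] = half if gabriel else min(radii)
    return filtration


def _threshold_edges(coords: np.ndarray, delta: float) -> Set[Edge]:
    """Distance-threshold fallback for degenerate (e.g. collinear) inputs."""
    D = squareform(pdist(coords))
    n = coords.shape[0]
    return {
        (i, j) for i in range(n) for j in range(i + 1, n) if 0 < D[i, j] <= delta
    }


def alpha_edges(coords: np.ndarray, delta: float) -> Set[Edge]:
    """Alpha-complex 1-skeleton at radius delta.

    Duplicate coordinates are jittered by a fixed-seed epsilon; collinear
    inputs (where a Delaunay triangulation does not exist) fall back to a
    distance-threshold graph at delta.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("alpha_edges requires at least 2 spots")
    if delta <= 0:
        return set()
    # jitter exact duplicates deterministically so Delaunay is well posed
    _, first = np.unique(coords, axis=0, return_index=True)
    if len(first) < n:
        rng = np.random.default_rng(_JITTER_SEED)
        coords = coords + rng.normal(scale=_JITTER_EPS, size=coords.shape)
        logger.warning("duplicate coordinates jittered by eps=%g", _JITTER_EPS)
    if n == 2:
        return _threshold_edges(coords, delta)
    try:
        filtration = alpha_filtration_edges(coords)
    except Exception:  # collinear / degenerate point sets
        logger.warning(
            "Delaunay triangulation failed (degenerate coordinates); "
            "falling back to a distance-threshold graph"
        )
        return _threshold_edges(coords, delta)
    return {e for e, r in filtration.items() if r <= delta}


def edges_to_adjacency(edges: Set[Edge], n: int) -> np.ndarray:
    A = np.zeros((n, n))
    for i, j in edges:
        A[i, j] = A[j, i] = 1.0
    return A


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops: D~^{-1/2} (A + I) D~^{-1/2}."""
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    return A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def os_nn_edges(nn_sets: Sequence[Sequence[int]]) -> Set[Edge]:
    """Symmetrized edge set from the OS nearest-neighbor lists."""
    edges: Set[Edge] = set()
    for i, nn in enumerate(nn_sets):
        for j in nn:
            edges.add(tuple(sorted((i, int(j)))))
    return edges


@dataclass
class SpatialGraph:
    """Alpha-complex (or OS-NN) graph with its normalized adjacency."""

    edges: Set[Edge]
    A: np.ndarray
    A_bar: np.ndarray
    delta: float
    k_delta: int = DEFAULT_K_DELTA
    meta: dict = field(default_factory=dict)

    @property
    def A_tilde(self) -> np.ndarray:
        return self.A + np.eye(self.A.shape[0])

    def write_edgelist(self, path: str) -> None:
        """Edge-list TSV, one 0-based (i, j) pair per line."""
        with open(path, "w") as fh:
            fh.write("i\tj\n")
            for i, j in sorted(self.edges):
                fh.write(f"{i}\t{j}\n")

    def to_graphml(self, path: str) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.A.shape[0]))
        g.add_edges_from(self.edges)
        nx.write_graphml(g, path)


def build_spatial_graph(
    coords: np.ndarray,
    k_delta: int = DEFAULT_K_DELTA,
    delta: Optional[float] = None,
    graph_source: str = "alpha",
    nn_sets: Optional[Sequence[Sequence[int]]] = None,
) -> SpatialGraph:
    """Construct the graph fed to the encoder (alpha complex by default)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if delta is None:
        delta = estimate_delta(coords, k_delta)
    if graph_source == "alpha":
        edges = alpha_edges(coords, delta)
    elif graph_source == "os_nn":
        if nn_sets is None:
            raise ValueError("graph_source='os_nn' requires nn_sets")
        edges = os_nn_edges(nn_sets)
    else:
        raise ValueError("graph_source must be 'alpha' or 'os_nn'")
    A = edges_to_adjacency(edges, n)
    return SpatialGraph(
        edges=edges,
        A=A,
        A_bar=normalize_adjacency(A),
        delta=float(delta),
        k_delta=k_delta,
        meta={"graph_source": graph_source},
    )
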