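"""Ligand-receptor signaling scores and multilayer communication networks.

Signaling from a sender region to a receiver spot is scored by mass
action with spatial decay: for pair (L, R) and receiver j,

    score_j(L, R) = R_j * sum_{s in senders} L_s * exp(-d_sj / length_scale)

The exponential distance kernel is this package's surrogate for a
diffusion-limited ligand field; its length scale defaults to the mean
nearest-neighbor distance of the tissue.  LR scores are then linked to
the autoencoder's latent dimensions by random-forest regression
(permutation importance), and genes driving each latent dimension are
found by seeded random perturbation of the trained encoder's inputs.
The three relations assemble into a multilayer network
ligand -> receptor -> embedding dimension -> target gene.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 500
DEFAULT_N_REPEATS = 20
DEFAULT_NOISE_SCALE = 1.0
DEFAULT_TOP_Q = 50


def read_lr_pairs(path: str) -> List[Tuple[str, str]]:
    """Two-column TSV (ligand, receptor); header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError("LR pair table must have two columns (ligand, receptor)")
    pairs = []
    for lig, rec in df.iloc[:, :2].itertuples(index=False):
        if str(lig).lower() == "ligand" and str(rec).lower() == "receptor":
            continue  # header row
        pairs.append((str(lig), str(rec)))
    return pairs


def mean_nn_distance(coords: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    coords = np.asarray(coords, dtype=float)
    d, _ = cKDTree(coords).query(coords, k=2)
    return float(d[:, 1].mean())


def lr_score(
    X: np.ndarray,
    coords: np.ndarray,
    sender_mask: np.ndarray,
    receiver_mask: np.ndarray,
    lr_pairs: Sequence[Tuple[str, str]],
    gene_ids: Sequence[str],
    length_scale: Optional[float] = None,
) -> pd.DataFrame:
    """Mass-action, distance-decayed LR scores per receiver spot.

    Returns a (receiver spots x LR pairs) frame indexed by receiver spot
    index; pairs whose genes are missing from the matrix are skipped with
    a warning.
    """
    X = np.asarray(X, dtype=float)
    coords = np.asarray(coords, dtype=float)
    sender_mask = np.asarray(sender_mask, dtype=bool)
    receiver_mask = np.asarray(receiver_mask, dtype=bool)
    if not sender_mask.any():
        raise ValueError("empty sender set")
    if not receiver_mask.any():
        raise ValueError("empty receiver set")
    if length_scale is None:
        length_scale = mean_nn_distance(coords)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    senders = np.flatnonzero(sender_mask)
    receivers = np.flatnonzero(receiver_mask)
    # decay kernel sender -> receiver
    Kd = np.exp(-cdist(coords[senders], coords[receivers]) / length_scale)
    cols: Dict[str, np.ndarray] = {}
    for lig, rec in lr_pairs:
        if lig not in gene_index or rec not in gene_index:
            logger.warning("LR pair (%s, %s) skipped: gene(s) missing", lig, rec)
            continue
        L = X[senders, gene_index[lig]]
        R = X[receivers, gene_index[rec]]
        cols[f"{lig}->{rec}"] = R * (L @ Kd)
    return pd.DataFrame(cols, index=receivers)


def region_interaction_strength(
    X: np.ndarray,
    coords: np.ndarray,
    labels: Sequence,
    lr_pairs: Sequence[Tuple[str, str]],
    gene_ids: Sequence[str],
    length_scale: Optional[float] = None,
) -> pd.DataFrame:
    """Mean summed LR score per (sender region, receiver region) pair."""
    labels = np.asarray(labels)
    regions = sorted(pd.unique(labels).tolist())
    out = pd.DataFrame(0.0, index=regions, columns=regions)
    for rs in regions:
        for rr in regions:
            scores = lr_score(
                X, coords, labels == rs, labels == rr, lr_pairs, gene_ids,
                length_scale=length_scale,
            )
            out.loc[rs, rr] = float(scores.sum(axis=1).mean()) if scores.shape[1] else 0.0
    return out


def link_lr_to_embeddings(
    lr_scores: pd.DataFrame,
    Z: np.ndarray,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    n_permutations: int = 10,
) -> pd.DataFrame:
    """Random-forest regression of each latent dimension on LR scores.

    Importance is seeded permutation importance, clipped at zero.
    Returns an (LR pair x embedding dimension) frame.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != lr_scores.shape[0]:
        raise ValueError("receiver spots of lr_scores and Z rows must align")
    if Z.shape[0] < 10:
        raise ValueError("need at least 10 receiver spots to fit the forest")
    F = lr_scores.to_numpy()
    dims = [f"dim_{k}" for k in range(Z.shape[1])]
    imp = np.zeros((F.shape[1], Z.shape[1]))
    for k in range(Z.shape[1]):
        rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                                   n_jobs=1)
        rf.fit(F, Z[:, k])
        pi = permutation_importance(rf, F, Z[:, k], n_repeats=n_permutations,
                                    random_state=seed, n_jobs=1)
        imp[:, k] = np.clip(pi.importances_mean, 0.0, None)
    return pd.DataFrame(imp, index=list(lr_scores.columns), columns=dims)


def gene_importance_perturbation(
    model,
    X_aug: np.ndarray,
    A_bar: np.ndarray,
    gene_ids: Sequence[str],
    n_repeats: int = DEFAULT_N_REPEATS,
    noise_scale: float = DEFAULT_NOISE_SCALE,
    seed: int = 0,
) -> pd.DataFrame:
    """Perturbation-based importance of each gene for each latent dimension.

    Gene g's column receives seeded Gaussian noise with sd equal to
    ``noise_scale`` times its empirical sd, the perturbed matrix is
    re-encoded, and the mean absolute embedding change per dimension over
    ``n_repeats`` draws is the importance.  Genes the encoder ignores
    (all-zero weight paths) score exactly 0.
    """
    if model is None or model.encoder is None:
        raise ValueError("gene_importance_perturbation requires a trained model")
    X_aug = np.asarray(X_aug, dtype=float)
    n, d = X_aug.shape
    if len(gene_ids) != d:
        raise ValueError("gene_ids length must match X_aug columns")
    rng = np.random.default_rng(seed)
    Z0 = model.embed(X_aug, A_bar)
    sds = X_aug.std(axis=0)
    imp = np.zeros((d, Z0.shape[1]))
    for g in range(d):
        if noise_scale == 0.0 or sds[g] == 0.0:
            # still average |dZ| over draws: zero noise => zero change
            pass
        acc = np.zeros(Z0.shape[1])
        for _ in range(n_repeats):
            noise = rng.normal(scale=noise_scale * sds[g], size=n)
            Xp = X_aug.copy()
            Xp[:, g] = Xp[:, g] + noise
            Zp = model.embed(Xp, A_bar)
            acc += np.abs(Zp - Z0).mean(axis=0)
        imp[g] = acc / n_repeats
    return pd.DataFrame(imp, index=list(gene_ids),
                        columns=[f"dim_{k}" for k in range(Z0.shape[1])])


@dataclass
class CommNetwork:
    """Multilayer ligand -> receptor -> embedding -> target-gene network."""

    nodes: List[dict]
    edges: List[dict]
    lr_importance: Optional[pd.DataFrame] = None
    gene_importance: Optional[pd.DataFrame] = None
    meta: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"nodes": self.nodes, "edges": self.edges}, fh,
                      indent=2, sort_keys=True)

    def to_graphml(self, path: str) -> None:
        import networkx as nx

        g = nx.DiGraph()
        for node in self.nodes:
            g.add_node(node["id"], layer=node["layer"])
        for e in self.edges:
            g.add_edge(e["source"], e["target"], weight=e["weight"],
                       kind=e["kind"])
        nx.write_graphml(g, path)


def build_multilayer_network(
    lr_importance: pd.DataFrame,
    gene_importance: pd.DataFrame,
    lr_threshold: float = 0.0,
    gene_top_q: int = DEFAULT_TOP_Q,
    gene_threshold: float = 0.0,
) -> CommNetwork:
    """Assemble the typed multilayer network from the two importance tables.

    Edges: ligand->receptor (one per LR pair), receptor->embedding
    (lr_importance strictly above ``lr_threshold``), embedding->target
    gene (top ``gene_top_q`` genes per dimension with importance strictly
    above ``gene_threshold``).  Empty results warn rather than error.
    """
    nodes: Dict[str, dict] = {}
    edges: List[dict] = []

    def add_node(node_id: str, layer: str) -> None:
        nodes.setdefault(node_id, {"id": node_id, "layer": layer})

    used_dims: set = set()
    for pair in lr_importance.index:
        lig, rec = pair.split("->")
        for dim in lr_importance.columns:
            w = float(lr_importance.loc[pair, dim])
            if w > lr_threshold and np.isfinite(w):
                add_node(lig, "ligand")
                add_node(rec, "receptor")
                add_node(dim, "embedding")
                edges.append({"source": lig, "target": rec, "weight": 1.0,
                              "kind": "ligand-receptor"})
                edges.append({"source": rec, "target": dim, "weight": w,
                              "kind": "receptor-embedding"})
                used_dims.add(dim)
    for dim in gene_importance.columns:
        if used_dims and dim not in used_dims:
            continue
        col = gene_importance[dim]
        top = col.sort_values(ascending=False, kind="stable").head(gene_top_q)
        for gene, w in top.items():
            if float(w) > gene_threshold:
                add_node(dim, "embedding")
                add_node(str(gene), "target_gene")
                edges.append({"source": dim, "target": str(gene),
                              "weight": float(w), "kind": "embedding-gene"})
    # de-duplicate ligand->receptor edges introduced per dimension
    seen = set()
    unique_edges = []
    for e in edges:
        key = (e["source"], e["target"], e["kind"])
        if key not in seen:
            seen.add(key)
            unique_edges.append(e)
    if not unique_edges:
        logger.warning("thresholds eliminated every edge; network is empty")
    return CommNetwork(nodes=list(nodes.values()), edges=unique_edges,
                       lr_importance=lr_importance,
                       gene_importance=gene_importance)
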