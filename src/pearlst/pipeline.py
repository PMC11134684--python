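"""End-to-end orchestration of the PearlST stages."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from pearlst import comm as comm_mod
from pearlst import diffusion, downstream, neighbors, spatial_graph, warga
from pearlst.preprocess import preprocess as _preprocess
from pearlst.config import RunConfig
from pearlst.dataset import SpotDataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    dataset: SpotDataset
    neighbor_model: neighbors.NeighborModel
    graph: spatial_graph.SpatialGraph
    embeddings: np.ndarray
    model: warga.WargaModel
    labels: np.ndarray
    psm: downstream.PseudotimeResult
    loss_trace: List[dict]
    cluster_graph: Optional[dict] = None
    network: Optional[comm_mod.CommNetwork] = None
    timings: dict = field(default_factory=dict)


def run_pipeline(
    ds: SpotDataset,
    config: RunConfig,
    lr_pairs: Optional[List[Tuple[str, str]]] = None,
    with_trajectory: bool = False,
) -> PipelineResult:
    """preprocess -> neighbors -> diffusion -> graph -> autoencoder -> downstream.

    The communication stage runs only when an LR pair table is supplied.
    Identical config + seed gives identical outputs.
    """
    timings: dict = {}

    def _stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s started", name)

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc_type is not None:
                    logger.error("stage %s failed: %s", name, exc)
                else:
                    logger.info("stage %s done in %.2fs", name, timings[name])

        return _T()

    try:
        with _stage("preprocess"):
            ds = _preprocess(
                ds, min_cells=config.min_cells, scale=config.scale,
                n_top=config.n_top,
            )
    except Exception as exc:
        raise RuntimeError(
            "stage 'preprocess' failed; check that the count matrix is "
            "non-negative and not empty after gene filtering"
        ) from exc

    with _stage("neighbors"):
        nm = neighbors.compute_neighbors(
            ds.processed, ds.coords, image_features=ds.image_features,
            k_nn=config.k_nn, m=config.m, dispersion=config.radius_dispersion,
        )

    with _stage("diffusion"):
        dcfg = diffusion.DiffusionConfig(
            K=config.K, lam=config.lam, n_iter=config.n_iter,
            grid_shape=config.grid_shape, coeff_mode=config.coeff_mode,
        )
        ds = diffusion.denoise_and_augment(ds, nm.nn_sets, dcfg)

    with _stage("graph"):
        graph = spatial_graph.build_spatial_graph(
            ds.coords, k_delta=config.k_delta,
            graph_source=config.graph_source, nn_sets=nm.nn_sets,
        )

    with _stage("embed"):
        tcfg = warga.TrainConfig(
            epochs=config.epochs, gp_lambda=config.gp_lambda,
            lr_gen=config.lr_gen, lr_critic=config.lr_critic,
            critic_steps=config.critic_steps, seed=config.seed,
            hidden_h=config.hidden_h, d_prime=config.d_prime,
            dropout=config.dropout, critic_mode=config.critic_mode,
            final_activation=config.final_activation,
        )
        Z, model, trace = warga.train(ds.augmented, graph.A_bar, graph.A, tcfg)

    with _stage("cluster"):
        labels = downstream.cluster_domains(
            Z, config.n_clusters, seed=config.seed, method=config.cluster_method,
        )

    with _stage("psm"):
        psm = downstream.compute_psm(
            Z, root=config.root, n_neighbors=config.dpt_neighbors,
            n_comps=config.dpt_comps,
        )

    cluster_graph = None
    if with_trajectory:
        with _stage("trajectory"):
            cluster_graph = downstream.trajectory_hook(Z, labels)

    network = None
    if lr_pairs:
        with _stage("comm"):
            gene_ids = list(ds.processed_gene_ids or ds.gene_ids)
            scores = comm_mod.lr_score(
                ds.augmented, ds.coords,
                sender_mask=np.ones(ds.n_spots, dtype=bool),
                receiver_mask=np.ones(ds.n_spots, dtype=bool),
                lr_pairs=lr_pairs, gene_ids=gene_ids,
                length_scale=config.lr_length_scale,
            )
            lr_imp = comm_mod.link_lr_to_embeddings(
                scores, Z, seed=config.seed, n_trees=config.rf_trees,
            )
            gene_imp = comm_mod.gene_importance_perturbation(
                model, ds.augmented, graph.A_bar, gene_ids,
                n_repeats=config.perturb_repeats,
                noise_scale=config.perturb_noise_scale, seed=config.seed,
            )
            network = comm_mod.build_multilayer_network(
                lr_imp, gene_imp, gene_top_q=config.gene_top_q,
            )

    return PipelineResult(
        dataset=ds, neighbor_model=nm, graph=graph, embeddings=Z,
        model=model, labels=labels, psm=psm, loss_trace=trace,
        cluster_graph=cluster_graph, network=network, timings=timings,
    )
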