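"""Run configuration: every tunable of the pipeline in one place.

Defaults equal the published values where the method states them
(min_cells=4, scale=10000, n_top=2000, k_nn=4, m=30, K=0.2, lam=0.1,
n_iter=4, grid 50x40, k_delta=30, d_prime=32); the remaining knobs are
this package's documented choices.  Unknown keys in a config file are
rejected so typos fail loudly, and the resolved config is echoed into
the output container for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Tuple

import yaml


@dataclass
class RunConfig:
    # preprocess
    min_cells: int = 4
    scale: float = 10_000.0
    n_top: int = 2_000
    # neighbors
    k_nn: int = 4
    m: int = 30
    radius_dispersion: str = "sd"
    # diffusion
    K: float = 0.2
    lam: float = 0.1
    n_iter: int = 4
    grid_shape: Tuple[int, int] = (50, 40)
    coeff_mode: str = "directional"
    # spatial graph
    k_delta: int = 30
    graph_source: str = "alpha"
    # autoencoder
    d_prime: int = 32
    hidden_h: int = 128
    epochs: int = 500
    dropout: float = 0.1
    gp_lambda: float = 10.0
    critic_mode: str = "gp"
    critic_steps: int = 5
    final_activation: str = "linear"
    lr_gen: float = 1e-3
    lr_critic: float = 1e-3
    # downstream
    n_clusters: int = 7
    cluster_method: str = "kmeans"
    root: Optional[int] = None
    dpt_neighbors: int = 15
    dpt_comps: int = 10
    # communication
    lr_length_scale: Optional[float] = None
    rf_trees: int = 500
    perturb_repeats: int = 20
    perturb_noise_scale: float = 1.0
    gene_top_q: int = 50
    # global
    seed: int = 0

    @classmethod
    def field_names(cls) -> set:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - cls.field_names()
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "grid_shape" in d:
            d = dict(d, grid_shape=tuple(d["grid_shape"]))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
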