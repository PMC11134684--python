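"""Synthetic layered-tissue datasets with known ground truth.

The generator emulates the structure of laminar tissues (cortical layers,
olfactory bulb rings): spots arranged in spatial domains, each domain
over-expressing its own gene program, optionally with a monotone shared
program along the layer order (a planted pseudotime gradient) and a
planted ligand-receptor pair driving one domain.  Counts are negative-
binomial with multiplicative log-normal noise and Bernoulli dropout
(zero inflation), the dominant noise modes of spot-level ST data.

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawning, so sub-generators (layout, expression, noise, dropout) are
mutually independent and the whole fixture is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from pearlst.dataset import SpotDataset

# fraction of genes given to each domain's marker program, and to the
# shared gradient program
MARKER_FRACTION = 0.10
GRADIENT_FRACTION = 0.20
NB_DISPERSION = 0.5  # alpha in var = mu + alpha * mu^2


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic tissue."""

    n_spots: int = 300
    n_genes: int = 200
    n_domains: int = 3
    layout: str = "layered_strips"
    effect_size: float = 2.0  # log-fold shift of domain marker programs
    noise_sd: float = 0.3     # sd of log-normal noise on the log-mean
    dropout_rate: float = 0.2
    gradient: bool = False
    planted_lr: Optional[Tuple[str, str, int]] = None  # (ligand, receptor, driven domain)
    seed: int = 0
    nb_dispersion: float = NB_DISPERSION

    def validate(self) -> None:
        problems = []
        if self.n_domains > self.n_spots:
            problems.append("n_domains exceeds n_spots")
        if self.effect_size < 0:
            problems.append("effect_size must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            problems.append("dropout_rate must be in [0, 1)")
        if self.layout not in ("layered_strips", "blobs", "grid"):
            problems.append(f"unknown layout {self.layout!r}")
        if self.planted_lr is not None and not (
            0 <= self.planted_lr[2] < self.n_domains
        ):
            problems.append("planted_lr driven domain out of range")
        if problems:
            raise ValueError("invalid fixture spec: " + "; ".join(problems))


def _layout(spec: FixtureSpec, rng: np.random.Generator):
    """Spot coordinates, domain labels, and layer-order position t in [0, 1]."""
    n, k = spec.n_spots, spec.n_domains
    per = n // k
    counts = [per] * k
    counts[-1] += n - per * k
    labels = np.repeat(np.arange(k), counts)
    if spec.layout in ("layered_strips", "grid"):
        coords = np.empty((n, 2))
        start = 0
        for d, c in enumerate(counts):
            if spec.layout == "grid":
                side = int(np.ceil(np.sqrt(c)))
                xs = np.arange(c) % side
                ys = np.arange(c) // side
                block = np.column_stack([xs + d * (side + 1), ys]).astype(float)
                block += rng.normal(scale=0.05, size=block.shape)
            else:
                block = np.column_stack([
                    rng.uniform(d, d + 1, size=c),
                    rng.uniform(0, 1, size=c),
                ])
            coords[start:start + c] = block
            start += c
        # layer order runs along x
        x = coords[:, 0]
        t = (x - x.min()) / (x.max() - x.min()) if x.max() > x.min() else np.zeros(n)
    else:  # blobs
        centers = rng.uniform(0, 10, size=(k, 2))
        coords = centers[labels] + rng.normal(scale=0.5, size=(n, 2))
        t = (labels / max(k - 1, 1)).astype(float)
    return coords, labels, t


def make_tissue(spec: FixtureSpec):
    """Generate one tissue: (SpotDataset, truth_labels, truth_pseudotime).

    Domain programs: each domain's marker block gets a log-fold shift of
    ``effect_size`` in that domain's spots.  With ``gradient=True`` a
    shared block scales linearly (amplitude 2 x effect_size) along the
    layer order, planting a monotone pseudotime signal.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_layout, rng_expr, rng_noise, rng_drop = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    n, g, k = spec.n_spots, spec.n_genes, spec.n_domains
    coords, labels, t = _layout(spec, rng_layout)

    base = rng_expr.normal(loc=1.0, scale=0.5, size=g)  # per-gene log-mean
    log_mu = np.tile(base, (n, 1))

    block = max(1, int(round(MARKER_FRACTION * g)))
    gene_ids = [f"gene_{j}" for j in range(g)]
    for d in range(k):
        cols = slice(d * block, min((d + 1) * block, g))
        log_mu[labels == d, cols] += spec.effect_size

    if spec.gradient:
        gblock = max(1, int(round(GRADIENT_FRACTION * g)))
        cols = slice(g - gblock, g)
        log_mu[:, cols] += (2.0 * spec.effect_size) * t[:, None]

    if spec.planted_lr is not None:
        lig, rec, driven = spec.planted_lr
        lig_idx, rec_idx = g - 2, g - 1
        gene_ids[lig_idx], gene_ids[rec_idx] = lig, rec
        sender = (driven + 1) % k
        log_mu[:, lig_idx] = base[lig_idx]
        log_mu[:, rec_idx] = base[rec_idx]
        log_mu[labels == sender, lig_idx] += 2.0
        log_mu[labels == driven, rec_idx] += 2.0

    if spec.noise_sd > 0:
        log_mu = log_mu + rng_noise.normal(scale=spec.noise_sd, size=log_mu.shape)

    mu = np.exp(log_mu)
    if spec.nb_dispersion > 0:
        r = 1.0 / spec.nb_dispersion  # gamma shape; var = mu + alpha mu^2
        lam = rng_expr.gamma(shape=r, scale=mu / r)
    else:
        lam = mu
    counts = rng_expr.poisson(lam).astype(float)
    if spec.dropout_rate > 0:
        keep = rng_drop.random(counts.shape) >= spec.dropout_rate
        counts = counts * keep

    ds = SpotDataset(
        counts=counts,
        coords=coords,
        gene_ids=gene_ids,
        labels=labels.copy(),
        meta={"fixture_spec": spec.__dict__.copy()},
    )
    return ds, labels, t


def make_image_features(
    truth_labels: np.ndarray,
    dim: int = 2048,
    sep: float = 5.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-domain Gaussian image-feature clouds at pairwise centroid distance sep.

    Stands in for histology features: with sep > 0 the morphological
    similarity is higher within than between domains; sep = 0 is the null.
    """
    truth_labels = np.asarray(truth_labels)
    rng = np.random.default_rng(seed)
    domains = np.unique(truth_labels)
    k = len(domains)
    # orthogonal unit directions scaled so centroids are pairwise sep apart
    centroids = np.zeros((k, dim))
    for i in range(min(k, dim)):
        centroids[i, i] = sep / np.sqrt(2.0)
    label_to_row = {d: i for i, d in enumerate(domains)}
    rows = np.array([label_to_row[d] for d in truth_labels])
    return centroids[rows] + rng.normal(size=(truth_labels.shape[0], dim))
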