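# Methods

This note documents the model implemented in `pearlst`, every tunable
with its default, the synthetic-data generator used for evaluation, the
numerical choices made during implementation, and known limitations.

## 1. Preprocessing (`pearlst.preprocess`)

Genes expressed in fewer than `min_cells = 4` spots are removed; counts
are depth-normalized to `scale = 10 000` per spot and log1p-transformed;
the `n_top = 2000` highly variable genes are kept by a binned dispersion
score: genes are binned by mean expression into value-quantile bins
(`min(20, n_genes // 2)` bins), the dispersion (variance/mean of
expression) is z-scored within each bin, and genes are ranked by that
z-score (raw dispersion for degenerate bins). Zero-variance genes rank
strictly last. Spots with zero total counts pass through unchanged with
a warning.

## 2. Multi-modal nearest neighbors (`pearlst.neighbors`)

Per spot pair the package computes

- **ES** — Pearson correlation of expression profiles across genes;
- **MS** — cosine similarity of per-spot image features (a null provider
  sets MS ≡ 1 when no histology features are supplied);
- **PS** — a hard spatial gate: 1 if `0 < d_ij < γ`, else 0, where
  γ = mean + sd of the pooled per-spot `m = 30` smallest spot–spot
  distances (`radius_dispersion` can switch sd → variance);
- **OS = ES ⊙ MS ⊙ PS** — the overall similarity.

Each spot's neighbor set is its `k_nn = 4` strictly positive top OS
entries; ties break to the lower index (stable argsort).

## 3. PDE denoising and augmentation (`pearlst.diffusion`)

Each spot's processed profile is reshaped row-major onto a
`grid_shape = (50, 40)` grid (trailing cells zero-padded and masked) and
evolved by the explicit Perona–Malik scheme

```
u <- u + λ Σ_dir c(∇_dir u) ∇_dir u,   c(g) = 1 / (1 + (g/K)^2)
```

with `K = 0.2`, `λ = 0.1`, `n_iter = 4`, zero-flux (Neumann) boundaries,
and masked cells excluded from the stencil. The default `coeff_mode =
"directional"` evaluates the diffusivity per directional difference; a
`"neighbor_pixel"` mode is available. Because `λ · Σ c ≤ 0.4 < 1` the
update satisfies a discrete extremum principle (verified by tests).

The same update then runs *across spots*: each spot's profile moves
toward its multi-modal nearest neighbors' profiles by a Jacobi sweep of
the identical nonlinear update, for another `n_iter = 4` iterations.
The result is the `augmented` matrix consumed by the autoencoder.

## 4. Spatial graph (`pearlst.spatial_graph`)

Nodes are spots; edges are the alpha-complex 1-skeleton at radius δ of
the Delaunay triangulation: a Gabriel edge enters the filtration at half
its length, a non-Gabriel edge at the smallest adjacent-triangle
circumradius. δ defaults to the mean over spots of the mean distance to
their `k_delta = 30` nearest neighbors. Exact duplicate coordinates are
jittered by a fixed-seed 1e-9 perturbation; collinear point sets fall
back to a distance-threshold graph. The encoder consumes the
symmetric-normalized self-looped adjacency
`A_bar = D̃^{-1/2} (A + I) D̃^{-1/2}`. `graph_source = "os_nn"` instead
symmetrizes the multi-modal neighbor sets.

## 5. Adversarial graph autoencoder (`pearlst.warga`)

Encoder: `Z = A_bar · act(A_bar · ReLU(A_bar X W1) · W2)` with
`hidden_h = 128`, `d_prime = 32`, dropout 0.1 on the hidden layer during
training. Decoder: `P = σ(Z Zᵀ)`; the reconstruction loss is
positive-weighted binary cross-entropy against `A + I` (positive weight
= #non-edges / #edges), computed in a softplus-stable form. A 3-layer
ReLU critic (widths 64, 64) is trained `critic_steps = 5` times per
generator step with the WGAN gradient penalty (`gp_lambda = 10`,
second-order gradients derived analytically with frozen ReLU masks;
`critic_mode = "clip"` gives weight clipping instead). Both players use
a hand-rolled Adam at `lr = 1e-3` for `epochs = 500`. All parameters,
forward passes, and gradients are pure NumPy; every analytic gradient is
finite-difference checked in the test suite (rel. error ~1e-10).

**Output activation.** The default `final_activation = "linear"` is a
deliberate deviation from a ReLU output layer. With a ReLU output the
embedding is confined to the non-negative orthant: inner products cannot
go below zero, so non-edge probabilities cannot fall below 0.5, the
latent distribution cannot match the N(0, I) prior, and Z = 0 is an
absorbing fixed point of both losses. In practice this caused
progressive death of latent dimensions and unstable domain recovery
(ARI 0.0–0.65); the linear output removes the pathology (ARI ≥ 0.9 at
default conditions) while leaving the rest of the architecture
unchanged. `final_activation = "relu"` is retained as an option.

## 6. Downstream (`pearlst.downstream`)

- **Domains**: K-means (k-means++, `n_init = 10`, seeded) on Z;
  `cluster_method = "louvain"` gives Leiden community detection.
- **pSM**: diffusion pseudotime (scanpy DPT, `dpt_neighbors = 15`,
  `dpt_comps = 10`) from a root spot chosen as the embedding with the
  largest summed Euclidean distance to all others (a user-supplied root
  overrides). Pseudotime is min-max scaled to [0, 1] with
  `psm[root] = 0`; disconnected k-NN graphs are handled per connected
  component.
- **Trajectories**: PAGA cluster graphs, serialized to JSON. When no
  k-NN edge crosses clusters the graph is returned edgeless (this also
  works around an upstream PAGA crash on empty coarse graphs).
- **Low-coverage mode**: for imaging-based platforms with small gene
  panels, each spot's profile is replaced by the mean of itself and its
  spatial neighbors and K-means runs directly on those profiles,
  skipping the PDE and autoencoder.

## 7. Communication networks (`pearlst.comm`)

For an LR pair (L, R) and receiver spot j the signaling score is the
mass-action, distance-decayed

```
score_j = R_j · Σ_{s ∈ senders} L_s · exp(−d_sj / length_scale)
```

with `length_scale` defaulting to the tissue's mean nearest-neighbor
distance (an exponential surrogate for a diffusion-limited ligand
field). Scores are linked to latent dimensions by random-forest
regression (`rf_trees = 500`) with seeded permutation importance, and
genes driving each dimension are found by perturbing one gene column at
a time with seeded Gaussian noise (sd = `perturb_noise_scale = 1.0` ×
gene sd, `perturb_repeats = 20`) and measuring the mean absolute
embedding change. The three relations assemble into a typed multilayer
network (top `gene_top_q = 50` target genes per dimension).

## 8. Synthetic-data generator (`pearlst.fixtures`)

`FixtureSpec` defaults: 300 spots, 200 genes, 3 domains, layered-strip
layout, `effect_size = 2.0` (log-fold marker shift), `noise_sd = 0.3`
log-normal noise, `dropout_rate = 0.2`, negative-binomial counts
(gamma–Poisson, dispersion 0.5). Each domain over-expresses its own 10%
marker block; `gradient=True` adds a shared 20% block scaling linearly
along the layer order (amplitude 2 × effect size), planting a monotone
pseudotime; `planted_lr` renames the last two genes to a ligand/receptor
pair boosted (+2 in log space) in a sender and a driven domain.
`make_image_features` plants per-domain Gaussian clouds at a chosen
centroid separation. All randomness flows from one seed through
`SeedSequence` spawning; fixtures are bit-reproducible.

`effect_size = 2.0` was calibrated once using a method-independent
oracle (PCA + K-means on log counts reaches ARI > 0.9); at 1.0 the
planted structure is not recoverable in principle (oracle ARI ≈ 0.44).
Generator parameters were never adjusted in response to pipeline test
outcomes.

**Scope**: the generator covers laminar/blob/grid geometries, NB
overdispersion, dropout, planted gradients, and one planted LR pair. It
does not model spatial autocorrelation of noise, batch effects, cell
type mixtures within spots, or segmentation errors.

## 9. Numerical choices

- Explicit (forward-Euler) PDE scheme; stability follows from
  `λ Σ c ≤ 0.4`.
- Circumradii via the exact determinant formula; degenerate triangles
  yield infinite radius.
- Reconstruction BCE in softplus form to avoid overflow at large
  logits.
- Gradient-penalty backpropagation freezes ReLU masks (the standard
  subgradient convention); correctness is finite-difference verified
  away from kinks.
- All tie-breaks (neighbor ranking, HVG ranking, root selection) are
  deterministic (lowest index / stable sorts), making every output
  bit-reproducible under a fixed seed.
- Training aborts with a clear error if any quantity becomes
  non-finite.

## 10. Limitations

- Training is full-batch dense NumPy: memory and time scale as
  O(N² d); practical up to a few thousand spots on one CPU.
- Domain-recovery ARI on the default fixture varies by seed
  (observed 0.72–0.92); the null control (effect size 0) typically
  yields |ARI| < 0.1 but has been observed at ≈ 0.13 on some seeds
  because spatial smoothing alone can create weakly spatially coherent
  clusters.
- The exponential ligand-field kernel and the perturbation-based gene
  importance are heuristics, not mechanistic models.
- The pSM root heuristic (most-distant embedding) may pick either end
  of a trajectory; supply `root` when the origin is known.
- Leiden clustering and PAGA delegate to scanpy/igraph; their internal
  parallelism is restricted to one thread only insofar as those
  libraries respect it.
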