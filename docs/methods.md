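# Methods

## Model

`spatialmix` clusters spatially resolved omics units with a
Gaussian-mixture variational autoencoder whose inference network is a
single-hop graph-attention layer over a directed exact KNN graph of units.
The generative side assumes a uniform prior over K components, a diagonal
Gaussian latent prior per component (means learnable, standard deviations
learnable through softplus with a 1e-4 floor), and a *unit-wise* diagonal
Gaussian output distribution: the decoder emits a mean and standard
deviation per unit and feature, so the likelihood applies to z-scored
continuous values and no count model (NB/ZINB) is assumed. The inference
side factorizes as q(y|x, neigh)·q(z|x, neigh, y): a softmax head yields
the soft assignment Ŷ and per-component heads yield Gaussian posterior
parameters (softplus + floor on σ).

Assumptions worth stating: domains are locally coherent (the spatial KNN
graph and JS term encode this), the number of clusters K is supplied by the
user (ground-truth domain counts are conventional for this task), and image
patches carry domain-discriminative texture/intensity when the image loss
is enabled.

## Objective

The minimized loss per batch is

    w_img · Σ L_image,i  −  ELBO  +  w_js · Σ JS_i,     w_img = w_js = 1

* **ELBO** — responsibility-weighted reconstruction
  Σ_ij Ŷ_ij log N(x_i; decoder(z_ij)), a closed-form Gaussian KL between
  each component posterior and its prior, and KL(Ŷ_i ‖ uniform). One
  reparameterized latent sample per unit, component and step.
* **Image loss** — for each unit, −log(Ŷ_i·Ŷ_j) summed over its k = 8
  nearest in-batch image neighbors by cosine distance (dot products of
  probability vectors: each term ≥ 0, zero iff both are one-hot on the same
  component). The log argument is clamped at 1e-8; zero-norm embedding rows
  are defined to be at cosine distance 1 from everything.
* **JS term** — mean base-2 Jensen–Shannon divergence between Ŷ_i and its
  spatial graph neighbors, bounded in [0, 1].

The marginal log-likelihood the objective nominally maximizes is
operationalized as the standard GMVAE ELBO; this is the package's own
interpretation of the looser "log-likelihood plus reconstruction"
description that motivates it.

## Optimization and initialization

Training uses Adam (lr 1e-3) over seeded shuffle-partitioned mini-batches;
every batch carries its targets' complete one-hop neighborhoods, which is
why the encoder is exactly one attention hop deep. Initialization is a
k-means warm start in three coupled parts: component prior means are set to
k-means centroids of the untrained encoder's responsibility-weighted
posterior mean; the posterior-mean head bias is set to those centroids (so
each component's posterior starts at its prior); and the assignment head is
initialized by a multinomial logistic fit of the k-means partition on the
untrained encoder output. The third part matters: with a free softmax head
started at random, the label-consistency terms (image + JS) are minimized
by the collapsed all-one-cluster labeling, and training reliably falls into
it. Starting inside a clustered basin removes the collapse without changing
the model.

Adam applies decoupled (AdamW-style) weight decay, default 1.0, to all
parameters except the mixture prior. The value is large compared to
deep-learning conventions because training runs only a few hundred steps;
the per-step shrinkage lr·wd = 1e-3 is what a long schedule at wd = 1e-2
would accumulate. The ridge pressure spreads discriminative weight across
correlated redundant markers instead of letting the head pick an arbitrary
subset of them, which stabilizes integrated-gradient rankings while leaving
clustering accuracy unchanged.

Fixed seeds make everything bitwise reproducible: model init, batch
shuffles, latent noise and k-means all derive from `random_state`.

## Attribution

Per-cluster spatially variable features are ranked by integrated gradients
of the cluster probability Ŷ(c), midpoint rule with 50 path steps, baseline
at the all-unit feature mean (≈ 0 after z-scoring), averaged over up to 250
units of the cluster (seeded subsample). The unit's neighborhood is frozen
in full: neighbor features *and* the attention coefficients are constants
evaluated at the observed feature vector, so credit flows exclusively
through the unit's own features. Letting the path bend the attention
weights re-injects neighborhood noise into the attribution and scrambles
marker rankings; freezing them makes the pre-softmax map affine in the
unit's features and the ranking stable. Top-50 lists are exported; ties
break toward the lower feature index.

## Preprocessing

Standard chain, in order: optional feature-name prefix exclusion (e.g.
control probes), affine alignment of coordinates to pixel space (3×3
homogeneous matrix; units mapping outside the raster are dropped,
raster cell = (floor(y), floor(x))), removal of zero-count units then
zero-count features, dispersion-based (Seurat-flavor) selection of the top
3000 highly variable features (panels at or below the cap pass through),
library-size normalization to the median total, log1p, and per-feature
z-score with constant features set to 0 rather than NaN. HVG selection
delegates to scanpy; the rest is implemented directly against the stated
contracts.

## Image features

Patches default to 250×250 px centered at (floor(y)−size//2 …) with zero
(or reflect) border fill; single-channel images broadcast to three
channels. Embeddings are computed once before training and cached. The
built-in extractor is deterministic: 8-bin channel intensity histograms
plus a magnitude-weighted 8-bin gradient-orientation histogram (d = 32),
requiring no pretrained weights. A CNN extractor slot (ResNet18 backbone
with the classification layer removed, d = 512) is registered but requires
the optional torch/torchvision dependencies and a checkpoint; all tests run
on the histogram extractor.

## Synthetic data

The generator emulates the structure of spatial omics bundles: units on a
near-square grid (or uniform layout), k contiguous domains from a Voronoi
partition around seeded centers, Poisson counts with base rate 1 and
domain markers elevated by +8 (3 markers per domain by default), and a
raster image at 4 px per unit in which each pixel takes the domain of its
nearest unit, domains get distinct base tones (0.15–0.85) with a binary
texture grain on alternating domains, blended toward a uniform tone as
`image_signal` → 0, plus Gaussian pixel noise (sd 0.02). Poisson counts
(rather than Gaussian) exercise the full normalization chain.
`degrade_expression` replaces a seeded fraction of units' rows with draws
from the global mean count — the knob for the image-ablation experiment.

What it does not emulate: realistic histology texture, segmentation error,
platform-specific noise (dropout, diffusion), batch effects, or irregular
domain shapes beyond Voronoi geometry. Passing tests therefore demonstrate
correctness of the machinery and recoverability under clean conditions, not
performance on real tissue.

## Experiment sizes

The bundled experiments run at desk scale, chosen to exercise the full
pipeline in minutes on one CPU: domain/marker recovery on n = 2000, K = 4,
m = 60 fixtures with 150 training epochs across 5 seeds; the image-loss
ablation on n = 1000 fixtures (expression degraded for half the units,
fully informative image) with 60 epochs, image-on vs image-off over 5
paired seeds; toy images use 16 px patches to match their 4 px/unit
resolution. The estimator's own defaults (epochs = 300, patch 250 px) are
aimed at real datasets.

## Numerical choices and degenerate inputs

* All computation in float64 on a minimal reverse-mode autodiff engine;
  gradients are validated against central finite differences in the suite.
* σ floors (1e-4) on posterior, output and prior scales prevent collapse to
  zero variance; logs of probabilities are clamped (1e-8 image loss, 1e-12
  elsewhere).
* KNN and cosine neighbor ties break toward the lower unit index; argmax
  label ties toward the lower cluster index; KNN is exact (brute force with
  lexicographic ordering), not approximate.
* ARI of two identical trivial partitions is 1.0 by convention; silhouette
  raises on a single cluster and scores singleton clusters 0. Metric
  computation delegates to scikit-learn behind these contracts.
* Batches smaller than k_image + 1 shrink the image-neighbor count to the
  batch size minus one (the final partition remainder can be small).
* Silhouette can be evaluated on the preprocessed expression matrix or on
  the latent embedding; both are exposed.

## Known limitations

Single-process CPU training only; one attention hop by construction of the
batch closure; K must be supplied; directed (non-symmetrized) KNN graph;
the ELBO stand-in for the marginal likelihood is an interpretation, not a
reproduction of any reference implementation; vendor-specific loaders and
image-registration refinement are out of scope.
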