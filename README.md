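# spatialmix

Image-aware clustering of spatially resolved transcriptomics (SRT) and
proteomics (SRP) data.

Spatial omics platforms (CosMx, Stereo-seq, Xenium, CODEX, ...) measure a
units × features matrix **X** (gene counts or protein abundances), 2-D
coordinates per unit (spot or cell), and often a whole-tissue morphology
image. The clustering task is to partition units into spatial domains —
contiguous tissue regions with shared molecular profiles. Most methods use
the image, if at all, to "enhance" the expression matrix; `spatialmix`
instead links image similarity **directly to the predicted cluster labels**,
the way a pathologist can call a region from morphology alone.

## Model

The clusterer is a Gaussian-mixture variational autoencoder (GMVAE) with a
single-hop graph-attention (GAT) encoder over a K-nearest-neighbor graph of
units (spatial or feature metric). For unit *i* and component
*j* ∈ {1..K}:

```
p(y_i = j)        = 1/K                                  (uniform prior)
p(z_i | y_i = j)  = N(μ_j^prior, diag σ_j^prior²)
p(x_i | z_i)      = N(μ_i^x, diag σ_i^x²)                (unit-wise Gaussian)

q(y_i = j | x_i, {x}_neigh)        = Ŷ_i(j)              (softmax head)
q(z_i | x_i, {x}_neigh, y_i = j)   = N(μ_ij^post, diag σ_ij^post²)
```

Training maximizes, over mini-batches with full one-hop neighbor closure,

```
Σ_i ( −L_image,i + log p(x_i) − JS_i )
```

where `log p(x_i)` is bounded by the standard responsibility-weighted ELBO,
`JS_i` is the mean base-2 Jensen–Shannon divergence between Ŷ_i and its
spatial neighbors' soft labels, and the image loss

```
L_image,i = Σ_{j ∈ image-neighbors(i)} −log( Ŷ_i · Ŷ_j )
```

pulls each unit toward the soft labels of its k = 8 most cosine-similar
image-patch embeddings within the batch. Patches (250 px default) are
embedded once before training by a pluggable extractor; a deterministic
histogram extractor is built in, and a pretrained-CNN extractor (ResNet18
backbone) can be registered. Per-cluster spatially variable features are
ranked by integrated gradients of the cluster probability Ŷ(c) with the
unit's neighborhood held fixed. Evaluation metrics (ARI, Fowlkes–Mallows,
silhouette) ship in `spatialmix.metrics`.

## Worked example

```python
import spatialmix as sm

# synthetic tissue: 4 contiguous domains, 60 features with 3 planted
# markers per domain, and a toy image whose tone encodes domain identity
ds = sm.generate(sm.SyntheticSpec(n_units=2000, k_domains=4,
                                  m_features=60, seed=0))
dsp = sm.preprocess(ds)          # filter -> HVG -> normalize -> z-score

est = sm.SpatialGMVAE(n_clusters=4, epochs=150, batch_size=512,
                      patch_size=16, random_state=0)
est.fit(dsp)

print("ARI vs planted domains:",
      round(sm.adjusted_rand_index(ds.labels, est.labels_), 3))

rank = sm.rank_svgs(est.result_, dsp, est, seed=0)
print("top-3 features for cluster 0:",
      [str(rank.feature_names[f]) for f in rank.top_features[0][:3]])
```

Output:

```
ARI vs planted domains: 1.0
top-3 features for cluster 0: ['feature_1', 'feature_0', 'feature_2']
```

ARI 1.0 means the fitted domains reproduce the planted ground truth
exactly (up to label naming); the top-3 integrated-gradient features for
cluster 0 are exactly the three markers planted for the domain it
recovered (features 0–2).

The same pipeline is scriptable from a shell:

```bash
spatialmix synth --n-units 2000 --k-domains 4 --out fixture.h5ad --image-out fixture.tif
spatialmix fit --input fixture.h5ad --image fixture.tif --k-clusters 4 \
    --patch-size 16 --epochs 150 --seed 0 --out result.h5ad
spatialmix evaluate --truth truth.tsv --pred result.h5ad
```

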