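"""Preprocessing chain for spatial omics matrices.

The standard chain, in order: drop excluded feature-name prefixes, drop
units falling outside the image after affine alignment, filter empty
units then empty features, select highly variable features, library-size
normalize to the median total, log1p, and z-score each feature.
"""

from __future__ import annotations

import numpy as np

from .data import AffineTransform, SpatialDataset


def exclude_feature_prefixes(ds: SpatialDataset, prefixes: list[str]) -> SpatialDataset:
    """Drop features whose name starts with any listed prefix (e.g. control
    probes named ``NegPrb*`` on some in-situ platforms)."""
    if not prefixes:
        return ds
    keep = ~np.array(
        [any(str(n).startswith(p) for p in prefixes) for n in ds.feature_names]
    )
    if not keep.any():
        raise ValueError("prefix exclusion removed every feature")
    return ds.subset_features(keep)


def filter_units_and_features(ds: SpatialDataset, min_counts: int = 1) -> SpatialDataset:
    """Remove units with total count < ``min_counts``, then features likewise.

    Unit filtering happens first, so a feature whose only counts sat in
    removed units is itself removed.
    """
    unit_keep = ds.X.sum(axis=1) >= min_counts
    if not unit_keep.any():
        raise ValueError("no units survive filtering")
    ds = ds.subset_units(unit_keep)
    feat_keep = ds.X.sum(axis=0) >= min_counts
    if not feat_keep.any():
        raise ValueError("no features survive filtering")
    return ds.subset_features(feat_keep)


def select_hvg(ds: SpatialDataset, n_top: int = 3000) -> SpatialDataset:
    """Keep the ``n_top`` most highly variable features.

    Dispersion-based (Seurat-flavor) selection on log-normalized data;
    datasets with at most ``n_top`` features (e.g. a 47-plex protein
    panel) pass through unchanged.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if ds.n_features <= n_top:
        return ds
    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(X=ds.X.astype(np.float64).copy())
    sc.pp.normalize_total(adata)
    sc.pp.log1p(adata)
    sc.pp.highly_variable_genes(adata, n_top_genes=n_top, flavor="seurat")
    keep = np.asarray(adata.var["highly_variable"].to_numpy())
    if keep.sum() != n_top:
        # tiny panels can tie/NaN out of the flag; rank on normalized then
        # raw dispersion
        dn = np.nan_to_num(adata.var["dispersions_norm"].to_numpy(), nan=-np.inf)
        dr = np.nan_to_num(adata.var["dispersions"].to_numpy(), nan=-np.inf)
        order = np.lexsort((np.arange(ds.n_features), -dr, -dn))
        keep = np.zeros(ds.n_features, dtype=bool)
        keep[order[:n_top]] = True
    return ds.subset_features(keep)


def normalize_log_scale(ds: SpatialDataset) -> SpatialDataset:
    """Median library-size normalization, log1p, then per-feature z-score.

    Per-unit totals are rescaled to the median pre-normalization total;
    constant features are assigned z-score 0 rather than NaN.
    """
    X = ds.X.astype(np.float64).copy()
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("units with zero total count; filter first")
    target = np.median(totals)
    X = X * (target / totals)[:, None]
    X = np.log1p(X)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Xz = np.zeros_like(X)
    nonconst = sd > 0
    Xz[:, nonconst] = (X[:, nonconst] - mu[nonconst]) / sd[nonconst]
    out = ds.subset_features(np.arange(ds.n_features))
    out.X = Xz
    return out


def apply_affine(coords: np.ndarray, transform: AffineTransform) -> np.ndarray:
    """Map n x 2 coordinates through a homogeneous affine transform."""
    coords = np.asarray(coords, dtype=np.float64)
    hom = np.column_stack([coords, np.ones(len(coords))])
    mapped = hom @ transform.matrix.T
    return mapped[:, :2]


def remove_units_outside_image(
    ds: SpatialDataset, transform: AffineTransform | None = None
) -> SpatialDataset:
    """Align coordinates to pixel space and drop units outside the raster.

    A unit at continuous pixel position (x, y) maps to raster cell
    (row=floor(y), col=floor(x)); units whose cell is off the raster are
    removed. No-op when the dataset carries no image.
    """
    if ds.image is None:
        if transform is not None:
            out = ds.subset_units(np.arange(ds.n_units))
            out.coords = apply_affine(ds.coords, transform)
            return out
        return ds
    coords = ds.coords if transform is None else apply_affine(ds.coords, transform)
    h, w = ds.image.shape[:2]
    rows = np.floor(coords[:, 1])
    cols = np.floor(coords[:, 0])
    keep = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    if not keep.any():
        raise ValueError("no units fall inside the image after alignment")
    out = ds.subset_units(keep)
    out.coords = coords[keep]
    return out


def preprocess(
    ds: SpatialDataset,
    n_top: int = 3000,
    min_counts: int = 1,
    exclude_prefixes: list[str] | None = None,
    transform: AffineTransform | None = None,
) -> SpatialDataset:
    """Run the full chain; see module docstring for the order."""
    ds = exclude_feature_prefixes(ds, exclude_prefixes or [])
    ds = remove_units_outside_image(ds, transform)
    ds = filter_units_and_features(ds, min_counts=min_counts)
    ds = select_hvg(ds, n_top=n_top)
    return normalize_log_scale(ds)
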