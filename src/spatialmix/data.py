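"""Containers and readers for spatial omics datasets.

A dataset bundles a units x features matrix (gene expression counts or
protein abundances), per-unit 2-D spatial coordinates, an optional
whole-tissue morphology image, and optional ground-truth labels.
Matrices are accepted as AnnData (.h5ad), Matrix Market triplets with
side index files, or delimited text; images as TIFF or PNG-like rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


@dataclass
class SpatialDataset:
    """Units x features matrix with coordinates, image and labels.

    Attributes
    ----------
    X : ndarray of shape (n_units, n_features)
        Non-negative counts before normalization, real-valued after.
    coords : ndarray of shape (n_units, 2)
        Spatial positions, (x, y) in continuous units (pixels once aligned).
    image : ndarray of shape (H, W) or (H, W, C), optional
        Morphology raster; C in {1, 3}.
    labels : ndarray of shape (n_units,), optional
        Ground-truth categorical labels for evaluation.
    unit_ids, feature_names : identifier arrays aligned to rows / columns.
    """

    X: np.ndarray
    coords: np.ndarray
    image: np.ndarray | None = None
    labels: np.ndarray | None = None
    unit_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    feature_names: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[0] < 1 or self.X.shape[1] < 1:
            raise ValueError("X must be a non-empty 2-D matrix")
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (self.n_units, 2):
            raise ValueError(
                f"coordinate rows ({self.coords.shape[0]}) != units ({self.n_units})"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.n_units:
                raise ValueError(
                    f"label rows ({self.labels.shape[0]}) != units ({self.n_units})"
                )
        if self.unit_ids is None:
            self.unit_ids = np.array([f"unit_{i}" for i in range(self.n_units)])
        else:
            self.unit_ids = np.asarray(self.unit_ids)
        if self.feature_names is None:
            self.feature_names = np.array(
                [f"feature_{j}" for j in range(self.n_features)]
            )
        else:
            self.feature_names = np.asarray(self.feature_names)

    @property
    def n_units(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset_units(self, mask_or_idx) -> "SpatialDataset":
        idx = np.asarray(mask_or_idx)
        return replace(
            self,
            X=self.X[idx],
            coords=self.coords[idx],
            labels=None if self.labels is None else self.labels[idx],
            unit_ids=self.unit_ids[idx],
        )

    def subset_features(self, mask_or_idx) -> "SpatialDataset":
        idx = np.asarray(mask_or_idx)
        return replace(self, X=self.X[:, idx], feature_names=self.feature_names[idx])


@dataclass(frozen=True)
class AffineTransform:
    """Homogeneous 3x3 affine transform mapping coordinates to pixel space."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError("affine matrix must be 3x3")
        if not np.allclose(m[2], [0.0, 0.0, 1.0]):
            raise ValueError("affine bottom row must be (0, 0, 1)")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("affine matrix is singular")
        object.__setattr__(self, "matrix", m)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3))

    @classmethod
    def from_file(cls, path) -> "AffineTransform":
        return cls(np.loadtxt(path))


# ---------------------------------------------------------------------------
# readers


def _read_table(path: Path) -> pd.DataFrame:
    """Delimited text with header/index auto-detection (numeric heuristics)."""
    sep = "," if path.suffix.lower() == ".csv" else None
    first = pd.read_csv(path, sep=sep, header=None, nrows=1, engine="python")
    has_header = not pd.api.types.is_numeric_dtype(first.iloc[0].infer_objects())
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None, engine="python")
    if df.shape[1] > 1 and df.iloc[:, 0].dtype == object:
        df = df.set_index(df.columns[0])
    return df


def _read_matrix(path: Path) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Return (X dense, unit_ids, feature_names) from a supported container."""
    suffix = path.suffix.lower()
    if suffix == ".h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
        return X, adata.obs_names.to_numpy(), adata.var_names.to_numpy()
    if suffix == ".mtx":
        X = scipy.io.mmread(path).toarray()
        unit_ids = feature_names = None
        rows = path.with_name(path.stem + "_rows.txt")
        cols = path.with_name(path.stem + "_cols.txt")
        if rows.exists():
            unit_ids = np.loadtxt(rows, dtype=str, ndmin=1)
        if cols.exists():
            feature_names = np.loadtxt(cols, dtype=str, ndmin=1)
        return X, unit_ids, feature_names
    df = _read_table(path)
    unit_ids = df.index.to_numpy(dtype=str) if df.index.dtype == object else None
    names = df.columns.to_numpy(dtype=str) if df.columns.dtype == object else None
    return df.to_numpy(dtype=np.float64), unit_ids, names


def read_image(path) -> np.ndarray:
    """Load a TIFF/PNG raster as (H, W) or (H, W, C) ndarray."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not readable: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            return np.asarray(tifffile.imread(path))
        import imageio.v3 as iio

        return np.asarray(iio.imread(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with the path attached
        raise IOError(f"could not read image {path}: {exc}") from exc


def load_dataset(
    matrix_path,
    coords_path,
    image_path=None,
    labels_path=None,
) -> SpatialDataset:
    """Assemble a :class:`SpatialDataset` from on-disk components.

    Raises a :class:`ValueError` naming both counts when the coordinate
    file does not have one row per matrix unit.
    """
    matrix_path = Path(matrix_path)
    X, unit_ids, feature_names = _read_matrix(matrix_path)

    coords_df = _read_table(Path(coords_path))
    coords = coords_df.to_numpy(dtype=np.float64)
    if coords.shape[1] > 2:
        coords = coords[:, :2]
    if coords.shape[0] != X.shape[0]:
        raise ValueError(
            f"coordinate rows ({coords.shape[0]}) != units ({X.shape[0]})"
        )

    labels = None
    if labels_path is not None:
        labels_df = _read_table(Path(labels_path))
        labels = labels_df.to_numpy().ravel()
        if labels.shape[0] != X.shape[0]:
            raise ValueError(
                f"label rows ({labels.shape[0]}) != units ({X.shape[0]})"
            )

    image = read_image(image_path) if image_path is not None else None
    return SpatialDataset(
        X=X,
        coords=coords,
        image=image,
        labels=labels,
        unit_ids=unit_ids,
        feature_names=feature_names,
    )


def to_anndata(ds: SpatialDataset, result=None):
    """Export a dataset (and optionally a fitted result) as AnnData.

    Cluster labels go to ``obs['domain']``, soft assignments to
    ``obsm['soft_assignment']`` and latent embeddings to
    ``obsm['X_embedding']``.
    """
    import anndata as ad

    adata = ad.AnnData(
        X=ds.X.astype(np.float32),
        obs=pd.DataFrame(index=pd.Index(ds.unit_ids.astype(str), name="unit")),
        var=pd.DataFrame(index=pd.Index(ds.feature_names.astype(str), name="feature")),
    )
    adata.obsm["spatial"] = ds.coords
    if ds.labels is not None:
        adata.obs["ground_truth"] = pd.Categorical(ds.labels.astype(str))
    if result is not None:
        adata.obs["domain"] = pd.Categorical(result.labels.astype(str))
        adata.obsm["soft_assignment"] = result.soft
        adata.obsm["X_embedding"] = result.embeddings
    return adata


def save_dataset(ds: SpatialDataset, matrix_path, image_path=None) -> None:
    """Write a dataset as .h5ad (+ TIFF image if present)."""
    adata = to_anndata(ds)
    adata.write_h5ad(Path(matrix_path))
    if image_path is not None and ds.image is not None:
        import tifffile

        tifffile.imwrite(Path(image_path), ds.image)
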