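"""Morphology-image patches, pluggable embedding extractors, cosine neighbors.

Each unit gets a fixed-size patch cropped around its pixel position,
embedded by a registered feature extractor into a fixed-length vector.
During training, the k most cosine-similar embeddings *within the same
mini-batch* define a unit's image neighbors, which the image loss pulls
toward shared soft cluster labels.

Extractors are pluggable. The built-in ``histogram`` extractor (channel
intensity histograms + gradient-orientation histogram) is fully
deterministic and needs no downloaded weights; a pretrained-CNN
extractor (ResNet18 backbone with its classification layer removed,
d=512) can be registered by the user when a deep-learning runtime and
checkpoint are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data import SpatialDataset


@dataclass(frozen=True)
class PatchSpec:
    """Patch geometry: ``size`` pixels square (default 250), padded at the
    image border with zeros or by reflection."""

    size: int = 250
    pad_mode: str = "zero"

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("patch size must be >= 1")
        if self.pad_mode not in ("zero", "reflect"):
            raise ValueError(f"unknown pad_mode: {self.pad_mode!r}")


@dataclass(frozen=True)
class ImageEmbeddingTable:
    E: np.ndarray  # (n, d)
    extractor_id: str

    @property
    def d(self) -> int:
        return self.E.shape[1]


def _as_three_channel(image: np.ndarray) -> np.ndarray:
    if image.ndim == 2:
        return np.broadcast_to(image[..., None], image.shape + (3,))
    if image.ndim == 3 and image.shape[2] == 1:
        return np.broadcast_to(image, image.shape[:2] + (3,))
    if image.ndim == 3 and image.shape[2] == 3:
        return image
    raise ValueError(f"image must be HxW or HxWxC with C in {{1,3}}, got {image.shape}")


def crop_patch(image: np.ndarray, center: tuple[float, float], spec: PatchSpec) -> np.ndarray:
    """Crop a ``size x size x 3`` patch around pixel position ``center``.

    ``center`` is (x, y) in continuous pixel coordinates; the patch spans
    rows ``floor(y) - size//2 .. floor(y) - size//2 + size - 1`` and the
    analogous columns. Regions outside the image are filled per
    ``spec.pad_mode``; single-channel images are broadcast to 3 channels.
    """
    img = _as_three_channel(np.asarray(image))
    h, w = img.shape[:2]
    x, y = center
    row0, col0 = int(np.floor(y)), int(np.floor(x))
    if not (0 <= row0 < h and 0 <= col0 < w):
        raise ValueError(
            f"patch center ({x}, {y}) outside image of shape {(h, w)}"
        )
    half = spec.size // 2
    r_lo, r_hi = row0 - half, row0 - half + spec.size
    c_lo, c_hi = col0 - half, col0 - half + spec.size

    out = np.zeros((spec.size, spec.size, 3), dtype=np.float64)
    rs, re = max(r_lo, 0), min(r_hi, h)
    cs, ce = max(c_lo, 0), min(c_hi, w)
    out[rs - r_lo : re - r_lo, cs - c_lo : ce - c_lo] = img[rs:re, cs:ce]
    if spec.pad_mode == "reflect" and (r_lo < 0 or c_lo < 0 or r_hi > h or c_hi > w):
        padded = np.pad(
            np.asarray(img, dtype=np.float64),
            (
                (max(-r_lo, 0), max(r_hi - h, 0)),
                (max(-c_lo, 0), max(c_hi - w, 0)),
                (0, 0),
            ),
            mode="reflect",
        )
        out = padded[
            r_lo + max(-r_lo, 0) : r_lo + max(-r_lo, 0) + spec.size,
            c_lo + max(-c_lo, 0) : c_lo + max(-c_lo, 0) + spec.size,
        ].astype(np.float64)
    return out


class FeatureExtractor:
    """Deterministic map from a size x size x 3 patch to a length-d vector."""

    id: str = "base"
    d: int = 0

    def __call__(self, patch: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class HistogramExtractor(FeatureExtractor):
    """Channel-wise intensity histograms plus a gradient-orientation histogram.

    Intensities are rescaled by the dtype maximum for integer rasters (or
    used as-is for floats, assumed in [0, 1]) and binned into ``n_bins``
    per channel; gradients of the grayscale patch (Sobel) contribute a
    magnitude-weighted orientation histogram. All histograms are
    L1-normalized, giving d = 4 * n_bins by default.
    """

    def __init__(self, n_bins: int = 8):
        self.n_bins = n_bins
        self.id = f"histogram{n_bins}"
        self.d = 4 * n_bins

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        patch = np.asarray(patch)
        if patch.ndim != 3 or patch.shape[2] != 3:
            raise ValueError(f"expected a HxWx3 patch, got shape {patch.shape}")
        if np.issubdtype(patch.dtype, np.integer):
            scale = float(np.iinfo(patch.dtype).max)
        else:
            scale = 1.0
        vals = np.clip(patch.astype(np.float64) / scale, 0.0, 1.0)
        edges = np.linspace(0.0, 1.0, self.n_bins + 1)
        parts = []
        for c in range(3):
            h, _ = np.histogram(vals[:, :, c], bins=edges)
            parts.append(h / max(h.sum(), 1))
        gray = vals.mean(axis=2)
        gy = ndimage.sobel(gray, axis=0, mode="nearest")
        gx = ndimage.sobel(gray, axis=1, mode="nearest")
        mag = np.hypot(gx, gy)
        theta = np.arctan2(gy, gx)  # [-pi, pi]
        hog, _ = np.histogram(
            theta, bins=np.linspace(-np.pi, np.pi, self.n_bins + 1), weights=mag
        )
        total = hog.sum()
        parts.append(hog / total if total > 0 else np.zeros(self.n_bins))
        return np.concatenate(parts)


def _cnn_extractor_factory():
    raise ImportError(
        "the 'cnn' extractor (ResNet18 backbone, final classification layer "
        "removed) requires the optional dependencies torch and torchvision "
        "plus a pretrained checkpoint; install them and register the "
        "extractor, or use the built-in 'histogram' extractor"
    )


EXTRACTORS: dict[str, object] = {
    "histogram": HistogramExtractor,
    "cnn": _cnn_extractor_factory,
}


def get_extractor(name: str, **kwargs) -> FeatureExtractor:
    if name not in EXTRACTORS:
        raise ValueError(f"unknown extractor {name!r}; registered: {sorted(EXTRACTORS)}")
    return EXTRACTORS[name](**kwargs)


def embed_patches(patches, extractor: FeatureExtractor) -> ImageEmbeddingTable:
    """Apply an extractor to a sequence of patches, row per patch."""
    rows = [np.asarray(extractor(p), dtype=np.float64) for p in patches]
    E = np.vstack(rows) if rows else np.zeros((0, extractor.d))
    if np.isnan(E).all(axis=1).any():
        raise ValueError("extractor produced an all-NaN embedding row")
    return ImageEmbeddingTable(E=E, extractor_id=extractor.id)


def embed_units(
    ds: SpatialDataset,
    extractor: FeatureExtractor,
    spec: PatchSpec | None = None,
) -> ImageEmbeddingTable:
    """Crop one patch per unit at its pixel position and embed all of them.

    Embeddings are computed once up front and cached by the caller; the
    training loop never touches raw pixels again.
    """
    if ds.image is None:
        raise ValueError("dataset has no image")
    spec = spec or PatchSpec()
    patches = (crop_patch(ds.image, (x, y), spec) for x, y in ds.coords)
    return embed_patches(patches, extractor)


def image_neighbors(E_batch: np.ndarray, k: int = 8) -> np.ndarray:
    """Indices of the k nearest rows by cosine distance, self excluded.

    Cosine distance is 1 - cosine similarity; zero-norm rows are defined
    to be at distance 1 from everything. Ties break toward lower index.
    """
    E = np.asarray(E_batch, dtype=np.float64)
    b = len(E)
    if b <= k:
        raise ValueError(f"need more rows than neighbors: batch={b}, k={k}")
    norms = np.linalg.norm(E, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    U = E / safe[:, None]
    U[norms == 0] = 0.0
    dist = 1.0 - U @ U.T
    np.fill_diagonal(dist, np.inf)
    order = np.lexsort((np.arange(b)[None, :].repeat(b, 0), dist), axis=1)
    return order[:, :k]
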