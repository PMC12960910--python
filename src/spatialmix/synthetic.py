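"""Seeded synthetic spatial omics fixtures with matched toy images.

The generator emulates the structure of real spatial transcriptomics /
proteomics bundles at desk scale: spatially contiguous domains (Voronoi
regions around seeded centers), Poisson counts with domain-specific
marker elevation, and a raster image whose per-domain base intensity and
texture correlate with domain identity in proportion to
``image_signal``. All randomness derives from the spec's seed, so the
same spec reproduces the same dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import SpatialDataset


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a generated fixture.

    n_units : number of units; placed on a near-square grid when
        ``layout='grid'`` (default) or uniformly at random.
    k_domains : number of contiguous spatial domains (>= 2).
    m_features : total feature count; the first
        ``k_domains * markers_per_domain`` are planted markers.
    marker_shift : added Poisson mean for a domain's own markers
        (expression effect size).
    base_rate : Poisson mean of background expression.
    noise_sd : sd of Gaussian noise added to counts (clipped at 0).
    image_signal : in [0, 1]; 1 means domain identity fully determines
        local image intensity, 0 blends all domains to a uniform tone.
    patch_noise_sd : sd of per-pixel Gaussian image noise.
    pixels_per_unit : image resolution scale (image spans the layout).
    """

    n_units: int = 2000
    k_domains: int = 4
    m_features: int = 60
    markers_per_domain: int = 3
    marker_shift: float = 8.0
    base_rate: float = 1.0
    noise_sd: float = 0.0
    image_signal: float = 1.0
    patch_noise_sd: float = 0.02
    layout: str = "grid"
    pixels_per_unit: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.k_domains < 2:
            raise ValueError("k_domains must be >= 2")
        if self.markers_per_domain * self.k_domains > self.m_features:
            raise ValueError("not enough features for the planted markers")
        if not 0.0 <= self.image_signal <= 1.0:
            raise ValueError("image_signal must lie in [0, 1]")
        if self.layout not in ("grid", "random"):
            raise ValueError(f"unknown layout: {self.layout!r}")


def marker_features(spec: SyntheticSpec) -> list[np.ndarray]:
    """Planted marker feature indices per domain."""
    p = spec.markers_per_domain
    return [np.arange(c * p, (c + 1) * p) for c in range(spec.k_domains)]


def _voronoi_domains(coords: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def generate(spec: SyntheticSpec) -> SpatialDataset:
    """Generate a dataset with ground-truth labels and a synthetic image.

    Domain layout is a Voronoi partition around k seeded centers, so
    domains are spatially contiguous. Unit i in domain c draws feature f
    from Poisson(base_rate + marker_shift * [f is a marker of c]); the
    image assigns each domain region a distinct base intensity plus a
    binary texture grain, blended toward a uniform tone as image_signal
    falls to 0, with Gaussian pixel noise on top.
    """
    rng = np.random.default_rng(spec.seed)
    n, K, m = spec.n_units, spec.k_domains, spec.m_features

    # layout on [0, side) x [0, side)
    side = float(np.ceil(np.sqrt(n)))
    if spec.layout == "grid":
        g = int(np.ceil(np.sqrt(n)))
        xs, ys = np.meshgrid(np.arange(g), np.arange(g))
        coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(np.float64)[:n]
        coords += 0.5
    else:
        coords = rng.uniform(0.0, side, size=(n, 2))

    centers = rng.uniform(0.0, side, size=(K, 2))
    labels = _voronoi_domains(coords, centers)
    # re-seed any empty domain at an unclaimed unit so every domain exists
    for c in range(K):
        while not np.any(labels == c):
            centers[c] = coords[rng.integers(n)] + rng.normal(0, 1e-3, 2)
            labels = _voronoi_domains(coords, centers)

    rates = np.full((n, m), spec.base_rate, dtype=np.float64)
    for c, feats in enumerate(marker_features(spec)):
        rows = labels == c
        rates[np.ix_(rows, feats)] += spec.marker_shift
    X = rng.poisson(rates).astype(np.float64)
    if spec.noise_sd > 0:
        X = np.clip(X + rng.normal(0.0, spec.noise_sd, size=X.shape), 0.0, None)

    # image: domain regions rendered at pixels_per_unit resolution; each
    # pixel takes the domain of its nearest unit, so the pixel under a unit
    # always carries that unit's domain tone
    H = W = int(side * spec.pixels_per_unit)
    px, py = np.meshgrid(np.arange(W) + 0.5, np.arange(H) + 0.5)
    pix_coords = np.column_stack([px.ravel(), py.ravel()]) / spec.pixels_per_unit
    pix_dom = np.empty(len(pix_coords), dtype=np.intp)
    for lo in range(0, len(pix_coords), 4096):
        chunk = pix_coords[lo : lo + 4096]
        d2 = ((chunk[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        pix_dom[lo : lo + 4096] = labels[np.argmin(d2, axis=1)]
    pix_dom = pix_dom.reshape(H, W)
    base_tone = np.linspace(0.15, 0.85, K)  # distinct intensity per domain
    img = base_tone[pix_dom]
    # domain-specific texture: odd domains carry a checker grain
    checker = ((px.astype(int) // 2 + py.astype(int) // 2) % 2).astype(np.float64)
    grain = 0.08 * checker * (pix_dom % 2)
    img = img + grain
    uniform_tone = float(base_tone.mean())
    img = spec.image_signal * img + (1.0 - spec.image_signal) * uniform_tone
    if spec.patch_noise_sd > 0:
        img = img + rng.normal(0.0, spec.patch_noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    return SpatialDataset(
        X=X,
        coords=coords * spec.pixels_per_unit,  # pixel space, (x, y)
        image=img,
        labels=labels,
    )


def degrade_expression(ds: SpatialDataset, fraction: float, seed: int) -> SpatialDataset:
    """Replace a random fraction of units' expression rows with draws from
    the global (domain-free) count distribution.

    Weakens the expression signal while leaving coordinates, labels and
    the image untouched — the image-ablation experiment's knob.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    out = ds.subset_units(np.arange(ds.n_units))
    if fraction == 0.0:
        return out
    rng = np.random.default_rng(seed)
    n, m = ds.X.shape
    n_swap = int(round(fraction * n))
    rows = rng.choice(n, size=n_swap, replace=False)
    global_rate = float(ds.X.mean())
    out.X = ds.X.copy()
    out.X[rows] = rng.poisson(global_rate, size=(n_swap, m)).astype(np.float64)
    return out
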