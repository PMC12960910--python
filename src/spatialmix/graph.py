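"""KNN graphs over units and mini-batches with one-hop neighbor closure.

The graph is directed: row i of ``neighbor_index`` lists the k nearest
units to i (self excluded) under Euclidean distance in either spatial or
feature space. Ties are broken by lower unit index so graphs are fully
reproducible. Mini-batches partition the units into target sets; each
batch also carries every target's neighbors so a single graph-attention
hop sees complete neighborhoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SpatialDataset


@dataclass(frozen=True)
class NeighborGraph:
    neighbor_index: np.ndarray  # (n, k) int
    metric: str  # "spatial_euclidean" | "feature_euclidean"

    @property
    def n_units(self) -> int:
        return self.neighbor_index.shape[0]

    @property
    def k(self) -> int:
        return self.neighbor_index.shape[1]

    def to_edge_list(self) -> np.ndarray:
        """(source, target, rank) rows; edges point neighbor -> unit."""
        n, k = self.neighbor_index.shape
        tgt = np.repeat(np.arange(n), k)
        src = self.neighbor_index.ravel()
        rank = np.tile(np.arange(k), n)
        return np.column_stack([src, tgt, rank])

    def save_edge_list(self, path) -> None:
        np.savetxt(
            path,
            self.to_edge_list(),
            fmt="%d",
            delimiter="\t",
            header="source\ttarget\trank",
            comments="",
        )


@dataclass(frozen=True)
class MiniBatch:
    """Targets plus the closure of their neighbors, re-indexed locally.

    ``local_neighbors[t]`` gives, for the t-th target, the positions of
    its k graph neighbors inside ``member_ids``; targets occupy the first
    ``len(target_ids)`` member positions.
    """

    target_ids: np.ndarray  # (b,) global unit indices
    member_ids: np.ndarray  # (M,) global indices; targets first
    local_X: np.ndarray  # (M, m)
    local_neighbors: np.ndarray  # (b, k) positions into member_ids

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    def local_edges(self) -> np.ndarray:
        """(source, target) pairs in local positions, self-loops excluded."""
        b, k = self.local_neighbors.shape
        tgt = np.repeat(np.arange(b), k)
        return np.column_stack([self.local_neighbors.ravel(), tgt])


def _exact_knn(points: np.ndarray, k: int, chunk: int = 512) -> np.ndarray:
    """Exact KNN with (distance, index) lexicographic tie-breaking."""
    n = len(points)
    out = np.empty((n, k), dtype=np.intp)
    sq = np.einsum("ij,ij->i", points, points)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d2 = sq[lo:hi, None] + sq[None, :] - 2.0 * points[lo:hi] @ points.T
        np.maximum(d2, 0.0, out=d2)
        rows = np.arange(lo, hi)
        d2[np.arange(hi - lo), rows] = np.inf  # exclude self
        # lexsort: primary key distance, secondary key index
        order = np.lexsort((np.arange(n)[None, :].repeat(hi - lo, 0), d2), axis=1)
        out[lo:hi] = order[:, :k]
    return out


def build_knn_graph(ds: SpatialDataset, k: int = 8, mode: str = "spatial") -> NeighborGraph:
    """Exact k-nearest-neighbor graph in spatial or feature space.

    Parameters
    ----------
    k : number of neighbors per unit; must satisfy 1 <= k < n_units.
    mode : "spatial" uses coordinates, "feature" the (preprocessed) matrix.
    """
    if mode not in ("spatial", "feature"):
        raise ValueError(f"unknown KNN mode: {mode!r}")
    n = ds.n_units
    if k < 1 or k >= n:
        raise ValueError(f"k must satisfy 1 <= k < n_units, got k={k}, n={n}")
    points = ds.coords if mode == "spatial" else ds.X
    idx = _exact_knn(np.ascontiguousarray(points, dtype=np.float64), k)
    return NeighborGraph(
        neighbor_index=idx,
        metric="spatial_euclidean" if mode == "spatial" else "feature_euclidean",
    )


def make_batches(
    g: NeighborGraph,
    X: np.ndarray,
    batch_size: int,
    seed: int,
) -> list[MiniBatch]:
    """Seeded shuffle-partition of units into target sets with closure.

    Target sets partition all units; every target's full neighbor list is
    included as batch members (neighbors may repeat across batches).
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    n = g.n_units
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    batches = []
    for lo in range(0, n, batch_size):
        targets = np.sort(order[lo : lo + batch_size])
        nbrs = g.neighbor_index[targets]
        extra = np.setdiff1d(nbrs.ravel(), targets)
        members = np.concatenate([targets, extra])
        pos = {int(u): p for p, u in enumerate(members)}
        local_nbrs = np.vectorize(pos.__getitem__, otypes=[np.intp])(nbrs)
        batches.append(
            MiniBatch(
                target_ids=targets,
                member_ids=members,
                local_X=X[members],
                local_neighbors=local_nbrs,
            )
        )
    return batches
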