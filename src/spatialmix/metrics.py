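"""External and internal clustering quality metrics.

ARI is computed from the truth/prediction contingency table
(c_ij = |a_i ∩ b_j|):

    ARI = [Σ C(c_ij,2) − Σ C(a_i,2) Σ C(b_j,2) / C(n,2)]
          / { [Σ C(a_i,2) + Σ C(b_j,2)]/2 − Σ C(a_i,2) Σ C(b_j,2) / C(n,2) }

ranging from −1 to 1; FMI = Σ C(c_ij,2) / sqrt(Σ C(a_i,2) Σ C(b_j,2)).
Computation delegates to scikit-learn; this module adds the contracts
(length checks, degenerate-case conventions, error messages).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray  # (t, p) int

    @classmethod
    def from_labels(cls, truth, pred) -> "ContingencyTable":
        truth = np.asarray(truth)
        pred = np.asarray(pred)
        _, ti = np.unique(truth, return_inverse=True)
        _, pi = np.unique(pred, return_inverse=True)
        counts = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
        np.add.at(counts, (ti, pi), 1)
        return cls(counts)

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def _check_lengths(truth, pred) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth).ravel()
    pred = np.asarray(pred).ravel()
    if len(truth) != len(pred):
        raise ValueError(
            f"label length mismatch: truth has {len(truth)}, prediction has {len(pred)}"
        )
    return truth, pred


def adjusted_rand_index(truth, pred) -> float:
    """Chance-adjusted pair-counting agreement in [-1, 1].

    When both partitions are identically trivial (one cluster each, or
    all singletons each) the score is 1.0 by convention, following the
    dominant ecosystem behavior.
    """
    truth, pred = _check_lengths(truth, pred)
    if len(truth) < 2:
        raise ValueError("ARI needs at least 2 units")
    return float(_skm.adjusted_rand_score(truth, pred))


def fowlkes_mallows(truth, pred) -> float:
    """Geometric mean of pairwise precision and recall, in [0, 1]; defined
    as 0 when either pair count is 0."""
    truth, pred = _check_lengths(truth, pred)
    if len(truth) < 2:
        raise ValueError("FMI needs at least 2 units")
    return float(_skm.fowlkes_mallows_score(truth, pred))


def silhouette(X_or_emb, labels) -> float:
    """Mean silhouette (b − a)/max(a, b) under Euclidean distance.

    ``X_or_emb`` may be the preprocessed expression matrix or the latent
    embedding; singleton clusters contribute 0. Raises when fewer than
    two clusters are present ("silhouette undefined").
    """
    X = np.asarray(X_or_emb, dtype=np.float64)
    labels = np.asarray(labels).ravel()
    if len(X) != len(labels):
        raise ValueError(
            f"label length mismatch: matrix has {len(X)}, labels have {len(labels)}"
        )
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    if len(X) < 3:
        raise ValueError("silhouette needs at least 3 units")
    return float(_skm.silhouette_score(X, labels, metric="euclidean"))


def evaluate_clustering(truth, pred, X_or_emb=None) -> dict[str, float]:
    """ARI and FMI, plus silhouette when a feature/embedding matrix is given."""
    out = {
        "ari": adjusted_rand_index(truth, pred),
        "fmi": fowlkes_mallows(truth, pred),
    }
    if X_or_emb is not None:
        out["silhouette"] = silhouette(X_or_emb, pred)
    return out
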