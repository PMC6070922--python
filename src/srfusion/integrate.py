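"""Weighted fusion of per-view similarity matrices and spectral clustering.

The K scaled possibility matrices are combined by a convex combination
W = sum_k w_k PM'_k with user weights on the probability simplex; the fused
W is treated as a graph affinity and patients are partitioned by spectral
clustering on its normalized Laplacian.  Because the best view weighting is
unknown a priori, the simplex is searched on a regular lattice and each
weighting is scored by the survival log-rank p-value of its clusters (plus
a silhouette coherence score).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .omics_io import SurvivalTable
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class SubtypeLabels:
    """Cluster assignment of each sample; labels are 1..m, every cluster non-empty."""

    samples: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.samples):
            raise ValueError("labels length must match samples")
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
            raise ValueError("labels must be consecutive integers 1..m with no empty cluster")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.samples, "cluster": self.labels})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "SubtypeLabels":
        df = pd.read_csv(path, sep="\t")
        return cls([str(s) for s in df["sample_id"]], df["cluster"].to_numpy())


def fuse(matrices: list[SimilarityMatrix], weights) -> SimilarityMatrix:
    """Convex combination of aligned similarity matrices.

    Weights must be non-negative and sum to 1 (within 1e-9); every fused
    entry therefore lies between the per-view min and max of that entry.
    """
    w = np.asarray(weights, dtype=float)
    if len(w) != len(matrices):
        raise ValueError(f"{len(matrices)} matrices but {len(w)} weights")
    if (w < 0).any():
        raise ValueError("negative weight")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {w.sum():.12f})")
    samples = matrices[0].samples
    for m in matrices[1:]:
        if m.samples != samples:
            raise ValueError("matrices are not aligned on the same sample order")
    W = np.einsum("k,kij->ij", w, np.stack([m.values for m in matrices]))
    fused = SimilarityMatrix(list(samples), W, "fused")
    fused.weights = w  # provenance
    return fused


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..m by decreasing size; ties by smallest member index."""
    uniq = np.unique(raw)
    order = sorted(uniq, key=lambda c: (-int((raw == c).sum()), int(np.argmax(raw == c))))
    remap = {c: new + 1 for new, c in enumerate(order)}
    return np.array([remap[c] for c in raw], dtype=int)


def spectral_embedding(W: np.ndarray, m: int) -> np.ndarray:
    """Row-normalized embedding from the m bottom eigenvectors of L = I - D^{-1/2} W D^{-1/2}."""
    d = W.sum(axis=1)
    if (d <= 0).any():
        raise ValueError(f"zero or negative row sum at sample index {int(np.argmax(d <= 0))}")
    inv_sqrt = 1.0 / np.sqrt(d)
    L = np.eye(len(W)) - inv_sqrt[:, None] * W * inv_sqrt[None, :]
    L = (L + L.T) / 2.0
    _, vecs = eigh(L, subset_by_index=(0, m - 1))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return vecs / norms


def spectral_cluster(W: SimilarityMatrix, m: int, seed: int = 0, n_restarts: int = 20) -> SubtypeLabels:
    """Spectral clustering of the fused affinity into m subtype clusters.

    The normalized-cut relaxation: embed samples with the m eigenvectors of
    the smallest eigenvalues of the normalized Laplacian (the diagonal is
    kept in the degree, as the affinity defines it), row-normalize to unit
    length, then k-means with ``n_restarts`` seeded restarts keeping the
    lowest within-cluster sum of squares.  Labels are canonicalized
    (size-descending, ties by smallest member id) so runs are comparable;
    all statistical comparisons should still use permutation-invariant
    scores such as the ARI.
    """
    vals = W.values
    n = len(vals)
    if m < 2 or m > n:
        raise ValueError(f"need 2 <= m <= n (m={m}, n={n})")
    if (vals < 0).any():
        raise ValueError("affinity entries must be non-negative")
    emb = spectral_embedding(vals, m)
    km = KMeans(n_clusters=m, n_init=n_restarts, random_state=seed % (2**31))
    raw = km.fit_predict(emb)
    if len(np.unique(raw)) < m:
        raise RuntimeError("k-means produced an empty cluster on a degenerate embedding")
    return SubtypeLabels(list(W.samples), _canonical_labels(raw))


def weight_lattice(K: int, step: float) -> np.ndarray:
    """All weight vectors on the simplex lattice {w_k = a_k * step, sum w = 1}.

    Includes the vertices and edge points (zero components are legal).  For
    s = 1/step steps the count is C(s + K - 1, K - 1).
    """
    s = round(1.0 / step)
    if abs(s - 1.0 / step) > 1e-9:
        raise ValueError(f"step {step} does not divide 1")
    grid = []
    for combo in itertools.combinations_with_replacement(range(K), s):
        counts = np.bincount(np.array(combo), minlength=K)
        grid.append(counts * step)
    grid = np.array(sorted(map(tuple, grid), reverse=True))
    return grid


def weight_grid(
    matrices: list[SimilarityMatrix],
    survival: SurvivalTable,
    m: int,
    step: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every lattice weighting by survival separation of its clusters.

    For each weight vector: fuse, cluster into m groups, then compute the
    multi-group log-rank p-value and the mean silhouette on the fused
    similarity.  Rows are sorted by ascending p; ties broken by higher
    silhouette, then lexicographically by the weights.  Samples lacking
    survival rows are dropped from the log-rank with a warning.
    """
    from .evaluation import logrank_test, silhouette_from_similarity

    K = len(matrices)
    grid = weight_lattice(K, step)
    records = []
    for w in grid:
        fused = fuse(matrices, w)
        labels = spectral_cluster(fused, m, seed=seed)
        lr = logrank_test(survival, labels)
        sil, _ = silhouette_from_similarity(fused, labels)
        records.append((*w, lr.p, sil))
    cols = [f"w{k + 1}" for k in range(K)] + ["logrank_p", "silhouette"]
    df = pd.DataFrame(records, columns=cols)
    df["neg_log10_p"] = -np.log10(df["logrank_p"].clip(lower=np.finfo(float).tiny))
    df = df.sort_values(
        by=["logrank_p", "silhouette"] + cols[:K],
        ascending=[True, False] + [True] * K,
        kind="mergesort",
    ).reset_index(drop=True)
    return df
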