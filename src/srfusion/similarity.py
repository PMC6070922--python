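"""Per-view patient similarity: Pearson correlation and its Fisher z-map.

The similarity between two patients within one omics view is the Pearson
correlation of their feature vectors.  Because correlations live on the
bounded interval [-1, 1], they are mapped to the real line with the Fisher
z-transformation r = arctanh(M) = 0.5*ln((1+M)/(1-M)) before any regression
is performed on them; the inverse map is tanh.

A :class:`SimilarityMatrix` carries the n x n values plus a ``stage`` tag
recording where in the pipeline it was produced (correlation -> fisher ->
possibility -> scaled -> fused).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .omics_io import OmicsView

logger = logging.getLogger(__name__)

STAGES = ("correlation", "fisher", "corrected", "possibility", "scaled", "fused")

#: Default clip distance from +/-1 before the Fisher map; duplicate samples
#: produce correlations of exactly 1 which must not become infinities.
FISHER_EPS = 1e-7


@dataclass
class SimilarityMatrix:
    samples: list[str]
    values: np.ndarray
    stage: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError(f"expected ({n}, {n}) matrix, got {self.values.shape}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)

    def write(self, path) -> None:
        """Serialize as TSV with a `# stage:` provenance comment line."""
        with open(path, "w") as fh:
            fh.write(f"# stage: {self.stage}\n")
            self.to_frame().to_csv(fh, sep="\t", float_format="%.17g")

    @classmethod
    def read(cls, path) -> "SimilarityMatrix":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# stage:"):
                raise ValueError(f"{path}: missing '# stage:' header line")
            stage = first.split(":", 1)[1].strip()
            df = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
        return cls(samples=[str(s) for s in df.index], values=df.to_numpy(), stage=stage)


def pearson_similarity(view: OmicsView) -> SimilarityMatrix:
    """Pearson correlation matrix between all sample pairs of one view.

    All features are used jointly (views are complete by contract).  The
    diagonal is exactly 1.  A sample whose feature vector is constant has an
    undefined correlation with every other sample; such pairs are set to 0
    with a warning rather than propagating NaN.
    """
    if view.n_features < 2:
        raise ValueError(
            f"view {view.name!r}: need >= 2 features for a meaningful correlation"
        )
    X = view.values
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms == 0
    safe = np.where(constant, 1.0, norms)
    C = (centered @ centered.T) / np.outer(safe, safe)
    if constant.any():
        ids = [s for s, c in zip(view.samples, constant) if c]
        warnings.warn(
            f"view {view.name!r}: constant sample vector(s) {ids}; their pairwise "
            "correlations are defined as 0",
            stacklevel=2,
        )
        C[constant, :] = 0.0
        C[:, constant] = 0.0
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return SimilarityMatrix(samples=list(view.samples), values=C, stage="correlation")


def fisher_transform(M: SimilarityMatrix, eps: float = FISHER_EPS) -> SimilarityMatrix:
    """Fisher z-transformation of a correlation matrix.

    Entries are first clipped to [-1+eps, 1-eps] so that exact +/-1
    correlations (duplicate samples, the diagonal) stay finite, then mapped
    through arctanh.  Strictly increasing and odd; tanh inverts it up to the
    clipping.
    """
    if M.stage != "correlation":
        raise ValueError(f"expected a correlation-stage matrix, got {M.stage!r}")
    if eps <= 0:
        raise ValueError("eps must be positive")
    clipped = np.clip(M.values, -1.0 + eps, 1.0 - eps)
    Z = np.arctanh(clipped)
    return SimilarityMatrix(samples=list(M.samples), values=Z, stage="fisher")
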