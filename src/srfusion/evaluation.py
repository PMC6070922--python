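"""Cluster validation: survival log-rank, Kaplan-Meier, silhouette, ARI, DE screen.

These are the standard checks applied to a candidate patient partition:
does it separate survival curves (multi-group log-rank), is it coherent as
a clustering (mean silhouette on similarity-derived distances, with >= 0.15
taken as the coherence rule), does it agree with an external clinical
labeling (adjusted Rand index), and which features differ across clusters
(Kruskal-Wallis with Benjamini-Hochberg FDR control).

The log-rank test here is the G-sample score test; fitting a Cox model
with a group factor gives the asymptotically identical statistic, so no
proportional-hazards model is ever fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import kruskal
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .integrate import SubtypeLabels
from .omics_io import OmicsView, SurvivalTable
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

#: Mean silhouette at or above this value counts as a coherent clustering.
COHERENCE_THRESHOLD = 0.15


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p: float


@dataclass
class ContingencyTable:
    """Cross-tabulation of two partitions (e.g. found clusters vs clinical subtypes)."""

    row_labels: list
    col_labels: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if (self.counts.sum(axis=1) > 0).sum() < 2 or (self.counts.sum(axis=0) > 0).sum() < 2:
            raise ValueError("need >= 2 rows and >= 2 columns with positive marginals")

    @classmethod
    def read(cls, path) -> "ContingencyTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy())


def logrank_test(survival: SurvivalTable, labels: SubtypeLabels) -> LogrankResult:
    """Multi-group log-rank test of survival separation between clusters.

    Standard observed-minus-expected chi-square over pooled event times with
    the hypergeometric variance and pooled ties; df = groups - 1.  Samples
    without survival rows are dropped with a warning.
    """
    surv_idx = {s: i for i, s in enumerate(survival.sample_id)}
    kept = [(s, g) for s, g in zip(labels.samples, labels.labels) if s in surv_idx]
    n_drop = len(labels.samples) - len(kept)
    if n_drop:
        logger.warning("logrank: %d clustered sample(s) lack survival data", n_drop)
    if not kept:
        raise ValueError("no clustered sample has survival data")
    rows = [surv_idx[s] for s, _ in kept]
    groups = np.array([g for _, g in kept])
    if len(np.unique(groups)) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    time = survival.time[rows]
    event = survival.event[rows]
    if event.sum() == 0:
        raise ValueError("no events observed in any group")
    res = multivariate_logrank_test(time, groups, event)
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=len(np.unique(groups)) - 1,
        p=float(res.p_value),
    )


def km_curve(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve for one group of subjects.

    Returns a step function as a frame with columns ``time`` and
    ``survival``; censored subjects shrink the risk set without a step.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def similarity_to_distance(W: np.ndarray) -> np.ndarray:
    """Convert a similarity matrix to a dissimilarity for silhouette scoring.

    d_ij = max_{a != b} W_ab - W_ij clipped at 0, with a zero diagonal; this
    preserves ordering and needs no assumption on the similarity's scale.
    """
    off = ~np.eye(len(W), dtype=bool)
    D = np.clip(W[off].max() - W, 0.0, None)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def silhouette_from_similarity(
    W: SimilarityMatrix, labels: SubtypeLabels
) -> tuple[float, bool]:
    """Mean silhouette of a partition on similarity-derived distances.

    Returns (score, coherent) where ``coherent`` applies the >= 0.15 rule.
    """
    if labels.n_clusters < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    if W.samples != labels.samples:
        raise ValueError("similarity and labels are not aligned")
    D = similarity_to_distance(W.values)
    if np.allclose(D, 0.0):
        return 0.0, False  # all similarities equal: a(i) = b(i) for every sample
    score = float(silhouette_score(D, labels.labels, metric="precomputed"))
    return score, score >= COHERENCE_THRESHOLD


def ari_from_contingency(table: ContingencyTable | np.ndarray) -> float:
    """Adjusted Rand index from a contingency table by pair counting.

    ARI = (sum_ij C(n_ij,2) - E) / ((a + b)/2 - E) with
    a = sum_i C(n_i.,2), b = sum_j C(n_.j,2), E = a*b / C(n,2).
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    counts = counts.astype(float)
    n = counts.sum()
    if n < 2:
        raise ValueError("contingency table must cover >= 2 samples")

    def _choose2(x):
        return (x * (x - 1) / 2.0).sum()

    sum_ij = _choose2(counts)
    a = _choose2(counts.sum(axis=1))
    b = _choose2(counts.sum(axis=0))
    expected = a * b / (n * (n - 1) / 2.0)
    max_index = (a + b) / 2.0
    if max_index == expected:  # both partitions trivial; agreement is vacuous
        return 0.0
    return float((sum_ij - expected) / (max_index - expected))


def adjusted_rand_index(labels_a: pd.Series | dict, labels_b: pd.Series | dict) -> float:
    """ARI between two labelings keyed by sample id.

    Samples labeled in only one input are dropped (clinical references often
    cover a subset of the cohort); errors if no sample is shared.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared labeled samples")
    if len(shared) < len(a) or len(shared) < len(b):
        logger.info("ARI computed on %d shared labeled samples", len(shared))
    ct = pd.crosstab(a.loc[shared], b.loc[shared])
    return ari_from_contingency(ct.to_numpy())


def labels_to_series(labels: SubtypeLabels) -> pd.Series:
    return pd.Series(labels.labels, index=labels.samples)


def kruskal_wallis_de(
    view: OmicsView,
    labels: SubtypeLabels,
    fdr_threshold: float = 1.0e-5,
) -> pd.DataFrame:
    """Per-feature Kruskal-Wallis screen for differential features across clusters.

    Tie-corrected H per feature; p-values adjusted over all tested features
    by Benjamini-Hochberg; ``significant`` flags q < ``fdr_threshold``.  A
    feature identical in all samples gets H = 0, p = 1.
    """
    if view.samples != labels.samples:
        raise ValueError("view and labels are not aligned")
    groups = [np.flatnonzero(labels.labels == c) for c in range(1, labels.n_clusters + 1)]
    if len(groups) < 2:
        raise ValueError("need >= 2 clusters")
    small = [i + 1 for i, g in enumerate(groups) if len(g) < 2]
    if small:
        raise ValueError(f"cluster(s) {small} have < 2 members")
    H = np.zeros(view.n_features)
    p = np.ones(view.n_features)
    for f in range(view.n_features):
        col = view.values[:, f]
        if np.ptp(col) == 0:
            continue  # all tied: H = 0, p = 1 by convention
        H[f], p[f] = kruskal(*(col[g] for g in groups))
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "feature": view.features,
            "H": H,
            "p": p,
            "q": q,
            "significant": q < fdr_threshold,
        }
    )
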