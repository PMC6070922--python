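"""Model/results interface over the similarity-regression-fusion pipeline.

:class:`SRF` is constructed from aligned omics views (plus optional
survival and clinical labels) and a :class:`~srfusion.omics_io.RunConfig`;
``fit`` runs the full chain — per-view Pearson similarity, Fisher
transform, per-pair regression correction, logistic possibility, scaled
transform, weighted fusion, spectral clustering — and returns an
:class:`SRFResults` carrying every stage, the subtype labels, and the
survival/coherence diagnostics, with a ``summary()`` table.

Typical use::

    views, truth, survival = simulate(SimSpec(seed=7))
    model = SRF(views, survival=survival, config=RunConfig(n_clusters=3))
    res = model.fit(weights=[1/3, 1/3, 1/3])
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluation, integrate, omics_io, regression, similarity
from .integrate import SubtypeLabels
from .omics_io import OmicsView, RunConfig, SurvivalTable
from .similarity import SimilarityMatrix


class SRF:
    """Similarity regression fusion of K omics views over one patient cohort.

    Parameters
    ----------
    views : sequence of OmicsView
        K >= 2 omics layers; aligned to their shared samples on construction.
    survival : SurvivalTable, optional
        Needed for log-rank diagnostics and weight selection.
    clinical_labels : pandas.Series, optional
        External categorical labels (by sample id) for ARI comparison; may
        cover a subset of the cohort.
    config : RunConfig
        Cluster number, mu, t, scale/regression modes, seed.
    """

    def __init__(
        self,
        views: Sequence[OmicsView],
        config: RunConfig,
        survival: SurvivalTable | None = None,
        clinical_labels: pd.Series | None = None,
    ):
        if len(views) < 2:
            raise ValueError("need >= 2 omics views")
        self.views = omics_io.align_views(list(views))
        self.samples = self.views[0].samples
        self.config = config
        self.survival = survival
        self.clinical_labels = clinical_labels
        self._scaled: list[SimilarityMatrix] | None = None
        self._fit_details: dict | None = None

    @classmethod
    def from_files(
        cls,
        view_paths: dict[str, str],
        config: RunConfig,
        survival_path: str | None = None,
        labels_path: str | None = None,
        orientation: str = "features_by_samples",
    ) -> "SRF":
        views = [
            omics_io.load_omics_view(path, name, orientation)
            for name, path in view_paths.items()
        ]
        survival = omics_io.load_survival(survival_path) if survival_path else None
        labels = omics_io.load_labels(labels_path) if labels_path else None
        return cls(views, config, survival=survival, clinical_labels=labels)

    # -- stages ------------------------------------------------------------
    def correlation_matrices(self) -> list[SimilarityMatrix]:
        return [similarity.pearson_similarity(v) for v in self.views]

    def fisher_matrices(self) -> list[SimilarityMatrix]:
        return [
            similarity.fisher_transform(M, self.config.fisher_eps)
            for M in self.correlation_matrices()
        ]

    def scaled_matrices(self, refit: bool = False) -> list[SimilarityMatrix]:
        """The K regression-corrected, scaled possibility matrices (cached).

        This is the expensive stage — O(K n^2) least-squares fits — and does
        not depend on the fusion weights, so weight searches reuse it.
        """
        if self._scaled is None or refit:
            self._scaled, self._fit_details = regression.corrected_possibility_matrices(
                self.fisher_matrices(), self.config, return_intermediate=True
            )
        return self._scaled

    # -- fitting -----------------------------------------------------------
    def fit(self, weights=None) -> "SRFResults":
        """Run the full pipeline with the given (or configured) view weights."""
        if weights is None:
            weights = self.config.weights
        if weights is None:
            K = len(self.views)
            weights = np.full(K, 1.0 / K)
        scaled = self.scaled_matrices()
        fused = integrate.fuse(scaled, weights)
        labels = integrate.spectral_cluster(
            fused, self.config.n_clusters, seed=self.config.random_seed
        )
        return SRFResults(model=self, weights=np.asarray(weights, float),
                          scaled=scaled, fused=fused, labels=labels)

    def select_weights(self, step: float | None = None) -> pd.DataFrame:
        """Grid-search the weight simplex, ranking by survival log-rank p."""
        if self.survival is None:
            raise ValueError("weight selection needs a survival table")
        return integrate.weight_grid(
            self.scaled_matrices(),
            self.survival,
            self.config.n_clusters,
            step=step if step is not None else self.config.grid_step,
            seed=self.config.random_seed,
        )


@dataclass
class SRFResults:
    """Fitted pipeline state: fused similarity, subtype labels, diagnostics."""

    model: SRF
    weights: np.ndarray
    scaled: list[SimilarityMatrix]
    fused: SimilarityMatrix
    labels: SubtypeLabels
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def logrank(self) -> evaluation.LogrankResult:
        if "logrank" not in self._cache:
            if self.model.survival is None:
                raise ValueError("no survival table attached to the model")
            self._cache["logrank"] = evaluation.logrank_test(self.model.survival, self.labels)
        return self._cache["logrank"]

    @property
    def silhouette(self) -> float:
        return self._silhouette[0]

    @property
    def coherent(self) -> bool:
        return self._silhouette[1]

    @property
    def _silhouette(self) -> tuple[float, bool]:
        if "sil" not in self._cache:
            self._cache["sil"] = evaluation.silhouette_from_similarity(self.fused, self.labels)
        return self._cache["sil"]

    @property
    def ari_clinical(self) -> float:
        if self.model.clinical_labels is None:
            raise ValueError("no clinical labels attached to the model")
        return evaluation.adjusted_rand_index(
            evaluation.labels_to_series(self.labels), self.model.clinical_labels
        )

    def ari_against(self, truth: SubtypeLabels) -> float:
        return evaluation.adjusted_rand_index(
            evaluation.labels_to_series(self.labels), evaluation.labels_to_series(truth)
        )

    def km_curves(self) -> dict[int, pd.DataFrame]:
        """Kaplan-Meier curve per cluster, on the samples with survival data."""
        surv = self.model.survival
        if surv is None:
            raise ValueError("no survival table attached to the model")
        curves = {}
        idx = {s: i for i, s in enumerate(surv.sample_id)}
        for c in range(1, self.labels.n_clusters + 1):
            members = [s for s, l in zip(self.labels.samples, self.labels.labels)
                       if l == c and s in idx]
            rows = [idx[s] for s in members]
            if rows:
                curves[c] = evaluation.km_curve(surv.time[rows], surv.event[rows])
        return curves

    def differential_features(self, view_name: str, fdr_threshold: float = 1e-5) -> pd.DataFrame:
        view = next(v for v in self.model.views if v.name == view_name)
        return evaluation.kruskal_wallis_de(view, self.labels, fdr_threshold)

    def cluster_sizes(self) -> pd.Series:
        return pd.Series(self.labels.labels).value_counts().sort_index()

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Similarity Regression Fusion results",
            "=" * 44,
            f"samples: {len(self.labels.samples)}    views: {len(self.scaled)}"
            f"    clusters: {cfg.n_clusters}",
            f"mu: {cfg.mu}    t: {cfg.t_scale}    scale: {cfg.scale_mode}"
            f"    regression: {cfg.regression_mode}",
            "view weights: " + ", ".join(
                f"{v.name}={w:.3f}" for v, w in zip(self.model.views, self.weights)
            ),
            "cluster sizes: " + ", ".join(
                f"C{c}={s}" for c, s in self.cluster_sizes().items()
            ),
        ]
        sil, coh = self._silhouette
        lines.append(f"mean silhouette: {sil:.3f} ({'coherent' if coh else 'not coherent'}"
                     f" at the 0.15 rule)")
        if self.model.survival is not None:
            lr = self.logrank
            lines.append(
                f"log-rank: chi2 = {lr.statistic:.3f} (df={lr.df}), p = {lr.p:.3g}"
            )
        if self.model.clinical_labels is not None:
            lines.append(f"ARI vs clinical labels: {self.ari_clinical:.3f}")
        return "\n".join(lines)
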