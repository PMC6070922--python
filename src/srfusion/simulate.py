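"""Synthetic multi-view omics cohorts with planted subtypes and linked survival.

The generator emulates the statistical structure the fusion method relies
on: patients of the same subtype share feature-mean shifts in every view
(so their Pearson similarity is elevated in each omics layer), and subtype
membership modulates the survival hazard.  Each view plants a
cluster-specific Gaussian mean shift on a fraction of its features and
fills the rest with pure noise; survival times are exponential with
per-cluster hazards under independent exponential censoring.  Everything
is a pure function of the spec and its seed.

Deliberately not emulated: real marginal distributions of omics assays
(methylation-beta bimodality, count overdispersion), feature-feature
correlation, batch structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .integrate import SubtypeLabels
from .omics_io import OmicsView, SurvivalTable
from .similarity import SimilarityMatrix


@dataclass
class ViewSpec:
    """Per-view generator settings.

    signal_strength is the cluster mean-shift amplitude on signal features,
    in units of the feature scale; noise_sd is the i.i.d. Gaussian noise sd.
    """

    n_features: int = 200
    signal_strength: float = 3.0
    signal_fraction: float = 0.5
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SimSpec:
    """Full specification of one synthetic multi-omics cohort.

    Default hazards span a 4-fold range across the three subtypes (roughly
    the survival contrast seen between good- and poor-prognosis subtype
    clusters in glioblastoma cohorts, on a days scale); the default
    censoring rate yields ~25-30% censored subjects.
    """

    n_samples: int = 90
    n_clusters: int = 3
    cluster_proportions: tuple = None
    views: list[ViewSpec] = field(default_factory=lambda: [ViewSpec() for _ in range(3)])
    hazards: tuple = (0.004, 0.002, 0.001)  # per day, one per cluster
    censoring_rate: float = 0.0008
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_proportions is None:
            self.cluster_proportions = tuple([1.0 / self.n_clusters] * self.n_clusters)
        props = np.asarray(self.cluster_proportions, dtype=float)
        if len(props) != self.n_clusters or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("cluster_proportions must have n_clusters entries summing to 1")
        if len(self.hazards) != self.n_clusters:
            raise ValueError("need one hazard per cluster")
        if any(h <= 0 for h in self.hazards):
            raise ValueError("hazards must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be non-negative")


def _cluster_sizes(spec: SimSpec) -> np.ndarray:
    sizes = np.floor(np.asarray(spec.cluster_proportions) * spec.n_samples).astype(int)
    # distribute the remainder to the largest fractional parts
    frac = np.asarray(spec.cluster_proportions) * spec.n_samples - sizes
    for idx in np.argsort(-frac)[: spec.n_samples - sizes.sum()]:
        sizes[idx] += 1
    if (sizes == 0).any():
        raise ValueError("cluster proportions leave an empty cluster at this n")
    return sizes


def simulate(spec: SimSpec) -> tuple[list[OmicsView], SubtypeLabels, SurvivalTable]:
    """Generate (views, truth labels, survival) for one synthetic cohort."""
    rng = np.random.default_rng(spec.seed)
    sizes = _cluster_sizes(spec)
    truth = np.repeat(np.arange(1, spec.n_clusters + 1), sizes)
    samples = [f"S{i:04d}" for i in range(spec.n_samples)]

    views = []
    for v, vs in enumerate(spec.views):
        n_signal = int(round(vs.signal_fraction * vs.n_features))
        # cluster centroids on the signal features; zero elsewhere
        centroids = np.zeros((spec.n_clusters, vs.n_features))
        centroids[:, :n_signal] = rng.normal(
            0.0, vs.signal_strength, size=(spec.n_clusters, n_signal)
        )
        values = centroids[truth - 1] + rng.normal(
            0.0, vs.noise_sd, size=(spec.n_samples, vs.n_features)
        )
        views.append(
            OmicsView(
                name=f"view{v + 1}",
                samples=list(samples),
                features=[f"v{v + 1}_f{t:05d}" for t in range(vs.n_features)],
                values=values,
            )
        )

    scale = 1.0 / np.asarray(spec.hazards)[truth - 1]
    event_time = rng.exponential(scale)
    if spec.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / spec.censoring_rate, size=spec.n_samples)
    else:
        censor_time = np.full(spec.n_samples, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    return (
        views,
        SubtypeLabels(list(samples), truth),
        SurvivalTable(list(samples), time, event),
    )


def simulate_regression_fixture(
    n: int,
    K: int,
    beta0: float,
    betas,
    sigma: float,
    seed: int = 0,
    predictor_noise: float = 0.3,
) -> tuple[list[SimilarityMatrix], SimilarityMatrix]:
    """Fisher-scale similarity matrices with a planted linear cross-view law.

    A latent block-structured symmetric matrix L is drawn; predictor views
    2..K are L plus independent symmetric perturbations (sd
    ``predictor_noise``, keeping the per-pair designs well conditioned), and
    view 1 is the exact linear combination beta0 + sum_t beta_t * view_t
    plus symmetric N(0, sigma^2) noise.  Returns the K matrices (view 1
    first) and the noiseless target for view 1, for denoising comparisons.
    With sigma = 0 every pair regression of view 1 on the others recovers
    (beta0, betas) exactly.
    """
    if K < 2:
        raise ValueError("need K >= 2")
    betas = np.asarray(betas, dtype=float)
    if len(betas) != K - 1:
        raise ValueError("need K - 1 coefficients")
    rng = np.random.default_rng(seed)
    samples = [f"S{i:04d}" for i in range(n)]

    def _sym(draw):
        M = draw((n, n))
        M = (M + M.T) / 2.0
        np.fill_diagonal(M, np.arctanh(1 - 1e-7))
        return M

    # latent 3-block structure so rows of the pair designs vary
    groups = np.arange(n) % 3
    base = np.where(groups[:, None] == groups[None, :], 1.0, 0.2)
    latent = base + _sym(lambda s: rng.normal(0.0, 0.1, size=s))
    np.fill_diagonal(latent, np.arctanh(1 - 1e-7))

    predictors = []
    for _ in range(K - 1):
        pert = rng.normal(0.0, predictor_noise, size=(n, n))
        pert = (pert + pert.T) / 2.0
        np.fill_diagonal(pert, 0.0)
        predictors.append(latent + pert)

    target_clean = beta0 + sum(b * P for b, P in zip(betas, predictors))
    if sigma > 0:
        noise = rng.normal(0.0, sigma, size=(n, n))
        noise = (noise + noise.T) / 2.0
        np.fill_diagonal(noise, 0.0)
        target = target_clean + noise
    else:
        target = target_clean.copy()

    mats = [SimilarityMatrix(list(samples), target, "fisher")]
    mats += [SimilarityMatrix(list(samples), P, "fisher") for P in predictors]
    clean = SimilarityMatrix(list(samples), target_clean, "fisher")
    return mats, clean
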