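"""Per-pair regression correction of similarities across omics views.

The idea: two patients who belong to the same subtype should relate to the
rest of the cohort similarly in every omics layer.  For each patient pair
(i, j) and each target view k, the similarities between i (and j) and all
other patients in view k are regressed, by ordinary least squares, on the
corresponding similarities in the remaining views.  The fitted linear model
is then evaluated at the pair's own cross-view similarities to obtain a
*corrected* similarity r'_{k,ij} on the Fisher scale:

    r'_{k,ij} = beta0 + sum_{t != k} beta_t * r_{t,ij}

The corrected value is mapped to a same-subtype possibility through a
logistic with gain mu,

    p_{k,ij} = exp(mu * r') / (1 + exp(mu * r')),

and finally through a scaled exponential transform with shift t that
sharpens the contrast between high and low possibilities.

Two training layouts are supported.  ``separate`` fits one model per
(view, pair): the response holds the 2(n-2) similarities of i and j to all
other patients in view k, and each predictor column holds the matching
similarities in one other view.  ``pooled`` stacks those row blocks over
every target view and fits a single model per pair, with predictor columns
taken in a canonical rotation relative to the target view; it trades
view-specific coefficients for more training rows when cohorts are small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .omics_io import RunConfig
from .similarity import SimilarityMatrix


@dataclass
class PairRegressionModel:
    """OLS fit for one patient pair.

    ``betas`` are the coefficients of the predictor views in canonical
    order; ``sigma2`` is the residual variance, an estimate of the
    similarity bias of this pair in the target view.  ``view_index`` is
    None for pooled-mode models, which are shared across target views.
    """

    view_index: int | None
    pair: tuple[int, int]
    beta0: float
    betas: np.ndarray
    sigma2: float
    n_rows: int

    def predict(self, r_others: np.ndarray) -> float:
        return corrected_similarity(self, r_others)


def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All unordered pairs i < j and, per pair, the complement indices.

    Returns (I, J, comp) with comp of shape (P, n-2) listing, in ascending
    order, the samples t not in {i, j}.
    """
    I, J = np.triu_indices(n, k=1)
    P = len(I)
    mask = np.ones((P, n), dtype=bool)
    rows = np.arange(P)
    mask[rows, I] = False
    mask[rows, J] = False
    comp = np.nonzero(mask)[1].reshape(P, n - 2)
    return I, J, comp


def _response_blocks(r: np.ndarray, I: np.ndarray, J: np.ndarray, comp: np.ndarray) -> np.ndarray:
    """Per pair: [r_{i,t} for t ascending, then r_{j,t}] -> shape (P, 2(n-2))."""
    return np.concatenate([r[I[:, None], comp], r[J[:, None], comp]], axis=1)


def build_pair_training(
    fisher: list[np.ndarray] | list[SimilarityMatrix],
    k: int,
    i: int,
    j: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Training data for the model of pair (i, j) in target view k.

    Y holds the view-k similarities of i to every other sample t (ascending
    t), followed by those of j; X has one column per predictor view p != k
    in canonical (input) order, each column matching Y's row layout.
    Swapping i and j permutes rows (the i- and j-blocks swap) and leaves any
    OLS fit unchanged.
    """
    mats = [m.values if isinstance(m, SimilarityMatrix) else np.asarray(m) for m in fisher]
    K = len(mats)
    if K < 2:
        raise ValueError("need >= 2 views")
    if i == j:
        raise ValueError("i and j must differ")
    n = mats[0].shape[0]
    if n < 4:
        raise ValueError(f"need >= 4 samples to train a pair model (got {n})")
    others = np.array([t for t in range(n) if t not in (i, j)])
    y = np.concatenate([mats[k][i, others], mats[k][j, others]])
    X = np.column_stack(
        [np.concatenate([mats[p][i, others], mats[p][j, others]]) for p in range(K) if p != k]
    )
    return X, y


def fit_pair_model(
    X: np.ndarray,
    Y: np.ndarray,
    view_index: int | None = None,
    pair: tuple[int, int] = (-1, -1),
) -> PairRegressionModel:
    """Ordinary least squares with intercept; minimum-norm under rank deficiency.

    Collinear predictors (e.g. duplicated views) are not an error: the
    Moore-Penrose solution spreads weight evenly and leaves predictions
    well-defined.  sigma2 = RSS / max(1, rows - coefficients).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float).ravel()
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X rows must match Y length")
    if Y.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    D = np.column_stack([np.ones(len(Y)), X])
    coef, _, _, _ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ coef
    dof = max(1, len(Y) - D.shape[1])
    return PairRegressionModel(
        view_index=view_index,
        pair=pair,
        beta0=float(coef[0]),
        betas=coef[1:],
        sigma2=float(resid @ resid) / dof,
        n_rows=len(Y),
    )


def corrected_similarity(model: PairRegressionModel, r_others: np.ndarray) -> float:
    """Evaluate the fitted linear model at the pair's cross-view similarities."""
    r_others = np.asarray(r_others, dtype=float).ravel()
    if r_others.shape[0] != model.betas.shape[0]:
        raise ValueError(
            f"expected {model.betas.shape[0]} predictor similarities, got {r_others.shape[0]}"
        )
    return float(model.beta0 + model.betas @ r_others)


def possibility(r_prime, mu: float = 3.0):
    """Logistic same-subtype possibility of a corrected similarity.

    Overflow-safe for large |mu * r'|; returns values strictly inside (0, 1)
    up to floating-point resolution.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    return expit(mu * np.asarray(r_prime, dtype=float))


def scale_possibility(p, t: float = 1.0, mode: str = "increasing"):
    """Scaled exponential transform of a possibility.

    ``increasing`` (default): 1 / (1 + exp(t - p)), order-preserving in p.
    ``as_printed``: 1 / (1 + exp(p - t)), the literal mirrored form, which
    is decreasing in p; offered for exact reproduction only.  Both equal 0.5
    at p = t.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    p = np.asarray(p, dtype=float)
    if mode == "increasing":
        return expit(p - t)
    if mode == "as_printed":
        return expit(t - p)
    raise ValueError(f"unknown scale mode {mode!r}")


def _batched_min_norm_ols(D: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve P independent least-squares problems D[p] beta ~ Y[p].

    D: (P, R, c), Y: (P, R).  Returns (beta (P, c), sigma2 (P,)).  The
    normal equations are solved through the pseudo-inverse of the Gram
    matrix, which yields the minimum-norm solution when D is rank
    deficient (pinv(D'D) D' == pinv(D)).
    """
    G = np.einsum("prc,prd->pcd", D, D)
    b = np.einsum("prc,pr->pc", D, Y)
    beta = np.einsum("pcd,pd->pc", np.linalg.pinv(G, hermitian=True), b)
    resid = Y - np.einsum("prc,pc->pr", D, beta)
    dof = max(1, D.shape[1] - D.shape[2])
    sigma2 = np.einsum("pr,pr->p", resid, resid) / dof
    return beta, sigma2


def corrected_possibility_matrices(
    fisher: list[SimilarityMatrix],
    config: RunConfig,
    return_intermediate: bool = False,
):
    """Correct every view's similarity matrix through the full chain.

    For each view k and each unordered pair (i, j): build the per-pair
    training data, fit by least squares, predict the corrected similarity
    r', and map through the logistic (gain ``config.mu``) and the scaled
    transform (shift ``config.t_scale``, ``config.scale_mode``).  All pair
    regressions for one view are solved in one batched normal-equations
    pass, which keeps the O(K n^2) fits fast.

    The diagonal of each scaled matrix is the transform's value at
    possibility 1 (maximal self-similarity); self-pairs never enter any
    training set.

    Returns the K scaled matrices; with ``return_intermediate`` also a dict
    holding the ``corrected`` (Fisher-scale) and ``possibility`` stages and
    the per-view arrays of regression coefficients and residual variances.
    """
    if len(fisher) < 2:
        raise ValueError("need >= 2 views")
    for m in fisher:
        if m.stage != "fisher":
            raise ValueError(f"expected fisher-stage matrices, got {m.stage!r}")
    samples = fisher[0].samples
    for m in fisher[1:]:
        if m.samples != samples:
            raise ValueError("views are not aligned on the same sample order")
    n = len(samples)
    if n < 4:
        raise ValueError(f"need >= 4 samples (got {n})")
    K = len(fisher)
    mats = [m.values for m in fisher]

    I, J, comp = _pair_index(n)
    P = len(I)
    blocks = [_response_blocks(r, I, J, comp) for r in mats]  # each (P, 2(n-2))
    ones = np.ones((P, 2 * (n - 2), 1))

    diag_scaled = float(scale_possibility(np.float64(1.0), config.t_scale, config.scale_mode))
    scaled, corrected, possib = [], [], []
    coef_store, sigma_store = [], []

    if config.regression_mode == "separate":
        for k in range(K):
            predictors = [p for p in range(K) if p != k]
            D = np.concatenate([ones] + [blocks[p][:, :, None] for p in predictors], axis=2)
            beta, sigma2 = _batched_min_norm_ols(D, blocks[k])
            r_pair = np.column_stack([mats[p][I, J] for p in predictors])
            r_prime = beta[:, 0] + np.einsum("pc,pc->p", beta[:, 1:], r_pair)
            scaled_k, corr_k, poss_k = _assemble(r_prime, I, J, n, config, diag_scaled)
            scaled.append(SimilarityMatrix(list(samples), scaled_k, "scaled"))
            corrected.append(SimilarityMatrix(list(samples), corr_k, "corrected"))
            possib.append(SimilarityMatrix(list(samples), poss_k, "possibility"))
            coef_store.append(beta)
            sigma_store.append(sigma2)
    else:  # pooled: one model per pair, rows stacked over target views
        D_parts, Y_parts = [], []
        for k in range(K):
            rotation = [(k + c) % K for c in range(1, K)]
            D_parts.append(
                np.concatenate([ones] + [blocks[p][:, :, None] for p in rotation], axis=2)
            )
            Y_parts.append(blocks[k])
        D = np.concatenate(D_parts, axis=1)
        Y = np.concatenate(Y_parts, axis=1)
        beta, sigma2 = _batched_min_norm_ols(D, Y)
        for k in range(K):
            rotation = [(k + c) % K for c in range(1, K)]
            r_pair = np.column_stack([mats[p][I, J] for p in rotation])
            r_prime = beta[:, 0] + np.einsum("pc,pc->p", beta[:, 1:], r_pair)
            scaled_k, corr_k, poss_k = _assemble(r_prime, I, J, n, config, diag_scaled)
            scaled.append(SimilarityMatrix(list(samples), scaled_k, "scaled"))
            corrected.append(SimilarityMatrix(list(samples), corr_k, "corrected"))
            possib.append(SimilarityMatrix(list(samples), poss_k, "possibility"))
            coef_store.append(beta)
            sigma_store.append(sigma2)

    if return_intermediate:
        return scaled, {
            "corrected": corrected,
            "possibility": possib,
            "coefficients": coef_store,
            "sigma2": sigma_store,
            "pairs": (I, J),
        }
    return scaled


def _assemble(r_prime, I, J, n, config: RunConfig, diag_scaled: float):
    """Fill symmetric matrices for the corrected / possibility / scaled stages."""
    p = possibility(r_prime, config.mu)
    s = scale_possibility(p, config.t_scale, config.scale_mode)
    corr = np.zeros((n, n))
    poss = np.zeros((n, n))
    scal = np.zeros((n, n))
    for arr, vals in ((corr, r_prime), (poss, p), (scal, s)):
        arr[I, J] = vals
        arr[J, I] = vals
    # self-similarity: a sample is in its own subtype with possibility 1
    np.fill_diagonal(corr, np.arctanh(1 - 1e-7))
    np.fill_diagonal(poss, 1.0)
    np.fill_diagonal(scal, diag_scaled)
    return scal, corr, poss
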