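"""KL-divergence matrix completion Z = Sd @ W @ H @ Sm.

The association matrix A (nd x nm, binary) is approximated by
``Zhat = Sd @ W @ H @ Sm`` with nonnegative factors W (nd x r) and
H (r x nm), where Sd and Sm are the integrated disease and miRNA
similarity matrices acting as feature maps.  The factors minimize the
generalized Kullback-Leibler divergence

    D(A || Zhat) = sum_ij [ A_ij ln(A_ij / Zhat_ij) - A_ij + Zhat_ij ]

subject to W, H >= 0, via alternating multiplicative updates that never
increase the objective and preserve nonnegativity.  The recovered Z scores
every disease-miRNA pair; high scores on zero entries of A are predicted
novel associations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .types import AssociationMatrix, SimilarityMatrix

#: floor for elementwise denominators and log arguments; A is sparse and the
#: reconstruction can underflow early in training
EPSILON = 1e-12

#: floor on the initialization target mean, so near-empty training folds
#: still start from a strictly positive reconstruction
_INIT_DENSITY_FLOOR = 1e-3


@dataclass(frozen=True)
class CompletionParams:
    """Factorization hyper-parameters.

    rank: latent dimension r, or "auto" to select it by PCA of Sm at
        ``pca_threshold`` cumulative explained variance.
    max_iter: multiplicative-update sweeps (default 100).
    tol: relative objective change for early stopping; set to 0 to force
        exactly ``max_iter`` sweeps.
    """

    rank: int | str = "auto"
    max_iter: int = 100
    epsilon: float = EPSILON
    seed: int = 0
    pca_threshold: float = 0.95
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if isinstance(self.rank, str):
            if self.rank != "auto":
                raise ValueError("rank must be a positive integer or 'auto'")
        elif self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0 < self.pca_threshold <= 1:
            raise ValueError("pca_threshold must lie in (0, 1]")


@dataclass
class FitResult:
    """Fitted factors, the resolved rank, and the per-iteration objective."""

    W: np.ndarray
    H: np.ndarray
    rank: int
    objective_trace: list[float] = field(default_factory=list)


def _as_array(x) -> np.ndarray:
    if isinstance(x, (AssociationMatrix, SimilarityMatrix)):
        return x.values
    return np.asarray(x, dtype=float)


def kl_objective(A, Sd, W, H, Sm, epsilon: float = EPSILON) -> float:
    """Generalized KL divergence D(A || Sd W H Sm).

    Terms with A_ij = 0 contribute Zhat_ij (0 ln 0 := 0); the log argument
    is floored at ``epsilon`` against underflow.
    """
    A, Sd, Sm = _as_array(A), _as_array(Sd), _as_array(Sm)
    W, H = np.asarray(W, float), np.asarray(H, float)
    if (W < 0).any() or (H < 0).any():
        raise ValueError("factors must be nonnegative")
    Zhat = Sd @ W @ H @ Sm
    pos = A > 0
    obj = float(Zhat.sum() - A.sum())
    if pos.any():
        obj += float(np.sum(A[pos] * np.log(A[pos] / np.maximum(Zhat[pos], epsilon))))
    return obj


def update_step(A, Sd, Sm, W, H, epsilon: float = EPSILON
                ) -> tuple[np.ndarray, np.ndarray]:
    """One alternating multiplicative sweep over W then H.

    W <- W * [Sd^T (A/Zhat) Sm^T H^T] / [Sd^T ONES Sm^T H^T], then Zhat is
    recomputed and H <- H * [W^T Sd^T (A/Zhat) Sm^T] / [W^T Sd^T ONES Sm^T];
    divisions are elementwise with denominators floored at ``epsilon``.
    Nonnegativity is preserved and the KL objective never increases.
    """
    A, Sd, Sm = _as_array(A), _as_array(Sd), _as_array(Sm)
    W = np.asarray(W, float).copy()
    H = np.asarray(H, float).copy()
    nd, nm = A.shape
    if Sd.shape != (nd, nd) or Sm.shape != (nm, nm):
        raise ValueError("similarity matrices are not conformable with A")
    if W.shape[0] != nd or H.shape[1] != nm or W.shape[1] != H.shape[0]:
        raise ValueError("factor shapes are not conformable")

    ones_num_m = Sm.T.sum(axis=0)          # column sums of ONES @ Sm.T
    Zhat = Sd @ W @ H @ Sm
    R = A / np.maximum(Zhat, epsilon)
    num = Sd.T @ R @ Sm.T @ H.T
    den = np.outer(Sd.T.sum(axis=1), ones_num_m @ H.T)
    W *= num / np.maximum(den, epsilon)

    Zhat = Sd @ W @ H @ Sm
    R = A / np.maximum(Zhat, epsilon)
    num = W.T @ Sd.T @ R @ Sm.T
    den = np.outer(W.T @ Sd.T.sum(axis=1), ones_num_m)
    H *= num / np.maximum(den, epsilon)
    return W, H


def fit(A, Sd, Sm, params: CompletionParams = CompletionParams()) -> FitResult:
    """Fit the factor pair by alternating multiplicative updates.

    W and H start as seeded uniform(0,1) matrices, rescaled so the initial
    reconstruction has mean ``max(mean(A), 1e-3)``; the run performs at most
    ``max_iter`` sweeps, stopping early when the relative objective change
    drops below ``tol``.
    """
    A_arr, Sd_arr, Sm_arr = _as_array(A), _as_array(Sd), _as_array(Sm)
    nd, nm = A_arr.shape
    if params.rank == "auto":
        r = select_rank(Sm, params.pca_threshold)
        r = min(r, nd, nm)
    else:
        r = int(params.rank)
        if r > min(nd, nm):
            raise ValueError("rank exceeds min(nd, nm)")

    rng = np.random.default_rng(params.seed)
    W = rng.uniform(size=(nd, r))
    H = rng.uniform(size=(r, nm))
    target = max(float(A_arr.mean()), _INIT_DENSITY_FLOOR)
    mean0 = float((Sd_arr @ W @ H @ Sm_arr).mean())
    if mean0 > 0:
        scale = np.sqrt(target / mean0)
        W *= scale
        H *= scale

    trace = [kl_objective(A_arr, Sd_arr, W, H, Sm_arr, params.epsilon)]
    for it in range(params.max_iter):
        W, H = update_step(A_arr, Sd_arr, Sm_arr, W, H, params.epsilon)
        obj = kl_objective(A_arr, Sd_arr, W, H, Sm_arr, params.epsilon)
        if not np.isfinite(obj):
            raise FloatingPointError(f"non-finite objective at iteration {it + 1}")
        trace.append(obj)
        denom = max(abs(trace[-2]), params.epsilon)
        if params.tol > 0 and abs(trace[-2] - trace[-1]) / denom < params.tol:
            break
    return FitResult(W=W, H=H, rank=r, objective_trace=trace)


def predict_scores(Sd, W, H, Sm) -> np.ndarray:
    """Recovered score matrix Z = Sd @ W @ H @ Sm."""
    Sd, Sm = _as_array(Sd), _as_array(Sm)
    W, H = np.asarray(W, float), np.asarray(H, float)
    return Sd @ W @ H @ Sm


def select_rank(S, threshold: float = 0.95) -> int:
    """Smallest PCA component count reaching the cumulative variance threshold.

    The similarity matrix is column-centered; the returned count is the
    number of principal components whose cumulative explained-variance
    ratio first reaches ``threshold``.
    """
    S = _as_array(S)
    if S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if S.var(axis=0).sum() <= 0:
        raise ValueError("degenerate input: zero total variance")
    pca = PCA()
    pca.fit(S)
    cum = np.cumsum(pca.explained_variance_ratio_)
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)
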