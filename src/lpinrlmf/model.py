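"""Neighborhood-regularized logistic matrix factorization (NRLMF).

The model places every lncRNA i and protein j in a shared r-dimensional
latent space (vectors u_i, v_j) and models the interaction probability as

    p_ij = sigmoid(u_i . v_j).

Known interactions (y_ij = 1) are experimentally validated and therefore
weighted c-fold (c > 1) relative to the unobserved pairs, giving the
weighted logistic loss

    sum_ij (1 + c*y_ij - y_ij) * log(1 + exp(u_i . v_j)) - c * y_ij * (u_i . v_j).

Two regularizers are added: Gaussian-prior ridge terms (lambda_l, lambda_p)
and neighborhood terms that pull each entity's latent vector toward those of
its K1 most sequence-similar entities, expressed through directed K-NN graph
Laplacians L = (D + D~) - (A + A^T):

    + 1/2 tr[U^T (lambda_l I + alpha L_l) U]
    + 1/2 tr[V^T (lambda_p I + beta L_p) V].

Training is alternating gradient descent with per-element adaptive step
scaling (accumulated squared gradients) and a monitored (backtracked) step so
the objective is non-increasing.  At prediction time, cold-start entities --
those with no known positive interaction -- have their latent vector replaced
by the similarity-weighted mean of their K2 nearest neighbors among entities
that do have positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import expit

from .exceptions import InputError, ModelError
from .kernels import SimilarityMatrix

_PROB_EPS = 1e-12  # predicted probabilities are clipped into the open (0,1)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class InteractionMatrix:
    """Binary m x n adjacency matrix Y over ordered lncRNA / protein ids."""

    lncrna_ids: list[str]
    protein_ids: list[str]
    Y: np.ndarray

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        m, n = len(self.lncrna_ids), len(self.protein_ids)
        if len(set(self.lncrna_ids)) != m or len(set(self.protein_ids)) != n:
            raise InputError("interaction matrix ids must be unique")
        if self.Y.shape != (m, n):
            raise InputError(
                f"Y shape {self.Y.shape} does not match {m} lncRNAs x {n} proteins"
            )
        if not np.isin(self.Y, (0.0, 1.0)).all():
            raise InputError("interaction matrix entries must be binary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.Y.shape

    @property
    def n_positives(self) -> int:
        return int(self.Y.sum())

    def positive_pairs(self) -> list[tuple[int, int]]:
        return [tuple(p) for p in np.argwhere(self.Y == 1)]


@dataclass(frozen=True)
class Hyperparameters:
    """Model and optimizer settings.

    K1 = K2 = 5 follow the method's stated neighborhood sizes; the remaining
    defaults are conventional for the logistic-MF family (the method's
    original values are unreported) and are all overridable via config.
    """

    r: int = 50
    c: float = 5.0
    lambda_l: float = 0.5
    lambda_p: float = 0.5
    alpha: float = 0.1
    beta: float = 0.1
    K1: int = 5
    K2: int = 5
    learning_rate: float = 0.1
    max_iters: int = 100
    seed: int = 0
    optimizer: str = "adagrad"  # or "fixed"

    def __post_init__(self):
        if self.r < 1:
            raise InputError("latent dimension r must be >= 1")
        if self.c < 1:
            # c = 1 is the degenerate plain-LMF weighting (every pair equal);
            # allowed so the reduction is expressible, though c > 1 is the
            # intended regime.
            raise InputError("importance weight c must be >= 1")
        if self.lambda_l < 0 or self.lambda_p < 0:
            raise InputError("lambda_l, lambda_p must be nonnegative")
        if self.alpha < 0 or self.beta < 0:
            raise InputError("alpha, beta must be nonnegative")
        if self.K1 < 1 or self.K2 < 1:
            raise InputError("neighborhood sizes K1, K2 must be positive")
        if self.learning_rate <= 0:
            raise InputError("learning rate must be positive")
        if self.max_iters < 1:
            raise InputError("max_iters must be positive")
        if self.optimizer not in ("adagrad", "fixed"):
            raise InputError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class NeighborhoodGraph:
    """Directed K-NN adjacency A (row i -> its K nearest neighbors, weights
    copied from the similarity matrix) and the Laplacian
    L = (D + D~) - (A + A^T) with D, D~ the row/column degree matrices."""

    A: np.ndarray
    L: np.ndarray
    K: int


@dataclass
class LatentModel:
    """Trained factors plus everything needed for smoothed prediction."""

    U: np.ndarray
    V: np.ndarray
    hyperparameters: Hyperparameters
    lncrna_ids: list[str]
    protein_ids: list[str]
    S_l: SimilarityMatrix
    S_p: SimilarityMatrix
    graph_l: NeighborhoodGraph
    graph_p: NeighborhoodGraph
    training_history: list[float] = field(default_factory=list)


@dataclass
class ScoreMatrix:
    """Predicted interaction probabilities, same ordering as the
    interaction matrix; entries strictly inside (0, 1)."""

    lncrna_ids: list[str]
    protein_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.lncrna_ids), len(self.protein_ids)):
            raise InputError("score matrix shape does not match ids")
        if not ((self.values > 0) & (self.values < 1)).all():
            raise InputError("scores must lie strictly in (0, 1)")


# ---------------------------------------------------------------------------
# numerics: overflow-safe primitives
# ---------------------------------------------------------------------------

def _softplus(x: np.ndarray) -> np.ndarray:
    """log(1 + exp(x)), stable for large |x|."""
    return np.logaddexp(0.0, x)


def _clip_open(p: np.ndarray) -> np.ndarray:
    return np.clip(p, _PROB_EPS, 1.0 - _PROB_EPS)


def interaction_probability(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """sigmoid(U V^T), overflow-safe, clipped into the open interval (0,1)."""
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if U.ndim != 2 or V.ndim != 2 or U.shape[1] != V.shape[1]:
        raise InputError(
            f"latent factor shapes {U.shape} and {V.shape} are incompatible"
        )
    return _clip_open(expit(U @ V.T))


# ---------------------------------------------------------------------------
# neighborhoods
# ---------------------------------------------------------------------------

def nearest_neighbors(S: np.ndarray, i: int, K: int, candidates=None) -> np.ndarray:
    """Indices of the K most similar entities to i, self excluded.

    Ties in similarity are broken by ascending entity index (stable sort on
    the negated similarities); K is truncated to the number of candidates.
    """
    q = S.shape[0]
    if candidates is None:
        cand = np.array([j for j in range(q) if j != i])
    else:
        cand = np.array([j for j in candidates if j != i])
    if cand.size == 0:
        return cand
    order = np.argsort(-S[i, cand], kind="stable")
    return cand[order[: min(K, cand.size)]]


def build_neighborhood(S: SimilarityMatrix, K: int) -> NeighborhoodGraph:
    """Directed K-NN graph from a similarity matrix and its Laplacian."""
    q = S.size
    if not (1 <= K <= q - 1):
        raise InputError(f"K={K} must satisfy 1 <= K <= {q - 1}")
    A = np.zeros((q, q))
    for i in range(q):
        nn = nearest_neighbors(S.values, i, K)
        A[i, nn] = S.values[i, nn]
    D = np.diag(A.sum(axis=1))
    D_tilde = np.diag(A.sum(axis=0))
    L = (D + D_tilde) - (A + A.T)
    return NeighborhoodGraph(A=A, L=L, K=K)


# ---------------------------------------------------------------------------
# objective and gradients
# ---------------------------------------------------------------------------

def _check_shapes(U, V, Y: InteractionMatrix):
    m, n = Y.shape
    if U.shape[0] != m or V.shape[0] != n or U.shape[1] != V.shape[1]:
        raise InputError(
            f"shapes U={U.shape}, V={V.shape} inconsistent with Y={Y.shape}"
        )


def objective(
    U: np.ndarray,
    V: np.ndarray,
    Y: InteractionMatrix,
    graph_l: NeighborhoodGraph,
    graph_p: NeighborhoodGraph,
    hp: Hyperparameters,
) -> float:
    """The regularized weighted logistic-MF loss being minimized."""
    _check_shapes(U, V, Y)
    X = U @ V.T
    W = 1.0 + (hp.c - 1.0) * Y.Y  # 1 + c*y - y
    data_term = float((W * _softplus(X)).sum() - hp.c * (Y.Y * X).sum())
    R_l = hp.lambda_l * np.eye(U.shape[0]) + hp.alpha * graph_l.L
    R_p = hp.lambda_p * np.eye(V.shape[0]) + hp.beta * graph_p.L
    reg = 0.5 * float(np.trace(U.T @ R_l @ U) + np.trace(V.T @ R_p @ V))
    return data_term + reg


def gradients(
    U: np.ndarray,
    V: np.ndarray,
    Y: InteractionMatrix,
    graph_l: NeighborhoodGraph,
    graph_p: NeighborhoodGraph,
    hp: Hyperparameters,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic partial gradients of the objective w.r.t. U and V.

    dL/dU = P V + (c-1)(Y o P) V - c Y V + (lambda_l I + alpha L_l) U,
    and symmetrically for V with transposes; o is the elementwise product.
    """
    _check_shapes(U, V, Y)
    P = expit(U @ V.T)
    M = P + (hp.c - 1.0) * Y.Y * P - hp.c * Y.Y
    dU = M @ V + (hp.lambda_l * U + hp.alpha * (graph_l.L @ U))
    dV = M.T @ U + (hp.lambda_p * V + hp.beta * (graph_p.L @ V))
    return dU, dV


def init_factors(
    m: int, n: int, r: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian initialization: entries ~ Normal(0, (1/sqrt(r))^2)."""
    if r < 1:
        raise InputError("latent dimension r must be >= 1")
    if m < 1 or n < 1:
        raise InputError("m and n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = 1.0 / np.sqrt(r)
    U0 = rng.normal(0.0, sd, size=(m, r))
    V0 = rng.normal(0.0, sd, size=(n, r))
    return U0, V0


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _backtracked_update(param, step, evaluate, current_obj, max_halvings=30):
    """Apply ``param - t*step`` with the largest t in {1, 1/2, ...} that does
    not increase the objective; returns (new_param, new_obj).  Falls back to
    no update if every trial step increases the objective."""
    t = 1.0
    for _ in range(max_halvings):
        candidate = param - t * step
        obj = evaluate(candidate)
        if obj <= current_obj:
            return candidate, obj
        t *= 0.5
    return param, current_obj


def fit(
    Y: InteractionMatrix,
    S_l: SimilarityMatrix,
    S_p: SimilarityMatrix,
    hp: Hyperparameters,
    init: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> LatentModel:
    """Train NRLMF by monitored alternating gradient descent.

    Updates U with V fixed, then V with U fixed, each along the negative
    gradient.  With ``optimizer="adagrad"`` each element's step is scaled by
    the inverse root of its accumulated squared gradient; ``"fixed"`` uses a
    constant global step.  Either way the step is backtracked (halved) until
    the objective does not increase, so the recorded training history is
    non-increasing and the final objective never exceeds the initial one.
    Fully deterministic given ``hp.seed``.
    """
    m, n = Y.shape
    if S_l.ids != Y.lncrna_ids:
        raise InputError(
            "lncRNA similarity ids do not align with interaction matrix ids; "
            f"offending ids: {sorted(set(S_l.ids) ^ set(Y.lncrna_ids))[:10] or 'order mismatch'}"
        )
    if S_p.ids != Y.protein_ids:
        raise InputError(
            "protein similarity ids do not align with interaction matrix ids; "
            f"offending ids: {sorted(set(S_p.ids) ^ set(Y.protein_ids))[:10] or 'order mismatch'}"
        )
    if hp.r >= min(m, n):
        raise InputError(f"latent dimension r={hp.r} must be < min(m, n)={min(m, n)}")
    if Y.n_positives < 1:
        raise InputError("interaction matrix has no known positives")
    if hp.K1 >= m or hp.K1 >= n:
        raise InputError(f"K1={hp.K1} must be < number of entities of each type")

    graph_l = build_neighborhood(S_l, hp.K1)
    graph_p = build_neighborhood(S_p, hp.K1)

    if init is not None:
        U, V = np.array(init[0], dtype=float), np.array(init[1], dtype=float)
        _check_shapes(U, V, Y)
    else:
        U, V = init_factors(m, n, hp.r, hp.seed)

    obj = objective(U, V, Y, graph_l, graph_p, hp)
    history = [obj]
    sum_sq_U = np.zeros_like(U)
    sum_sq_V = np.zeros_like(V)

    for _ in range(hp.max_iters):
        dU, _ = gradients(U, V, Y, graph_l, graph_p, hp)
        if hp.optimizer == "adagrad":
            sum_sq_U += dU**2
            step_U = hp.learning_rate * dU / np.sqrt(sum_sq_U + 1e-12)
        else:
            step_U = hp.learning_rate * dU
        U, obj = _backtracked_update(
            U, step_U, lambda Uc: objective(Uc, V, Y, graph_l, graph_p, hp), obj
        )

        _, dV = gradients(U, V, Y, graph_l, graph_p, hp)
        if hp.optimizer == "adagrad":
            sum_sq_V += dV**2
            step_V = hp.learning_rate * dV / np.sqrt(sum_sq_V + 1e-12)
        else:
            step_V = hp.learning_rate * dV
        V, obj = _backtracked_update(
            V, step_V, lambda Vc: objective(U, Vc, Y, graph_l, graph_p, hp), obj
        )
        history.append(obj)

    return LatentModel(
        U=U,
        V=V,
        hyperparameters=hp,
        lncrna_ids=list(Y.lncrna_ids),
        protein_ids=list(Y.protein_ids),
        S_l=S_l,
        S_p=S_p,
        graph_l=graph_l,
        graph_p=graph_p,
        training_history=history,
    )


# ---------------------------------------------------------------------------
# cold-start smoothing and prediction
# ---------------------------------------------------------------------------

def _smooth_side(
    factors: np.ndarray, S: np.ndarray, degrees: np.ndarray, K2: int, kind: str
) -> np.ndarray:
    """Replace each zero-degree entity's latent vector by the similarity-
    weighted mean of its K2 nearest neighbors among positive-degree
    entities.  A neighborhood whose similarity weights sum to zero yields
    the zero vector."""
    positive = np.flatnonzero(degrees > 0)
    cold = np.flatnonzero(degrees == 0)
    if cold.size == 0:
        return factors
    if positive.size == 0:
        raise ModelError(
            f"every {kind} is cold-start: no positive entities to smooth from"
        )
    smoothed = factors.copy()
    for i in cold:
        nn = nearest_neighbors(S, i, K2, candidates=positive)
        w = S[i, nn]
        total = w.sum()
        if total > 0:
            smoothed[i] = (w[:, None] * factors[nn]).sum(axis=0) / total
        else:
            smoothed[i] = 0.0
    return smoothed


def smoothed_latent_vectors(
    model: LatentModel, Y: InteractionMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Latent factors after cold-start smoothing.

    Entities with at least one known positive in Y keep their trained
    vector; entities with none get the similarity-weighted mean of the K2
    most similar positive-set entities (neighbor selection uses the same
    rule as training: ties broken by ascending index).
    """
    if Y.shape != (model.U.shape[0], model.V.shape[0]):
        raise InputError("interaction matrix shape does not match the model")
    K2 = model.hyperparameters.K2
    U_s = _smooth_side(model.U, model.S_l.values, Y.Y.sum(axis=1), K2, "lncRNA")
    V_s = _smooth_side(model.V, model.S_p.values, Y.Y.sum(axis=0), K2, "protein")
    return U_s, V_s


def predict(model: LatentModel, Y: InteractionMatrix) -> ScoreMatrix:
    """Smoothed interaction probabilities sigmoid(u~_i . v~_j).

    Identical to ``interaction_probability(U, V)`` when no entity is
    cold-start.
    """
    U_s, V_s = smoothed_latent_vectors(model, Y)
    return ScoreMatrix(
        lncrna_ids=model.lncrna_ids,
        protein_ids=model.protein_ids,
        values=interaction_probability(U_s, V_s),
    )
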