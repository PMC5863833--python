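"""Graph diffusion scoring: transition matrix and regularized Laplacian kernel.

Given the evolved matrix EA and the binary training adjacency A, the
transition matrix is the elementwise sigmoid

    T = sigmoid(EA' + EA + A),

symmetric by construction.  Pairwise interaction scores come from the
regularized Laplacian kernel over T:

    P = (I + alpha * L)^(-1) = sum_k alpha^k (-L)^k,   L = D - T,

where D is the diagonal of T's row sums and 0 < alpha < 1/rho(L) with
rho(L) the spectral radius of L; the Neumann series and the matrix inverse
agree under that bound.  P[i, j] scores the interaction between proteins i
and j.  The kernel applied directly to the raw binary adjacency is the
ADJ-RL baseline.

Because EA's entries lie in (0, 1), the sigmoid argument lies in (0, 3) and
every entry of T is inside (0.5, 0.953): T is dense even when A is sparse,
which is what lets scores diffuse across disconnected training components.

alpha is parameterised by ``alpha_fraction`` = alpha * rho(L) in (0, 1), so
the spectral bound holds for any input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin

from ._io import save_matrix_tsv
from .enn import ENNConfig, EvolutionNetwork
from .network import AdjacencyMatrix, ProteinNetwork, to_adjacency

__all__ = [
    "TransitionMatrix",
    "ScoreMatrix",
    "build_transition",
    "laplacian",
    "spectral_radius",
    "regularized_laplacian",
    "adj_rl_baseline",
    "run_ennrl",
    "RegularizedLaplacianScorer",
    "ENNRL",
    "AdjacencyRL",
]


@dataclass(frozen=True)
class TransitionMatrix:
    """Symmetric transition matrix T with entries in (0, 1)."""

    values: np.ndarray
    node_order: tuple[str, ...]


@dataclass(frozen=True)
class ScoreMatrix:
    """Inference matrix P; P[i,j] scores the pair (i, j)."""

    values: np.ndarray
    node_order: tuple[str, ...]
    alpha_rl: float
    spectral_radius_used: float


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def build_transition(ea, trainingAdj: AdjacencyMatrix) -> TransitionMatrix:
    """T = sigmoid(EA' + EA + A); symmetric because EA'+EA and A are."""
    ea_values = ea.values if hasattr(ea, "values") else np.asarray(ea, dtype=float)
    node_order = tuple(getattr(ea, "node_order", trainingAdj.node_order))
    A = trainingAdj.values
    if ea_values.shape != A.shape:
        raise ValueError(
            f"shape mismatch: EA {ea_values.shape} vs adjacency {A.shape}"
        )
    if node_order != tuple(trainingAdj.node_order):
        raise ValueError("EA and training adjacency disagree on node order")
    T = _sigmoid(ea_values.T + ea_values + A)
    T = (T + T.T) / 2.0  # remove any floating-point asymmetry
    return TransitionMatrix(T, node_order)


def laplacian(T: TransitionMatrix | np.ndarray) -> np.ndarray:
    """Weighted graph Laplacian L = D - T; every row sums to zero."""
    W = T.values if isinstance(T, TransitionMatrix) else np.asarray(T, dtype=float)
    return np.diag(W.sum(axis=1)) - W


def spectral_radius(
    L: np.ndarray, tol: float = 1e-8, max_iter: int = 10_000
) -> float:
    """Largest absolute eigenvalue of a symmetric matrix by power iteration.

    Falls back to a dense eigendecomposition (m <= 2000) if the iteration
    has not converged to relative tolerance ``tol`` within ``max_iter``.
    """
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(L, L.T, atol=1e-10):
        raise ValueError("spectral_radius expects a symmetric matrix")
    m = L.shape[0]
    if m == 0 or not np.any(L):
        return 0.0
    # deterministic start with components along every coordinate
    v = np.ones(m) + np.linspace(0.0, 0.5, m)
    v /= np.linalg.norm(v)
    for _ in range(max_iter):
        w = L @ v
        mu = float(v @ w)  # Rayleigh quotient (signed)
        if mu != 0.0 and np.linalg.norm(w - mu * v) <= tol * abs(mu):
            return abs(mu)
        nrm = float(np.linalg.norm(w))
        if nrm == 0.0:
            return 0.0
        v = w / nrm
    if m <= 2000:
        return float(np.max(np.abs(scipy.linalg.eigvalsh(L))))
    raise RuntimeError("power iteration did not converge")


def _rl_kernel(W: np.ndarray, node_order, alpha_fraction: float) -> ScoreMatrix:
    if not 0.0 < alpha_fraction < 1.0:
        raise ValueError(f"alpha_fraction must be in (0,1), got {alpha_fraction}")
    L = laplacian(W)
    rho = spectral_radius(L)
    m = W.shape[0]
    if rho == 0.0:
        # empty diffusion operator: the kernel degenerates to the identity
        return ScoreMatrix(np.eye(m), tuple(node_order), alpha_rl=0.0,
                           spectral_radius_used=0.0)
    alpha = alpha_fraction / rho
    P = scipy.linalg.solve(np.eye(m) + alpha * L, np.eye(m), assume_a="pos")
    P = (P + P.T) / 2.0
    return ScoreMatrix(P, tuple(node_order), alpha_rl=alpha,
                       spectral_radius_used=rho)


def regularized_laplacian(
    T: TransitionMatrix, alpha_fraction: float = 0.5
) -> ScoreMatrix:
    """Apply the regularized Laplacian kernel to a transition matrix.

    ``alpha_fraction`` sets alpha = alpha_fraction / rho(L), which keeps
    alpha inside the convergence bound of the Neumann series.  The kernel
    is evaluated as a symmetric positive-definite linear solve rather than
    an explicit inverse or a truncated series.
    """
    return _rl_kernel(T.values, T.node_order, alpha_fraction)


def adj_rl_baseline(
    trainingAdj: AdjacencyMatrix, alpha_fraction: float = 0.5
) -> ScoreMatrix:
    """ADJ-RL: the kernel applied directly to the binary training adjacency."""
    return _rl_kernel(trainingAdj.values, trainingAdj.node_order, alpha_fraction)


class RegularizedLaplacianScorer(BaseEstimator, TransformerMixin):
    """Regularized Laplacian kernel as a transformer over weight matrices.

    ``fit(X)`` treats X as a symmetric nonnegative weight (transition)
    matrix and computes the score matrix; ``transform`` returns it.
    """

    def __init__(self, alpha_fraction: float = 0.5):
        self.alpha_fraction = alpha_fraction

    def fit(self, X, y=None):
        W = np.asarray(X, dtype=float)
        res = _rl_kernel(W, tuple(map(str, range(W.shape[0]))), self.alpha_fraction)
        self.scores_ = res.values
        self.alpha_ = res.alpha_rl
        self.spectral_radius_ = res.spectral_radius_used
        self.n_features_in_ = W.shape[0]
        return self

    def transform(self, X=None) -> np.ndarray:
        if not hasattr(self, "scores_"):
            raise AttributeError("RegularizedLaplacianScorer is not fitted yet")
        return self.scores_


class ENNRL(BaseEstimator):
    """End-to-end ENN-RL scorer: evolution network then diffusion kernel.

    ``fit(X)`` takes the binary training adjacency, trains the evolution
    network on its rows, builds T = sigmoid(EA'+EA+X) and applies the
    regularized Laplacian kernel.

    Attributes
    ----------
    evolved_matrix_, transition_, scores_ : ndarrays (m, m)
    alpha_, spectral_radius_ : kernel parameters actually used
    enn_ : the fitted :class:`EvolutionNetwork`
    """

    def __init__(
        self,
        alpha_fraction: float = 0.5,
        hidden_sizes: tuple[int, int, int] | None = None,
        dropout_rate: float = 0.2,
        learning_rate: float = 1e-3,
        max_epochs: int = 500,
        batch_size: int | None = None,
        patience: int = 20,
        loss_tolerance: float = 1e-6,
        input_mode: str = "zeros",
        random_state: int = 0,
    ):
        self.alpha_fraction = alpha_fraction
        self.hidden_sizes = hidden_sizes
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.loss_tolerance = loss_tolerance
        self.input_mode = input_mode
        self.random_state = random_state

    def fit(self, X, y=None):
        A = np.asarray(X, dtype=float)
        enn = EvolutionNetwork(
            hidden_sizes=self.hidden_sizes,
            dropout_rate=self.dropout_rate,
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            patience=self.patience,
            loss_tolerance=self.loss_tolerance,
            input_mode=self.input_mode,
            random_state=self.random_state,
        ).fit(A)
        ea = enn.evolved_matrix_
        T = _sigmoid(ea.T + ea + A)
        T = (T + T.T) / 2.0
        res = _rl_kernel(T, tuple(map(str, range(A.shape[0]))), self.alpha_fraction)
        self.enn_ = enn
        self.evolved_matrix_ = ea
        self.transition_ = T
        self.scores_ = res.values
        self.alpha_ = res.alpha_rl
        self.spectral_radius_ = res.spectral_radius_used
        self.n_features_in_ = A.shape[0]
        return self

    def predict(self, pairs) -> np.ndarray:
        """Scores for an array of (i, j) node-index pairs."""
        if not hasattr(self, "scores_"):
            raise AttributeError("ENNRL is not fitted yet")
        pairs = np.asarray(pairs, dtype=int)
        return self.scores_[pairs[:, 0], pairs[:, 1]]


class AdjacencyRL(BaseEstimator):
    """ADJ-RL baseline estimator: the kernel on the raw training adjacency."""

    def __init__(self, alpha_fraction: float = 0.5):
        self.alpha_fraction = alpha_fraction

    def fit(self, X, y=None):
        A = np.asarray(X, dtype=float)
        res = _rl_kernel(A, tuple(map(str, range(A.shape[0]))), self.alpha_fraction)
        self.scores_ = res.values
        self.alpha_ = res.alpha_rl
        self.spectral_radius_ = res.spectral_radius_used
        self.n_features_in_ = A.shape[0]
        return self

    def predict(self, pairs) -> np.ndarray:
        if not hasattr(self, "scores_"):
            raise AttributeError("AdjacencyRL is not fitted yet")
        pairs = np.asarray(pairs, dtype=int)
        return self.scores_[pairs[:, 0], pairs[:, 1]]


def run_ennrl(
    net_train: ProteinNetwork,
    enn_config: ENNConfig | None = None,
    alpha_fraction: float = 0.5,
    outdir: str | Path | None = None,
) -> ScoreMatrix:
    """Full pipeline: adjacency -> ENN -> transition -> RL scores.

    If ``outdir`` is given, EA, T and P are persisted there as TSV matrices
    together with a JSON metadata record (alpha_fraction, alpha, rho(L),
    epochs, final loss).
    """
    cfg = enn_config or ENNConfig()
    adj = to_adjacency(net_train)
    est = ENNRL(
        alpha_fraction=alpha_fraction,
        hidden_sizes=cfg.hidden_sizes,
        dropout_rate=cfg.dropout_rate,
        learning_rate=cfg.learning_rate,
        max_epochs=cfg.max_epochs,
        batch_size=cfg.batch_size,
        patience=cfg.patience,
        loss_tolerance=cfg.loss_tolerance,
        input_mode=cfg.input_mode,
        random_state=cfg.seed,
    ).fit(adj.values)
    scores = ScoreMatrix(
        est.scores_, tuple(net_train.nodes), alpha_rl=est.alpha_,
        spectral_radius_used=est.spectral_radius_,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_matrix_tsv(est.evolved_matrix_, net_train.nodes, outdir / "EA.tsv")
        save_matrix_tsv(est.transition_, net_train.nodes, outdir / "T.tsv")
        save_matrix_tsv(est.scores_, net_train.nodes, outdir / "P.tsv")
        meta = {
            "alpha_fraction": alpha_fraction,
            "alpha": est.alpha_,
            "spectral_radius": est.spectral_radius_,
            "epochs_run": est.enn_.n_epochs_,
            "final_loss": est.enn_.final_loss_,
            "input_mode": cfg.input_mode,
            "seed": cfg.seed,
        }
        (outdir / "predict_meta.json").write_text(json.dumps(meta, indent=2))
    return scores
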