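"""Evolution neural network: a five-layer zero-input network over adjacency rows.

The network has layers of sizes ``m, h1, h2, h3, m`` with a sigmoid
activation at every layer and dropout between layers during training.  Each
training example is one protein: the input is either the all-zero vector
(``input_mode="zeros"``, expressing zero prior knowledge of interactions) or
the one-hot row indicator (``input_mode="identity"``), and the label is that
protein's row of the training adjacency matrix.  The narrow middle layer
plays the role of a smaller "ancient" interactome that the observed
interactions must be reconstructed through.  The loss is binary
cross-entropy, averaged over rows and summed over output units, and no
layer-wise pretraining is used.

With literal all-zero inputs every example is identical, so the trained
network is a constant predictor: each row of the evolved matrix EA converges
to the column means of the training adjacency.  This degeneracy is inherent
to the zero-input formulation and is kept as the default; ``identity`` mode
is offered as the row-distinguishing alternative.

There is no GPU requirement: the layers are small dense matrices, trained
with the Adam optimizer in numpy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .network import AdjacencyMatrix

__all__ = ["ENNConfig", "EvolvedMatrix", "EvolutionNetwork", "train_enn", "enn_loss"]

_LOSS_EPS = 1e-7  # probability clamp so log(0) never occurs


def enn_loss(outputs: np.ndarray, labels: np.ndarray) -> float:
    """Binary cross-entropy: mean over rows of the per-unit sum.

    ``outputs`` are probabilities; values at exactly 0 or 1 are clamped to
    ``[eps, 1-eps]`` with eps = 1e-7.
    """
    p = np.asarray(outputs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: outputs {p.shape} vs labels {y.shape}")
    p = np.clip(p, _LOSS_EPS, 1.0 - _LOSS_EPS)
    per_row = -(y * np.log(p) + (1.0 - y) * np.log1p(-p)).sum(axis=1)
    return float(per_row.mean())


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class ENNConfig:
    """Training configuration for the evolution network.

    ``hidden_sizes=None`` resolves to the mirror-image default
    ``h1 = h3 = max(16, ceil(m/2))``, ``h2 = max(8, ceil(m/8))``.
    ``batch_size=None`` means full batch for m <= 1000, else 256.
    """

    hidden_sizes: tuple[int, int, int] | None = None
    dropout_rate: float = 0.2
    learning_rate: float = 1e-3
    max_epochs: int = 500
    batch_size: int | None = None
    patience: int = 20
    loss_tolerance: float = 1e-6
    seed: int = 0
    input_mode: str = "zeros"


@dataclass(frozen=True)
class EvolvedMatrix:
    """EA: row i is the trained network's output for protein i."""

    values: np.ndarray
    node_order: tuple[str, ...]
    training_log: tuple[tuple[int, float], ...]


class EvolutionNetwork(BaseEstimator, TransformerMixin):
    """Five-layer zero-input sigmoid network trained on adjacency rows.

    Parameters
    ----------
    hidden_sizes : (h1, h2, h3) or None
        Sizes of the three hidden layers; ``None`` uses the mirror-image
        default (see :class:`ENNConfig`).  Requires ``h2 <= min(h1, h3)``.
    dropout_rate : float in [0, 1)
        Inverted dropout applied to the input and hidden activations during
        training only; disabled when the evolved matrix is read out.
    learning_rate, max_epochs, batch_size, patience, loss_tolerance
        Adam step size and stopping rules: training ends at ``max_epochs``
        or once the epoch loss has improved by less than ``loss_tolerance``
        for ``patience`` consecutive epochs.
    input_mode : {"zeros", "identity"}
        Per-row input: the all-zero vector, or the one-hot row indicator.
    random_state : int
        Seeds weight initialisation, dropout masks and batch shuffling;
        a fixed seed makes training bitwise reproducible.

    Attributes
    ----------
    evolved_matrix_ : ndarray of shape (m, m)
        EA; entries strictly inside (0, 1).
    training_log_ : tuple of (epoch, loss)
        Full-data loss (dropout off) after each epoch.
    n_epochs_, final_loss_ : training summary.
    """

    def __init__(
        self,
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
        self.hidden_sizes = hidden_sizes
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.loss_tolerance = loss_tolerance
        self.input_mode = input_mode
        self.random_state = random_state

    # ------------------------------------------------------------------ #

    def _validate_adjacency(self, X: np.ndarray) -> np.ndarray:
        A = np.asarray(X, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("training adjacency must be a square matrix")
        if not np.array_equal(A, A.T):
            raise ValueError("training adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("training adjacency must have a zero diagonal")
        if not np.isin(A, (0.0, 1.0)).all():
            raise ValueError("training adjacency must be binary")
        return A

    def _resolve_sizes(self, m: int) -> tuple[int, int, int]:
        if self.hidden_sizes is None:
            h1 = h3 = max(16, math.ceil(m / 2))
            h2 = max(8, math.ceil(m / 8))
        else:
            h1, h2, h3 = (int(h) for h in self.hidden_sizes)
        if min(h1, h2, h3) < 1:
            raise ValueError("hidden sizes must be positive")
        if h2 > min(h1, h3):
            raise ValueError("middle layer must not be wider than its neighbours")
        if max(h1, h3) >= m:
            warnings.warn(
                f"hidden size {max(h1, h3)} >= network size {m}; the "
                "'smaller ancient interactome' interpretation no longer holds",
                stacklevel=3,
            )
        return h1, h2, h3

    def fit(self, X, y=None):
        """Train on the rows of a symmetric binary adjacency matrix."""
        A = self._validate_adjacency(X)
        m = A.shape[0]
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0,1)")
        if self.input_mode not in ("zeros", "identity"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        sizes = (m, *self._resolve_sizes(m), m)
        rng = np.random.default_rng(self.random_state)

        # Glorot-uniform initialisation, zero biases.
        W = []
        b = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = math.sqrt(6.0 / (fan_in + fan_out))
            W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            b.append(np.zeros(fan_out))

        inputs = np.eye(m) if self.input_mode == "identity" else np.zeros((m, m))
        labels = A
        batch = self.batch_size
        if batch is None:
            batch = m if m <= 1000 else 256
        batch = min(batch, m)

        # Adam state
        mW = [np.zeros_like(w) for w in W]
        vW = [np.zeros_like(w) for w in W]
        mb = [np.zeros_like(x) for x in b]
        vb = [np.zeros_like(x) for x in b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        def forward(x: np.ndarray, train: bool):
            acts = [x]
            masks = []
            h = x
            for k in range(4):
                if train and self.dropout_rate > 0.0:
                    mask = (
                        rng.random(h.shape) >= self.dropout_rate
                    ) / (1.0 - self.dropout_rate)
                    h = h * mask
                else:
                    mask = None
                masks.append(mask)
                h = _sigmoid(h @ W[k] + b[k])
                acts.append(h)
            return acts, masks

        log: list[tuple[int, float]] = []
        best = math.inf
        streak = 0
        order = np.arange(m)
        for epoch in range(1, self.max_epochs + 1):
            if batch < m:
                rng.shuffle(order)
            for start in range(0, m, batch):
                rows = order[start : start + batch]
                x, yb = inputs[rows], labels[rows]
                acts, masks = forward(x, train=True)
                nb = len(rows)
                t += 1
                # output delta of summed BCE through the sigmoid: p - y
                delta = (acts[-1] - yb) / nb
                for k in range(3, -1, -1):
                    a_in = acts[k]
                    if masks[k] is not None:
                        a_in = a_in * masks[k]
                    gW = a_in.T @ delta
                    gb = delta.sum(axis=0)
                    if k > 0:
                        delta = delta @ W[k].T
                        if masks[k] is not None:
                            delta = delta * masks[k]
                        delta = delta * acts[k] * (1.0 - acts[k])
                    for g, w_, m_, v_ in ((gW, W[k], mW[k], vW[k]), (gb, b[k], mb[k], vb[k])):
                        m_ *= beta1
                        m_ += (1 - beta1) * g
                        v_ *= beta2
                        v_ += (1 - beta2) * g * g
                        mhat = m_ / (1 - beta1 ** t)
                        vhat = v_ / (1 - beta2 ** t)
                        w_ -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)

            acts, _ = forward(inputs, train=False)
            loss = enn_loss(acts[-1], labels)
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "try a smaller learning_rate"
                )
            log.append((epoch, loss))
            if best - loss < self.loss_tolerance:
                streak += 1
                if streak >= self.patience:
                    break
            else:
                streak = 0
            best = min(best, loss)

        acts, _ = forward(inputs, train=False)
        ea = np.clip(acts[-1], 1e-12, 1.0 - 1e-12)
        self.evolved_matrix_ = ea
        self.training_log_ = tuple(log)
        self.n_epochs_ = log[-1][0] if log else 0
        self.final_loss_ = log[-1][1] if log else math.nan
        self.n_features_in_ = m
        self.hidden_sizes_ = sizes[1:4]
        return self

    def transform(self, X=None) -> np.ndarray:
        """Return the evolved matrix EA (the fitted network's row outputs)."""
        if not hasattr(self, "evolved_matrix_"):
            raise AttributeError("EvolutionNetwork is not fitted yet")
        return self.evolved_matrix_

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, y).transform()


def train_enn(trainingAdj: AdjacencyMatrix, config: ENNConfig | None = None) -> EvolvedMatrix:
    """Train the evolution network on a training adjacency; return EA."""
    cfg = config or ENNConfig()
    est = EvolutionNetwork(
        hidden_sizes=cfg.hidden_sizes,
        dropout_rate=cfg.dropout_rate,
        learning_rate=cfg.learning_rate,
        max_epochs=cfg.max_epochs,
        batch_size=cfg.batch_size,
        patience=cfg.patience,
        loss_tolerance=cfg.loss_tolerance,
        input_mode=cfg.input_mode,
        random_state=cfg.seed,
    ).fit(trainingAdj.values)
    return EvolvedMatrix(
        values=est.evolved_matrix_,
        node_order=tuple(trainingAdj.node_order),
        training_log=est.training_log_,
    )
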