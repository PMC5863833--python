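"""Heterogeneous feature kernels and nonnegative weight optimisation (WOLP).

Feature kernels are symmetric m x m similarity matrices over the shared
node order.  Graph-topology kernels (Jaccard, shared neighbours) are always
computed from the *training* network only, so held-out test edges never
leak into features.  Sequence, expression or domain kernels enter as
precomputed matrices loaded from disk.

Weight optimisation fits a nonnegative linear combination of the training
adjacency G_tn and the feature kernels to a target transition matrix T by
minimising the squared Frobenius norm

    || W0 * G_tn + sum_i Wi * Ki  -  T ||^2,   W >= 0,

solved as nonnegative least squares over the vectorised matrices.  With the
ENN transition matrix as target this is the ENNlp fusion mode; equal
weights give the EW baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
from sklearn.base import BaseEstimator, TransformerMixin

from ._io import save_matrix_tsv
from .network import AdjacencyMatrix, ProteinNetwork
from .propagate import TransitionMatrix

__all__ = [
    "FeatureKernel",
    "KernelWeights",
    "jaccard_kernel",
    "shared_neighbors_kernel",
    "load_kernel_matrix",
    "save_kernel_matrix",
    "normalize_kernel",
    "fuse_kernels",
    "optimize_weights",
    "KernelFusion",
]


@dataclass(frozen=True)
class FeatureKernel:
    """Symmetric similarity matrix with its node order and a name."""

    values: np.ndarray
    node_order: tuple[str, ...]
    name: str


@dataclass(frozen=True)
class KernelWeights:
    """Fitted fusion weights: w0 for G_tn, one weight per kernel, residual.

    ``residual`` is the squared Frobenius distance achieved at the optimum.
    """

    w0: float
    w: tuple[float, ...]
    residual: float


def jaccard_kernel(net: ProteinNetwork) -> FeatureKernel:
    """Neighbourhood-overlap kernel: |N(i) & N(j)| / |N(i) | N(j)|.

    Pairs whose neighbourhood union is empty score 0.  The diagonal is 1
    for nodes with at least one neighbour and 0 for isolated nodes.
    """
    m = net.n_nodes
    A = np.zeros((m, m))
    for i, j in net.edges:
        A[i, j] = A[j, i] = 1.0
    deg = A.sum(axis=1)
    inter = A @ A
    union = deg[:, None] + deg[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(K, (deg > 0).astype(float))
    return FeatureKernel(K, net.nodes, "Jaccard")


def shared_neighbors_kernel(net: ProteinNetwork) -> FeatureKernel:
    """Degree-sum kernel: raw entry degree(i) + degree(j), min-max normalised."""
    deg = net.degrees().astype(float)
    raw = deg[:, None] + deg[None, :]
    return normalize_kernel(FeatureKernel(raw, net.nodes, "SN"))


def normalize_kernel(K: FeatureKernel) -> FeatureKernel:
    """Min-max rescale all entries to [0, 1]; constant matrices map to zeros."""
    v = np.asarray(K.values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError(f"kernel {K.name!r} contains non-finite entries")
    lo, hi = v.min(), v.max()
    if hi == lo:
        out = np.zeros_like(v)
    else:
        out = (v - lo) / (hi - lo)
    return FeatureKernel(out, K.node_order, K.name)


def save_kernel_matrix(K: FeatureKernel, path: str | Path) -> None:
    save_matrix_tsv(K.values, K.node_order, path)


def load_kernel_matrix(
    path: str | Path, node_order: Sequence[str], name: str | None = None
) -> FeatureKernel:
    """Load a precomputed kernel matrix and align it to ``node_order``.

    The file's first row and column are protein IDs; rows/columns are
    reordered to match ``node_order``.  Unknown or missing IDs are errors,
    as is asymmetry beyond 1e-6 (smaller asymmetries are averaged away).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"kernel file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    want = list(node_order)
    have = set(df.index)
    unknown = [i for i in df.index if i not in set(want)]
    if unknown:
        raise ValueError(f"{path}: unknown protein ID {unknown[0]!r}")
    missing = [i for i in want if i not in have]
    if missing:
        raise ValueError(f"{path}: missing protein ID {missing[0]!r}")
    v = df.loc[want, want].to_numpy(dtype=float)
    asym = np.max(np.abs(v - v.T)) if v.size else 0.0
    if asym > 1e-6:
        raise ValueError(f"{path}: kernel asymmetry {asym:.3g} exceeds 1e-6")
    v = (v + v.T) / 2.0
    return FeatureKernel(v, tuple(want), name or path.stem)


def _stack(gtn_adj: AdjacencyMatrix, kernels: Sequence[FeatureKernel]) -> np.ndarray:
    mats = [gtn_adj.values]
    order = tuple(gtn_adj.node_order)
    for k in kernels:
        if tuple(k.node_order) != order:
            raise ValueError(f"kernel {k.name!r} node order differs from adjacency")
        if k.values.shape != gtn_adj.values.shape:
            raise ValueError(f"kernel {k.name!r} shape mismatch")
        mats.append(np.asarray(k.values, dtype=float))
    return np.stack(mats)


def fuse_kernels(
    gtn_adj: AdjacencyMatrix,
    kernels: Sequence[FeatureKernel],
    weights: KernelWeights | Sequence[float] | str = "equal",
) -> FeatureKernel:
    """Weighted sum W0*G_tn + sum_i Wi*Ki.

    ``weights`` may be a fitted :class:`KernelWeights`, an explicit sequence
    (W0, W1, ..., Wn), or the string ``"equal"`` which sets every weight to
    1/(n+1).
    """
    stack = _stack(gtn_adj, kernels)
    n = len(kernels)
    if isinstance(weights, str):
        if weights != "equal":
            raise ValueError(f"unknown weight mode {weights!r}")
        wvec = np.full(n + 1, 1.0 / (n + 1))
    elif isinstance(weights, KernelWeights):
        wvec = np.array([weights.w0, *weights.w], dtype=float)
    else:
        wvec = np.asarray(list(weights), dtype=float)
    if wvec.shape != (n + 1,):
        raise ValueError(f"expected {n + 1} weights, got {wvec.shape[0]}")
    fused = np.tensordot(wvec, stack, axes=1)
    return FeatureKernel(fused, tuple(gtn_adj.node_order), "fused")


class KernelFusion(BaseEstimator, TransformerMixin):
    """Nonnegative least-squares fit of fusion weights to a target matrix.

    ``fit(X, y)`` takes ``X`` of shape (k, m, m) — the stacked training
    adjacency and feature kernels — and a target matrix ``y`` of shape
    (m, m); it solves the vectorised nonnegative least-squares problem.

    Attributes
    ----------
    weights_ : ndarray of shape (k,)
        Fitted nonnegative weights, first entry for the training adjacency.
    residual_ : float
        Squared Frobenius distance at the optimum.
    """

    def fit(self, X, y):
        stack = np.asarray(X, dtype=float)
        target = np.asarray(y, dtype=float)
        if stack.ndim != 3 or stack.shape[1:] != target.shape:
            raise ValueError(
                f"X must stack matrices of shape {target.shape}, got {stack.shape}"
            )
        for k, mat in enumerate(stack):
            if not np.any(mat):
                raise ValueError(f"matrix {k} in the stack is all zeros")
        design = stack.reshape(stack.shape[0], -1).T
        w, rnorm = scipy.optimize.nnls(design, target.ravel())
        self.weights_ = w
        self.residual_ = float(rnorm**2)
        self.n_features_in_ = stack.shape[0]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "weights_"):
            raise AttributeError("KernelFusion is not fitted yet")
        stack = np.asarray(X, dtype=float)
        return np.tensordot(self.weights_, stack, axes=1)


def optimize_weights(
    gtn_adj: AdjacencyMatrix,
    kernels: Sequence[FeatureKernel],
    target: TransitionMatrix | np.ndarray,
) -> KernelWeights:
    """Fit nonnegative fusion weights against a target transition matrix."""
    if len(kernels) < 1:
        raise ValueError("need at least one feature kernel")
    stack = _stack(gtn_adj, kernels)
    tv = target.values if isinstance(target, TransitionMatrix) else np.asarray(target)
    est = KernelFusion().fit(stack, tv)
    return KernelWeights(
        w0=float(est.weights_[0]),
        w=tuple(float(x) for x in est.weights_[1:]),
        residual=est.residual_,
    )
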