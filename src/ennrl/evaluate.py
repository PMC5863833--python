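"""Evaluation: ROC/AUC against held-out edges, repeated benchmarks, and
component-reconnection curves.

Positives are the held-out test edges; candidate negatives are every
unordered non-self pair absent from the full golden-standard edge set
(training and test).  AUC is the rank-based probability that a random
positive outscores a random negative, with ties given half credit.  The
negative set is either exhaustive ("all", the default for networks up to
2000 nodes) or a seeded sample of ``neg_ratio`` negatives per positive.

The reconnection analysis ranks all candidate pairs (excluding training
edges) by score, declares the top fraction rho predicted positives G_pp,
intersects with the test edges to get G_ptp, and counts the connected
components of the training network once those recovered edges are added
back.  Larger rho can only merge components, so the count is
non-increasing in rho, from components(G_tn) down to components of the
full golden-standard network at rho = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .enn import ENNConfig
from .kernels import fuse_kernels, jaccard_kernel, optimize_weights, shared_neighbors_kernel
from .network import EdgeSplit, ProteinNetwork, split_golden_standard, to_adjacency
from .propagate import ScoreMatrix, adj_rl_baseline, _rl_kernel, run_ennrl

__all__ = [
    "RocResult",
    "ReconnectionCurve",
    "roc_auc",
    "repeat_benchmark",
    "reconnection_curve",
    "KNOWN_METHODS",
]

KNOWN_METHODS = ("ennrl", "adjrl", "ewrl", "ennlp")


@dataclass(frozen=True)
class RocResult:
    """AUC plus the full ROC curve and the evaluation design that produced it."""

    auc: float
    curve: np.ndarray  # (k, 2) array of (FPR, TPR) points
    n_pos: int
    n_neg: int
    negative_policy: str
    seed: int


@dataclass(frozen=True)
class ReconnectionCurve:
    rho_values: tuple[float, ...]
    component_counts: tuple[int, ...]
    baseline_components: int
    union_components: int


def _score_values(P: ScoreMatrix | np.ndarray) -> np.ndarray:
    return P.values if isinstance(P, ScoreMatrix) else np.asarray(P, dtype=float)


def _candidate_arrays(m: int, split: EdgeSplit):
    """Upper-triangle pair indices plus membership masks for train/test edges."""
    iu, ju = np.triu_indices(m, k=1)
    in_train = np.zeros((m, m), dtype=bool)
    in_test = np.zeros((m, m), dtype=bool)
    for i, j in split.training.edges:
        in_train[i, j] = True
    for i, j in split.test_edges:
        in_test[i, j] = True
    return iu, ju, in_train[iu, ju], in_test[iu, ju]


def roc_auc(
    P: ScoreMatrix | np.ndarray,
    split: EdgeSplit,
    negative_policy: str = "all",
    neg_ratio: int = 10,
    seed: int = 0,
) -> RocResult:
    """ROC/AUC of a score matrix against the held-out test edges.

    Scores are read from the upper triangle of P (P is symmetric, so the
    choice is immaterial but fixed for determinism).  With
    ``negative_policy="sampled"``, ``neg_ratio * n_pos`` negatives are
    drawn uniformly without replacement under ``seed``.
    """
    if not split.test_edges:
        raise ValueError("no test edges to evaluate")
    if negative_policy not in ("all", "sampled"):
        raise ValueError(f"unknown negative_policy {negative_policy!r}")
    values = _score_values(P)
    m = values.shape[0]
    iu, ju, train_mask, test_mask = _candidate_arrays(m, split)
    scores = values[iu, ju]

    pos_scores = scores[test_mask]
    neg_mask = ~(train_mask | test_mask)
    neg_scores = scores[neg_mask]
    if negative_policy == "sampled":
        if neg_ratio < 1:
            raise ValueError("neg_ratio must be >= 1")
        rng = np.random.default_rng(seed)
        k = min(neg_ratio * pos_scores.size, neg_scores.size)
        neg_scores = neg_scores[
            rng.choice(neg_scores.size, size=k, replace=False)
        ]
    y = np.concatenate([np.ones(pos_scores.size), np.zeros(neg_scores.size)])
    s = np.concatenate([pos_scores, neg_scores])
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        auc=auc,
        curve=np.column_stack([fpr, tpr]),
        n_pos=int(pos_scores.size),
        n_neg=int(neg_scores.size),
        negative_policy=negative_policy,
        seed=seed,
    )


def _method_scores(
    method: str,
    split: EdgeSplit,
    enn_config: ENNConfig,
    alpha_fraction: float,
    extra_kernels,
) -> np.ndarray:
    adj = to_adjacency(split.training)
    if method == "adjrl":
        return adj_rl_baseline(adj, alpha_fraction).values
    if method == "ennrl":
        return run_ennrl(split.training, enn_config, alpha_fraction).values
    if method in ("ewrl", "ennlp"):
        kernels = [jaccard_kernel(split.training), shared_neighbors_kernel(split.training)]
        if extra_kernels:
            kernels.extend(extra_kernels)
        if method == "ewrl":
            fused = fuse_kernels(adj, kernels, "equal")
        else:
            from .enn import train_enn
            from .propagate import build_transition

            ea = train_enn(adj, enn_config)
            T = build_transition(ea, adj)
            weights = optimize_weights(adj, kernels, T)
            fused = fuse_kernels(adj, kernels, weights)
        return _rl_kernel(fused.values, fused.node_order, alpha_fraction).values
    raise ValueError(f"unknown method {method!r}; expected one of {KNOWN_METHODS}")


def repeat_benchmark(
    net: ProteinNetwork,
    ratio_cap: float,
    methods: Iterable[str],
    n_repeats: int,
    base_seed: int,
    enn_config: ENNConfig | None = None,
    alpha_fraction: float = 0.5,
    extra_kernels=None,
    negative_policy: str | None = None,
    neg_ratio: int = 10,
) -> pd.DataFrame:
    """Repeatedly re-split, run each method on the same split, and summarise.

    Repeat r uses split seed ``base_seed + r`` (which also seeds the ENN).
    Returns a table with columns (method, ratio_cap, mean_auc, std_auc,
    n_repeats); the standard deviation is the sample (n-1) estimate.
    """
    methods = list(methods)
    for mth in methods:
        if mth not in KNOWN_METHODS:
            raise ValueError(f"unknown method {mth!r}; expected one of {KNOWN_METHODS}")
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    if negative_policy is None:
        negative_policy = "all" if net.n_nodes <= 2000 else "sampled"
    base_cfg = enn_config or ENNConfig()
    aucs: dict[str, list[float]] = {mth: [] for mth in methods}
    for r in range(n_repeats):
        seed = base_seed + r
        split = split_golden_standard(net, ratio_cap, seed)
        cfg = ENNConfig(**{**base_cfg.__dict__, "seed": seed})
        for mth in methods:
            values = _method_scores(mth, split, cfg, alpha_fraction, extra_kernels)
            res = roc_auc(values, split, negative_policy, neg_ratio, seed)
            aucs[mth].append(res.auc)
    rows = [
        {
            "method": mth,
            "ratio_cap": ratio_cap,
            "mean_auc": float(np.mean(aucs[mth])),
            "std_auc": float(np.std(aucs[mth], ddof=1)),
            "n_repeats": n_repeats,
        }
        for mth in methods
    ]
    return pd.DataFrame(rows)


def reconnection_curve(
    P: ScoreMatrix | np.ndarray,
    split: EdgeSplit,
    rho_values: Sequence[float],
) -> ReconnectionCurve:
    """Component counts of G_tn after adding back correctly predicted edges.

    For each top fraction rho, the highest-scoring ``floor(rho * N)``
    candidate pairs (all non-self pairs excluding training edges, ranked by
    score with deterministic lexicographic tie-breaks) are the predicted
    positives; those that are genuine test edges are added to the training
    network and its components recounted.
    """
    rho_values = tuple(float(r) for r in rho_values)
    if not rho_values:
        raise ValueError("empty rho grid")
    if any(not 0.0 < r <= 1.0 for r in rho_values):
        raise ValueError("rho values must lie in (0, 1]")
    if any(b <= a for a, b in zip(rho_values, rho_values[1:])):
        raise ValueError("rho values must be strictly increasing")

    values = _score_values(P)
    m = values.shape[0]
    iu, ju, train_mask, test_mask = _candidate_arrays(m, split)
    cand = ~train_mask
    ci, cj, cs = iu[cand], ju[cand], values[iu, ju][cand]
    ctest = test_mask[cand]
    order = np.lexsort((cj, ci, -cs))  # score desc, then (i, j) ascending
    ctest_ranked = ctest[order]
    n_cand = ci.size

    base_graph = split.training.to_networkx()
    baseline = nx.number_connected_components(base_graph)
    full_graph = base_graph.copy()
    full_graph.add_edges_from(split.test_edges)
    union_components = nx.number_connected_components(full_graph)

    ranked_i, ranked_j = ci[order], cj[order]
    counts = []
    for rho in rho_values:
        k = math.floor(rho * n_cand)
        hit = ctest_ranked[:k]
        g = base_graph.copy()
        g.add_edges_from(zip(ranked_i[:k][hit].tolist(), ranked_j[:k][hit].tolist()))
        counts.append(nx.number_connected_components(g))
    return ReconnectionCurve(
        rho_values=rho_values,
        component_counts=tuple(counts),
        baseline_components=baseline,
        union_components=union_components,
    )
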