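"""Network propagation of mutation scores (random walk with restart).

The weighted adjacency matrix W of the cohort network is column-normalized,
W' = W D^-1 with D = diag of column sums, and per-sample scores are iterated

    S(t+1) = alpha * W' S(t) + (1 - alpha) * S(0)

until the maximum per-column L1 change drops below a tolerance. Because W'
is column-stochastic, the spectral radius of alpha*W' is at most alpha < 1,
so the iteration contracts geometrically and converges to the unique
non-negative stationary solution

    S = (1 - alpha) (I - alpha W')^-1 S(0),

which :func:`propagate_closed_form` computes directly and serves as the
verification oracle for the iterative path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .netio import WeightedNetwork

__all__ = [
    "NormalizedAdjacency",
    "PropagationConfig",
    "column_normalize",
    "align_seed",
    "propagate_iterative",
    "propagate_closed_form",
]

_DENSE_SOLVE_GUARD = 5000  # largest node count for the dense closed-form solve


@dataclass(frozen=True)
class PropagationConfig:
    """Propagation parameters: restart complement alpha, stopping tolerance, iteration cap."""

    alpha: float = 0.8
    tolerance: float = 1e-8
    max_iterations: int = 350

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1); got {self.alpha} (convergence requires alpha < 1)")
        if self.tolerance <= 0 or self.max_iterations < 1:
            raise ValueError("tolerance must be positive and max_iterations >= 1")


@dataclass(frozen=True)
class NormalizedAdjacency:
    """Column-stochastic W' over a fixed lexicographic node order."""

    matrix: sp.csr_matrix
    nodes: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.nodes)


def column_normalize(net: WeightedNetwork) -> NormalizedAdjacency:
    """W' = W D^-1 over the lexicographically ordered node list.

    Requires every node to have at least one edge (no zero column sums);
    netio guarantees this for largest-connected-component outputs.
    """
    nodes = tuple(sorted(net.graph.nodes))
    if not nodes:
        raise ValueError("cannot normalize an empty network")
    index = {n: i for i, n in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u, v, w in net.edges():
        i, j = index[u], index[v]
        rows.extend((i, j))
        cols.extend((j, i))
        vals.extend((w, w))
    W = sp.csr_matrix((vals, (rows, cols)), shape=(len(nodes), len(nodes)))
    colsum = np.asarray(W.sum(axis=0)).ravel()
    if (colsum <= 0).any():
        bad = [nodes[i] for i in np.flatnonzero(colsum <= 0)]
        raise ValueError(f"zero column sum for nodes {bad[:5]} — isolated nodes present")
    return NormalizedAdjacency(matrix=W @ sp.diags(1.0 / colsum), nodes=nodes)


def align_seed(scores: pd.DataFrame, adj: NormalizedAdjacency) -> tuple[np.ndarray, list[str]]:
    """Restrict a gene x sample score frame to the network's node order.

    Genes absent from the network are dropped (returned as the sidecar
    list); network genes absent from the frame seed at zero.
    """
    dropped = sorted(set(scores.index) - set(adj.nodes))
    seed = scores.reindex(list(adj.nodes), fill_value=0).to_numpy(dtype=float)
    return seed, dropped


def _check_seed(S0: np.ndarray, n: int) -> np.ndarray:
    S0 = np.asarray(S0, dtype=float)
    if S0.ndim == 1:
        S0 = S0[:, None]
    if S0.shape[0] != n:
        raise ValueError(f"seed has {S0.shape[0]} rows but the network has {n} nodes")
    if np.isnan(S0).any():
        raise ValueError("seed contains NaN")
    if (S0 < 0).any():
        raise ValueError("seed contains negative scores")
    return S0


def propagate_iterative(
    adj: NormalizedAdjacency,
    S0: np.ndarray,
    cfg: PropagationConfig = PropagationConfig(),
) -> tuple[np.ndarray, int, bool]:
    """Iterate to convergence; samples (columns) propagate independently.

    Returns ``(final, iterations_used, converged)``. Stops when the maximum
    per-column L1 change falls below ``cfg.tolerance`` or at
    ``cfg.max_iterations``.
    """
    S0 = _check_seed(S0, adj.n)
    W = adj.matrix
    a, restart = cfg.alpha, (1.0 - cfg.alpha) * S0
    S = S0.copy()
    for it in range(1, cfg.max_iterations + 1):
        S_next = a * (W @ S) + restart
        delta = np.abs(S_next - S).sum(axis=0).max()
        S = S_next
        if delta < cfg.tolerance:
            return S, it, True
    return S, cfg.max_iterations, False


def propagate_closed_form(adj: NormalizedAdjacency, S0: np.ndarray, alpha: float = 0.8) -> np.ndarray:
    """Exact stationary solution S = (1 - alpha)(I - alpha W')^-1 S(0) by dense solve."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if adj.n > _DENSE_SOLVE_GUARD:
        raise ValueError(f"closed-form solve guarded to <= {_DENSE_SOLVE_GUARD} nodes; got {adj.n}")
    S0 = _check_seed(S0, adj.n)
    A = np.eye(adj.n) - alpha * adj.matrix.toarray()
    S = np.linalg.solve(A, (1.0 - alpha) * S0)
    # (I - alpha W')^-1 is inverse-positive, so tiny negatives are round-off
    assert S.min() > -1e-9, "closed-form propagation produced negative scores"
    return np.clip(S, 0.0, None)
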