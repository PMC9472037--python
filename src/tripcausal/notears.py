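"""Continuous DAG structure learning with an acyclicity constraint.

Learns a weighted adjacency matrix W from a standardized trip table by
minimizing the penalized least-squares score

    (1/2n) * ||X - XW||_F^2 + lambda1 * ||W||_1

subject to the smooth acyclicity constraint h(W) = tr(exp(W o W)) - d = 0,
handled by an augmented Lagrangian with dual ascent. A-priori impossible
effects (e.g. from post-drive emotions back to pre-drive emotions) are
excluded by a forbidden-edge mask enforced by parameter elimination: masked
entries are not free variables, so they are exactly zero in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize

__all__ = [
    "NotearsOptions",
    "NotearsNonconvergence",
    "ForbiddenEdgeSet",
    "acyclicity_value",
    "notears_fit",
    "threshold_graph",
    "temporal_forbidden_set",
]

#: Temporal stage of each category; an edge may never point to a strictly
#: earlier stage, and nothing may point into predetermined factors.
_STAGE = {
    "predetermined": 0,
    "emotion_before": 1,
    "behavior": 2,
    "trip_factor": 2,
    "emotion_after": 3,
}


class NotearsNonconvergence(RuntimeError):
    """Acyclicity tolerance not reached; carries the best iterate found."""

    def __init__(self, message: str, W: np.ndarray, h: float):
        super().__init__(message)
        self.W = W
        self.h = h


@dataclass(frozen=True)
class NotearsOptions:
    """Hyperparameters of the continuous structure-learning optimizer.

    lambda1 is the L1 sparsity penalty, omega the post-hoc edge-pruning
    threshold; rho_* and h_tol drive the augmented-Lagrangian schedule. The
    published analysis prints no hyperparameters, so the defaults are the
    reference algorithm's customary settings; all are configurable.
    """

    lambda1: float = 0.1
    omega: float = 0.3
    rho_init: float = 1.0
    rho_max: float = 1e16
    rho_factor: float = 10.0
    h_tol: float = 1e-8
    max_outer: int = 100
    forbidden_mask: np.ndarray | None = None
    require_standardized: bool = True

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.omega < 0:
            raise ValueError("lambda1 and omega must be nonnegative")
        if self.rho_factor <= 1:
            raise ValueError("rho_factor must exceed 1")
        if self.h_tol <= 0:
            raise ValueError("h_tol must be positive")


class ForbiddenEdgeSet(frozenset):
    """A-priori excluded directed pairs (source, target).

    Behaves as a frozenset of label pairs; :meth:`mask` renders it as the
    boolean matrix the optimizer consumes.
    """

    def mask(self, nodes) -> np.ndarray:
        nodes = list(nodes)
        m = np.zeros((len(nodes), len(nodes)), dtype=bool)
        for s, t in self:
            if s not in nodes or t not in nodes:
                raise KeyError(f"forbidden pair ({s!r}, {t!r}) references unknown node")
            m[nodes.index(s), nodes.index(t)] = True
        return m


def temporal_forbidden_set(categories: dict[str, str]) -> ForbiddenEdgeSet:
    """Directed pairs excluded by the study's temporal ordering.

    Later stages cannot affect earlier ones: post-drive emotions cannot cause
    anything measured before or during the drive; driving behavior and
    trip-dependent factors cannot cause pre-drive emotions; and nothing causes
    the predetermined factors, which are fixed before the trip starts.
    """
    for node, cat in categories.items():
        if cat not in _STAGE:
            raise KeyError(f"unknown category {cat!r} for node {node!r}")
    pairs = set()
    for s, cs in categories.items():
        for t, ct in categories.items():
            if s == t:
                continue
            if ct == "predetermined" or _STAGE[ct] < _STAGE[cs]:
                pairs.add((s, t))
    return ForbiddenEdgeSet(pairs)


def acyclicity_value(W: np.ndarray) -> float:
    """h(W) = tr(exp(W o W)) - d; zero iff the support of W is acyclic."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"W must be square, got shape {W.shape}")
    E = scipy.linalg.expm(W * W)
    return float(np.trace(E) - W.shape[0])


def _h_and_grad(W: np.ndarray) -> tuple[float, np.ndarray]:
    E = scipy.linalg.expm(W * W)
    return float(np.trace(E) - W.shape[0]), E.T * W * 2.0


def notears_fit(
    X: np.ndarray,
    opts: NotearsOptions | None = None,
) -> np.ndarray:
    """Fit the weighted adjacency matrix of a linear SEM to data.

    Parameters
    ----------
    X
        n x d data matrix, no missing values. The method scores structures by
        least squares and is sensitive to variable scale, so standardized
        input is required unless ``opts.require_standardized`` is switched
        off (as in raw-scale recovery benchmarks).
    opts
        :class:`NotearsOptions`; ``opts.forbidden_mask`` entries are held at
        exactly zero throughout the optimization.

    Returns
    -------
    The unthresholded weight matrix W with h(W) <= opts.h_tol.

    Raises
    ------
    NotearsNonconvergence
        If the acyclicity tolerance is not reached before the penalty cap;
        the best iterate is attached to the exception.
    """
    opts = opts or NotearsOptions()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 rows")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; drop incomplete rows first")
    n, d = X.shape
    if opts.require_standardized:
        mu = np.abs(X.mean(axis=0)).max()
        sd = np.abs(X.std(axis=0, ddof=1) - 1.0).max()
        if mu > 1e-6 or sd > 1e-6:
            raise ValueError(
                "input is not standardized (the score is scale-sensitive); "
                "standardize first or set require_standardized=False"
            )

    mask = opts.forbidden_mask
    if mask is None:
        mask = np.zeros((d, d), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (d, d):
            raise ValueError(
                f"forbidden_mask shape {mask.shape} does not match d={d}"
            )
        mask = mask.copy()
    np.fill_diagonal(mask, True)  # no self-loops
    free = ~mask
    idx = np.flatnonzero(free.ravel())
    m = idx.size
    if m == 0:
        return np.zeros((d, d))

    G = X.T @ X  # Gram matrix: loss and gradient cost O(d^3), not O(nd^2)
    tr_G = float(np.trace(G))

    def unpack(theta: np.ndarray) -> np.ndarray:
        W = np.zeros(d * d)
        W[idx] = theta[:m] - theta[m:]
        return W.reshape(d, d)

    def objective(theta: np.ndarray, rho: float, alpha: float):
        W = unpack(theta)
        # least squares via the Gram matrix
        GW = G @ W
        loss = 0.5 / n * (tr_G - 2.0 * np.trace(GW) + float(np.sum(W * GW)))
        g_loss = (G @ (W - np.eye(d))) / n
        h, g_h = _h_and_grad(W)
        obj = loss + 0.5 * rho * h * h + alpha * h + opts.lambda1 * theta.sum()
        g_W = g_loss + (rho * h + alpha) * g_h
        g_flat = g_W.ravel()[idx]
        grad = np.concatenate([g_flat, -g_flat]) + opts.lambda1
        return obj, grad

    theta = np.zeros(2 * m)
    bounds = [(0.0, None)] * (2 * m)
    rho, alpha, h = opts.rho_init, 0.0, np.inf
    for _ in range(opts.max_outer):
        theta_new, h_new = theta, None
        while rho < opts.rho_max:
            sol = scipy.optimize.minimize(
                objective,
                theta,
                args=(rho, alpha),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
            )
            theta_new = sol.x
            h_new = acyclicity_value(unpack(theta_new))
            if h_new > 0.25 * h:
                rho *= opts.rho_factor
            else:
                break
        theta, h = theta_new, h_new if h_new is not None else h
        alpha += rho * h
        if h <= opts.h_tol or rho >= opts.rho_max:
            break
    W = unpack(theta)
    if h > opts.h_tol:
        raise NotearsNonconvergence(
            f"acyclicity constraint not met: h={h:.3e} > h_tol={opts.h_tol:.1e}",
            W,
            h,
        )
    return W


def threshold_graph(W: np.ndarray, omega: float, labels, categories=None):
    """Prune entries with ``|w| < omega`` and wrap the result as a CausalDAG.

    Raises if a directed cycle survives the pruning (possible only when the
    unthresholded W exceeded the acyclicity tolerance).
    """
    import networkx as nx

    from .graph import CausalDAG

    W = np.asarray(W, dtype=float)
    Wt = np.where(np.abs(W) >= omega, W, 0.0)
    support = nx.DiGraph(zip(*np.nonzero(Wt)))
    if not nx.is_directed_acyclic_graph(support):
        raise ValueError("thresholded weight matrix still contains a cycle")
    return CausalDAG.from_weight_matrix(Wt, labels, categories=categories)
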