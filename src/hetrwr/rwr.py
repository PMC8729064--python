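"""Random walk with restart to its stationary distribution.

The iteration is P^{t+1} = (1 - lambda) W^T P^t + lambda P^0 with W the
row-stochastic transition matrix (W_ij = probability of moving from i to
j), so propagation is column-stochastic and P stays a probability
distribution.  Convergence is declared when the L1 difference of successive
iterates drops below the tolerance (default 1e-6).  Since the update is a
contraction with factor (1 - lambda), at most ~log(tol)/log(1-lambda)
iterations are needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import scipy.sparse as sp

from .errors import ConvergenceError, ParameterError
from .registry import EntityRegistry, LayerLayout

__all__ = ["WalkResult", "walk", "closed_form", "rank_layer"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WalkResult:
    """Stationary distribution with convergence diagnostics."""

    p_inf: np.ndarray
    iterations: int
    residual: float


def _validate(p0: np.ndarray, lam: float) -> np.ndarray:
    p0 = np.asarray(p0, dtype=float).ravel()
    if (p0 < 0).any():
        raise ValueError("initial probability vector has negative entries")
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError(f"initial probability vector sums to {p0.sum()}, expected 1")
    if not 0.0 < lam <= 1.0:
        raise ParameterError(f"restart probability must lie in (0, 1], got {lam}")
    return p0


def walk(
    W: sp.spmatrix | np.ndarray,
    p0: np.ndarray,
    lam: float = 0.7,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> WalkResult:
    """Iterate the restart walk until the L1 residual drops below ``tol``.

    Dangling rows of W leak probability mass; any deficit is re-injected by
    renormalizing the iterate back to unit mass (logged once).
    """
    p0 = _validate(p0, lam)
    WT = W.T.tocsr() if sp.issparse(W) else np.asarray(W, dtype=float).T
    p = p0.copy()
    warned = False
    for t in range(1, max_iter + 1):
        p_next = (1.0 - lam) * (WT @ p) + lam * p0
        mass = p_next.sum()
        if mass < 1.0 - 1e-12:
            if not warned:
                logger.warning(
                    "dangling rows leak %.3e probability mass per step; renormalizing",
                    1.0 - mass,
                )
                warned = True
            p_next /= mass
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            return WalkResult(p, t, residual)
    raise ConvergenceError(max_iter, residual, tol)


def closed_form(W: sp.spmatrix | np.ndarray, p0: np.ndarray, lam: float) -> np.ndarray:
    """Exact fixed point lambda (I - (1-lambda) W^T)^{-1} P^0 by direct solve.

    Intended as a verification oracle on systems small enough for a dense
    factorization.
    """
    p0 = _validate(p0, lam)
    Wd = W.toarray() if sp.issparse(W) else np.asarray(W, dtype=float)
    A = np.eye(Wd.shape[0]) - (1.0 - lam) * Wd.T
    return lam * np.linalg.solve(A, p0)


def rank_layer(
    scores: np.ndarray | WalkResult,
    layout: LayerLayout,
    registry: EntityRegistry,
    exclude: Iterable[str] = (),
) -> list[tuple[str, float]]:
    """Entities of one layer sorted by stationary score, descending.

    Ties break by registry order, so rankings are deterministic.  Entities
    in ``exclude`` (e.g. known training associations) are dropped.
    """
    vec = scores.p_inf if isinstance(scores, WalkResult) else np.asarray(scores)
    layer_scores = vec[layout.block(registry.layer)]
    excluded = set(exclude)
    order = sorted(range(len(registry)), key=lambda i: (-layer_scores[i], i))
    return [
        (registry.ids[i], float(layer_scores[i]))
        for i in order
        if registry.ids[i] not in excluded
    ]
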