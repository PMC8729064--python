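"""Gaussian interaction profile (GIP) kernel similarity.

Each entity's interaction profile IP(i) is its binary association row (or
column) in a bipartite association matrix.  The kernel is

    G(i, j) = exp(-r * ||IP(i) - IP(j)||^2)

with a data-driven bandwidth r = r' / mean_i ||IP(i)||^2 (the *squared*
convention of the original kernel; the *literal* convention divides by the
mean unsquared norm instead) and regulation parameter r' = 1 by default.
Profiles are binary, so ||IP||^2 is simply the number of associations.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import DegenerateKernelError, ParameterError

__all__ = ["gip_bandwidth", "gip_similarity"]

_CONVENTIONS = ("squared", "literal")


def _profiles(matrix: np.ndarray, axis: str) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("profile matrix must be 2-dimensional")
    if axis == "rows":
        return m
    if axis == "columns":
        return m.T
    raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")


def gip_bandwidth(
    matrix: np.ndarray,
    axis: str = "rows",
    r_prime: float = 1.0,
    convention: str = "squared",
) -> float:
    """Kernel bandwidth r = r' / mean profile norm (squared or literal).

    The mean runs over *all* profiles along the axis, including all-zero
    ones; only an entirely zero profile set is degenerate.
    """
    if r_prime <= 0:
        raise ParameterError(f"r_prime must be > 0, got {r_prime}")
    if convention not in _CONVENTIONS:
        raise ParameterError(f"norm convention must be one of {_CONVENTIONS}, got {convention!r}")
    profiles = _profiles(matrix, axis)
    sq_norms = np.einsum("ij,ij->i", profiles, profiles)
    if not np.any(sq_norms):
        raise DegenerateKernelError(f"all profiles along {axis} are zero")
    mean = sq_norms.mean() if convention == "squared" else np.sqrt(sq_norms).mean()
    return float(r_prime / mean)


def gip_similarity(
    matrix: np.ndarray,
    axis: str = "rows",
    r_prime: float = 1.0,
    convention: str = "squared",
) -> np.ndarray:
    """Symmetric GIP kernel matrix with unit diagonal and entries in (0, 1]."""
    r = gip_bandwidth(matrix, axis=axis, r_prime=r_prime, convention=convention)
    profiles = _profiles(matrix, axis)
    if profiles.shape[0] == 1:
        return np.ones((1, 1))
    sq_dist = squareform(pdist(profiles, metric="sqeuclidean"))
    return np.exp(-r * sq_dist)
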