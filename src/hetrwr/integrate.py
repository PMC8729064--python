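"""Merge functional/semantic similarity with GIP kernel similarity.

The merged intra-layer similarity uses the functional (or semantic) value
for a pair of entities unless either member carries no functional
information, in which case the pair falls back to the interaction-profile
kernel.  The rule is a hard switch, not a blend.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .registry import EntityRegistry

__all__ = ["no_info_entities", "integrate"]


def no_info_entities(func_sim: np.ndarray, registry: EntityRegistry) -> frozenset[str]:
    """Entities whose functional-similarity row is zero off-diagonal."""
    m = np.asarray(func_sim)
    off = m - np.diag(np.diag(m))
    mask = ~off.any(axis=1)
    return frozenset(registry.ids[i] for i in np.flatnonzero(mask))


def integrate(
    func_sim: np.ndarray,
    gip_sim: np.ndarray,
    noinfo: Iterable[int] | np.ndarray,
) -> np.ndarray:
    """Entrywise switch: GIP where either index is no-information, else functional.

    ``noinfo`` is a boolean mask or an iterable of row indices.
    """
    func_sim = np.asarray(func_sim, dtype=float)
    gip_sim = np.asarray(gip_sim, dtype=float)
    if func_sim.shape != gip_sim.shape or func_sim.ndim != 2:
        raise ValueError(
            f"shape mismatch: functional {func_sim.shape} vs GIP {gip_sim.shape}"
        )
    n = func_sim.shape[0]
    mask = np.zeros(n, dtype=bool)
    noinfo = np.asarray(list(noinfo) if not isinstance(noinfo, np.ndarray) else noinfo)
    if noinfo.dtype == bool:
        if noinfo.shape != (n,):
            raise ValueError("boolean no-info mask has wrong length")
        mask = noinfo
    elif noinfo.size:
        mask[noinfo.astype(int)] = True
    pair = mask[:, None] | mask[None, :]
    return np.where(pair, gip_sim, func_sim)


def noinfo_indices(noinfo_ids: Iterable[str], registry: EntityRegistry) -> np.ndarray:
    """Translate no-information entity identifiers to registry indices."""
    return np.array(sorted(registry.index(e) for e in noinfo_ids), dtype=int)
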