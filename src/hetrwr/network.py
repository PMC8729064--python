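"""Assembly of the global 16-block Laplacian-normalized transition matrix.

The global network stacks the four layers in the fixed order lncRNA, miRNA,
gene, disease.  Each of the twelve inter-layer blocks is the Laplacian
normalization of the corresponding bipartite association matrix, row
normalized and scaled by its transition parameter P_XY (so every nonzero
row of an inter block sums exactly to P_XY).  Each of the four intra-layer
blocks is the Laplacian-normalized, row-normalized similarity matrix scaled
row-by-row with the residual mass 1 minus the sum of P_XY over the inter
blocks that are actually nonzero in that row: a node with no inter-layer
links keeps its full unit mass inside its own layer.  Rows of the assembled
matrix therefore sum to 1, except fully dangling nodes whose rows are zero.

Laplacian normalization of a nonnegative matrix A divides each entry by the
geometric mean of its row and column sums: A(i,j)/sqrt(rowsum_i*colsum_j),
with zero kept where either sum vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import ParameterError
from .registry import LAYERS, LayerLayout

__all__ = [
    "TransitionParams",
    "laplacian_normalize",
    "inter_block",
    "intra_block",
    "assemble_transition",
    "initial_vector",
]

#: Canonical (row-layer, column-layer) orientations of the six association matrices.
ASSOC_PAIRS: tuple[tuple[str, str], ...] = (
    ("lncRNA", "miRNA"),
    ("lncRNA", "gene"),
    ("lncRNA", "disease"),
    ("miRNA", "gene"),
    ("miRNA", "disease"),
    ("gene", "disease"),
)


@dataclass(frozen=True)
class TransitionParams:
    """The ten walk parameters.

    ``p_xy`` is the probability of jumping from layer X to layer Y (symmetric
    across direction); ``p_l/p_m/p_g`` weight the layers in the restart
    vector, the disease layer receiving ``1 - p_l - p_m - p_g``.
    """

    p_lm: float = 0.2
    p_lg: float = 0.2
    p_ld: float = 0.2
    p_mg: float = 0.2
    p_md: float = 0.2
    p_gd: float = 0.2
    p_l: float = 0.4
    p_m: float = 0.1
    p_g: float = 0.1

    def __post_init__(self):
        for name in ("p_lm", "p_lg", "p_ld", "p_mg", "p_md", "p_gd", "p_l", "p_m", "p_g"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        sums = {
            "p_lm+p_lg+p_ld": self.p_lm + self.p_lg + self.p_ld,
            "p_lm+p_mg+p_md": self.p_lm + self.p_mg + self.p_md,
            "p_lg+p_mg+p_gd": self.p_lg + self.p_mg + self.p_gd,
            "p_ld+p_md+p_gd": self.p_ld + self.p_md + self.p_gd,
            "p_l+p_m+p_g": self.p_l + self.p_m + self.p_g,
        }
        for name, s in sums.items():
            if s > 1.0 + 1e-12:
                raise ParameterError(f"constraint {name} <= 1 violated (sum {s})")

    _KEY = {"lncRNA": "l", "miRNA": "m", "gene": "g", "disease": "d"}

    def inter(self, x: str, y: str) -> float:
        """P_XY for an ordered layer pair (symmetric: P_XY = P_YX)."""
        a, b = self._KEY[x], self._KEY[y]
        for attr in (f"p_{a}{b}", f"p_{b}{a}"):
            if hasattr(self, attr):
                return getattr(self, attr)
        raise KeyError(f"no inter-layer parameter for {x}->{y}")

    def layer_weight(self, layer: str) -> float:
        return {
            "lncRNA": self.p_l,
            "miRNA": self.p_m,
            "gene": self.p_g,
            "disease": 1.0 - self.p_l - self.p_m - self.p_g,
        }[layer]


def laplacian_normalize(matrix: np.ndarray) -> np.ndarray:
    """A(i,j) / sqrt(rowsum_i * colsum_j), zero where either sum vanishes."""
    a = np.asarray(matrix, dtype=float)
    if (a < 0).any():
        raise ValueError("Laplacian normalization requires a nonnegative matrix")
    rs = a.sum(axis=1)
    cs = a.sum(axis=0)
    denom = np.sqrt(np.outer(rs, cs))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, a / denom, 0.0)
    return out


def _row_normalize(a: np.ndarray) -> np.ndarray:
    rs = a.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(rs > 0, a / rs, 0.0)


def inter_block(assoc: np.ndarray, p_xy: float) -> np.ndarray:
    """Inter-layer transition block: each nonzero row sums exactly to p_xy."""
    if not 0.0 <= p_xy <= 1.0:
        raise ParameterError(f"inter-layer probability must lie in [0, 1], got {p_xy}")
    return p_xy * _row_normalize(laplacian_normalize(assoc))


def intra_block(
    sim: np.ndarray,
    inter_row_nonzero: Sequence[np.ndarray],
    inter_params: Sequence[float],
) -> np.ndarray:
    """Intra-layer block with per-row residual mass.

    ``inter_row_nonzero`` holds one boolean vector per companion layer
    marking which rows of that (normalized) inter block are nonzero;
    ``inter_params`` the matching P_XY values.  Row i of the result is the
    row-normalized Laplacian-normalized similarity row scaled by
    ``1 - sum of P_XY over active inter blocks``; rows with zero similarity
    stay zero (dangling if no inter links either).
    """
    flags = np.stack([np.asarray(v, dtype=bool) for v in inter_row_nonzero], axis=1)
    ps = np.asarray(inter_params, dtype=float)
    if flags.shape[1] != ps.size:
        raise ValueError("one parameter required per inter block")
    residual = 1.0 - flags @ ps
    if (residual < -1e-12).any():
        raise ParameterError("negative residual intra-layer mass; parameter sums exceed 1")
    return np.clip(residual, 0.0, None)[:, None] * _row_normalize(laplacian_normalize(sim))


def assemble_transition(
    sims: Mapping[str, np.ndarray],
    assocs: Mapping[tuple[str, str], np.ndarray],
    params: TransitionParams,
) -> tuple[sp.csr_matrix, LayerLayout]:
    """Assemble the row-stochastic global transition matrix W.

    ``sims`` maps each layer to its integrated similarity matrix; ``assocs``
    maps the six canonical (row-layer, col-layer) pairs to binary
    association matrices.  Returns W in CSR form together with the layer
    layout of its rows/columns.
    """
    sizes = {layer: np.asarray(sims[layer]).shape[0] for layer in LAYERS}
    lap: dict[tuple[str, str], np.ndarray] = {}
    for (x, y) in ASSOC_PAIRS:
        a = np.asarray(assocs[(x, y)], dtype=float)
        if a.shape != (sizes[x], sizes[y]):
            raise ValueError(
                f"association {x}-{y} has shape {a.shape}, expected {(sizes[x], sizes[y])}"
            )
        ln = laplacian_normalize(a)
        lap[(x, y)] = ln
        lap[(y, x)] = ln.T

    blocks: list[list[sp.spmatrix | None]] = []
    for x in LAYERS:
        row: list[sp.spmatrix | None] = []
        others = [y for y in LAYERS if y != x]
        flags = [lap[(x, y)].sum(axis=1) > 0 for y in others]
        ps = [params.inter(x, y) for y in others]
        intra = intra_block(sims[x], flags, ps)
        for y in LAYERS:
            if y == x:
                row.append(sp.csr_matrix(intra))
            else:
                row.append(sp.csr_matrix(params.inter(x, y) * _row_normalize(lap[(x, y)])))
        blocks.append(row)
    W = sp.bmat(blocks, format="csr")
    return W, LayerLayout(tuple(sizes[layer] for layer in LAYERS))


def initial_vector(
    seeds: Mapping[str, Sequence[int]],
    params: TransitionParams,
    layout: LayerLayout,
) -> np.ndarray:
    """Restart vector: per-layer uniform mass over seeds, weighted by layer.

    A layer with no seeds forfeits its weight, which is redistributed
    proportionally over the seeded layers so the vector still sums to 1.
    """
    weights = {layer: params.layer_weight(layer) for layer in LAYERS}
    seeded = [layer for layer in LAYERS if len(seeds.get(layer, ())) > 0]
    if not seeded:
        raise ValueError("no seed nodes in any layer")
    total = sum(weights[layer] for layer in seeded)
    if total <= 0:
        raise ValueError("all seeded layers carry zero weight; restart vector undefined")
    p0 = np.zeros(layout.total)
    for layer in seeded:
        idx = np.asarray(list(seeds[layer]), dtype=int)
        if idx.min() < 0 or idx.max() >= layout.size(layer):
            raise IndexError(f"seed index out of range for layer {layer}")
        p0[layout.offset(layer) + idx] = weights[layer] / total / idx.size
    return p0
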