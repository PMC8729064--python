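"""Entity registries and the fixed layer layout of the global network.

Every matrix in the package is indexed by an :class:`EntityRegistry`: an
ordered list of unique identifiers whose position is the row/column index
everywhere (0-based).  The four layers are always stacked in the order
lncRNA, miRNA, gene, disease when the global transition matrix is built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import UnknownTermError

#: Canonical layer order used for block stacking (L, M, G, D).
LAYERS: tuple[str, ...] = ("lncRNA", "miRNA", "gene", "disease")


@dataclass(frozen=True)
class EntityRegistry:
    """Ordered, duplicate-free identifiers for one layer."""

    layer: str
    ids: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        index = {}
        for i, ident in enumerate(self.ids):
            if ident in index:
                raise ValueError(f"duplicate identifier {ident!r} in {self.layer} registry")
            index[ident] = i
        object.__setattr__(self, "_index", index)

    @classmethod
    def from_ids(cls, layer: str, ids: Iterable[str]) -> "EntityRegistry":
        """Build a registry, keeping first-seen order and dropping repeats."""
        seen: dict[str, None] = {}
        for ident in ids:
            seen.setdefault(str(ident).strip(), None)
        return cls(layer, tuple(seen))

    def index(self, ident: str) -> int:
        try:
            return self._index[ident]
        except KeyError:
            raise UnknownTermError(f"{ident!r} not in {self.layer} registry") from None

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, ident: object) -> bool:
        return ident in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self.ids)


@dataclass(frozen=True)
class LayerLayout:
    """Sizes and offsets of the four stacked layers inside global vectors/matrices."""

    sizes: tuple[int, int, int, int]

    @classmethod
    def from_registries(cls, registries: dict[str, EntityRegistry]) -> "LayerLayout":
        return cls(tuple(len(registries[layer]) for layer in LAYERS))

    @property
    def total(self) -> int:
        return sum(self.sizes)

    def offset(self, layer: str) -> int:
        i = LAYERS.index(layer)
        return sum(self.sizes[:i])

    def size(self, layer: str) -> int:
        return self.sizes[LAYERS.index(layer)]

    def block(self, layer: str) -> slice:
        """Slice selecting a layer's entries in a stacked vector."""
        start = self.offset(layer)
        return slice(start, start + self.size(layer))
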