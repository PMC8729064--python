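"""Wang-method semantic similarity on ontology DAGs and best-match-average
functional similarity between annotated entities.

The model: every ontology term ``T`` induces a sub-DAG of its ancestor
closure ``Ans(T)`` (including ``T``).  Each ancestor ``d`` contributes
``Delta^k`` to the semantic value of ``T``, where ``k`` is the length of the
shortest descending path from ``d`` down to ``T`` and ``Delta`` in (0,1) is
the attenuation factor (the max rule over children realises this).  Two
terms are compared by the contributions of their shared ancestors relative
to their total semantic values; two entities (each annotated by a set of
terms) are compared by the best-match average of those term similarities.

This applies identically to diseases on a disease-ontology DAG and to genes
annotated with GO terms; lncRNA/miRNA "annotations" are their associated
disease sets, so the same machinery yields their functional similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import ParameterError, UnknownTermError
from .registry import EntityRegistry

__all__ = [
    "OntologyDAG",
    "contribution_table",
    "semantic_value",
    "term_similarity",
    "set_similarity",
    "entity_similarity",
    "similarity_matrix",
    "term_similarity_matrix",
    "annotations_from_matrix",
]


class OntologyDAG:
    """A rooted-or-not directed acyclic graph of terms, stored child -> parents.

    Parameters
    ----------
    parent_edges:
        Mapping ``child -> iterable of parents``.  Terms appearing only as
        parents are declared implicitly.
    terms:
        Optional extra terms with no edges.
    """

    def __init__(self, parent_edges: Mapping[str, Iterable[str]], terms: Iterable[str] = ()):
        parents: dict[str, frozenset[str]] = {}
        declared: set[str] = set(terms)
        for child, ps in parent_edges.items():
            ps = frozenset(ps)
            if child in ps:
                raise ValueError(f"self-loop at term {child!r}")
            parents[child] = ps
            declared.add(child)
            declared |= ps
        self._parents = {t: parents.get(t, frozenset()) for t in declared}
        children: dict[str, set[str]] = {t: set() for t in declared}
        for child, ps in self._parents.items():
            for p in ps:
                children[p].add(child)
        self._children = {t: frozenset(c) for t, c in children.items()}
        self._terms = frozenset(declared)
        self._assert_acyclic()
        self._anc_cache: dict[str, frozenset[str]] = {}

    def _assert_acyclic(self) -> None:
        # Kahn's algorithm on the child->parent graph.
        indeg = {t: len(self._parents[t]) for t in self._terms}
        queue = [t for t, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            t = queue.pop()
            seen += 1
            for c in self._children[t]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if seen != len(self._terms):
            raise ValueError("ontology graph contains a cycle")

    @property
    def terms(self) -> frozenset[str]:
        return self._terms

    def __contains__(self, term: object) -> bool:
        return term in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def parents(self, term: str) -> frozenset[str]:
        self._check(term)
        return self._parents[term]

    def children(self, term: str) -> frozenset[str]:
        self._check(term)
        return self._children[term]

    def ancestors(self, term: str) -> frozenset[str]:
        """Ancestor closure of ``term``, including ``term`` itself."""
        self._check(term)
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        closure: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in closure:
                continue
            closure.add(t)
            stack.extend(self._parents[t])
        result = frozenset(closure)
        self._anc_cache[term] = result
        return result

    def _check(self, term: str) -> None:
        if term not in self._terms:
            raise UnknownTermError(f"unknown ontology term {term!r}")


def _check_delta(delta: float) -> float:
    delta = float(delta)
    if not 0.0 < delta < 1.0:
        raise ParameterError(f"attenuation factor must lie in (0, 1), got {delta}")
    return delta


def contribution_table(dag: OntologyDAG, anchor: str, delta: float) -> dict[str, float]:
    """Semantic contribution of every ancestor of ``anchor`` to its semantic value.

    The anchor contributes 1 to itself; any other ancestor ``d`` contributes
    ``max(delta * contribution(child))`` over its children inside the
    anchor's ancestor closure.
    """
    delta = _check_delta(delta)
    anc = dag.ancestors(anchor)
    table: dict[str, float] = {anchor: 1.0}

    def value(d: str) -> float:
        got = table.get(d)
        if got is not None:
            return got
        v = max(delta * value(c) for c in dag.children(d) if c in anc)
        table[d] = v
        return v

    for d in anc:
        value(d)
    return table


def semantic_value(table: Mapping[str, float]) -> float:
    """Sum of all contributions; >= 1 since the anchor contributes 1."""
    if not table:
        raise ValueError("empty contribution table")
    return float(sum(table.values()))


def term_similarity(dag: OntologyDAG, t1: str, t2: str, delta: float) -> float:
    """Shared-ancestor contribution ratio between two terms; in [0, 1]."""
    tab1 = contribution_table(dag, t1, delta)
    tab2 = contribution_table(dag, t2, delta)
    shared = tab1.keys() & tab2.keys()
    if not shared:
        return 0.0
    num = sum(tab1[d] + tab2[d] for d in shared)
    return float(num / (semantic_value(tab1) + semantic_value(tab2)))


def set_similarity(dag: OntologyDAG, term: str, group: Iterable[str], delta: float) -> float:
    """Best match of ``term`` against a nonempty group of terms."""
    group = list(group)
    if not group:
        raise ValueError("term group must be nonempty")
    return max(term_similarity(dag, term, g, delta) for g in group)


def entity_similarity(
    ann: Mapping[str, frozenset[str]],
    dag: OntologyDAG,
    e1: str,
    e2: str,
    delta: float,
) -> float | None:
    """Best-match-average similarity of two annotated entities.

    Returns ``None`` when either entity carries no annotations (the caller
    records it as a no-information entity; the integration step then falls
    back to the interaction-profile kernel).
    """
    s1 = ann.get(e1) or frozenset()
    s2 = ann.get(e2) or frozenset()
    if not s1 or not s2:
        return None
    fwd = sum(set_similarity(dag, t, s2, delta) for t in s1)
    bwd = sum(set_similarity(dag, t, s1, delta) for t in s2)
    return float((fwd + bwd) / (len(s1) + len(s2)))


def term_similarity_matrix(dag: OntologyDAG, terms: list[str], delta: float) -> np.ndarray:
    """Dense pairwise term-similarity matrix with one contribution table per term."""
    delta = _check_delta(delta)
    tabs = [contribution_table(dag, t, delta) for t in terms]
    dvs = [semantic_value(tab) for tab in tabs]
    n = len(terms)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            shared = tabs[i].keys() & tabs[j].keys()
            if shared:
                num = sum(tabs[i][d] + tabs[j][d] for d in shared)
                out[i, j] = out[j, i] = num / (dvs[i] + dvs[j])
    return out


@dataclass(frozen=True)
class _SimResult:
    matrix: np.ndarray
    noinfo: frozenset[str]

    def __iter__(self):  # allow `matrix, noinfo = similarity_matrix(...)`
        return iter((self.matrix, self.noinfo))


def similarity_matrix(
    registry: EntityRegistry,
    ann: Mapping[str, frozenset[str]],
    dag: OntologyDAG,
    delta: float,
) -> _SimResult:
    """Batch best-match-average similarity over a registry.

    Entities without annotations get an all-zero row/column and are reported
    in the no-information set.  Annotated entities have unit diagonal.
    """
    used: dict[str, int] = {}
    sets: list[np.ndarray | None] = []
    noinfo: set[str] = set()
    for e in registry:
        terms = ann.get(e) or frozenset()
        for t in terms:
            if t not in dag:
                raise UnknownTermError(f"annotation term {t!r} of {e!r} not in ontology")
            used.setdefault(t, len(used))
        if terms:
            sets.append(np.array(sorted(used[t] for t in terms), dtype=int))
        else:
            sets.append(None)
            noinfo.add(e)

    ts = term_similarity_matrix(dag, list(used), delta) if used else np.zeros((0, 0))
    n = len(registry)
    out = np.zeros((n, n))
    for i in range(n):
        si = sets[i]
        if si is None:
            continue
        out[i, i] = 1.0
        for j in range(i + 1, n):
            sj = sets[j]
            if sj is None:
                continue
            sub = ts[np.ix_(si, sj)]
            bma = (sub.max(axis=1).sum() + sub.max(axis=0).sum()) / (len(si) + len(sj))
            out[i, j] = out[j, i] = bma
    return _SimResult(out, frozenset(noinfo))


def annotations_from_matrix(
    assoc: np.ndarray,
    row_registry: EntityRegistry,
    col_registry: EntityRegistry,
) -> dict[str, frozenset[str]]:
    """Derive entity -> associated-term sets from a binary bipartite matrix rows."""
    assoc = np.asarray(assoc)
    out: dict[str, frozenset[str]] = {}
    for i, e in enumerate(row_registry):
        cols = np.flatnonzero(assoc[i])
        if cols.size:
            out[e] = frozenset(col_registry.ids[j] for j in cols)
    return out
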