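"""Synthetic four-layer benchmark data with planted community structure.

The generator emulates the shape of curated lncRNA/miRNA/gene/disease
association compendia without any download: every entity is assigned to one
of C communities, each of the six bipartite association matrices draws an
edge with probability ``p_in`` when the two endpoints share a community and
``p_out`` otherwise, the disease-ontology DAG places each community's
diseases under a community-specific clade (so same-community diseases share
ancestors and hence high semantic similarity), and genes are annotated with
GO terms drawn from their community's clade of a synthetic GO DAG.

All randomness flows through one ``numpy.random.default_rng`` stream seeded
from the spec, so a given spec reproduces the identical dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ontology import OntologyDAG
from .pipeline import HeteroDataset
from .registry import EntityRegistry

logger = logging.getLogger(__name__)

__all__ = ["SynthSpec", "SyntheticDataset", "random_dag", "planted_network"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the planted-structure benchmark (defaults = the
    package's standard test conditions)."""

    n_lncrna: int = 40
    n_mirna: int = 40
    n_gene: int = 60
    n_disease: int = 20
    n_communities: int = 2
    p_in: float = 0.3
    p_out: float = 0.02
    dag_depth: int = 3
    dag_branching: int = 2
    go_terms_per_community: int = 6
    max_annotations_per_gene: int = 3
    seed: int = 42

    def __post_init__(self):
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        for n in (self.n_lncrna, self.n_mirna, self.n_gene, self.n_disease):
            if n < self.n_communities:
                raise ValueError("every layer must hold at least one entity per community")
        if self.n_communities < 1:
            raise ValueError("need at least one community")


@dataclass
class SyntheticDataset:
    """A generated dataset plus its planted ground truth."""

    data: HeteroDataset
    communities: dict[str, np.ndarray] = field(default_factory=dict)
    spec: SynthSpec | None = None


def random_dag(
    depth: int,
    branching: int,
    seed: int | None = None,
    prefix: str = "T",
    extra_parent_prob: float = 0.0,
    rng: np.random.Generator | None = None,
) -> OntologyDAG:
    """A rooted layered DAG: ``depth`` levels, ``branching`` children per node.

    Children only point to earlier levels, so the result is acyclic by
    construction.  With ``extra_parent_prob`` > 0 each non-root node may
    gain one extra random parent from any earlier level (multi-parent DAGs).
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    levels: list[list[str]] = [[f"{prefix}0_0"]]
    edges: dict[str, set[str]] = {}
    for lvl in range(1, depth):
        nodes = []
        for i in range(branching ** lvl):
            name = f"{prefix}{lvl}_{i}"
            parent = levels[lvl - 1][i // branching]
            edges[name] = {parent}
            if extra_parent_prob > 0 and rng.random() < extra_parent_prob:
                earlier = [t for level in levels for t in level if t != parent]
                if earlier:
                    edges[name].add(earlier[rng.integers(len(earlier))])
            nodes.append(name)
        levels.append(nodes)
    return OntologyDAG(edges, terms=[levels[0][0]])


def _planted_bipartite(
    rng: np.random.Generator,
    comm_a: np.ndarray,
    comm_b: np.ndarray,
    p_in: float,
    p_out: float,
) -> np.ndarray:
    prob = np.where(comm_a[:, None] == comm_b[None, :], p_in, p_out)
    return (rng.random(prob.shape) < prob).astype(float)


def planted_network(spec: SynthSpec | None = None, max_attempts: int = 10) -> SyntheticDataset:
    """Generate registries, the six association matrices, both DAGs, and
    annotations, with community structure planted across all layers."""
    spec = spec or SynthSpec()
    rng = np.random.default_rng(spec.seed)
    C = spec.n_communities

    sizes = {
        "lncRNA": spec.n_lncrna,
        "miRNA": spec.n_mirna,
        "gene": spec.n_gene,
        "disease": spec.n_disease,
    }
    prefixes = {"lncRNA": "LNC", "miRNA": "MIR", "gene": "GEN", "disease": "DIS"}
    registries = {
        layer: EntityRegistry.from_ids(
            layer, (f"{prefixes[layer]}{i:03d}" for i in range(n))
        )
        for layer, n in sizes.items()
    }
    communities = {
        layer: rng.permutation(np.arange(n) % C) for layer, n in sizes.items()
    }

    # Disease ontology: root -> one clade node per community -> a short chain
    # -> the community's diseases, so same-community diseases share three
    # ancestors while cross-community pairs share only the root.
    d_edges: dict[str, set[str]] = {}
    for c in range(C):
        d_edges[f"CLADE{c}"] = {"ROOT"}
        d_edges[f"CLADE{c}_CORE"] = {f"CLADE{c}"}
    for i, d in enumerate(registries["disease"]):
        d_edges[d] = {f"CLADE{communities['disease'][i]}_CORE"}
    disease_dag = OntologyDAG(d_edges)

    # GO DAG with the same clade trick; genes annotated from their clade.
    go_edges: dict[str, set[str]] = {}
    go_terms: dict[int, list[str]] = {}
    for c in range(C):
        go_edges[f"GO:CLADE{c}"] = {"GO:ROOT"}
        go_terms[c] = []
        for j in range(spec.go_terms_per_community):
            term = f"GO:{c}_{j:02d}"
            go_edges[term] = {f"GO:CLADE{c}"}
            go_terms[c].append(term)
    go_dag = OntologyDAG(go_edges)
    gene_annotations: dict[str, frozenset[str]] = {}
    for i, g in enumerate(registries["gene"]):
        pool = go_terms[int(communities["gene"][i])]
        k = int(rng.integers(1, spec.max_annotations_per_gene + 1))
        picked = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        gene_annotations[g] = frozenset(pool[j] for j in picked)

    cl, cm, cg, cd = (
        communities["lncRNA"],
        communities["miRNA"],
        communities["gene"],
        communities["disease"],
    )
    for attempt in range(max_attempts):
        mats = {
            "ld": _planted_bipartite(rng, cl, cd, spec.p_in, spec.p_out),
            "lm": _planted_bipartite(rng, cl, cm, spec.p_in, spec.p_out),
            "lg": _planted_bipartite(rng, cl, cg, spec.p_in, spec.p_out),
            "mg": _planted_bipartite(rng, cm, cg, spec.p_in, spec.p_out),
            "md": _planted_bipartite(rng, cm, cd, spec.p_in, spec.p_out),
            "gd": _planted_bipartite(rng, cg, cd, spec.p_in, spec.p_out),
        }
        if all(m.any() for m in mats.values()):
            break
        logger.warning("a layer drew zero edges (attempt %d); regenerating", attempt + 1)
    else:
        raise RuntimeError("could not draw a non-degenerate network; increase p_in or sizes")

    data = HeteroDataset(
        registries=registries,
        disease_dag=disease_dag,
        go_dag=go_dag,
        gene_annotations=gene_annotations,
        **mats,
    )
    return SyntheticDataset(data=data, communities=communities, spec=spec)
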