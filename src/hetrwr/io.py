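"""Readers and writers for the package's plain-text formats.

Edge lists, ontologies and annotations are two-column TSV ('#' comments and
blank lines skipped, identifiers whitespace-trimmed, case preserved);
similarity/transition matrices travel as MatrixMarket with a one-column
node-order sidecar; a dataset directory bundles the six edge lists, both
DAGs, the gene annotations and per-layer node lists so that isolated nodes
survive a round trip.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from .errors import InputFormatError
from .ontology import OntologyDAG
from .pipeline import HeteroDataset
from .registry import LAYERS, EntityRegistry

logger = logging.getLogger(__name__)

__all__ = [
    "read_pairs",
    "read_edge_list",
    "build_assoc",
    "read_ontology_tsv",
    "read_obo",
    "read_annotations",
    "write_matrix",
    "read_matrix",
    "write_rankings",
    "write_dataset",
    "read_dataset",
    "write_manifest",
]


def _rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        yield lineno, [f.strip() for f in line.rstrip("\n").split("\t")]


def read_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV -> ordered (a, b) identifier pairs (duplicates kept)."""
    pairs: list[tuple[str, str]] = []
    for lineno, fields in _rows(path):
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise InputFormatError("expected two tab-separated identifiers", path, lineno)
        pairs.append((fields[0], fields[1]))
    return pairs


def build_assoc(
    pairs: Sequence[tuple[str, str]],
    reg_a: EntityRegistry,
    reg_b: EntityRegistry,
) -> np.ndarray:
    """Binary association matrix over fixed registries; duplicates collapsed."""
    m = np.zeros((len(reg_a), len(reg_b)))
    dupes = 0
    for a, b in pairs:
        i, j = reg_a.index(a), reg_b.index(b)
        if m[i, j]:
            dupes += 1
        m[i, j] = 1.0
    if dupes:
        logger.warning("collapsed %d duplicate %s-%s edges", dupes, reg_a.layer, reg_b.layer)
    return m


def read_edge_list(
    path: str | Path, layer_a: str, layer_b: str
) -> tuple[np.ndarray, EntityRegistry, EntityRegistry]:
    """Read a bipartite TSV and build registries from first-seen order."""
    if layer_a == layer_b:
        raise InputFormatError(f"self-layer edge list ({layer_a}) is not bipartite", path)
    pairs = read_pairs(path)
    reg_a = EntityRegistry.from_ids(layer_a, (a for a, _ in pairs))
    reg_b = EntityRegistry.from_ids(layer_b, (b for _, b in pairs))
    return build_assoc(pairs, reg_a, reg_b), reg_a, reg_b


def read_ontology_tsv(path: str | Path) -> OntologyDAG:
    """child<TAB>parent rows -> OntologyDAG (terms seen only as parents included)."""
    edges: dict[str, set[str]] = {}
    for child, parent in read_pairs(path):
        edges.setdefault(child, set()).add(parent)
    return OntologyDAG(edges)


def read_obo(path: str | Path) -> OntologyDAG:
    """Minimal OBO subset: only ``id:`` and ``is_a:`` tags inside [Term] stanzas."""
    edges: dict[str, set[str]] = {}
    terms: set[str] = set()
    current: str | None = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line == "[Term]":
            current = None
        elif line.startswith("id:"):
            current = line[3:].strip()
            terms.add(current)
        elif line.startswith("is_a:") and current is not None:
            parent = line[5:].strip().split("!")[0].strip()
            edges.setdefault(current, set()).add(parent)
    return OntologyDAG(edges, terms=terms)


def read_annotations(path: str | Path) -> dict[str, frozenset[str]]:
    """entity<TAB>term rows -> deduplicated entity -> term-set map."""
    out: dict[str, set[str]] = {}
    for entity, term in read_pairs(path):
        out.setdefault(entity, set()).add(term)
    return {e: frozenset(s) for e, s in out.items()}


# ---------------------------------------------------------------------------
# matrices and rankings


def write_matrix(matrix, path: str | Path, node_order: Sequence[str] | None = None) -> None:
    """MatrixMarket output (symmetric header when applicable) + optional sidecar."""
    path = Path(path)
    m = matrix if sp.issparse(matrix) else sp.coo_matrix(np.asarray(matrix))
    symmetry = "general"
    if m.shape[0] == m.shape[1]:
        diff = abs(m - m.T)
        if diff.nnz == 0 or abs(diff).max() == 0:
            symmetry = "symmetric"
    scipy.io.mmwrite(str(path), m, symmetry=symmetry, precision=12)
    if node_order is not None:
        path.with_suffix(path.suffix + ".index").write_text(
            "".join(f"{ident}\n" for ident in node_order)
        )


def read_matrix(path: str | Path) -> np.ndarray:
    m = scipy.io.mmread(str(path))
    return m.toarray() if sp.issparse(m) else np.asarray(m)


def write_rankings(ranks: Sequence[tuple], path: str | Path, header: Sequence[str]) -> None:
    """Rank table as TSV with a 1-based rank column and 12-significant-digit floats."""
    lines = ["\t".join(["rank", *header])]
    for i, row in enumerate(ranks, start=1):
        cells = [f"{v:.12g}" if isinstance(v, float) else str(v) for v in row]
        lines.append("\t".join([str(i), *cells]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# dataset directories

_ASSOC_FILES = {
    "ld": ("lncRNA", "disease"),
    "lm": ("lncRNA", "miRNA"),
    "lg": ("lncRNA", "gene"),
    "mg": ("miRNA", "gene"),
    "md": ("miRNA", "disease"),
    "gd": ("gene", "disease"),
}


def write_dataset(data: HeteroDataset, outdir: str | Path) -> None:
    """Write a dataset as TSV files readable by :func:`read_dataset`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for layer in LAYERS:
        (outdir / f"nodes_{layer}.txt").write_text(
            "".join(f"{e}\n" for e in data.registry(layer))
        )
    for name, (la, lb) in _ASSOC_FILES.items():
        m = getattr(data, name)
        reg_a, reg_b = data.registry(la), data.registry(lb)
        lines = [f"# {la}\t{lb}"]
        for i, j in np.argwhere(m == 1):
            lines.append(f"{reg_a.ids[i]}\t{reg_b.ids[j]}")
        (outdir / f"{name}.tsv").write_text("\n".join(lines) + "\n")
    for fname, dag in (("disease_dag.tsv", data.disease_dag), ("go_dag.tsv", data.go_dag)):
        lines = ["# child\tparent"]
        for term in sorted(dag.terms):
            for parent in sorted(dag.parents(term)):
                lines.append(f"{term}\t{parent}")
        (outdir / fname).write_text("\n".join(lines) + "\n")
    lines = ["# gene\tgo_term"]
    for gene in data.registry("gene"):
        for term in sorted(data.gene_annotations.get(gene, frozenset())):
            lines.append(f"{gene}\t{term}")
    (outdir / "gene_annotations.tsv").write_text("\n".join(lines) + "\n")


def read_dataset(indir: str | Path) -> HeteroDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    indir = Path(indir)
    registries = {
        layer: EntityRegistry.from_ids(
            layer, (indir / f"nodes_{layer}.txt").read_text().split()
        )
        for layer in LAYERS
    }
    mats = {}
    for name, (la, lb) in _ASSOC_FILES.items():
        pairs = read_pairs(indir / f"{name}.tsv")
        mats[name] = build_assoc(pairs, registries[la], registries[lb])
    return HeteroDataset(
        registries=registries,
        disease_dag=read_ontology_tsv(indir / "disease_dag.tsv"),
        go_dag=read_ontology_tsv(indir / "go_dag.tsv"),
        gene_annotations=read_annotations(indir / "gene_annotations.tsv"),
        **mats,
    )


def write_manifest(path: str | Path, config_dict: dict, inputs: Sequence[str | Path], seed: int) -> None:
    """Record config hash, input checksums and seed for bit-reproduction."""
    checksums = {}
    for p in inputs:
        p = Path(p)
        if p.is_file():
            checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "input_sha256": checksums,
        "seed": seed,
        "version": "0.1.0",
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
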