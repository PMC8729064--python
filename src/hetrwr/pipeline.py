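"""End-to-end glue: dataset container, similarity construction, prediction.

A :class:`HeteroDataset` holds the four entity registries, the six binary
association matrices in canonical orientation (lncRNA x miRNA, lncRNA x
gene, lncRNA x disease, miRNA x gene, miRNA x disease, gene x disease), the
disease ontology, and the GO DAG with gene annotations.

:class:`SimilarityBuilder` caches every similarity that does not depend on
the lncRNA-disease matrix (disease semantic, miRNA functional from
miRNA-disease links, gene functional from GO, miRNA/gene GIP from the
miRNA-gene matrix) and rebuilds the LD-derived pieces (lncRNA functional
similarity, lncRNA/disease GIP) for any training version of LD — the hook
that keeps cross-validation free of test-label leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import scipy.sparse as sp

from .config import RunConfig
from .gip import gip_similarity
from .integrate import integrate, noinfo_indices
from .network import ASSOC_PAIRS, assemble_transition, initial_vector
from .ontology import OntologyDAG, annotations_from_matrix, similarity_matrix
from .registry import LAYERS, EntityRegistry, LayerLayout
from .rwr import WalkResult, rank_layer, walk

logger = logging.getLogger(__name__)

__all__ = ["HeteroDataset", "SimilarityBuilder", "seed_sets", "predict_disease"]


@dataclass
class HeteroDataset:
    """All inputs of a run, with matrices indexed by the registries."""

    registries: dict[str, EntityRegistry]
    ld: np.ndarray  # lncRNA x disease
    lm: np.ndarray  # lncRNA x miRNA
    lg: np.ndarray  # lncRNA x gene
    mg: np.ndarray  # miRNA x gene
    md: np.ndarray  # miRNA x disease
    gd: np.ndarray  # gene x disease
    disease_dag: OntologyDAG
    go_dag: OntologyDAG
    gene_annotations: dict[str, frozenset[str]]

    def __post_init__(self):
        n = {layer: len(self.registries[layer]) for layer in LAYERS}
        expected = {
            "ld": (n["lncRNA"], n["disease"]),
            "lm": (n["lncRNA"], n["miRNA"]),
            "lg": (n["lncRNA"], n["gene"]),
            "mg": (n["miRNA"], n["gene"]),
            "md": (n["miRNA"], n["disease"]),
            "gd": (n["gene"], n["disease"]),
        }
        for name, shape in expected.items():
            m = np.asarray(getattr(self, name))
            if m.shape != shape:
                raise ValueError(f"{name} has shape {m.shape}, expected {shape}")
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"association matrix {name} must be binary")
            setattr(self, name, m.astype(float))

    def registry(self, layer: str) -> EntityRegistry:
        return self.registries[layer]

    def n(self, layer: str) -> int:
        return len(self.registries[layer])

    def assoc_dict(self, ld: np.ndarray | None = None) -> dict[tuple[str, str], np.ndarray]:
        """The six associations keyed by canonical layer pair; LD overridable."""
        mats = {
            ("lncRNA", "miRNA"): self.lm,
            ("lncRNA", "gene"): self.lg,
            ("lncRNA", "disease"): self.ld if ld is None else ld,
            ("miRNA", "gene"): self.mg,
            ("miRNA", "disease"): self.md,
            ("gene", "disease"): self.gd,
        }
        assert set(mats) == set(ASSOC_PAIRS)
        return mats

    @property
    def positive_pairs(self) -> np.ndarray:
        """Known lncRNA-disease pairs as an (n, 2) index array."""
        return np.argwhere(self.ld == 1)


class SimilarityBuilder:
    """Builds the four integrated intra-layer similarity matrices.

    Everything independent of the lncRNA-disease matrix is computed once at
    construction; :meth:`build` takes the (possibly fold-masked) LD matrix
    and returns the final LL/MM/GG/DD dictionary plus per-layer
    no-information sets.
    """

    def __init__(self, data: HeteroDataset, config: RunConfig | None = None):
        self.data = data
        self.config = config or RunConfig()
        cfg = self.config
        d_reg = data.registry("disease")

        # Disease semantic similarity: each disease annotated by itself in the DO DAG.
        d_ann = {d: frozenset([d]) for d in d_reg if d in data.disease_dag}
        self._ds, self._noinfo_d = similarity_matrix(
            d_reg, d_ann, data.disease_dag, cfg.delta_disease
        )

        # miRNA functional similarity from miRNA-disease association rows.
        m_reg = data.registry("miRNA")
        m_ann = annotations_from_matrix(data.md, m_reg, d_reg)
        m_ann = {e: s & data.disease_dag.terms for e, s in m_ann.items()}
        m_ann = {e: s for e, s in m_ann.items() if s}
        ms, noinfo_m = similarity_matrix(m_reg, m_ann, data.disease_dag, cfg.delta_disease)

        # Gene functional similarity from GO annotations.
        g_reg = data.registry("gene")
        gs, noinfo_g = similarity_matrix(
            g_reg, data.gene_annotations, data.go_dag, cfg.delta_go
        )

        # miRNA and gene GIP kernels come from the miRNA-gene matrix.
        gam = gip_similarity(data.mg, "rows", cfg.gip_r_prime, cfg.gip_norm_convention)
        gag = gip_similarity(data.mg, "columns", cfg.gip_r_prime, cfg.gip_norm_convention)
        self._mm = integrate(ms, gam, noinfo_indices(noinfo_m, m_reg))
        self._gg = integrate(gs, gag, noinfo_indices(noinfo_g, g_reg))
        self._noinfo_m, self._noinfo_g = noinfo_m, noinfo_g

    def build(
        self, ld: np.ndarray | None = None
    ) -> tuple[dict[str, np.ndarray], dict[str, frozenset[str]]]:
        """Integrated similarities for a given (training) LD matrix."""
        data, cfg = self.data, self.config
        ld = data.ld if ld is None else np.asarray(ld, dtype=float)
        l_reg, d_reg = data.registry("lncRNA"), data.registry("disease")

        l_ann = annotations_from_matrix(ld, l_reg, d_reg)
        l_ann = {e: s & data.disease_dag.terms for e, s in l_ann.items()}
        l_ann = {e: s for e, s in l_ann.items() if s}
        ls, noinfo_l = similarity_matrix(l_reg, l_ann, data.disease_dag, cfg.delta_disease)

        gal = gip_similarity(ld, "rows", cfg.gip_r_prime, cfg.gip_norm_convention)
        gad = gip_similarity(ld, "columns", cfg.gip_r_prime, cfg.gip_norm_convention)

        sims = {
            "lncRNA": integrate(ls, gal, noinfo_indices(noinfo_l, l_reg)),
            "miRNA": self._mm,
            "gene": self._gg,
            "disease": integrate(self._ds, gad, noinfo_indices(self._noinfo_d, d_reg)),
        }
        noinfo = {
            "lncRNA": noinfo_l,
            "miRNA": self._noinfo_m,
            "gene": self._noinfo_g,
            "disease": self._noinfo_d,
        }
        return sims, noinfo

    def transition(
        self, ld: np.ndarray | None = None, sims: Mapping[str, np.ndarray] | None = None
    ) -> tuple[sp.csr_matrix, LayerLayout]:
        """Assemble W for a given training LD (similarities rebuilt unless given)."""
        if sims is None:
            sims, _ = self.build(ld)
        return assemble_transition(sims, self.data.assoc_dict(ld), self.config.params)


def seed_sets(
    data: HeteroDataset,
    query_layer: str,
    query_index: int,
    ld: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Seed node indices per layer for a query disease or lncRNA.

    For a disease d: its known lncRNAs/miRNAs/genes (via LD/MD/GD columns)
    plus d itself.  For an lncRNA l: the mirror image via the LD/LM/LG rows.
    """
    ld = data.ld if ld is None else np.asarray(ld)
    if query_layer == "disease":
        return {
            "lncRNA": np.flatnonzero(ld[:, query_index]),
            "miRNA": np.flatnonzero(data.md[:, query_index]),
            "gene": np.flatnonzero(data.gd[:, query_index]),
            "disease": np.array([query_index]),
        }
    if query_layer == "lncRNA":
        return {
            "lncRNA": np.array([query_index]),
            "miRNA": np.flatnonzero(data.lm[query_index]),
            "gene": np.flatnonzero(data.lg[query_index]),
            "disease": np.flatnonzero(ld[query_index]),
        }
    raise ValueError(f"queries must be diseases or lncRNAs, got layer {query_layer!r}")


def predict_disease(
    data: HeteroDataset,
    disease: str,
    config: RunConfig | None = None,
    builder: SimilarityBuilder | None = None,
) -> tuple[list[tuple[str, float, bool]], WalkResult]:
    """Rank candidate lncRNAs for one disease on the full known data.

    Returns (lncRNA id, stationary score, is-known-association) triples in
    rank order, plus the raw walk result.
    """
    config = config or RunConfig()
    builder = builder or SimilarityBuilder(data, config)
    d_idx = data.registry("disease").index(disease)
    W, layout = builder.transition()
    p0 = initial_vector(seed_sets(data, "disease", d_idx), config.params, layout)
    result = walk(W, p0, lam=config.lam, tol=config.tol, max_iter=config.max_iter)
    ranking = rank_layer(result, layout, data.registry("lncRNA"))
    known = {
        data.registry("lncRNA").ids[i] for i in np.flatnonzero(data.ld[:, d_idx])
    }
    return [(name, score, name in known) for name, score in ranking], result
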