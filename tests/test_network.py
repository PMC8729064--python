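"""Laplacian normalization, block construction and global assembly."""

import numpy as np
import pytest
import scipy.sparse as sp

from hetrwr import (
    LAYERS,
    ParameterError,
    TransitionParams,
    assemble_transition,
    initial_vector,
    inter_block,
    intra_block,
    laplacian_normalize,
)
from hetrwr.registry import LayerLayout


class TestLaplacianNormalize:
    @pytest.mark.parametrize(
        "matrix, expected",
        [
            ([[0, 2], [2, 0]], [[0, 1], [1, 0]]),
            ([[1, 1], [1, 1]], [[0.5, 0.5], [0.5, 0.5]]),
            ([[0, 0], [0, 0]], [[0, 0], [0, 0]]),
        ],
    )
    def test_worked_examples(self, matrix, expected):
        np.testing.assert_allclose(laplacian_normalize(np.array(matrix)), expected, atol=1e-15)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            laplacian_normalize(np.array([[1.0, -1.0], [0.0, 0.0]]))

    def test_symmetric_input_stays_symmetric_with_spectral_radius_le_one(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.random((8, 8))
            a = (a + a.T) / 2
            norm = laplacian_normalize(a)
            np.testing.assert_allclose(norm, norm.T, atol=1e-14)
            assert np.abs(np.linalg.eigvalsh(norm)).max() <= 1 + 1e-10


class TestInterBlock:
    def test_single_edge(self):
        out = inter_block(np.array([[1.0, 0.0], [0.0, 0.0]]), 0.2)
        np.testing.assert_allclose(out, [[0.2, 0.0], [0.0, 0.0]], atol=1e-15)

    def test_symmetric_split_of_one_row(self):
        np.testing.assert_allclose(
            inter_block(np.array([[1.0, 1.0]]), 0.2), [[0.1, 0.1]], atol=1e-15
        )

    def test_zero_probability_zeroes_the_block(self):
        assert not inter_block(np.array([[1.0, 1.0], [0.0, 1.0]]), 0.0).any()

    def test_nonzero_rows_sum_to_parameter_exactly(self):
        rng = np.random.default_rng(1)
        a = (rng.random((7, 5)) < 0.4).astype(float)
        out = inter_block(a, 0.2)
        rs = out.sum(axis=1)
        nz = a.any(axis=1)
        np.testing.assert_allclose(rs[nz], 0.2, atol=1e-12)
        assert not rs[~nz].any()


class TestIntraBlock:
    def test_all_inter_active_leaves_residual_mass(self):
        sim = np.ones((2, 2))
        flags = [np.array([True, True])] * 3
        out = intra_block(sim, flags, [0.2, 0.2, 0.2])
        np.testing.assert_allclose(out.sum(axis=1), 0.4, atol=1e-12)

    def test_isolated_row_keeps_full_mass(self):
        sim = np.ones((2, 2))
        flags = [np.array([False, False])] * 3
        out = intra_block(sim, flags, [0.2, 0.2, 0.2])
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_similarity_row_dangles(self):
        sim = np.array([[1.0, 0.0], [0.0, 0.0]])
        flags = [np.array([False, False])] * 3
        out = intra_block(sim, flags, [0.2, 0.2, 0.2])
        assert out[0].sum() == pytest.approx(1.0) and not out[1].any()

    def test_negative_residual_rejected(self):
        with pytest.raises(ParameterError):
            intra_block(np.ones((1, 1)), [np.array([True])] * 3, [0.5, 0.4, 0.3])


def _tiny_inputs(rng, sizes=(5, 4, 6, 3), density=0.5):
    sims, assocs = {}, {}
    n = dict(zip(LAYERS, sizes))
    for layer in LAYERS:
        a = rng.random((n[layer], n[layer]))
        sims[layer] = (a + a.T) / 2 + np.eye(n[layer])
    from hetrwr.network import ASSOC_PAIRS

    for x, y in ASSOC_PAIRS:
        assocs[(x, y)] = (rng.random((n[x], n[y])) < density).astype(float)
    return sims, assocs


class TestAssembly:
    def test_one_node_per_layer_fully_connected(self):
        sims = {layer: np.ones((1, 1)) for layer in LAYERS}
        from hetrwr.network import ASSOC_PAIRS

        assocs = {pair: np.ones((1, 1)) for pair in ASSOC_PAIRS}
        W, layout = assemble_transition(sims, assocs, TransitionParams())
        W = W.toarray()
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(np.diag(W), 0.4)  # 1 - 3 * 0.2 intra mass
        assert layout.sizes == (1, 1, 1, 1)

    def test_no_associations_gives_block_diagonal_intra(self):
        rng = np.random.default_rng(2)
        sims, assocs = _tiny_inputs(rng)
        assocs = {pair: np.zeros_like(a) for pair, a in assocs.items()}
        W, layout = assemble_transition(sims, assocs, TransitionParams())
        W = W.toarray()
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)
        for layer in LAYERS:
            block = layout.block(layer)
            outside = W[block].copy()
            outside[:, block] = 0.0
            assert not outside.any()

    def test_row_stochastic_and_inter_mass_exact(self):
        rng = np.random.default_rng(9)
        sims, assocs = _tiny_inputs(rng)
        params = TransitionParams()
        W, layout = assemble_transition(sims, assocs, params)
        W = W.toarray()
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-10)
        # each nonzero inter-block row carries exactly its parameter mass
        for (x, y), a in assocs.items():
            bx, by = layout.block(x), layout.block(y)
            inter = W[bx, by]
            rs = inter.sum(axis=1)
            nz = a.any(axis=1)
            np.testing.assert_allclose(rs[nz], params.inter(x, y), atol=1e-12)

    def test_permutation_equivariance_within_a_layer(self):
        rng = np.random.default_rng(12)
        sims, assocs = _tiny_inputs(rng)
        W, layout = assemble_transition(sims, assocs, TransitionParams())
        perm = rng.permutation(layout.size("lncRNA"))
        sims2 = dict(sims)
        sims2["lncRNA"] = sims["lncRNA"][np.ix_(perm, perm)]
        assocs2 = dict(assocs)
        for (x, y), a in assocs.items():
            if x == "lncRNA":
                assocs2[(x, y)] = a[perm]
        W2, _ = assemble_transition(sims2, assocs2, TransitionParams())
        full = np.arange(layout.total)
        full[layout.block("lncRNA")] = perm
        np.testing.assert_allclose(
            W2.toarray(), W.toarray()[np.ix_(full, full)], atol=1e-12
        )


class TestTransitionParams:
    def test_defaults_are_the_operating_point(self):
        p = TransitionParams()
        assert p.p_lm == p.p_gd == 0.2 and (p.p_l, p.p_m, p.p_g) == (0.4, 0.1, 0.1)
        assert p.layer_weight("disease") == pytest.approx(0.4)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p_lm": 0.5, "p_lg": 0.4, "p_ld": 0.3},
            {"p_l": 0.8, "p_m": 0.3},
            {"p_lm": -0.1},
            {"p_ld": 1.2},
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            TransitionParams(**kwargs)


class TestInitialVector:
    def test_layer_weighted_uniform_seeds(self):
        layout = LayerLayout((2, 1, 1, 1))
        seeds = {"lncRNA": [0, 1], "miRNA": [0], "gene": [0], "disease": [0]}
        p0 = initial_vector(seeds, TransitionParams(), layout)
        np.testing.assert_allclose(p0, [0.2, 0.2, 0.1, 0.1, 0.4], atol=1e-15)
        assert p0.sum() == pytest.approx(1.0)

    def test_novel_disease_redistributes_to_disease_layer(self):
        layout = LayerLayout((2, 2, 2, 2))
        p0 = initial_vector({"disease": [1]}, TransitionParams(), layout)
        assert p0[layout.offset("disease") + 1] == pytest.approx(1.0)
        assert p0.sum() == pytest.approx(1.0)

    def test_empty_layer_weight_shared_proportionally(self):
        layout = LayerLayout((1, 1, 1, 1))
        p0 = initial_vector({"lncRNA": [0], "disease": [0]}, TransitionParams(), layout)
        np.testing.assert_allclose(p0, [0.5, 0.0, 0.0, 0.5], atol=1e-15)

    def test_unit_layer_weight_concentrates(self):
        layout = LayerLayout((3, 1, 1, 1))
        params = TransitionParams(p_l=1.0, p_m=0.0, p_g=0.0)
        p0 = initial_vector({"lncRNA": [2], "disease": [0]}, params, layout)
        assert p0[2] == pytest.approx(1.0) and p0.sum() == pytest.approx(1.0)

    def test_no_seeds_anywhere_rejected(self):
        with pytest.raises(ValueError):
            initial_vector({}, TransitionParams(), LayerLayout((1, 1, 1, 1)))
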