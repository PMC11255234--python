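"""Network correctness: LPE, residual graph convolutions, pooling, head."""

import math

import numpy as np
import pytest

import odorgraph as og
from odorgraph.autodiff import Tensor
from odorgraph.model import MoleculeFeatures, featurize_for_model, pad_batch
from odorgraph.training import LossSpec, loss_tensor

from conftest import random_toy_molecule


def zero_all(model):
    for p in model.parameters():
        p.data[:] = 0.0


def small_config(**kw):
    defaults = dict(o=2, p=4, d=8, lpe_heads=2, n_gcn_layers=2, seed=0)
    defaults.update(kw)
    return og.ModelConfig(**defaults)


def selu(x):
    scale, alpha = 1.0507009873554805, 1.6732632423543772
    return scale * (x if x > 0 else alpha * (math.exp(x) - 1.0))


def naive_gcn_layer(H, X, Wg, bg, Wl, bl):
    """Straight-line loop reimplementation of the residual graph convolution."""
    n, d = H.shape[0], Wg.shape[1]
    out = np.zeros((n, d))
    for a in range(n):
        for k in range(d):
            msg = 0.0
            for b in range(n):
                inner = sum(H[b, j] * Wg[j, k] for j in range(H.shape[1]))
                msg += X[a, b] * inner
            lin = sum(H[a, j] * Wl[j, k] for j in range(H.shape[1]))
            out[a, k] = selu(msg + bg[k]) + lin + bl[k]
    return out


class TestLPE:
    def test_zero_inputs_and_zero_parameters_give_zero_encoding(self):
        model = og.init_parameters(small_config(init_mode="lpe", bias=False))
        zero_all(model)
        h0 = model.lpe_encode(np.zeros((1, 3, 4, 2)))
        assert (h0.data == 0).all()

    def test_identical_spectral_rows_give_identical_embeddings(self):
        model = og.init_parameters(small_config(init_mode="lpe"))
        lam = np.random.default_rng(0).normal(size=(4, 2))
        inputs = np.stack([lam, lam])[None]  # two atoms, same spectral input
        h0 = model.lpe_encode(inputs)
        np.testing.assert_allclose(h0.data[0, 0], h0.data[0, 1], atol=1e-12)

    def test_atom_permutation_permutes_encoding_rows(self):
        model = og.init_parameters(small_config(init_mode="lpe"))
        rng = np.random.default_rng(1)
        inputs = rng.normal(size=(1, 5, 4, 2))
        perm = rng.permutation(5)
        a = model.lpe_encode(inputs).data[0]
        b = model.lpe_encode(inputs[:, perm]).data[0]
        np.testing.assert_allclose(b, a[perm], atol=1e-12)


class TestGCNLayer:
    def test_matches_naive_loop_reimplementation(self):
        cfg = small_config(init_mode="random", d=6, h=6, n_gcn_layers=1)
        model = og.init_parameters(cfg)
        rng = np.random.default_rng(5)
        H = rng.normal(size=(1, 5, 6))
        X = rng.normal(size=(1, 5, 5))
        X = (X + X.transpose(0, 2, 1)) / 2
        out = model.gcn_layer(Tensor(H), Tensor(X), 0, Tensor(np.ones((1, 5, 1))))
        expected = naive_gcn_layer(
            H[0], X[0],
            model.w_graph[0].weight.data, model.w_graph[0].bias.data,
            model.w_linear[0].weight.data, model.w_linear[0].bias.data,
        )
        np.testing.assert_allclose(out.data[0], expected, rtol=1e-6, atol=1e-9)

    def test_zero_graph_reduces_to_linear_path(self):
        cfg = small_config(init_mode="random", bias=False)
        model = og.init_parameters(cfg)
        rng = np.random.default_rng(2)
        H = rng.normal(size=(1, 4, 8))
        out = model.gcn_layer(Tensor(H), Tensor(np.zeros((1, 4, 4))), 0,
                              Tensor(np.ones((1, 4, 1))))
        np.testing.assert_allclose(out.data, H @ model.w_linear[0].weight.data, atol=1e-12)

    def test_identity_wiring_gives_selu(self):
        cfg = small_config(init_mode="random", d=8, h=8, bias=False)
        model = og.init_parameters(cfg)
        model.w_graph[0].weight.data = np.eye(8)
        model.w_linear[0].weight.data[:] = 0.0
        rng = np.random.default_rng(3)
        H = rng.normal(size=(1, 4, 8))
        out = model.gcn_layer(Tensor(H), Tensor(np.eye(4)[None]), 0,
                              Tensor(np.ones((1, 4, 1))))
        expected = np.vectorize(selu)(H)
        np.testing.assert_allclose(out.data, expected, rtol=1e-12)


@pytest.fixture(scope="module")
def molecule_features():
    rng = np.random.default_rng(42)
    cfg = small_config(init_mode="lpe")
    mols = [random_toy_molecule(rng, 4, 9) for _ in range(20)]
    return cfg, mols


class TestForward:
    def test_invariant_to_atom_permutation(self, molecule_features):
        cfg, mols = molecule_features
        model = og.init_parameters(cfg)
        rng = np.random.default_rng(0)
        for mol in mols:
            feats = featurize_for_model(mol, cfg)
            m0, y0 = model.predict([feats])
            for _ in range(5):
                perm = rng.permutation(mol.n_atoms)
                permuted = og.Molecule(
                    "p", "", [mol.atomic_numbers[i] for i in perm],
                    mol.coordinates[perm], [],
                )
                m1, y1 = model.predict([featurize_for_model(permuted, cfg)])
                np.testing.assert_allclose(m1, m0, atol=1e-5)
                np.testing.assert_allclose(y1, y0, atol=1e-5)

    def test_zero_head_gives_half_probability(self, molecule_features):
        cfg, mols = molecule_features
        model = og.init_parameters(cfg)
        model.w_clf.weight.data[:] = 0.0
        model.w_clf.bias.data[:] = 0.0
        _, y = model.predict([featurize_for_model(mols[0], cfg)])
        np.testing.assert_allclose(y, 0.5, atol=1e-15)

    def test_duplicate_molecule_in_batch_gets_identical_outputs(self, molecule_features):
        cfg, mols = molecule_features
        model = og.init_parameters(cfg)
        f = featurize_for_model(mols[0], cfg)
        m, y = model.predict([f, f])
        np.testing.assert_allclose(m[0], m[1], atol=1e-12)
        np.testing.assert_allclose(y[0], y[1], atol=1e-12)

    def test_padding_does_not_change_outputs(self, molecule_features):
        """Masked atoms contribute exactly zero to pooling and messages."""
        cfg, mols = molecule_features
        model = og.init_parameters(cfg)
        small = featurize_for_model(mols[0], cfg)
        big = featurize_for_model(max(mols, key=lambda m: m.n_atoms), cfg)
        assert big.n_atoms > small.n_atoms
        m_solo, y_solo = model.predict([small])
        m_pad, y_pad = model.predict([small, big])
        np.testing.assert_allclose(m_pad[0], m_solo[0], atol=1e-12)
        np.testing.assert_allclose(y_pad[0], y_solo[0], atol=1e-12)

    def test_sum_pool_is_size_extensive_in_random_mode(self):
        cfg = small_config(init_mode="random", bias=False)
        model = og.init_parameters(cfg)
        rng = np.random.default_rng(8)
        a = random_toy_molecule(rng, 3, 5)
        b = random_toy_molecule(rng, 3, 5)
        fa = featurize_for_model(a, cfg)
        fb = featurize_for_model(b, cfg)
        X = np.zeros((fa.n_atoms + fb.n_atoms,) * 2)
        X[: fa.n_atoms, : fa.n_atoms] = fa.X
        X[fa.n_atoms :, fa.n_atoms :] = fb.X
        combined = MoleculeFeatures(
            "ab", X, np.concatenate([fa.atomic_numbers, fb.atomic_numbers]), None
        )
        m_ab, _ = model.predict([combined])
        m_a, _ = model.predict([fa])
        m_b, _ = model.predict([fb])
        np.testing.assert_allclose(m_ab, m_a + m_b, atol=1e-9)


class TestParameters:
    def test_initialization_is_seed_deterministic(self):
        a = og.init_parameters(small_config(seed=5))
        b = og.init_parameters(small_config(seed=5))
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            assert np.array_equal(pa.data, pb.data)
        c = og.init_parameters(small_config(seed=6))
        assert any(
            not np.array_equal(pa.data, pc.data)
            for (_, pa), (_, pc) in zip(a.named_parameters(), c.named_parameters())
        )

    def test_shapes_match_config(self):
        cfg = small_config(o=7, d=8, init_mode="lpe")
        model = og.init_parameters(cfg)
        assert model.lpe_w0.weight.shape == (2, 8)
        assert model.w_clf.weight.shape == (8, 7)
        for l in range(cfg.n_gcn_layers):
            assert model.w_graph[l].weight.shape[1] == 8

    def test_checkpoint_round_trip_is_bit_exact(self, tmp_path):
        model = og.init_parameters(small_config(init_mode="lpe", seed=3))
        path = tmp_path / "ckpt.zip"
        model.save(path)
        loaded = og.OdorPredictor.load(path)
        assert loaded.config == model.config
        for (_, p0), (_, p1) in zip(model.named_parameters(), loaded.named_parameters()):
            assert np.array_equal(p0.data, p1.data)

    def test_presets_cover_the_three_architectures(self):
        adj = og.preset("adjacency_gcn", o=3)
        assert adj.init_mode == "random" and adj.matrix_source == "adjacency"
        cgcn = og.preset("coulomb_gcn", o=3)
        assert cgcn.init_mode == "random" and cgcn.matrix_source == "coulomb-frobenius"
        sym = og.preset("lpe_sym", o=3)
        assert sym.init_mode == "lpe" and sym.laplacian_kind == "symmetric"
        asym = og.preset("lpe_asym", o=3)
        assert asym.laplacian_kind == "asymmetric"


class TestGradients:
    def test_head_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(11)
        cfg = small_config(init_mode="lpe", o=3)
        model = og.init_parameters(cfg)
        mols = [random_toy_molecule(rng, 3, 6) for _ in range(3)]
        batch = pad_batch([featurize_for_model(m, cfg) for m in mols])
        y_true = rng.integers(0, 2, size=(3, 3)).astype(float)
        spec = LossSpec(np.array([0.9, 0.5, 0.7]))

        def loss_value():
            _, y = model.forward(batch)
            return float(loss_tensor(y, y_true, spec).data)

        for p in model.parameters():
            p.grad = None
        _, y = model.forward(batch)
        loss_tensor(y, y_true, spec).backward()
        W = model.w_clf.weight
        eps = 1e-6
        for (i, j) in [(0, 0), (3, 1), (7, 2)]:
            orig = W.data[i, j]
            W.data[i, j] = orig + eps
            hi = loss_value()
            W.data[i, j] = orig - eps
            lo = loss_value()
            W.data[i, j] = orig
            fd = (hi - lo) / (2 * eps)
            assert W.grad[i, j] == pytest.approx(fd, rel=1e-4)
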