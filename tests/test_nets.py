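"""Equivariance and correctness of the EGNN/GVP message-passing layers."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from keydiff.autodiff import Tensor
from keydiff.nets import EGNNLayer, GVP, GVPLayer, NodeState, egnn_layer, gvp_layer
from keydiff.nn import RBF_NUM, rbf_expand


def full_edges(n):
    return np.array([(i, j) for i in range(n) for j in range(n) if i != j])


def rigid(rng):
    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.normal(0, 5, size=3)
    return R, t


class TestEGNN:
    def test_empty_edge_list_leaves_positions_unchanged(self, rng):
        layer = EGNNLayer(8, rng)
        h, x = Tensor(rng.normal(size=(4, 8))), Tensor(rng.normal(size=(4, 3)))
        h2, x2 = layer(h, x, np.empty((0, 2)))
        assert np.array_equal(x2.data, x.data)

    def test_rigid_motion_equivariance(self, rng):
        layer = EGNNLayer(8, rng)
        h = rng.normal(size=(6, 8))
        x = rng.normal(0, 3, size=(6, 3))
        edges = full_edges(6)
        h1, x1 = layer(Tensor(h), Tensor(x), edges)
        R, t = rigid(rng)
        h2, x2 = layer(Tensor(h), Tensor(x @ R.T + t), edges)
        assert np.allclose(h1.data, h2.data, atol=1e-10)
        assert np.allclose(x1.data @ R.T + t, x2.data, atol=1e-10)

    def test_hand_computed_two_node_update(self, rng):
        """With φ_x forced to output 1 and a 2-node graph, the coordinate
        update must equal Σ_j (x_i−x_j)/(‖x_i−x_j‖+1) exactly."""
        layer = EGNNLayer(4, rng)
        # force message MLP output to a constant via zero weights + bias
        layer.phi_e.lin1.weight.data[:] = 0.0
        layer.phi_e.lin1.bias.data[:] = 0.0
        layer.phi_e.lin2.weight.data[:] = 0.0
        layer.phi_e.lin2.bias.data[:] = 1.0  # pre-activation 1 → silu(1)
        layer.phi_x.weight.data[:] = 0.0
        layer.phi_x.weight.data[0, 0] = 1.0 / (1.0 / (1.0 + np.exp(-1.0)))  # φ_x(m)=m₀/silu(1)=1
        x = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        h = np.zeros((2, 4))
        _, x2 = layer(Tensor(h), Tensor(x), np.array([(0, 1), (1, 0)]))
        # node 1 receives from node 0: Δ = (x1−x0)·1/(2+1) = (2/3, 0, 0)
        assert np.allclose(x2.data[1], [2 + 2 / 3, 0, 0], atol=1e-12)
        assert np.allclose(x2.data[0], [-2 / 3, 0, 0], atol=1e-12)

    def test_movable_mask_freezes_context_nodes(self, rng):
        layer = EGNNLayer(8, rng)
        h, x = rng.normal(size=(5, 8)), rng.normal(size=(5, 3))
        mask = np.array([0, 0, 1, 1, 1.0])
        _, x2 = layer(Tensor(h), Tensor(x), full_edges(5), movable_mask=mask)
        assert np.array_equal(x2.data[:2], x[:2])
        assert not np.allclose(x2.data[2:], x[2:])


class TestGVP:
    def test_zero_vectors_give_rotation_invariant_scalars(self, rng):
        gvp = GVP(6, 2, 5, 3, rng)
        s = Tensor(rng.normal(size=(4, 6)))
        v = Tensor(np.zeros((4, 2, 3)))
        s1, v1 = gvp(s, v)
        assert np.allclose(v1.data, 0)
        R, _ = rigid(rng)
        s2, _ = gvp(s, Tensor(np.zeros((4, 2, 3)) @ R.T))
        assert np.allclose(s1.data, s2.data)

    def test_hand_computed_single_vector_gating(self, rng):
        """One vector channel (1,0,0) through identity mixes: the output
        vector must be the input scaled by sigmoid(gate(scalar_out))."""
        gvp = GVP(1, 1, 1, 1, rng)
        gvp.w_h.data[:] = 1.0
        gvp.w_mu.data[:] = 1.0
        gvp.scalar.weight.data[:] = 0.0
        gvp.scalar.bias.data[:] = 0.7
        gvp.gate.weight.data[:] = 0.0
        gvp.gate.bias.data[:] = -0.2
        s, v = gvp(Tensor(np.zeros((1, 1))), Tensor(np.array([[[1.0, 0, 0]]])))
        gate = 1 / (1 + np.exp(0.2))
        silu07 = 0.7 / (1 + np.exp(-0.7))
        assert np.allclose(v.data, [[[gate, 0, 0]]], atol=1e-12)
        assert np.allclose(s.data, [[silu07]], atol=1e-12)

    def test_layer_equivariance_and_translation_invariance(self, rng):
        layer = GVPLayer(8, 4, rng)
        h = rng.normal(size=(6, 8))
        x = rng.normal(0, 3, size=(6, 3))
        v = rng.normal(size=(6, 4, 3))
        edges = full_edges(6)
        h1, v1 = layer(Tensor(h), Tensor(x), Tensor(v), edges)
        R, t = rigid(rng)
        h2, v2 = layer(Tensor(h), Tensor(x @ R.T + t), Tensor(v @ R.T), edges)
        assert np.allclose(h1.data, h2.data, atol=1e-10)
        assert np.allclose(v1.data @ R.T, v2.data, atol=1e-10)

    def test_missing_vector_features_rejected(self, rng):
        states = [NodeState(h=np.zeros(4), x=np.zeros(3)) for _ in range(2)]
        with pytest.raises(ValueError):
            gvp_layer(states, np.array([(0, 1)]), GVPLayer(4, 2, rng))


class TestProperties:
    @pytest.mark.parametrize("backbone", ["egnn", "gvp"])
    def test_equivariance_suite_over_random_motions(self, backbone, rng):
        """Max deviation of the equivariance identity stays < 1e-8 in double
        precision over 100 random rigid motions and random graphs."""
        worst = 0.0
        layer = None
        for trial in range(100):
            n = int(rng.integers(3, 30))
            h = rng.normal(size=(n, 8))
            x = rng.normal(0, 4, size=(n, 3))
            edges = full_edges(n)
            R, t = rigid(rng)
            if backbone == "egnn":
                if trial % 10 == 0:
                    layer = EGNNLayer(8, rng)
                h1, x1 = layer(Tensor(h), Tensor(x), edges)
                h2, x2 = layer(Tensor(h), Tensor(x @ R.T + t), edges)
                worst = max(worst, np.abs(h1.data - h2.data).max())
                worst = max(worst, np.abs(x1.data @ R.T + t - x2.data).max())
            else:
                v = rng.normal(size=(n, 4, 3))
                if trial % 10 == 0:
                    layer = GVPLayer(8, 4, rng)
                h1, v1 = layer(Tensor(h), Tensor(x), Tensor(v), edges)
                h2, v2 = layer(Tensor(h), Tensor(x @ R.T + t), Tensor(v @ R.T), edges)
                worst = max(worst, np.abs(h1.data - h2.data).max())
                worst = max(worst, np.abs(v1.data @ R.T - v2.data).max())
        assert worst < 1e-8

    @pytest.mark.parametrize("backbone", ["egnn", "gvp"])
    def test_permutation_equivariance(self, backbone, rng):
        n = 7
        h = rng.normal(size=(n, 8))
        x = rng.normal(size=(n, 3))
        v = rng.normal(size=(n, 4, 3))
        edges = full_edges(n)
        perm = rng.permutation(n)
        # node i of the permuted graph is node perm[i] of the original
        inv = np.argsort(perm)
        pedges = np.stack([inv[edges[:, 0]], inv[edges[:, 1]]], axis=1)
        if backbone == "egnn":
            layer = EGNNLayer(8, rng)
            h1, x1 = layer(Tensor(h), Tensor(x), edges)
            h2, x2 = layer(Tensor(h[perm]), Tensor(x[perm]), pedges)
            assert np.allclose(h1.data[perm], h2.data, atol=1e-12)
            assert np.allclose(x1.data[perm], x2.data, atol=1e-12)
        else:
            layer = GVPLayer(8, 4, rng)
            h1, v1 = layer(Tensor(h), Tensor(x), Tensor(v), edges)
            h2, v2 = layer(Tensor(h[perm]), Tensor(x[perm]), Tensor(v[perm]), pedges)
            assert np.allclose(h1.data[perm], h2.data, atol=1e-12)
            assert np.allclose(v1.data[perm], v2.data, atol=1e-12)

    def test_three_stacked_layers_stay_equivariant(self, rng):
        layers = [GVPLayer(8, 4, rng) for _ in range(3)]
        n = 9
        h, x, v = rng.normal(size=(n, 8)), rng.normal(0, 3, size=(n, 3)), rng.normal(size=(n, 4, 3))
        edges = full_edges(n)
        R, t = rigid(rng)
        h1, v1 = Tensor(h), Tensor(v)
        h2, v2 = Tensor(h), Tensor(v @ R.T)
        for layer in layers:
            h1, v1 = layer(h1, Tensor(x), v1, edges)
            h2, v2 = layer(h2, Tensor(x @ R.T + t), v2, edges)
        assert np.allclose(h1.data, h2.data, atol=1e-9)
        assert np.allclose(v1.data @ R.T, v2.data, atol=1e-9)

    def test_functional_state_wrappers_round_trip(self, rng):
        states = [
            NodeState(h=rng.normal(size=4), x=rng.normal(size=3), v=rng.normal(size=(2, 3)))
            for _ in range(4)
        ]
        edges = full_edges(4)
        out = gvp_layer(states, edges, GVPLayer(4, 2, rng))
        assert len(out) == 4 and out[0].h.shape == (4,)
        out2 = egnn_layer(
            [NodeState(h=s.h, x=s.x) for s in states], edges, EGNNLayer(4, rng)
        )
        assert len(out2) == 4 and out2[0].x.shape == (3,)


def test_rbf_expansion_shape_and_peak(rng):
    d = Tensor(np.array([[0.0], [10.0 / (RBF_NUM - 1)]]))
    out = rbf_expand(d)
    assert out.shape == (2, RBF_NUM)
    assert out.data[0, 0] == pytest.approx(1.0)  # distance 0 peaks the first basis
    assert out.data[1, 1] == pytest.approx(1.0)  # one spacing peaks the second
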