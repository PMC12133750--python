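"""Branch contracts: GAT oracle equivalence, equivariance, GRU gating,
attention normalisation, frequency filter bank, fusion arithmetic."""

import numpy as np
import pytest

from mbeeg.autodiff import Tensor, no_grad
from mbeeg.connectivity import AdjacencyGraph
from mbeeg.model import ModelConfig, MultiBranchModel
from mbeeg.nn import GATLayer, GRU, MultiHeadSelfAttention

rng = np.random.default_rng(7)


def small_config(**kw):
    defaults = dict(
        n_channels=6,
        n_time=64,
        gru_hidden=16,
        d_time=8,
        ff_width=32,
        transformer_layers=1,
        attn_heads=4,
        d_low=16,
        d_spatial=8,
        conv_channels=4,
        dropout=0.0,
        bands=(("Alpha", 8.0, 13.0), ("Beta", 13.0, 30.0)),
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


def ring_adjacency(c):
    a = np.eye(c)
    for i in range(c):
        a[i, (i + 1) % c] = a[(i + 1) % c, i] = 1.0
    return a


class TestGATLayer:
    def brute_force(self, h, W, a_src, a_dst, adj, alpha=0.2):
        """Scalar-by-scalar evaluation of single-head graph attention."""
        C = h.shape[0]
        wh = h @ W
        out = np.zeros_like(wh)
        lrelu = lambda v: v if v > 0 else alpha * v
        for i in range(C):
            neigh = [j for j in range(C) if adj[i, j] > 0]
            scores = np.array([
                lrelu(float(wh[i] @ a_src) + float(wh[j] @ a_dst)) for j in neigh
            ])
            e = np.exp(scores - scores.max())
            att = e / e.sum()
            for w_ij, j in zip(att, neigh):
                out[i] += w_ij * wh[j]
        return np.array([[lrelu(v) for v in row] for row in out])

    def test_matches_brute_force_on_path_graph(self):
        adj = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]], dtype=float)
        layer = GATLayer(2, 2, heads=1, rng=np.random.default_rng(0))
        W = np.array([[0.3, -0.2], [0.1, 0.4]])
        a_s = np.array([[0.5], [-0.3]])
        a_d = np.array([[0.2], [0.1]])
        layer.w[0].data = W
        layer.a_src[0].data = a_s
        layer.a_dst[0].data = a_d
        h = np.array([[0.1, 0.2], [-0.3, 0.4], [0.5, -0.1]])
        with no_grad():
            out = layer(Tensor(h[None]), adj).data[0]
        expected = self.brute_force(h, W, a_s.ravel(), a_d.ravel(), adj)
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_singleton_node_attention_is_one(self):
        layer = GATLayer(2, 3, heads=1, rng=np.random.default_rng(1))
        h = np.array([[[0.4, -0.7]]])
        with no_grad():
            out = layer(Tensor(h), np.array([[1.0]])).data
        assert layer.last_attention[0, 0, 0, 0] == pytest.approx(1.0, abs=1e-12)
        wh = h[0] @ layer.w[0].data
        expected = np.where(wh > 0, wh, 0.2 * wh)
        np.testing.assert_allclose(out[0], expected, atol=1e-12)

    def test_attention_rows_sum_to_one(self):
        adj = ring_adjacency(6)
        layer = GATLayer(4, 3, heads=2, rng=np.random.default_rng(2))
        with no_grad():
            layer(Tensor(rng.standard_normal((2, 6, 4))), adj)
        sums = layer.last_attention.sum(axis=-1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_isolated_node_rejected(self):
        adj = np.eye(3)
        adj[1, 1] = 0.0
        layer = GATLayer(2, 2, heads=1, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="self-loop"):
            layer(Tensor(np.zeros((1, 3, 2))), adj)


class TestSpatialBranch:
    def test_output_shape(self):
        cfg = small_config()
        net = MultiBranchModel(cfg, fs=128.0)
        x = Tensor(rng.standard_normal((3, 6, 64)))
        with no_grad():
            out = net.spatial(x, ring_adjacency(6))
        assert out.shape == (3, 6, cfg.d_spatial)

    def test_channel_permutation_equivariance(self):
        cfg = small_config()
        net = MultiBranchModel(cfg, fs=128.0)
        adj = ring_adjacency(6)
        x = rng.standard_normal((2, 6, 64))
        perm = np.random.default_rng(5).permutation(6)
        with no_grad():
            base = net.spatial(Tensor(x), adj).data
            permuted = net.spatial(Tensor(x[:, perm]), adj[np.ix_(perm, perm)]).data
        np.testing.assert_allclose(permuted, base[:, perm], atol=1e-5)

    def test_identity_adjacency_isolates_channels(self):
        cfg = small_config()
        net = MultiBranchModel(cfg, fs=128.0)
        x = rng.standard_normal((1, 6, 64))
        x2 = x.copy()
        x2[0, 3] = 0.0
        with no_grad():
            a = net.spatial(Tensor(x), np.eye(6)).data
            b = net.spatial(Tensor(x2), np.eye(6)).data
        # all rows except the zeroed channel are untouched
        rows = [i for i in range(6) if i != 3]
        np.testing.assert_allclose(a[0, rows], b[0, rows], atol=1e-12)
        assert not np.allclose(a[0, 3], b[0, 3])


class TestTemporalBranch:
    def test_gru_zero_input_stays_zero(self):
        gru = GRU(4, 8, np.random.default_rng(0))
        with no_grad():
            out = gru(Tensor(np.zeros((2, 10, 4))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_self_attention_rows_sum_to_one(self):
        cfg = small_config()
        net = MultiBranchModel(cfg, fs=128.0)
        with no_grad():
            net.temporal(Tensor(rng.standard_normal((2, 6, 64))))
        att = net.temporal.encoder[0].attn.last_attention
        np.testing.assert_allclose(att.sum(axis=-1), 1.0, atol=1e-6)

    def test_not_causal(self):
        """Self-attention is bidirectional: perturbing the last time step
        changes outputs at earlier steps."""
        cfg = small_config()
        net = MultiBranchModel(cfg, fs=128.0)
        x = rng.standard_normal((1, 6, 64))
        x2 = x.copy()
        x2[0, :, -1] += 5.0
        with no_grad():
            a = net.temporal(Tensor(x)).data
            b = net.temporal(Tensor(x2)).data
        assert not np.allclose(a[0, :32], b[0, :32])

    def test_time_reversal_changes_output(self):
        cfg = small_config()
        net = MultiBranchModel(cfg, fs=128.0)
        x = rng.standard_normal((1, 6, 64))
        with no_grad():
            a = net.temporal(Tensor(x)).data
            b = net.temporal(Tensor(x[:, :, ::-1].copy())).data
        assert not np.allclose(a, b)


class TestFrequencyBranch:
    def test_feature_width_is_sum_of_band_widths(self):
        cfg = small_config()
        net = MultiBranchModel(cfg, fs=128.0)
        with no_grad():
            out = net.frequency(Tensor(rng.standard_normal((2, 6, 64))), 128.0)
        assert out.shape[1] == len(cfg.bands) * cfg.conv_channels

    def test_alpha_tone_leaves_beta_subbranch_empty(self):
        from mbeeg.autodiff import band_mask_fft

        fs = 128.0
        t = np.arange(256) / fs
        x = np.sin(2 * np.pi * 10 * t)[None, None, :]  # pure Alpha content
        with no_grad():
            alpha_in = band_mask_fft(Tensor(x), 8.0, 13.0, fs).data
            beta_in = band_mask_fft(Tensor(x), 13.0, 30.0, fs).data
        rms = lambda v: np.sqrt(np.mean(v**2))
        assert rms(beta_in) < 0.02 * rms(alpha_in)

    def test_positive_homogeneity_at_zero_bias(self):
        cfg = small_config()
        net = MultiBranchModel(cfg, fs=128.0)  # conv biases start at zero
        x = rng.standard_normal((1, 6, 64))
        with no_grad():
            a = net.frequency(Tensor(x), 128.0).data
            b = net.frequency(Tensor(2.0 * x), 128.0).data
        np.testing.assert_allclose(b, 2.0 * a, atol=1e-5)

    def test_band_above_nyquist_named_in_error(self):
        cfg = small_config(bands=(("Gamma", 30.0, 100.0),))
        net = MultiBranchModel(cfg, fs=128.0)
        with pytest.raises(ValueError, match="Gamma"):
            with no_grad():
                net.frequency(Tensor(rng.standard_normal((1, 6, 64))), 128.0)


class TestFusionAndForward:
    def test_fusion_width_arithmetic(self):
        cfg = ModelConfig(d_spatial=32, d_time=64, conv_channels=8)  # 5 bands x 8 = 40
        assert cfg.fusion_width == 32 + 64 + 40 == 136

    def test_softmax_output_rows_sum_to_one(self):
        cfg = small_config()
        net = MultiBranchModel(cfg, fs=128.0)
        with no_grad():
            p = net.predict_proba_tensor(Tensor(rng.standard_normal((4, 6, 64))), ring_adjacency(6))
        np.testing.assert_allclose(p.data.sum(axis=1), 1.0, atol=1e-6)

    def test_identical_trials_identical_rows(self):
        cfg = small_config()
        net = MultiBranchModel(cfg, fs=128.0)
        x = np.tile(rng.standard_normal((1, 6, 64)), (2, 1, 1))
        with no_grad():
            p = net.predict_proba_tensor(Tensor(x), ring_adjacency(6)).data
        np.testing.assert_array_equal(p[0], p[1])

    def test_eval_mode_repeatable_bitwise(self):
        cfg = small_config()
        net = MultiBranchModel(cfg, fs=128.0)
        x = Tensor(rng.standard_normal((3, 6, 64)))
        with no_grad():
            a = net.predict_proba_tensor(x, ring_adjacency(6)).data
            b = net.predict_proba_tensor(x, ring_adjacency(6)).data
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize(
        "kw",
        [dict(use_spatial=False), dict(use_transformer=False), dict(use_frequency=False),
         dict(use_temporal=False)],
    )
    def test_ablated_configs_produce_valid_rows(self, kw):
        cfg = small_config(**kw)
        net = MultiBranchModel(cfg, fs=128.0)
        with no_grad():
            p = net.predict_proba_tensor(Tensor(rng.standard_normal((2, 6, 64))), ring_adjacency(6)).data
        assert np.all(p >= 0) and np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        cfg = small_config()
        net = MultiBranchModel(cfg, fs=128.0)
        with pytest.raises(ValueError, match="does not match config"):
            net.logits(Tensor(np.zeros((1, 5, 64))), ring_adjacency(5))

    def test_gradient_reaches_all_branches(self):
        from mbeeg.nn import cross_entropy

        cfg = small_config()
        net = MultiBranchModel(cfg, fs=128.0)
        x = Tensor(rng.standard_normal((4, 6, 64)))
        loss = cross_entropy(net.logits(x, ring_adjacency(6)), np.array([0, 1, 2, 3]))
        loss.backward()
        for branch in (net.spatial, net.temporal, net.frequency):
            norms = [np.linalg.norm(p.grad) for p in branch.parameters() if p.grad is not None]
            assert norms and max(norms) > 0


class TestCheckpoint:
    def test_roundtrip_and_hash_guard(self, tmp_path):
        from mbeeg.model import TrainedModel, load_checkpoint, save_checkpoint

        cfg = small_config()
        net = MultiBranchModel(cfg, fs=128.0)
        adj = AdjacencyGraph(weights=ring_adjacency(6), builder="distance")
        model = TrainedModel(config=cfg, network=net, adjacency=adj, class_labels=(1, 2, 3, 4, 5))
        save_checkpoint(model, tmp_path / "m.npz", tmp_path / "m.json")
        back = load_checkpoint(tmp_path / "m.npz", tmp_path / "m.json")
        x = rng.standard_normal((2, 6, 64))
        np.testing.assert_array_equal(back.predict_proba(x), model.predict_proba(x))
        # corrupt the sidecar hash
        import json

        sidecar = json.loads((tmp_path / "m.json").read_text())
        sidecar["config_hash"] = "deadbeef"
        (tmp_path / "m.json").write_text(json.dumps(sidecar))
        with pytest.raises(ValueError, match="hash mismatch"):
            load_checkpoint(tmp_path / "m.npz", tmp_path / "m.json")


def test_config_validation():
    with pytest.raises(ValueError, match="4-8"):
        small_config(gat_heads=3)
    with pytest.raises(ValueError, match="at least one branch"):
        small_config(use_spatial=False, use_temporal=False, use_frequency=False)
    with pytest.raises(ValueError, match="divisible"):
        small_config(d_low=15)
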