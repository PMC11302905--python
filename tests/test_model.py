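"""The graph transformer: parameter counts, attention semantics, invariances."""

import dataclasses

import numpy as np
import pytest

import pocketgt as pg
import pocketgt.autodiff as ad
from pocketgt.errors import ConfigError
from pocketgt.model import (
    attention_logits,
    bce_loss_from_logits,
    forward,
    gt_layer,
    multi_head_attention,
    wrap_parameters,
)
from conftest import make_random_graph, random_rigid_transform


def dense_masked_attention(f, edge_rbf_full, adjacency, params, cfg, prefix):
    """Independent dense reference: [N, N] logits with non-edges at -inf.

    ``edge_rbf_full`` is an [N, N, d] array of distance RBF features.
    Computed entirely with plain numpy, no shared code with the sparse path.
    """
    n, d = f.shape
    H, dh = cfg.n_heads, cfg.head_dim
    q = f @ params[prefix + "q_W"] + params[prefix + "q_b"]
    k = f @ params[prefix + "k_W"] + params[prefix + "k_b"]
    v = f @ params[prefix + "v_W"] + params[prefix + "v_b"]
    b = edge_rbf_full @ params[prefix + "e_W"] + params[prefix + "e_b"]
    out = np.zeros((n, H, dh))
    for h in range(H):
        sl = slice(h * dh, (h + 1) * dh)
        logits = np.einsum("ik,jk,ijk->ij", q[:, sl], k[:, sl], b[:, :, sl]) / np.sqrt(dh)
        logits = np.clip(logits, -cfg.clamp_bound, cfg.clamp_bound)
        logits = np.where(adjacency, logits, -np.inf)
        for i in range(n):
            row = logits[i]
            if not np.isfinite(row).any():
                continue  # isolated node: zero output
            w = np.exp(row - row[np.isfinite(row)].max())
            w[~np.isfinite(row)] = 0.0
            out[i, h] = (w / w.sum()) @ v[:, sl]
    return out.reshape(n, d)


class TestParameterCount:
    def test_baseline_model_size(self):
        cfg = pg.ModelConfig(n_layers=8, hidden_dim=128, n_heads=8, use_sasa=True)
        n = pg.count_parameters(pg.init_model(cfg, 0))
        assert abs(n - 1.28e6) / 1.28e6 < 0.10

    def test_large_model_size(self):
        cfg = pg.ModelConfig(n_layers=12, hidden_dim=256, n_heads=8, use_sasa=True)
        n = pg.count_parameters(pg.init_model(cfg, 0))
        assert abs(n - 7.34e6) / 7.34e6 < 0.10

    def test_init_is_deterministic(self):
        cfg = pg.ModelConfig(n_layers=1, hidden_dim=16, n_heads=2)
        a = pg.init_model(cfg, 7)
        b = pg.init_model(cfg, 7)
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ConfigError):
            pg.ModelConfig(hidden_dim=30, n_heads=8)


class TestAttentionLogits:
    def test_all_ones_bias_reduces_to_dot_product(self, rng):
        q, k = rng.standard_normal((2, 6))
        got = attention_logits(q, k, np.ones(6), clamp_bound=100.0)
        assert got == pytest.approx(q @ k / np.sqrt(6))

    def test_clamped_to_bound(self):
        q = k = b = np.full(4, 2.0)  # raw = 4*8/2 = 16
        assert attention_logits(q, k, b, clamp_bound=5.0) == 5.0
        assert attention_logits(q, -k, b, clamp_bound=5.0) == -5.0

    def test_matches_scalar_loop(self, rng):
        q, k, b = rng.standard_normal((3, 4))
        loop = sum(q[i] * k[i] * b[i] for i in range(4)) / np.sqrt(4)
        loop = float(np.clip(loop, -5, 5))
        assert attention_logits(q, k, b) == pytest.approx(loop, rel=1e-12)


def _full_edge_rbf(g, cfg):
    fcfg = cfg.features
    dmat = np.linalg.norm(g.node_coords[:, None] - g.node_coords[None], axis=-1)
    return pg.rbf_embed(dmat.ravel(), fcfg.dist_centers, fcfg.dist_gamma).reshape(
        g.n_nodes, g.n_nodes, cfg.hidden_dim
    )


class TestSparseVsDense:
    @pytest.mark.parametrize("draw", range(5))
    def test_mha_matches_dense_masked_reference(self, draw):
        rng = np.random.default_rng(100 + draw)
        cfg = pg.ModelConfig(n_layers=1, hidden_dim=16, n_heads=4, dropout=0.0)
        params = pg.init_model(cfg, seed=200 + draw)
        n = int(rng.integers(3, 11))
        g = make_random_graph(rng, n_nodes=n, box=30.0)
        f = rng.standard_normal((n, cfg.hidden_dim))
        from pocketgt.graphs import edge_features

        tp = wrap_parameters(params, requires_grad=False)
        e_bias = (
            ad.Tensor(edge_features(g, cfg.features)) @ tp["layer0.e_W"]
            + tp["layer0.e_b"]
        )
        sparse = multi_head_attention(
            ad.Tensor(f), e_bias, g.edges, tp, cfg, "layer0."
        ).data
        adjacency = np.zeros((n, n), bool)
        adjacency[g.edges[:, 0], g.edges[:, 1]] = True
        dense = dense_masked_attention(f, _full_edge_rbf(g, cfg), adjacency, params, cfg, "layer0.")
        assert np.abs(sparse - dense).max() < 1e-10


class TestGtLayer:
    def test_attention_rows_sum_to_one(self, rng):
        cfg = pg.ModelConfig(n_layers=1, hidden_dim=8, n_heads=2, dropout=0.0)
        params = wrap_parameters(pg.init_model(cfg, 0), requires_grad=False)
        g = make_random_graph(rng, n_nodes=6, box=15.0)
        from pocketgt.graphs import edge_features

        # recompute the attention weights the way the layer does
        f = ad.Tensor(rng.standard_normal((6, 8)))
        e_bias = ad.Tensor(edge_features(g, cfg.features)) @ params["layer0.e_W"] + params["layer0.e_b"]
        q = (f @ params["layer0.q_W"] + params["layer0.q_b"]).data
        k = (f @ params["layer0.k_W"] + params["layer0.k_b"]).data
        centers, neighbors = g.edges[:, 0], g.edges[:, 1]
        dh = cfg.head_dim
        qe = q[centers].reshape(-1, 2, dh)
        ke = k[neighbors].reshape(-1, 2, dh)
        be = e_bias.data.reshape(-1, 2, dh)
        logits = np.clip((qe * ke * be).sum(-1) / np.sqrt(dh), -5, 5)
        w = np.exp(logits)
        denom = np.zeros((6, 2))
        np.add.at(denom, centers, w)
        attn = w / denom[centers]
        sums = np.zeros((6, 2))
        np.add.at(sums, centers, attn)
        degree = np.bincount(centers, minlength=6)
        np.testing.assert_allclose(sums[degree > 0], 1.0, atol=1e-12)
        assert np.all(np.abs(logits) <= 5.0)

    def test_zero_attention_weights_leave_norm_of_residual(self, rng):
        cfg = pg.ModelConfig(n_layers=1, hidden_dim=8, n_heads=2, dropout=0.0)
        params = pg.init_model(cfg, 0)
        for name in ("v_W", "o_W", "ffn1_W", "ffn2_W"):
            params["layer0." + name] = np.zeros_like(params["layer0." + name])
        tp = wrap_parameters(params, requires_grad=False)
        g = make_random_graph(rng, n_nodes=5, box=10.0)
        f = rng.standard_normal((5, 8))
        from pocketgt.graphs import edge_features
        from pocketgt.model import _layer_norm

        out = gt_layer(ad.Tensor(f), ad.Tensor(edge_features(g, cfg.features)),
                       g.edges, tp, cfg, 0)
        ln1 = _layer_norm(ad.Tensor(f), tp["layer0.ln1_g"], tp["layer0.ln1_b"])
        expected = _layer_norm(ln1, tp["layer0.ln2_g"], tp["layer0.ln2_b"])
        np.testing.assert_allclose(out.data, expected.data, atol=1e-12)

    def test_isolated_nodes_survive(self, rng):
        # two nodes farther apart than the cutoff: no edges at all
        g = pg.PocketGraph(
            node_aa=[0, 1],
            node_sasa=[5.0, 10.0],
            node_coords=[[0, 0, 0], [40.0, 0, 0]],
            edges=np.empty((0, 2), int),
            node_residue_keys=(("A", "1"), ("A", "2")),
        )
        cfg = pg.ModelConfig(n_layers=2, hidden_dim=8, n_heads=2, dropout=0.0)
        params = pg.init_model(cfg, 1)
        score = pg.predict_scores(params, [g], cfg)[0]
        assert 0.0 < score < 1.0


class TestForward:
    def test_score_strictly_inside_unit_interval(self, rng):
        cfg = pg.ModelConfig(n_layers=2, hidden_dim=16, n_heads=4)
        params = pg.init_model(cfg, 2)
        graphs = [make_random_graph(rng, n_nodes=int(n)) for n in rng.integers(2, 15, 8)]
        scores = pg.predict_scores(params, graphs, cfg)
        assert np.all((scores > 0) & (scores < 1))

    def test_zero_head_weights_give_exactly_half(self, rng):
        cfg = pg.ModelConfig(n_layers=1, hidden_dim=8, n_heads=2)
        params = pg.init_model(cfg, 3)
        params["mlp2_W"] = np.zeros_like(params["mlp2_W"])
        params["mlp2_b"] = np.zeros_like(params["mlp2_b"])
        g = make_random_graph(rng, n_nodes=4)
        assert pg.predict_scores(params, [g], cfg)[0] == 0.5

    def test_batched_equals_per_graph(self, rng, tiny_graphs):
        cfg = pg.ModelConfig(n_layers=2, hidden_dim=16, n_heads=4)
        params = pg.init_model(cfg, 4)
        graphs = list(tiny_graphs[:6])
        batched = pg.predict_scores(params, graphs, cfg)
        single = [pg.predict_scores(params, [g], cfg)[0] for g in graphs]
        np.testing.assert_allclose(batched, single, atol=1e-12)

    def test_e3_invariance(self, rng):
        cfg = pg.ModelConfig(n_layers=2, hidden_dim=16, n_heads=4)
        params = pg.init_model(cfg, 5)
        g = make_random_graph(rng, n_nodes=10)
        base = pg.predict_scores(params, [g], cfg)[0]
        for trial in range(10):
            R, t = random_rigid_transform(rng, reflect=(trial == 9))
            moved = dataclasses.replace(g, node_coords=g.node_coords @ R.T + t)
            assert abs(pg.predict_scores(params, [moved], cfg)[0] - base) < 1e-9

    def test_node_permutation_invariance(self, rng):
        cfg = pg.ModelConfig(n_layers=2, hidden_dim=16, n_heads=4)
        params = pg.init_model(cfg, 6)
        g = make_random_graph(rng, n_nodes=9)
        base = pg.predict_scores(params, [g], cfg)[0]
        perm = rng.permutation(9)
        inv = np.argsort(perm)
        g2 = pg.PocketGraph(
            node_aa=g.node_aa[perm],
            node_sasa=g.node_sasa[perm],
            node_coords=g.node_coords[perm],
            edges=inv[g.edges],
            node_residue_keys=tuple(g.node_residue_keys[i] for i in perm),
        )
        assert abs(pg.predict_scores(params, [g2], cfg)[0] - base) < 1e-5

    def test_full_model_gradient_check(self, rng):
        cfg = pg.ModelConfig(n_layers=1, hidden_dim=8, n_heads=2, dropout=0.0)
        params = pg.init_model(cfg, 8)
        g = make_random_graph(rng, n_nodes=4, box=15.0)
        labels = np.array([1.0])
        tp = wrap_parameters(params)
        _, logits = forward([g], tp, cfg)
        bce_loss_from_logits(logits, labels).backward()

        def loss_at():
            _, lg = forward([g], params, cfg)
            return float(bce_loss_from_logits(lg, labels).data)

        checked = 0
        for key in ("aa_embed", "in_proj_W", "layer0.q_W", "layer0.e_W",
                    "layer0.ln1_g", "layer0.ffn2_W", "mlp1_W", "mlp2_b"):
            arr = params[key]
            idx = tuple(int(rng.integers(0, s)) for s in arr.shape)
            old = arr[idx]
            eps = 1e-6
            arr[idx] = old + eps
            hi = loss_at()
            arr[idx] = old - eps
            lo = loss_at()
            arr[idx] = old
            num = (hi - lo) / (2 * eps)
            ana = tp[key].grad[idx]
            assert abs(num - ana) <= 1e-3 * max(1.0, abs(num), abs(ana))
            checked += 1
        assert checked == 8


class TestBceLoss:
    @pytest.mark.parametrize(
        "y,y_star,expected",
        [(0.5, 0, np.log(2)), (0.5, 1, np.log(2)), (0.9, 1, -np.log(0.9)),
         (0.1, 0, -np.log(0.9))],
    )
    def test_closed_form_values(self, y, y_star, expected):
        assert pg.bce_loss(y, y_star) == pytest.approx(expected, rel=1e-9)

    def test_loss_vanishes_as_score_approaches_label(self):
        assert pg.bce_loss(1 - 1e-12, 1) < 1e-9
        assert pg.bce_loss(1e-12, 0) < 1e-9

    def test_training_loss_matches_scalar_definition(self, rng):
        logits = ad.Tensor(rng.standard_normal(5))
        labels = rng.integers(0, 2, 5).astype(float)
        got = float(bce_loss_from_logits(logits, labels).data)
        from scipy.special import expit

        expected = np.mean([pg.bce_loss(float(expit(z)), int(t))
                            for z, t in zip(logits.data, labels)])
        assert got == pytest.approx(expected, rel=1e-9)


class TestCheckpoint:
    def test_round_trip_single_and_ensemble(self, tmp_path, rng):
        cfg = pg.ModelConfig(n_layers=1, hidden_dim=8, n_heads=2)
        members = [pg.init_model(cfg, s) for s in range(3)]
        path = pg.save_checkpoint(tmp_path / "ens.npz", members, cfg)
        back, cfg2 = pg.load_checkpoint(path)
        assert cfg2 == cfg
        assert len(back) == 3
        g = make_random_graph(rng, n_nodes=5)
        for orig, loaded in zip(members, back):
            assert pg.predict_scores(orig, [g], cfg)[0] == pytest.approx(
                pg.predict_scores(loaded, [g], cfg)[0], abs=1e-15
            )
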