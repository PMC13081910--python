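"""Network contracts: gating, segment masking, graph locality, padding
inertness, state handling."""

import dataclasses

import numpy as np
import pytest

from epigat.autodiff import Tensor, no_grad
from epigat.mga_model import (DyMGate, MaskedGraphAttentionNet, ModelConfig,
                              ModelState, partition_of)
from epigat.structure_io import ResidueGraph
from epigat.synthetic import SyntheticSpec, generate_complex, to_batch


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(D=30, H=4)
    with pytest.raises(ValueError):
        ModelConfig(n_gnn_layers=0)
    with pytest.raises(ValueError):
        ModelConfig(dropout=1.0)
    assert ModelConfig().H == 16 and ModelConfig().D == 256


class TestEmbedTokens:
    def test_lookup_identity_and_shape(self, tiny_cfg):
        model = MaskedGraphAttentionNet(tiny_cfg, seed=0)
        toks = np.zeros((2, 4, 8), dtype=int)
        toks[0, 0, 0] = 5
        toks[1, 3, 7] = 5
        out = model.embed_tokens(toks)
        assert out.shape == (2, 4, 8, tiny_cfg.D)
        np.testing.assert_array_equal(out.data[0, 0, 0], out.data[1, 3, 7])

    def test_out_of_range_token_rejected(self, tiny_cfg):
        model = MaskedGraphAttentionNet(tiny_cfg, seed=0)
        with pytest.raises(ValueError):
            model.embed_tokens(np.full((1, 2, 3), tiny_cfg.vocab_size))

    def test_zero_table_gives_zero_output(self, tiny_cfg):
        model = MaskedGraphAttentionNet(tiny_cfg, seed=0)
        model.embed.data[:] = 0.0
        assert np.all(model.embed_tokens(np.zeros((1, 2, 3), int)).data == 0)


class TestDyMGate:
    def test_zero_params_give_half_mask(self):
        gate = DyMGate(4, np.random.default_rng(0))
        gate.proj.weight.data[:] = 0
        gate.proj.bias.data[:] = 0
        x = Tensor(np.random.default_rng(1).normal(size=(5, 4)))
        gated, mask = gate(x)
        np.testing.assert_allclose(mask.data, 0.5)
        np.testing.assert_allclose(gated.data, 0.5 * x.data)

    def test_large_negative_bias_suppresses(self):
        gate = DyMGate(4, np.random.default_rng(0))
        gate.proj.weight.data[:] = 0
        gate.proj.bias.data[:] = -50.0
        x = Tensor(np.ones((3, 4)))
        gated, mask = gate(x)
        assert mask.data.max() < 1e-20 and np.abs(gated.data).max() < 1e-20

    def test_zero_input_with_bias_two(self):
        gate = DyMGate(4, np.random.default_rng(0))
        gate.proj.bias.data[:] = 2.0
        gated, mask = gate(Tensor(np.zeros((3, 4))))
        np.testing.assert_allclose(mask.data, 1 / (1 + np.exp(-2.0)), rtol=1e-12)
        assert np.all(gated.data == 0)

    def test_mask_strictly_inside_unit_interval(self, tiny_cfg, tiny_batches):
        model = MaskedGraphAttentionNet(tiny_cfg, seed=3)
        fwd = model.forward(tiny_batches[0])
        for v in fwd.dym_masks.values():
            assert np.all((v > 0) & (v < 1))


class TestForwardContracts:
    def test_output_shapes(self, tiny_cfg, tiny_batches):
        model = MaskedGraphAttentionNet(tiny_cfg, seed=0)
        fwd = model.forward(tiny_batches[:2])
        L, H = tiny_cfg.L, tiny_cfg.H
        assert fwd.logits_ss.shape == (2, L, 8)
        assert fwd.logits_itf.shape == (2, L, 2)
        assert fwd.logits_ctm.shape == (2, 2, L, L)
        assert fwd.attn_last.shape == (2, H, L, L)

    def test_forward_deterministic_without_dropout(self, tiny_cfg, tiny_batches):
        model = MaskedGraphAttentionNet(tiny_cfg, seed=0)
        a = model.forward(tiny_batches[0]).logits_itf.data
        b = model.forward(tiny_batches[0]).logits_itf.data
        np.testing.assert_array_equal(a, b)

    def test_padding_invariance(self, tiny_cfg):
        sc = generate_complex(SyntheticSpec(n_heavy=12, n_light=6, n_antigen=14,
                                            seed=5))
        short = to_batch(sc, M=4, L=40, seed=0)
        long = to_batch(sc, M=4, L=64, seed=0)
        model = MaskedGraphAttentionNet(tiny_cfg, seed=0)
        with no_grad():
            f_short = model.forward(short)
            f_long = model.forward(long)
        v = np.where(short.labels.valid)[0]  # same column layout in both paddings
        np.testing.assert_allclose(f_short.logits_itf.data[0, v],
                                   f_long.logits_itf.data[0, v], atol=1e-5)
        np.testing.assert_allclose(f_short.logits_ss.data[0, v],
                                   f_long.logits_ss.data[0, v], atol=1e-5)

    def test_itf_gradient_reaches_every_backbone_parameter(self, tiny_cfg, tiny_batches):
        from epigat.objectives import combined_loss

        model = MaskedGraphAttentionNet(tiny_cfg, seed=1)
        b = tiny_batches[0]
        fwd = model.forward(b)
        combined_loss(fwd, [b.labels], [b.col_edges], 3, "itf").total.backward()
        for name, p in model.named_parameters():
            if partition_of(name) == "backbone":
                assert p.grad is not None and np.abs(p.grad).sum() > 0, name


class TestAttentionMasking:
    def test_cross_segment_row_attention_exactly_zero(self, tiny_cfg, tiny_batches):
        model = MaskedGraphAttentionNet(tiny_cfg, seed=0)
        b = tiny_batches[0]
        fwd = model.forward(b, record_row_attn=True)
        ra = fwd.row_attn[0]  # [M, H, L, L]
        spans = [(s, e + 1) for _, s, e in b.chain_segments]
        for qa, qb in spans:
            for ka, kb in spans:
                if (qa, qb) != (ka, kb):
                    assert np.all(ra[:, :, qa:qb, ka:kb] == 0.0)

    def test_attention_rows_sum_to_one_over_valid_keys(self, tiny_cfg, tiny_batches):
        model = MaskedGraphAttentionNet(tiny_cfg, seed=0)
        b = tiny_batches[0]
        attn = model.forward(b).attn_last.data[0]
        v = b.valid_cols
        np.testing.assert_allclose(attn[:, v, :].sum(axis=-1), 1.0, atol=1e-12)
        assert np.all(attn[:, :, ~v] == 0.0)  # padded keys get no weight


class TestSaturatedGateEquivalence:
    def test_saturated_gates_match_ungated_reference(self, tiny_cfg, tiny_batches):
        model = MaskedGraphAttentionNet(tiny_cfg, seed=2)
        model.saturate_gates(bias=60.0)
        with no_grad():
            gated = model.forward(tiny_batches[0]).logits_itf.data
            object.__setattr__(model, "gates_enabled", False)
            ungated = model.forward(tiny_batches[0]).logits_itf.data
        object.__setattr__(model, "gates_enabled", True)
        v = tiny_batches[0].labels.valid
        np.testing.assert_allclose(gated[0, v], ungated[0, v], atol=1e-6)


class TestGNNReceptiveField:
    def _probe(self, n_layers, edges, L=8, D=8):
        cfg = ModelConfig(M=2, L=L, D=D, H=2, n_msa_blocks=1,
                          n_gnn_layers=n_layers, n_attn_layers=1, dropout=0.0)
        model = MaskedGraphAttentionNet(cfg, seed=0)
        graph = ResidueGraph(L, np.array(edges, int).reshape(-1, 2), 10.0)
        rng = np.random.default_rng(4)
        x = rng.normal(size=(1, 1, L, D))
        with no_grad():
            base = model.gnn_forward(Tensor(x), graph).data
        influenced = []
        for j in range(L):
            xp = x.copy()
            xp[0, 0, j, 0] += 1.0  # single-feature bump survives the pre-norm
            with no_grad():
                out = model.gnn_forward(Tensor(xp), graph).data
            delta = np.abs(out - base)[0, 0].sum(axis=-1)
            influenced.append(set(np.where(delta > 1e-12)[0]))
        return influenced

    def test_no_edges_is_purely_local(self):
        influenced = self._probe(1, np.empty((0, 2)))
        assert all(inf == {j} for j, inf in enumerate(influenced))

    def test_one_layer_reaches_only_neighbors(self):
        influenced = self._probe(1, [(0, 1), (1, 2), (2, 3)])
        assert influenced[0] == {0, 1}
        assert influenced[1] == {0, 1, 2}
        assert influenced[3] == {2, 3}
        assert influenced[5] == {5}

    def test_two_layers_reach_two_hops(self):
        influenced = self._probe(2, [(0, 1), (1, 2), (2, 3)])
        assert influenced[0] == {0, 1, 2}
        assert influenced[1] == {0, 1, 2, 3}

    def test_symmetric_inputs_give_symmetric_outputs(self):
        cfg = ModelConfig(M=2, L=4, D=8, H=2, n_msa_blocks=1, n_gnn_layers=1,
                          n_attn_layers=1, dropout=0.0)
        model = MaskedGraphAttentionNet(cfg, seed=0)
        model.pos_emb.data[:] = 0.0  # remove the one position-dependent input
        # 4-cycle, identical features -> identical outputs on every node
        graph = ResidueGraph(4, np.array([(0, 1), (1, 2), (2, 3), (0, 3)]), 10.0)
        x = np.tile(np.random.default_rng(0).normal(size=(1, 1, 1, 8)), (1, 1, 4, 1))
        with no_grad():
            out = model.gnn_forward(Tensor(x), graph).data[0, 0]
        np.testing.assert_allclose(out, np.tile(out[0], (4, 1)), atol=1e-10)


class TestExtractQuery:
    def test_slice_semantics(self, tiny_cfg):
        x = Tensor(np.random.default_rng(0).normal(size=(2, 4, 8, 16)))
        q = MaskedGraphAttentionNet.extract_query(x)
        assert q.shape == (2, 1, 8, 16)
        np.testing.assert_array_equal(q.data[:, 0], x.data[:, 0])
        x.data[:, 1:] = 0.0  # rows >= 1 are irrelevant to the slice
        np.testing.assert_array_equal(
            MaskedGraphAttentionNet.extract_query(x).data, q.data)


class TestState:
    def test_partition_labels(self, tiny_cfg):
        model = MaskedGraphAttentionNet(tiny_cfg, seed=0)
        st = model.get_state()
        parts = set(st.partition.values())
        assert parts == {"backbone", "head_ss", "head_itf", "head_ctm"}

    def test_save_load_round_trip(self, tiny_cfg, tmp_path):
        model = MaskedGraphAttentionNet(tiny_cfg, seed=0)
        st = model.get_state()
        st.save(tmp_path / "ckpt")
        back = ModelState.load(tmp_path / "ckpt")
        assert back.config == tiny_cfg
        for k in st.params:
            np.testing.assert_array_equal(back.params[k], st.params[k])

    def test_backbone_only_load(self, tiny_cfg):
        m1 = MaskedGraphAttentionNet(tiny_cfg, seed=0)
        m2 = MaskedGraphAttentionNet(tiny_cfg, seed=9)
        heads_before = {k: p.data.copy() for k, p in m2.named_parameters()
                        if partition_of(k) != "backbone"}
        m2.set_state(m1.get_state(), mode="backbone")
        for k, p in m2.named_parameters():
            if partition_of(k) == "backbone":
                np.testing.assert_array_equal(p.data, dict(m1.named_parameters())[k].data)
            else:
                np.testing.assert_array_equal(p.data, heads_before[k])
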