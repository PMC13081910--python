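"""Training engine: schedules, regularization, averaging, transfer, stages."""

import numpy as np
import pytest

from epigat.ctsr_training import (AveragedStates, CTSRSchedule, Stage,
                                  TrainConfig, apply_regularization,
                                  clip_gradients, final_predict, lr_at_step,
                                  train_stage, transfer_backbone, update_ema,
                                  update_swa)
from epigat.mga_model import MaskedGraphAttentionNet, ModelState, partition_of
from epigat.msa_features import TokenVocabulary

TC = TrainConfig()


class TestLRSchedule:
    def test_warmup_endpoints(self):
        assert lr_at_step(0, TC, base_lr=1e-3) == 0.0
        assert lr_at_step(TC.warmup_epochs, TC, base_lr=1e-3) == pytest.approx(1e-3)

    def test_cosine_midpoint_closed_form(self):
        base = 1e-3
        mid = TC.warmup_epochs + (TC.max_epochs - TC.warmup_epochs) / 2
        floor = base * TC.lr_floor_ratio
        expect = floor + (base - floor) * (1 + np.cos(np.pi / 2)) / 2
        assert lr_at_step(mid, TC, base_lr=base) == pytest.approx(expect)

    def test_decays_to_floor(self):
        base = 1e-3
        assert lr_at_step(TC.max_epochs, TC, base_lr=base) == pytest.approx(
            base * TC.lr_floor_ratio)


class TestRegularization:
    def test_zero_rates_leave_batch_unchanged(self, tiny_batches):
        cfg = TrainConfig(edge_dropout_range=(0.0, 0.0), token_mask_prob=0.0)
        out = apply_regularization(tiny_batches[0], cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(out.tokens, tiny_batches[0].tokens)
        np.testing.assert_array_equal(out.col_edges, tiny_batches[0].col_edges)

    def test_full_edge_dropout_keeps_self_loops_and_query(self, tiny_batches):
        cfg = TrainConfig(edge_dropout_range=(1.0, 1.0), token_mask_prob=0.0)
        out = apply_regularization(tiny_batches[0], cfg, np.random.default_rng(0))
        assert len(out.col_edges) == 0
        np.testing.assert_array_equal(out.gnn_src, out.gnn_dst)  # loops only
        np.testing.assert_array_equal(out.tokens[0], tiny_batches[0].tokens[0])

    def test_token_mask_rate_binomial_band(self, tiny_batches):
        cfg = TrainConfig(edge_dropout_range=(0.0, 0.0), token_mask_prob=0.1)
        rng = np.random.default_rng(1)
        vocab = TokenVocabulary()
        hits = total = 0
        for _ in range(30):  # ~10^4 maskable tokens across repeats
            out = apply_regularization(tiny_batches[0], cfg, rng)
            maskable = ((tiny_batches[0].tokens[1:] != vocab.pad_id)
                        & (tiny_batches[0].tokens[1:] != vocab.eoc_id))
            changed = out.tokens[1:] != tiny_batches[0].tokens[1:]
            # masking writes the unknown token; positions already unknown can
            # be hit without changing, so count only originally-non-X tokens
            countable = maskable & (tiny_batches[0].tokens[1:] != vocab.unk_id)
            hits += int((changed & countable).sum())
            total += int(countable.sum())
        rate = hits / total
        sigma = np.sqrt(0.1 * 0.9 / total)
        assert abs(rate - 0.1) < 3 * sigma

    def test_labels_untouched(self, tiny_batches):
        cfg = TrainConfig()
        out = apply_regularization(tiny_batches[0], cfg, np.random.default_rng(2))
        assert out.labels is tiny_batches[0].labels


class TestTransfer:
    def test_backbone_copied_bitwise_and_head_reinitialized(self, tiny_cfg):
        src = MaskedGraphAttentionNet(tiny_cfg, seed=0).get_state()
        out = transfer_backbone(src, "ss", seed=1)
        for k in src.params:
            part = partition_of(k)
            if part == "backbone" or part in ("head_itf", "head_ctm"):
                np.testing.assert_array_equal(out.params[k], src.params[k])
        assert any(not np.array_equal(out.params[k], src.params[k])
                   for k in src.params if partition_of(k) == "head_ss"
                   and src.params[k].size > 1)

    def test_round_trip_restores_backbone_exactly(self, tiny_cfg):
        src = MaskedGraphAttentionNet(tiny_cfg, seed=0).get_state()
        back = transfer_backbone(transfer_backbone(src, "ss", 1), "itf", 2)
        for k in src.params:
            if partition_of(k) == "backbone":
                np.testing.assert_array_equal(back.params[k], src.params[k])

    def test_unknown_task_rejected(self, tiny_cfg):
        src = MaskedGraphAttentionNet(tiny_cfg, seed=0).get_state()
        with pytest.raises(ValueError):
            transfer_backbone(src, "nope")


def _scalar_state(value, cfg):
    return ModelState({"w": np.array([float(value)])}, cfg)


class TestAveraging:
    def test_ema_three_step_closed_form(self, tiny_cfg):
        ema = _scalar_state(0.0, tiny_cfg)
        cur = _scalar_state(1.0, tiny_cfg)
        for _ in range(3):
            update_ema(ema, cur, 0.995)
        assert ema.params["w"][0] == pytest.approx(1 - 0.995**3, abs=1e-9)

    def test_ema_degenerate_decay(self, tiny_cfg):
        ema = _scalar_state(5.0, tiny_cfg)
        update_ema(ema, _scalar_state(1.0, tiny_cfg), 0.0)
        assert ema.params["w"][0] == 1.0

    def test_swa_is_running_mean(self, tiny_cfg):
        avg = AveragedStates(ema=_scalar_state(0, tiny_cfg))
        update_swa(avg, _scalar_state(0.0, tiny_cfg))
        assert avg.swa.params["w"][0] == 0.0 and avg.swa_count == 1
        update_swa(avg, _scalar_state(2.0, tiny_cfg))
        assert avg.swa.params["w"][0] == pytest.approx(1.0)

    def test_swa_matches_independent_mean(self, tiny_cfg):
        rng = np.random.default_rng(0)
        model = MaskedGraphAttentionNet(tiny_cfg, seed=0)
        states = []
        for _ in range(5):
            s = model.get_state().copy()
            for k in s.params:
                s.params[k] = rng.normal(size=s.params[k].shape)
            states.append(s)
        avg = AveragedStates(ema=states[0].copy())
        for s in states:
            update_swa(avg, s)
        for k in states[0].params:
            mean = np.mean([s.params[k] for s in states], axis=0)
            np.testing.assert_allclose(avg.swa.params[k], mean, atol=1e-12)


def _tiny_train_cfg(**kw):
    defaults = dict(warmup_epochs=1, max_epochs=3, swa_start_epoch=1,
                    edge_dropout_range=(0.05, 0.15), seed=0)
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestTrainStage:
    def test_smoke_two_epochs_logs_and_argmax(self, tiny_cfg, tiny_batches):
        model = MaskedGraphAttentionNet(tiny_cfg, seed=0)
        data = {"train": tiny_batches[:4], "val": tiny_batches[4:6]}
        cfg = _tiny_train_cfg(max_epochs=2)
        best, avg, log = train_stage(model, data, Stage("itf", 5e-4, 2), cfg)
        assert len(log) == 2
        assert all(r["task"] == "itf" for r in log)
        assert avg.swa is not None

    def test_gradient_clipping_bound_holds(self, tiny_cfg, tiny_batches):
        model = MaskedGraphAttentionNet(tiny_cfg, seed=0)
        data = {"train": tiny_batches[:4], "val": tiny_batches[4:6]}
        _, _, log = train_stage(model, data, Stage("itf", 5e-4, 2),
                                _tiny_train_cfg(max_epochs=2))
        assert all(r["max_clip_norm"] <= 0.5 + 1e-6 for r in log)

    def test_overfit_one_batch_reduces_loss(self, tiny_cfg, tiny_batches):
        model = MaskedGraphAttentionNet(tiny_cfg, seed=1)
        cfg = _tiny_train_cfg(max_epochs=6, warmup_epochs=1,
                              edge_dropout_range=(0.0, 0.0), token_mask_prob=0.0)
        data = {"train": tiny_batches[:1], "val": tiny_batches[:1]}
        _, _, log = train_stage(model, data, Stage("itf", 1e-3, 6), cfg)
        assert log[-1]["train_loss"] < log[0]["train_loss"]

    def test_determinism_across_runs(self, tiny_cfg, tiny_batches):
        data = {"train": tiny_batches[:3], "val": tiny_batches[3:5]}
        logs = []
        for _ in range(2):
            model = MaskedGraphAttentionNet(tiny_cfg, seed=0)
            _, _, log = train_stage(model, data, Stage("itf", 5e-4, 2),
                                    _tiny_train_cfg(max_epochs=2), seed=3)
            logs.append([(r["train_loss"], r["val_aupr"]) for r in log])
        for (l1, v1), (l2, v2) in zip(*logs):
            assert l1 == pytest.approx(l2, abs=1e-6)
            assert v1 == pytest.approx(v2, abs=1e-6)


class TestFinalPredict:
    def test_identical_states_equal_single_state(self, tiny_cfg, tiny_batches):
        model = MaskedGraphAttentionNet(tiny_cfg, seed=0)
        st = model.get_state()
        both = final_predict(model, st, st, tiny_batches[0])[0]
        single = final_predict(model, st, None, tiny_batches[0])[0]
        np.testing.assert_allclose(both, single, atol=1e-12)

    def test_output_is_mean_of_per_state_probabilities(self, tiny_cfg, tiny_batches):
        m = MaskedGraphAttentionNet(tiny_cfg, seed=0)
        s1 = m.get_state()
        s2 = MaskedGraphAttentionNet(tiny_cfg, seed=5).get_state()
        avg = final_predict(m, s1, s2, tiny_batches[0])[0]
        p1 = final_predict(m, s1, None, tiny_batches[0])[0]
        p2 = final_predict(m, None, s2, tiny_batches[0])[0]
        np.testing.assert_allclose(avg, (p1 + p2) / 2, atol=1e-12)
        assert np.all((avg >= 0) & (avg <= 1) & np.isfinite(avg))

    def test_requires_at_least_one_state(self, tiny_cfg, tiny_batches):
        model = MaskedGraphAttentionNet(tiny_cfg, seed=0)
        with pytest.raises(ValueError):
            final_predict(model, None, None, tiny_batches[0])


def test_ctsr_run_is_reproducible_and_ordered(tiny_cfg, tiny_batches):
    from epigat.ctsr_training import ctsr_run

    data = {"train": tiny_batches[:4], "val": tiny_batches[4:6]}
    reports = []
    for _ in range(2):
        model = MaskedGraphAttentionNet(tiny_cfg, seed=0)
        cfg = _tiny_train_cfg(max_epochs=2)
        sched = CTSRSchedule.default(cfg, [1, 1, 1, 1, 1])
        _, _, rep = ctsr_run(model, data, sched, cfg, seed=0)
        reports.append(rep)
    a, b = reports
    assert [s["task"] for s in a["stages"]] == ["itf", "ss", "itf", "ctm", "itf"]
    for sa, sb in zip(a["stages"], b["stages"]):
        assert sa["best_val_aupr"] == pytest.approx(sb["best_val_aupr"], abs=1e-6)
        # each stage starts from the previous stage's best backbone
    for i in range(1, len(a["stages"])):
        assert a["stages"][i]["start_backbone_digest"] == \
            a["stages"][i - 1]["end_backbone_digest"]


def test_schedule_must_start_and_end_with_interface():
    with pytest.raises(ValueError):
        CTSRSchedule([Stage("ss", 1e-4, 5)])
    sched = CTSRSchedule.default(TrainConfig(), [2, 1, 1, 1, 2])
    assert [s.task for s in sched.stages] == ["itf", "ss", "itf", "ctm", "itf"]


def test_clip_gradients_scales_to_bound(tiny_cfg):
    model = MaskedGraphAttentionNet(tiny_cfg, seed=0)
    for p in model.parameters():
        p.grad = np.ones_like(p.data)
    norm = clip_gradients(model, 0.5)
    assert norm == pytest.approx(0.5)
    total = np.sqrt(sum(float((p.grad**2).sum()) for p in model.parameters()))
    assert total == pytest.approx(0.5, rel=1e-9)
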