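"""Desk-scale reference experiments on planted-signal synthetic data.

These drive the package end to end at a size a laptop CPU handles in
seconds-to-minutes: a reduced model (M=4 alignment rows, L=64 columns, D=32,
H=4, one block per stage) trained on a few dozen synthetic complexes whose
interface is recoverable from planted MSA conservation plus cross-chain graph
edges.  The learning rate is raised to 1e-3 for the interface stage (5e-4 for
auxiliary stages): the full-scale default of 2e-4 underfits badly at this
model size and data volume, and the schedule shape (warmup + cosine) is kept.
"""

from __future__ import annotations

import numpy as np

from .ctsr_training import (CTSRSchedule, Stage, TrainConfig, ctsr_run,
                            final_predict, train_stage)
from .eval_interpret import exact_aupr
from .mga_model import MaskedGraphAttentionNet, ModelConfig
from .objectives import LossConfig
from .synthetic import SyntheticSpec, synthetic_batches

TINY_MODEL = dict(B=1, M=4, L=64, D=32, H=4, n_msa_blocks=1, n_gnn_layers=1,
                  n_attn_layers=1, dropout=0.05)
DESK_LR_ITF = 1e-3
DESK_LR_AUX = 5e-4
CTSR_STAGE_EPOCHS = [12, 5, 5, 5, 8]


def _train_config(seed: int, max_epochs: int) -> TrainConfig:
    return TrainConfig(lr_itf=DESK_LR_ITF, lr_ss=DESK_LR_AUX, lr_ctm=DESK_LR_AUX,
                       warmup_epochs=3, max_epochs=max_epochs,
                       swa_start_epoch=int(0.6 * max_epochs), seed=seed)


def make_data(seed: int, n_train: int = 34, n_val: int = 6, n_test: int = 10,
              spec: SyntheticSpec | None = None):
    """Featurized synthetic complexes split at the complex level."""
    spec = spec or SyntheticSpec()
    total = n_train + n_val + n_test
    batches = synthetic_batches(total, spec, seed=seed, M=4, L=64)
    return {"train": batches[:n_train],
            "val": batches[n_train:n_train + n_val],
            "test": batches[n_train + n_val:]}


def learnability_experiment(seed: int, epochs: int = 30) -> dict:
    """One interface-task training stage; reports held-out AUPR vs base rate."""
    data = make_data(seed)
    model = MaskedGraphAttentionNet(ModelConfig(**TINY_MODEL), seed=seed)
    cfg = _train_config(seed, epochs)
    best, avg, log = train_stage(model, {"train": data["train"], "val": data["val"]},
                                 Stage("itf", cfg.lr_itf, epochs), cfg,
                                 LossConfig(), seed=seed)
    model.set_state(best)
    probs = final_predict(model, avg.ema, avg.swa, data["test"])
    p = np.concatenate([pr[b.labels.valid] for pr, b in zip(probs, data["test"])])
    y = np.concatenate([b.labels.itf[b.labels.valid] for b in data["test"]])
    aupr = exact_aupr(p, y)
    base = float(y.mean())
    return {"test_aupr": aupr, "base_rate": base, "ratio": aupr / base,
            "best_val_aupr": max(r["val_aupr"] for r in log),
            "n_test_residues": int(y.size)}


def ctsr_experiment(seed: int, epochs_per_stage=None) -> dict:
    """Full itf→ss→itf→ctm→itf cycle; reports first vs final interface AUPR."""
    epochs_per_stage = epochs_per_stage or CTSR_STAGE_EPOCHS
    data = make_data(seed, n_test=0)
    model = MaskedGraphAttentionNet(ModelConfig(**TINY_MODEL), seed=seed)
    cfg = _train_config(seed, max(epochs_per_stage))
    schedule = CTSRSchedule.default(cfg, epochs_per_stage)
    _, _, report = ctsr_run(model, {"train": data["train"], "val": data["val"]},
                            schedule, cfg, LossConfig(), seed=seed)
    return {
        "stage_tasks": [s["task"] for s in report["stages"]],
        "stage_best_aupr": [s["best_val_aupr"] for s in report["stages"]],
        "handoff_ok": all(
            report["stages"][i]["start_backbone_digest"]
            == report["stages"][i - 1]["end_backbone_digest"]
            for i in range(1, len(report["stages"]))),
        "first_itf_aupr": report["first_itf_val_aupr"],
        "final_itf_aupr": report["final_itf_val_aupr"],
    }
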