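"""Training engine: AdamW with warmup+cosine schedule, graph/token
regularization, EMA and SWA weight averaging, backbone transfer between
tasks, and the cyclic-transfer-with-soft-restart (CTSR) orchestrator.

CTSR cycles the shared backbone through the interface task and auxiliary
structural tasks (secondary structure, contact map): each stage restarts the
optimizer state and learning-rate schedule ("soft restart") while the model
weights carry over, with the incoming stage's task head freshly initialized.
The default cycle is itf → ss → itf → ctm → itf.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import no_grad
from .batch import ComplexBatch
from .eval_interpret import exact_aupr
from .mga_model import (MaskedGraphAttentionNet, ModelConfig, ModelState,
                        partition_of)
from .objectives import LossConfig, combined_loss
from .nn import Dropout


@dataclass
class TrainConfig:
    lr_itf: float = 2e-4
    lr_ss: float = 1e-4
    lr_ctm: float = 1e-4
    warmup_epochs: int = 10
    max_epochs: int = 50
    lr_floor_ratio: float = 0.01     # cosine decays to base_lr * this
    grad_clip_norm: float = 0.5
    grad_accumulation_steps: int = 2
    swa_start_epoch: int = 20
    ema_decay: float = 0.995
    edge_dropout_range: tuple = (0.05, 0.15)
    token_mask_prob: float = 0.1
    weight_decay: float = 0.01
    gradient_noise: float = 0.0      # default off; std of per-step Gaussian noise
    finetune_lr_factor: float = 0.5
    finetune_dropout_delta: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.warmup_epochs >= self.max_epochs:
            raise ValueError("warmup must be shorter than max_epochs")
        for p in (*self.edge_dropout_range, self.token_mask_prob, self.ema_decay):
            if not 0 <= p <= 1:
                raise ValueError("rates/probabilities must lie in [0, 1]")


@dataclass
class Stage:
    task: str                        # itf | ss | ctm
    lr: float
    max_epochs: int
    finetune: bool = False           # reduced lr, increased dropout


@dataclass
class CTSRSchedule:
    stages: list

    def __post_init__(self):
        if not self.stages or self.stages[0].task != "itf" or self.stages[-1].task != "itf":
            raise ValueError("CTSR schedule must start and end with the interface task")

    @staticmethod
    def default(cfg: TrainConfig, epochs_per_stage=None) -> "CTSRSchedule":
        e = epochs_per_stage or [cfg.max_epochs] * 5
        return CTSRSchedule([
            Stage("itf", cfg.lr_itf, e[0]),
            Stage("ss", cfg.lr_ss, e[1]),
            Stage("itf", cfg.lr_itf * cfg.finetune_lr_factor, e[2], finetune=True),
            Stage("ctm", cfg.lr_ctm, e[3]),
            Stage("itf", cfg.lr_itf * cfg.finetune_lr_factor, e[4], finetune=True),
        ])


@dataclass
class AveragedStates:
    ema: ModelState
    swa: ModelState | None = None
    swa_count: int = 0


# ---------------------------------------------------------------------------
# Schedules and optimizer
# ---------------------------------------------------------------------------

def lr_at_step(epoch: float, cfg: TrainConfig, base_lr: float | None = None,
               max_epochs: int | None = None) -> float:
    """Linear warmup from 0 to base over ``warmup_epochs``, then cosine decay
    to ``base * lr_floor_ratio`` over the remaining epochs."""
    base = cfg.lr_itf if base_lr is None else base_lr
    total = cfg.max_epochs if max_epochs is None else max_epochs
    w = min(cfg.warmup_epochs, total - 1)
    if epoch < w:
        return base * epoch / w
    floor = base * cfg.lr_floor_ratio
    span = max(total - w, 1)
    t = min((epoch - w) / span, 1.0)
    return floor + (base - floor) * (1 + np.cos(np.pi * t)) / 2


class AdamW:
    """Decoupled-weight-decay Adam over a named parameter dict."""

    def __init__(self, params: dict, weight_decay: float = 0.01,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, lr: float):
        self.t += 1
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            if p.data.ndim >= 2 and self.wd > 0:
                p.data *= 1 - lr * self.wd
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_gradients(model, max_norm: float) -> float:
    """Global-norm gradient clipping; returns the post-clip norm."""
    grads = [p.grad for p in model.parameters() if p.grad is not None]
    total = float(np.sqrt(sum(float((g**2).sum()) for g in grads))) if grads else 0.0
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale
        return max_norm
    return total


# ---------------------------------------------------------------------------
# Regularization
# ---------------------------------------------------------------------------

def apply_regularization(item: ComplexBatch, cfg: TrainConfig,
                         rng: np.random.Generator) -> ComplexBatch:
    """Per-batch edge dropout and token masking (query row untouched).

    The edge-dropout probability is drawn uniformly from the configured range
    once per call; each graph edge is then dropped independently.  MSA tokens
    in rows ≥ 1 are replaced by the unknown token with the configured
    probability; self-loops, labels and the query row are never modified.
    """
    lo, hi = cfg.edge_dropout_range
    p_edge = rng.uniform(lo, hi)
    edges = item.col_edges
    keep = rng.random(len(edges)) >= p_edge
    edges = edges[keep]
    cols = item.residue_cols
    if len(edges):
        src = np.concatenate([edges[:, 0], edges[:, 1], cols])
        dst = np.concatenate([edges[:, 1], edges[:, 0], cols])
    else:
        src = dst = cols.copy()

    tokens = item.tokens.copy()
    if cfg.token_mask_prob > 0 and tokens.shape[0] > 1:
        from .msa_features import TokenVocabulary

        vocab = TokenVocabulary()
        maskable = np.zeros_like(tokens, dtype=bool)
        maskable[1:] = (tokens[1:] != vocab.pad_id) & (tokens[1:] != vocab.eoc_id)
        hit = maskable & (rng.random(tokens.shape) < cfg.token_mask_prob)
        tokens[hit] = vocab.unk_id
    return ComplexBatch(
        complex_id=item.complex_id, tokens=tokens, valid_cols=item.valid_cols,
        residue_cols=item.residue_cols, chain_segments=item.chain_segments,
        gnn_src=src.astype(int), gnn_dst=dst.astype(int), labels=item.labels,
        sides=item.sides, restypes=item.restypes, row_mask=item.row_mask,
        col_edges=edges,
    )


# ---------------------------------------------------------------------------
# State averaging and transfer
# ---------------------------------------------------------------------------

def update_ema(ema: ModelState, current: ModelState, decay: float) -> ModelState:
    for k in ema.params:
        ema.params[k] = decay * ema.params[k] + (1 - decay) * current.params[k]
    return ema


def update_swa(avg: AveragedStates, current: ModelState) -> AveragedStates:
    if avg.swa is None:
        avg.swa = current.copy()
        avg.swa_count = 1
    else:
        n = avg.swa_count
        for k in avg.swa.params:
            avg.swa.params[k] += (current.params[k] - avg.swa.params[k]) / (n + 1)
        avg.swa_count = n + 1
    return avg


def transfer_backbone(src: ModelState, dst_task: str, seed: int = 0) -> ModelState:
    """Copy the backbone, re-initialize the destination task head (seeded),
    keep the remaining heads as they are."""
    if dst_task not in ("itf", "ss", "ctm"):
        raise ValueError(f"unknown task {dst_task!r}")
    fresh = MaskedGraphAttentionNet(src.config, seed=seed).get_state()
    out = src.copy()
    head = f"head_{dst_task}"
    for name in out.params:
        if partition_of(name) == head:
            if fresh.params[name].shape != out.params[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            out.params[name] = fresh.params[name].copy()
    return out


# ---------------------------------------------------------------------------
# Stage training
# ---------------------------------------------------------------------------

def _validation_metric(model, val_items, task: str, loss_cfg: LossConfig) -> float:
    """Validation AUPR for the stage task (macro over classes for SS)."""
    model.eval()
    ps, ys = [], []
    with no_grad():
        for it in val_items:
            fwd = model.forward(it)
            lb = it.labels
            v = lb.valid
            if task == "itf":
                from .autodiff import log_softmax

                p = np.exp(log_softmax(fwd.logits_itf).data)[0, :, 1]
                ps.append(p[v])
                ys.append(lb.itf[v])
            elif task == "ctm":
                z = fwd.logits_ctm.data[0]
                z = (z + z.transpose(0, 2, 1)) / 2
                p = np.exp(z[1] - np.logaddexp(z[0], z[1]))
                pv = np.outer(v, v)
                ps.append(p[pv])
                ys.append(lb.ctm[pv])
            else:  # ss: one-vs-rest per class
                e = np.exp(fwd.logits_ss.data[0] - fwd.logits_ss.data[0].max(-1, keepdims=True))
                p = e / e.sum(-1, keepdims=True)
                vv = v & (lb.ss >= 0)
                ps.append(p[vv])
                ys.append(lb.ss[vv])
    model.train()
    p = np.concatenate(ps)
    y = np.concatenate(ys)
    if task == "ss":
        scores = []
        for c in np.unique(y):
            yc = (y == c).astype(int)
            if 0 < yc.sum() < yc.size:
                scores.append(exact_aupr(p[:, c], yc))
        return float(np.mean(scores)) if scores else 0.0
    try:
        return exact_aupr(p, y)
    except ValueError:
        return 0.0


def train_stage(model: MaskedGraphAttentionNet, data: dict, stage: Stage,
                cfg: TrainConfig, loss_cfg: LossConfig | None = None,
                seed: int | None = None, log_path=None):
    """Train one CTSR stage; returns (best_state, AveragedStates, log records).

    ``data``: {"train": [ComplexBatch...], "val": [ComplexBatch...]}.
    Model selection is by highest validation AUPR for the stage task.
    """
    loss_cfg = loss_cfg or LossConfig()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    opt = AdamW(dict(model.named_parameters()), cfg.weight_decay)
    avg = AveragedStates(ema=model.get_state().copy())
    log: list = []
    best = (-1.0, model.get_state().copy())
    train_items = list(data["train"])
    model.train()

    for epoch in range(stage.max_epochs):
        lr = lr_at_step(epoch, cfg, base_lr=stage.lr, max_epochs=stage.max_epochs)
        order = rng.permutation(len(train_items))
        model.zero_grad()
        micro, epoch_records, clip_norms = 0, [], []
        for pos in order:
            item = apply_regularization(train_items[pos], cfg, rng)
            fwd = model.forward(item, rng=rng)
            lb = combined_loss(fwd, [item.labels], [item.col_edges], epoch,
                               stage.task, loss_cfg)
            if not np.isfinite(lb.total.data):
                raise FloatingPointError(
                    f"non-finite loss on complex {item.complex_id} "
                    f"(epoch {epoch}, task {stage.task})")
            (lb.total / cfg.grad_accumulation_steps).backward()
            epoch_records.append(lb.as_record())
            micro += 1
            if micro % cfg.grad_accumulation_steps == 0 or micro == len(order):
                if cfg.gradient_noise > 0:
                    for p in model.parameters():
                        if p.grad is not None:
                            p.grad += rng.normal(0, cfg.gradient_noise, p.grad.shape)
                clip_norms.append(clip_gradients(model, cfg.grad_clip_norm))
                opt.step(lr)
                model.zero_grad()
                update_ema(avg.ema, model.get_state(), cfg.ema_decay)
        if epoch >= cfg.swa_start_epoch:
            update_swa(avg, model.get_state())
        val = _validation_metric(model, data["val"], stage.task, loss_cfg) \
            if data.get("val") else 0.0
        rec = {"epoch": epoch, "task": stage.task, "lr": lr,
               "train_loss": float(np.mean([r["total"] for r in epoch_records])),
               "val_aupr": val,
               "max_clip_norm": float(max(clip_norms)) if clip_norms else 0.0}
        rec["loss_components"] = {k: float(np.mean([r[k] for r in epoch_records]))
                                  for k in ("ce", "aupr_surrogate", "smooth")}
        log.append(rec)
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(json.dumps(rec) + "\n")
        if val >= best[0]:
            best = (val, model.get_state().copy())
    if avg.swa is None:  # stage shorter than swa_start: fall back to final weights
        avg.swa = model.get_state().copy()
        avg.swa_count = 0
    return best[1], avg, log


def ctsr_run(model: MaskedGraphAttentionNet, data: dict, schedule: CTSRSchedule,
             cfg: TrainConfig, loss_cfg: LossConfig | None = None,
             seed: int | None = None, log_path=None):
    """Run the full cyclic schedule; returns (final_state, report).

    Between stages the previous stage's best backbone is transferred and the
    incoming task head re-initialized; optimizer state restarts each stage.
    Fine-tune stages run with reduced lr (already baked into the schedule)
    and increased dropout.
    """
    loss_cfg = loss_cfg or LossConfig()
    seed = cfg.seed if seed is None else seed
    report = {"stages": []}
    state = model.get_state()
    averaged = None
    base_dropout = model.cfg.dropout
    for i, stage in enumerate(schedule.stages):
        if i > 0:
            state = transfer_backbone(state, stage.task, seed=seed + 1000 + i)
            model.set_state(state)
        _set_dropout(model, base_dropout + (cfg.finetune_dropout_delta if stage.finetune else 0.0))
        start_backbone = _backbone_digest(model.get_state())
        best, averaged, log = train_stage(model, data, stage, cfg, loss_cfg,
                                          seed=seed + i, log_path=log_path)
        model.set_state(best)
        state = best
        report["stages"].append({
            "index": i, "task": stage.task, "finetune": stage.finetune,
            "start_backbone_digest": start_backbone,
            "end_backbone_digest": _backbone_digest(best),
            "best_val_aupr": max(r["val_aupr"] for r in log),
            "log": log,
        })
    _set_dropout(model, base_dropout)
    itf_stages = [s for s in report["stages"] if s["task"] == "itf"]
    report["first_itf_val_aupr"] = itf_stages[0]["best_val_aupr"]
    report["final_itf_val_aupr"] = itf_stages[-1]["best_val_aupr"]
    return state, averaged, report


def _set_dropout(model, rate: float):
    stack = [model]
    while stack:
        m = stack.pop()
        if isinstance(m, Dropout):
            object.__setattr__(m, "rate", float(rate))
        stack.extend(m._modules.values())


def _backbone_digest(state: ModelState) -> float:
    """Cheap fingerprint of backbone weights for hand-off assertions."""
    return float(sum(float(np.abs(v).sum()) for k, v in sorted(state.params.items())
                     if partition_of(k) == "backbone"))


def final_predict(model: MaskedGraphAttentionNet, ema_state: ModelState | None,
                  swa_state: ModelState | None, items) -> list:
    """Average the EMA-weights and SWA-weights positive-class probabilities.

    Falls back to whichever averaged state exists; at least one is required.
    """
    from .autodiff import log_softmax

    states = [s for s in (ema_state, swa_state) if s is not None]
    if not states:
        raise ValueError("need at least one of ema_state, swa_state")
    if isinstance(items, ComplexBatch):
        items = [items]
    keep = model.get_state()
    out = []
    model.eval()
    try:
        per_state = []
        for st in states:
            model.set_state(st)
            probs = []
            with no_grad():
                for it in items:
                    fwd = model.forward(it)
                    probs.append(np.exp(log_softmax(fwd.logits_itf).data)[0, :, 1])
            per_state.append(probs)
        for i in range(len(items)):
            out.append(np.mean([ps[i] for ps in per_state], axis=0))
    finally:
        model.set_state(keep)
        model.train()
    return out
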