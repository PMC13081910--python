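"""Imbalance-aware composite training objective.

The interface task is trained with

    L = (1 - alpha) * L_CE + alpha * L_AUPR + lambda * L_smooth

where L_CE is class-weighted label-smoothed cross-entropy, L_AUPR is a
differentiable surrogate for (one minus) the area under the precision–recall
curve built from soft threshold sweeps, and L_smooth penalizes squared
differences of positive-class probability across graph edges.  The positive
class weight decays exponentially over epochs (hard emphasis early, unbiased
late) and the smoothness coefficient ramps in linearly.  Auxiliary tasks
(secondary structure, contact map) use plain smoothed cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, log_softmax
from .mga_model import ForwardOutput


@dataclass
class LossConfig:
    alpha: float = 0.4
    epsilon_smooth: float = 0.05
    K_bins: int = 64
    temperature: float = 0.05
    lambda_max: float = 0.05
    lambda_ramp: tuple = (5, 15)
    w0: float = 20.0
    w_inf: float = 1.0
    tau_epochs: float = 8.0
    stabilizer_eps: float = 1e-8

    def __post_init__(self):
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.K_bins < 2:
            raise ValueError("K_bins must be >= 2")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not self.w0 >= self.w_inf >= 0:
            raise ValueError("need w0 >= w_inf >= 0")


@dataclass
class LossBreakdown:
    total: Tensor
    ce: float
    aupr_surrogate: float
    smooth: float
    alpha: float
    lam: float
    w_pos: float
    aupr_fallback: bool = False  # True when degenerate labels forced CE-only

    def as_record(self) -> dict:
        return {"total": float(self.total.data), "ce": self.ce,
                "aupr_surrogate": self.aupr_surrogate, "smooth": self.smooth,
                "alpha": self.alpha, "lambda": self.lam, "w_pos": self.w_pos,
                "aupr_fallback": self.aupr_fallback}


# ---------------------------------------------------------------------------
# Components
# ---------------------------------------------------------------------------

def weighted_smoothed_ce(logits: Tensor, labels: np.ndarray, valid: np.ndarray,
                         w_pos: float = 1.0, epsilon_smooth: float = 0.0,
                         positive_class: int = 1) -> Tensor:
    """Mean over valid positions of class-weighted, label-smoothed CE.

    Smoothed target: 1 - eps + eps/C on the true class, eps/C elsewhere.
    Positions whose label equals ``positive_class`` are weighted ``w_pos``,
    all others 1.
    """
    labels = np.asarray(labels)
    valid = np.asarray(valid, dtype=bool)
    idx = np.where(valid.reshape(-1))[0]
    if idx.size == 0:
        raise ValueError("no valid positions for cross-entropy")
    C = logits.shape[-1]
    flat = logits.reshape(-1, C)[idx]
    lab = labels.reshape(-1)[idx]
    if lab.min() < 0 or lab.max() >= C:
        raise ValueError("label outside class range on a valid position")
    logp = log_softmax(flat, axis=-1)
    q = np.full((idx.size, C), epsilon_smooth / C)
    q[np.arange(idx.size), lab] += 1.0 - epsilon_smooth
    w = np.where(lab == positive_class, w_pos, 1.0)
    per_pos = -(logp * Tensor(q)).sum(axis=-1)
    return (per_pos * Tensor(w)).sum() / idx.size


def soft_aupr(probs: Tensor, labels: np.ndarray, valid: np.ndarray,
              K_bins: int = 64, temperature: float = 0.05,
              stabilizer_eps: float = 1e-8):
    """Differentiable AUPR surrogate from a soft threshold sweep.

    Thresholds t_k = (k - 1/2)/K; each yields soft TP/FP/FN via
    sigmoid((p - t_k)/temperature).  Bins are ordered by decreasing threshold
    (increasing recall) and precision is integrated over recall with R_0 = 0.
    Returns ``(aupr_hat, loss)`` with ``loss = 1 - aupr_hat``.
    """
    labels = np.asarray(labels).reshape(-1)
    valid = np.asarray(valid, dtype=bool).reshape(-1)
    idx = np.where(valid)[0]
    y = labels[idx].astype(float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("soft AUPR undefined for single-class labels")
    p = probs.reshape(-1)[idx].reshape(1, -1)
    t = (np.arange(K_bins, 0, -1) - 0.5) / K_bins  # decreasing -> recall increasing
    s = ((p - Tensor(t[:, None])) / temperature).sigmoid()     # [K, n]
    tp = (s * Tensor(y[None, :])).sum(axis=1)
    fp = (s * Tensor(1.0 - y[None, :])).sum(axis=1)
    fn = ((1.0 - s) * Tensor(y[None, :])).sum(axis=1)
    prec = tp / (tp + fp + stabilizer_eps)
    rec = tp / (tp + fn + stabilizer_eps)
    prev = concat([Tensor(np.zeros(1)), rec[:-1]], axis=0)
    aupr_hat = (prec * (rec - prev)).sum()
    return aupr_hat, 1.0 - aupr_hat


def smoothness_penalty(probs: Tensor, edges: np.ndarray) -> Tensor:
    """Mean squared probability difference over (deduplicated) graph edges."""
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    if edges.shape[0] == 0:
        return Tensor(0.0)
    lo = np.minimum(edges[:, 0], edges[:, 1])
    hi = np.maximum(edges[:, 0], edges[:, 1])
    uniq = np.unique(np.stack([lo, hi], axis=1), axis=0)
    p = probs.reshape(-1)
    diff = p[uniq[:, 0]] - p[uniq[:, 1]]
    return (diff**2).mean()


def pos_weight_at_epoch(epoch: float, cfg: LossConfig) -> float:
    """w(e) = w_inf + (w0 - w_inf) * exp(-e / tau)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.w_inf + (cfg.w0 - cfg.w_inf) * float(np.exp(-epoch / cfg.tau_epochs))


def lambda_at_epoch(epoch: float, cfg: LossConfig) -> float:
    """Linear ramp of the smoothness coefficient over the configured interval."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    lo, hi = cfg.lambda_ramp
    if epoch < lo:
        return 0.0
    if epoch > hi:
        return cfg.lambda_max
    return cfg.lambda_max * (epoch - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Composite loss
# ---------------------------------------------------------------------------

def combined_loss(fwd: ForwardOutput, labels, graphs, epoch: float, task: str,
                  cfg: LossConfig | None = None) -> LossBreakdown:
    """Task-dispatching composite loss.

    ``labels``: LabelSet or list of LabelSets (one per batch item);
    ``graphs``: per-item undirected edge arrays in the same column
    coordinates as the logits (used by the smoothness term).  ``task`` is
    one of ``itf`` (full composite), ``ss`` or ``ctm`` (plain smoothed CE).
    """
    cfg = cfg or LossConfig()
    labels = labels if isinstance(labels, (list, tuple)) else [labels]
    if graphs is None:
        graphs = [np.empty((0, 2), dtype=int)] * len(labels)
    graphs = graphs if isinstance(graphs, (list, tuple)) else [graphs]
    B = len(labels)
    L = labels[0].valid.size
    valid = np.stack([lb.valid for lb in labels])           # [B, L]

    if task == "ss":
        lab = np.stack([lb.ss for lb in labels])
        v = valid & (lab >= 0)
        ce = weighted_smoothed_ce(fwd.logits_ss, np.where(v, lab, 0), v,
                                  w_pos=1.0, epsilon_smooth=cfg.epsilon_smooth)
        return LossBreakdown(ce, float(ce.data), 0.0, 0.0, 0.0, 0.0, 1.0)

    if task == "ctm":
        z = fwd.logits_ctm                                   # [B, 2, L, L]
        z = (z + z.swapaxes(-1, -2)) / 2.0                   # contact maps are symmetric
        z = z.transpose(0, 2, 3, 1)                          # [B, L, L, 2]
        lab = np.stack([lb.ctm for lb in labels])
        pv = np.stack([np.outer(lb.valid, lb.valid) for lb in labels])
        ce = weighted_smoothed_ce(z.reshape(-1, 2), lab.reshape(-1), pv.reshape(-1),
                                  w_pos=1.0, epsilon_smooth=cfg.epsilon_smooth)
        return LossBreakdown(ce, float(ce.data), 0.0, 0.0, 0.0, 0.0, 1.0)

    if task != "itf":
        raise ValueError(f"unknown task {task!r}")

    lab = np.stack([lb.itf for lb in labels])
    w_pos = pos_weight_at_epoch(epoch, cfg)
    lam = lambda_at_epoch(epoch, cfg)
    ce = weighted_smoothed_ce(fwd.logits_itf, lab, valid, w_pos=w_pos,
                              epsilon_smooth=cfg.epsilon_smooth)
    p_full = log_softmax(fwd.logits_itf.reshape(-1, 2), axis=-1).exp()[:, 1]  # [B*L]

    alpha = cfg.alpha
    fallback = False
    if alpha > 0:
        try:
            _, aupr_loss = soft_aupr(p_full, lab, valid, cfg.K_bins,
                                     cfg.temperature, cfg.stabilizer_eps)
        except ValueError:
            alpha, aupr_loss, fallback = 0.0, Tensor(0.0), True
    else:
        aupr_loss = Tensor(0.0)

    if lam > 0:
        offset_edges = [np.asarray(g, dtype=int).reshape(-1, 2) + b * L
                        for b, g in enumerate(graphs)]
        edges = np.concatenate(offset_edges, axis=0) if offset_edges else np.empty((0, 2), int)
        smooth = smoothness_penalty(p_full, edges)
    else:
        smooth = Tensor(0.0)

    total = (1.0 - alpha) * ce + alpha * aupr_loss + lam * smooth
    return LossBreakdown(total, float(ce.data), float(aupr_loss.data),
                         float(smooth.data), alpha, lam, w_pos, fallback)
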