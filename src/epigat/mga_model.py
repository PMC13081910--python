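"""Masked graph attention network for residue-level interface prediction.

Architecture (per forward pass):

1. token embedding of the stacked MSA matrix ``[B, M, L] → [B, M, L, D]``,
   immediately gated by a dynamic mask (DyM);
2. ``n_msa_blocks`` MSA blocks — row-wise self-attention computed
   independently within each chain segment, column-wise self-attention across
   the M alignment rows, and a position-wise feed-forward, every sublayer
   DyM-gated with a pre-norm residual;
3. the query row (row 0) is extracted, a learned positional embedding added,
   and ``n_gnn_layers`` of multi-head graph attention run over the residue
   contact graph;
4. ``n_attn_layers`` of full-length self-attention refine the representation;
   the final layer's attention weights ``[B, H, L, L]`` feed the contact-map
   head and are exported for interpretation;
5. task heads: secondary structure ``[B, L, 8]``, interface ``[B, L, 2]``,
   and contact map ``[B, 2, L, L]`` (a linear map over the head axis).

The dynamic mask (DyM) is the imbalance device: a sigmoid-activated linear
projection of each residue embedding yields a scalar in (0, 1) that
multiplicatively rescales that residue's features, letting the network
suppress the uninformative background and concentrate capacity on putative
interface residues.  All recorded mask values are exposed for interpretation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, embedding_lookup, index_select, scatter_add, stack
from .batch import ComplexBatch
from .nn import Dropout, FeedForward, LayerNorm, Linear, Module, MultiHeadSelfAttention
from .structure_io import ResidueGraph

HEAD_PREFIXES = ("head_ss", "head_itf", "head_ctm")


@dataclass
class ModelConfig:
    B: int = 4
    M: int = 64
    L: int = 1600
    D: int = 256
    H: int = 16
    n_msa_blocks: int = 2
    n_gnn_layers: int = 2
    n_attn_layers: int = 2
    ss_classes: int = 8
    itf_classes: int = 2
    dropout: float = 0.1
    drop_path: float = 0.0
    vocab_size: int = 24

    def __post_init__(self):
        if self.D % self.H:
            raise ValueError("D must be divisible by H")
        if min(self.n_msa_blocks, self.n_gnn_layers, self.n_attn_layers) < 1:
            raise ValueError("all depths must be >= 1")
        for r in (self.dropout, self.drop_path):
            if not 0 <= r < 1:
                raise ValueError("rates must lie in [0, 1)")


@dataclass
class ForwardOutput:
    logits_ss: Tensor      # [B, L, 8]
    logits_itf: Tensor     # [B, L, 2]
    logits_ctm: Tensor     # [B, 2, L, L]
    attn_last: Tensor      # [B, H, L, L]
    dym_masks: dict        # name -> [B, L] ndarray (query-row values)
    row_attn: np.ndarray | None = None  # optional diagnostic [B, H, L, L]


def partition_of(name: str) -> str:
    head = name.split(".", 1)[0]
    return head if head in HEAD_PREFIXES else "backbone"


@dataclass
class ModelState:
    """Named parameter snapshot plus per-parameter partition labels."""

    params: dict                       # name -> ndarray
    config: ModelConfig

    @property
    def partition(self) -> dict:
        return {name: partition_of(name) for name in self.params}

    def copy(self) -> "ModelState":
        return ModelState({k: v.copy() for k, v in self.params.items()}, self.config)

    def save(self, prefix):
        prefix = Path(prefix)
        np.savez(str(prefix) + ".npz", **self.params)
        meta = {"config": asdict(self.config), "partition": self.partition}
        Path(str(prefix) + ".json").write_text(json.dumps(meta, indent=1) + "\n")

    @staticmethod
    def load(prefix) -> "ModelState":
        prefix = Path(prefix)
        with np.load(str(prefix) + ".npz") as z:
            params = {k: z[k].copy() for k in z.files}
        meta = json.loads(Path(str(prefix) + ".json").read_text())
        return ModelState(params, ModelConfig(**meta["config"]))


class DyMGate(Module):
    """Dynamic mask: per-position sigmoid gate, one scalar broadcast over D."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.proj = Linear(dim, 1, rng)

    def __call__(self, x: Tensor):
        mask = self.proj(x).sigmoid()      # [..., T, 1]
        return x * mask, mask


def dym_gate(x: Tensor, gate: DyMGate):
    """Functional form of the dynamic-mask gate (returns gated value and mask)."""
    return gate(x)


class _GatedSublayer(Module):
    """Pre-norm residual wrapper: x + dropout(DyM(f(LN(x))))."""

    def __init__(self, dim: int, rng: np.random.Generator, dropout: float):
        super().__init__()
        self.norm = LayerNorm(dim)
        self.gate = DyMGate(dim, rng)
        self.drop = Dropout(dropout)


class MSABlock(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        D = cfg.D
        self.row = _GatedSublayer(D, rng, cfg.dropout)
        self.row_attn = MultiHeadSelfAttention(D, cfg.H, rng)
        self.col = _GatedSublayer(D, rng, cfg.dropout)
        self.col_attn = MultiHeadSelfAttention(D, cfg.H, rng)
        self.ffw = _GatedSublayer(D, rng, cfg.dropout)
        self.ffn = FeedForward(D, 2 * D, rng)

    def __call__(self, x: Tensor, spans, valid_cols, row_mask, *, gates=True,
                 rng=None, record=None, name="", record_row_attn=False):
        M, L, D = x.shape

        # --- row-wise attention, independent within each chain span ---------
        h = self.row.norm(x)
        pieces, attn_blocks = [], []
        cursor = 0
        for s, e in spans:
            if s > cursor:
                pieces.append(Tensor(np.zeros((M, s - cursor, D))))
            out, attn = self.row_attn(h[:, s:e, :], valid_cols[s:e])
            pieces.append(out)
            attn_blocks.append((s, e, attn.data))
            cursor = e
        if cursor < L:
            pieces.append(Tensor(np.zeros((M, L - cursor, D))))
        upd = concat(pieces, axis=1)
        x = self._apply(x, upd, self.row, gates, rng, record, name + ".row")

        row_attn_full = None
        if record_row_attn:
            H = attn_blocks[0][2].shape[1] if attn_blocks else 0
            row_attn_full = np.zeros((M, H, L, L))
            for s, e, a in attn_blocks:
                row_attn_full[:, :, s:e, s:e] = a

        # --- column-wise attention across alignment rows ---------------------
        h = self.col.norm(x)
        ht = h.swapaxes(0, 1)                      # [L, M, D]
        out, _ = self.col_attn(ht, row_mask.T)     # key mask [L, M]
        upd = out.swapaxes(0, 1)
        x = self._apply(x, upd, self.col, gates, rng, record, name + ".col")

        # --- position-wise feed-forward --------------------------------------
        upd = self.ffn(self.ffw.norm(x))
        x = self._apply(x, upd, self.ffw, gates, rng, record, name + ".ffn")
        return x, row_attn_full

    @staticmethod
    def _apply(x, upd, sub: _GatedSublayer, gates, rng, record, key):
        if gates:
            upd, mask = sub.gate(upd)
            if record is not None:
                val = mask.data[..., 0]
                record[key] = val[0] if val.ndim == 2 else val  # query row for MSA-stage masks
        return x + sub.drop(upd, rng)


class GraphAttentionLayer(Module):
    """Multi-head graph attention over an explicit directed edge list."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        D, H = cfg.D, cfg.H
        self.dh = D // H
        self.heads = H
        self.norm = LayerNorm(D)
        self.w = Linear(D, D, rng, bias=False)
        self.a_src = Tensor(rng.normal(0, 0.1, size=(H, self.dh)), requires_grad=True)
        self.a_dst = Tensor(rng.normal(0, 0.1, size=(H, self.dh)), requires_grad=True)
        self.out = Linear(D, D, rng)
        self.gate = DyMGate(D, rng)
        self.drop = Dropout(cfg.dropout)

    def __call__(self, h: Tensor, src: np.ndarray, dst: np.ndarray, *,
                 gates=True, rng=None, record=None, name=""):
        L, D = h.shape
        H, dh = self.heads, self.dh
        z = self.w(self.norm(h)).reshape(L, H, dh)
        s_src = (z * self.a_src).sum(axis=-1)      # [L, H]
        s_dst = (z * self.a_dst).sum(axis=-1)
        e = (index_select(s_src, src) + index_select(s_dst, dst)).leaky_relu(0.2)
        # per-destination max shift (constant) for a stable segment softmax
        shift = np.full((L, H), -np.inf)
        np.maximum.at(shift, dst, e.data)
        shift = np.where(np.isfinite(shift), shift, 0.0)
        ex = (e - Tensor(shift[dst])).exp()
        denom = scatter_add(ex, dst, L)
        alpha = ex / index_select(denom, dst)      # [E, H]
        msg = alpha.reshape(-1, H, 1) * index_select(z, src)
        agg = scatter_add(msg, dst, L).reshape(L, D)
        upd = self.out(agg)
        if gates:
            upd, mask = self.gate(upd)
            if record is not None:
                record[name] = mask.data[:, 0]
        return h + self.drop(upd, rng)


class AttentionLayer(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        D = cfg.D
        self.att = _GatedSublayer(D, rng, cfg.dropout)
        self.mha = MultiHeadSelfAttention(D, cfg.H, rng)
        self.ffw = _GatedSublayer(D, rng, cfg.dropout)
        self.ffn = FeedForward(D, 2 * D, rng)

    def __call__(self, x: Tensor, valid_cols, *, gates=True, rng=None,
                 record=None, name=""):
        out, attn = self.mha(self.att.norm(x), valid_cols)
        x = MSABlock._apply(x, out, self.att, gates, rng, record, name + ".attn")
        upd = self.ffn(self.ffw.norm(x))
        x = MSABlock._apply(x, upd, self.ffw, gates, rng, record, name + ".ffn")
        return x, attn


class MaskedGraphAttentionNet(Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        object.__setattr__(self, "cfg", cfg)
        object.__setattr__(self, "gates_enabled", True)
        self.embed = Tensor(rng.normal(0, 0.02, size=(cfg.vocab_size, cfg.D)),
                            requires_grad=True)
        self.gate_embed = DyMGate(cfg.D, rng)
        self.msa_blocks = [MSABlock(cfg, rng) for _ in range(cfg.n_msa_blocks)]
        self.pos_emb = Tensor(rng.normal(0, 0.02, size=(cfg.L, cfg.D)),
                              requires_grad=True)
        self.gnn_layers = [GraphAttentionLayer(cfg, rng) for _ in range(cfg.n_gnn_layers)]
        self.attn_layers = [AttentionLayer(cfg, rng) for _ in range(cfg.n_attn_layers)]
        self.head_ss = Linear(cfg.D, cfg.ss_classes, rng)
        self.head_itf = Linear(cfg.D, cfg.itf_classes, rng)
        self.head_ctm = Linear(cfg.H, 2, rng)

    # ---- spec operations, batched over leading axis -------------------------
    def embed_tokens(self, tokens: np.ndarray) -> Tensor:
        """[B, M, L] int → [B, M, L, D] learned lookup."""
        tokens = np.asarray(tokens)
        if tokens.min() < 0 or tokens.max() >= self.cfg.vocab_size:
            raise ValueError("token id outside vocabulary range")
        return embedding_lookup(self.embed, tokens)

    @staticmethod
    def extract_query(x: Tensor) -> Tensor:
        """[B, M, L, D] → [B, 1, L, D], the query-row slice."""
        return x[:, 0:1]

    def gnn_forward(self, x: Tensor, graph: ResidueGraph, *, valid_cols=None) -> Tensor:
        """[B, 1, L, D] through positional embedding + graph attention stack."""
        B, _, L, D = x.shape
        if len(graph.edges) and graph.edges.max() >= L:
            raise ValueError("graph edge index exceeds padded length")
        e = graph.edges
        loops = np.arange(graph.n_residues)
        src = np.concatenate([e[:, 0], e[:, 1], loops]) if len(e) else loops
        dst = np.concatenate([e[:, 1], e[:, 0], loops]) if len(e) else loops
        outs = []
        for b in range(B):
            h = x[b, 0] + self.pos_emb[:L]
            for i, layer in enumerate(self.gnn_layers):
                h = layer(h, src, dst, gates=self.gates_enabled)
            outs.append(h)
        return stack(outs, axis=0).reshape(B, 1, L, D)

    def attention_module(self, x: Tensor, valid_cols: np.ndarray):
        """[B, 1, L, D] → refined features and last-layer attention [B, H, L, L]."""
        B, _, L, D = x.shape
        feats, attns = [], []
        for b in range(B):
            h = x[b, 0]
            attn = None
            for i, layer in enumerate(self.attn_layers):
                h, attn = layer(h, valid_cols[b], gates=self.gates_enabled)
            feats.append(h)
            attns.append(attn)
        return (stack(feats, axis=0).reshape(B, 1, L, D), stack(attns, axis=0))

    # ---- full forward --------------------------------------------------------
    def _forward_one(self, item: ComplexBatch, rng=None, record_row_attn=False):
        cfg = self.cfg
        record: dict = {}
        emb = self.embed_tokens(item.tokens[None])[0]        # [M, L, D]
        if self.gates_enabled:
            emb, mask = self.gate_embed(emb)
            record["embed"] = mask.data[0, :, 0]
        spans = _attention_spans(item.chain_segments)
        row_attn = None
        x = emb
        for i, blk in enumerate(self.msa_blocks):
            x, ra = blk(x, spans, item.valid_cols, item.row_mask,
                        gates=self.gates_enabled, rng=rng, record=record,
                        name=f"msa{i}", record_row_attn=record_row_attn)
            if ra is not None:
                row_attn = ra
        q = x[0] + self.pos_emb[:item.L]                     # [L, D]
        for i, layer in enumerate(self.gnn_layers):
            q = layer(q, item.gnn_src, item.gnn_dst, gates=self.gates_enabled,
                      rng=rng, record=record, name=f"gnn{i}")
        attn = None
        for i, layer in enumerate(self.attn_layers):
            q, attn = layer(q, item.valid_cols, gates=self.gates_enabled,
                            rng=rng, record=record, name=f"attn{i}")
        logits_ss = self.head_ss(q)
        logits_itf = self.head_itf(q)
        # contact head: linear map over the attention-head axis
        ctm_in = attn.transpose(1, 2, 0)                     # [L, L, H]
        logits_ctm = self.head_ctm(ctm_in).transpose(2, 0, 1)  # [2, L, L]
        return dict(ss=logits_ss, itf=logits_itf, ctm=logits_ctm, attn=attn,
                    record=record, row_attn=row_attn)

    def forward(self, items, rng=None, record_row_attn=False) -> ForwardOutput:
        if isinstance(items, ComplexBatch):
            items = [items]
        outs = [self._forward_one(it, rng=rng, record_row_attn=record_row_attn)
                for it in items]
        masks = {}
        for key in outs[0]["record"]:
            masks[key] = np.stack([o["record"][key] for o in outs])
        row_attn = None
        if record_row_attn and outs[0]["row_attn"] is not None:
            row_attn = np.stack([o["row_attn"] for o in outs])
        return ForwardOutput(
            logits_ss=stack([o["ss"] for o in outs]),
            logits_itf=stack([o["itf"] for o in outs]),
            logits_ctm=stack([o["ctm"] for o in outs]),
            attn_last=stack([o["attn"] for o in outs]),
            dym_masks=masks,
            row_attn=row_attn,
        )

    __call__ = forward

    # ---- state handling ------------------------------------------------------
    def get_state(self) -> ModelState:
        return ModelState(self.state_dict(), self.cfg)

    def set_state(self, state: ModelState, mode: str = "strict"):
        if mode == "strict":
            self.load_state_dict(state.params)
        elif mode == "backbone":
            own = dict(self.named_parameters())
            for name, arr in state.params.items():
                if partition_of(name) == "backbone":
                    if name not in own:
                        raise KeyError(f"backbone parameter {name} missing in model")
                    if own[name].data.shape != arr.shape:
                        raise ValueError(f"backbone shape mismatch for {name}")
                    own[name].data = arr.copy()
        else:
            raise ValueError(f"unknown load mode {mode!r}")

    def saturate_gates(self, bias: float = 40.0):
        """Push every DyM gate toward 1 (diagnostic: recovers the ungated net)."""
        for name, p in self.named_parameters():
            if ".gate.proj." in name or name.startswith("gate_embed.proj."):
                p.data = np.full_like(p.data, bias) if p.data.ndim == 1 else np.zeros_like(p.data)


def _attention_spans(chain_segments) -> list:
    """Row-attention spans: each chain's residue columns plus its eoc column."""
    spans = []
    for _, start, end in chain_segments:
        spans.append((start, end + 1))
    for (a, b), (c, d) in zip(spans, spans[1:]):
        if b != c:
            raise ValueError("chain segments must be contiguous")
    if spans and spans[0][0] != 0:
        raise ValueError("first chain segment must start at column 0")
    return spans
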