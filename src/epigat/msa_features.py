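"""Multiple-sequence-alignment featurization.

Per-chain alignments (a3m or aligned FASTA) are reduced to a fixed number of
diverse rows, tokenized with an ESM-style vocabulary, and stacked along the
length axis in the order heavy → light → antigen, one end-of-chain column
after each chain, padded to a fixed length L.  The resulting integer matrix
[M, L] (query in row 0) is what the model embeds; graph indices are expressed
in the same column coordinate system so sequence and structure line up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_io import AA_ORDER, ROLES

DEFAULT_M = 64
DEFAULT_L = 1600


@dataclass(frozen=True)
class TokenVocabulary:
    """Symbol → id table: 20 amino acids + unknown, gap, padding, end-of-chain."""

    symbols: tuple = tuple(AA_ORDER) + ("X", "-", "<pad>", "<eoc>")

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("duplicate symbols in vocabulary")

    def __len__(self):
        return len(self.symbols)

    @property
    def pad_id(self) -> int:
        return self.symbols.index("<pad>")

    @property
    def eoc_id(self) -> int:
        return self.symbols.index("<eoc>")

    @property
    def gap_id(self) -> int:
        return self.symbols.index("-")

    @property
    def unk_id(self) -> int:
        return self.symbols.index("X")

    def encode(self, seq: str) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.symbols)}
        unk = self.unk_id
        return np.array([idx.get(c, unk) for c in seq.upper()], dtype=int)

    def decode(self, ids) -> str:
        return "".join(self.symbols[i] for i in ids)


@dataclass
class MSAMatrix:
    tokens: np.ndarray                 # [M, L] int
    chain_segments: list               # [(role, start, end)] half-open, residue columns
    valid_cols: np.ndarray             # [L] bool (residue + eoc columns)
    vocab: TokenVocabulary = field(default_factory=TokenVocabulary)

    def __post_init__(self):
        if self.tokens.min() < 0 or self.tokens.max() >= len(self.vocab):
            raise ValueError("token id outside vocabulary range")

    @property
    def M(self) -> int:
        return self.tokens.shape[0]

    @property
    def L(self) -> int:
        return self.tokens.shape[1]

    def residue_columns(self) -> np.ndarray:
        """Column index of each residue in concatenated global residue order."""
        cols = []
        for _, start, end in self.chain_segments:
            cols.extend(range(start, end))
        return np.array(cols, dtype=int)

    def row_mask(self) -> np.ndarray:
        """[M, L] bool — True where a token is not padding."""
        return self.tokens != self.vocab.pad_id


# ---------------------------------------------------------------------------
# Reading alignments
# ---------------------------------------------------------------------------

def read_alignment(path) -> list:
    """Read an a3m or aligned-FASTA file; first record is the query.

    a3m lowercase insertion states are removed so every row shares the query's
    column space.
    """
    path = Path(path)
    records = []
    header, seq = None, []
    for line in path.read_text().splitlines():
        if line.startswith(">"):
            if header is not None:
                records.append("".join(seq))
            header, seq = line, []
        elif line.strip():
            seq.append(line.strip())
    if header is not None:
        records.append("".join(seq))
    if not records:
        raise ValueError(f"empty alignment file {path}")
    cleaned = ["".join(c for c in s if not c.islower()) for s in records]
    lengths = {len(s) for s in cleaned}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment after a3m normalization in {path}: lengths {sorted(lengths)}")
    return cleaned


# ---------------------------------------------------------------------------
# Diversity selection
# ---------------------------------------------------------------------------

def _onehot_profile(seqs: list, vocab: TokenVocabulary) -> np.ndarray:
    toks = np.stack([vocab.encode(s) for s in seqs])
    n, L = toks.shape
    V = len(vocab)
    out = np.zeros((n, L * V))
    out[np.arange(n)[:, None], np.arange(L)[None, :] * V + toks] = 1.0
    return out


def select_diverse_rows(seqs: list, M: int = DEFAULT_M, seed: int = 0,
                        vocab: TokenVocabulary | None = None) -> list:
    """Pick M rows maximizing diversity: query first, then one representative
    per k-means cluster (M−1 centers over one-hot column profiles)."""
    from sklearn.cluster import KMeans

    if M < 1:
        raise ValueError("M must be >= 1")
    if not seqs:
        raise ValueError("no sequences")
    if len(seqs) <= M:
        return list(seqs)
    vocab = vocab or TokenVocabulary()
    query, rest = seqs[0], seqs[1:]
    feats = _onehot_profile(rest, vocab)
    k = M - 1
    km = KMeans(n_clusters=k, random_state=seed, n_init=4).fit(feats)
    picks = []
    for c in range(k):
        d = np.linalg.norm(feats - km.cluster_centers_[c], axis=1)
        order = np.argsort(d, kind="stable")
        picks.append(int(order[0]))
    # de-duplicate while preserving order, then top up with the most distant
    # unused rows so the output size is exactly M
    seen, uniq = set(), []
    for p in picks:
        if p not in seen:
            seen.add(p)
            uniq.append(p)
    if len(uniq) < k:
        dmin = np.min(np.linalg.norm(
            feats[:, None, :] - km.cluster_centers_[None, :, :], axis=2), axis=1)
        for p in np.argsort(-dmin, kind="stable"):
            if int(p) not in seen:
                uniq.append(int(p))
                seen.add(int(p))
            if len(uniq) == k:
                break
    return [query] + [rest[i] for i in uniq]


# ---------------------------------------------------------------------------
# Tokenization and stacking
# ---------------------------------------------------------------------------

def tokenize_and_stack(per_chain_msas: dict, vocab: TokenVocabulary | None = None,
                       M: int = DEFAULT_M, L: int = DEFAULT_L,
                       reference_sequences: dict | None = None) -> MSAMatrix:
    """Stack per-chain alignments into one [M, L] token matrix.

    ``per_chain_msas`` maps role → list of aligned sequences (query first).
    ``reference_sequences`` (role → query string from the structure) is
    checked against each alignment's query when provided.
    """
    vocab = vocab or TokenVocabulary()
    roles = [r for r in ROLES if r in per_chain_msas]
    total = sum(len(per_chain_msas[r][0]) for r in roles) + len(roles)
    if total > L:
        raise ValueError(f"stacked length {total} exceeds L={L}; increase L")
    if reference_sequences:
        for role in roles:
            ref = reference_sequences.get(role)
            if ref is None:
                continue
            q = per_chain_msas[role][0].replace("-", "")
            if q != ref:
                mism = next((i for i, (a, b) in enumerate(zip(q, ref)) if a != b),
                            min(len(q), len(ref)))
                raise ValueError(
                    f"{role} chain query disagrees with structure sequence at position {mism}")

    tokens = np.full((M, L), vocab.pad_id, dtype=int)
    valid = np.zeros(L, dtype=bool)
    segments = []
    cursor = 0
    for role in roles:
        seqs = per_chain_msas[role]
        width = len(seqs[0])
        for m, s in enumerate(seqs[:M]):
            tokens[m, cursor:cursor + width] = vocab.encode(s)
        segments.append((role, cursor, cursor + width))
        valid[cursor:cursor + width] = True
        tokens[:, cursor + width] = vocab.eoc_id
        valid[cursor + width] = True
        cursor += width + 1
    return MSAMatrix(tokens=tokens, chain_segments=segments, valid_cols=valid, vocab=vocab)


def save_msa(msa: MSAMatrix, prefix):
    """Write the token matrix (TSV) plus a JSON sidecar."""
    prefix = Path(prefix)
    np.savetxt(str(prefix) + ".tokens.tsv", msa.tokens, fmt="%d", delimiter="\t")
    sidecar = {
        "M": msa.M, "L": msa.L,
        "segments": [[r, int(a), int(b)] for r, a, b in msa.chain_segments],
        "valid_cols": msa.valid_cols.astype(int).tolist(),
        "vocab": list(msa.vocab.symbols),
    }
    Path(str(prefix) + ".json").write_text(json.dumps(sidecar) + "\n")


def load_msa(prefix) -> MSAMatrix:
    prefix = Path(prefix)
    tokens = np.loadtxt(str(prefix) + ".tokens.tsv", dtype=int, delimiter="\t", ndmin=2)
    sidecar = json.loads(Path(str(prefix) + ".json").read_text())
    return MSAMatrix(
        tokens=tokens,
        chain_segments=[(r, a, b) for r, a, b in sidecar["segments"]],
        valid_cols=np.array(sidecar["valid_cols"], dtype=bool),
        vocab=TokenVocabulary(tuple(sidecar["vocab"])),
    )
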