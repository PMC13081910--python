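"""Per-complex feature bundle consumed by the network.

Everything lives in the *column* coordinate system of the stacked MSA matrix
(residue columns plus one end-of-chain column per chain, then padding), so the
token matrix, the residue graph and the label tensors share indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa_features import MSAMatrix
from .structure_io import ComplexStructure, LabelSet, ResidueGraph


@dataclass
class ComplexBatch:
    complex_id: str
    tokens: np.ndarray          # [M, L] int
    valid_cols: np.ndarray      # [L] bool (residue + eoc columns)
    residue_cols: np.ndarray    # [N] column index of each residue (global order)
    chain_segments: list        # [(role, start, end)] residue columns, half-open
    gnn_src: np.ndarray         # directed edges incl. self-loops, column coords
    gnn_dst: np.ndarray
    labels: LabelSet | None
    sides: np.ndarray           # [L] '', 'antibody' or 'antigen' per column
    restypes: np.ndarray        # [L] one-letter code or '' per column
    row_mask: np.ndarray = None  # [M, L] bool, token != pad
    col_edges: np.ndarray = None  # [E, 2] undirected residue-column edges

    @property
    def L(self) -> int:
        return self.tokens.shape[1]

    @property
    def M(self) -> int:
        return self.tokens.shape[0]


def make_batch(cx: ComplexStructure, msa: MSAMatrix, graph: ResidueGraph,
               itf: np.ndarray, ss: np.ndarray | None = None,
               ctm: np.ndarray | None = None, complex_id: str = "") -> ComplexBatch:
    """Assemble a :class:`ComplexBatch`, re-indexing residue-level arrays into
    MSA column coordinates."""
    L = msa.L
    cols = msa.residue_columns()
    n = cx.n_residues
    if len(cols) != n:
        raise ValueError(f"MSA has {len(cols)} residue columns, complex has {n} residues")
    # attention sees residue + end-of-chain columns; losses see residues only
    valid = np.zeros(L, dtype=bool)
    valid[cols] = True

    itf_l = np.zeros(L, dtype=int)
    itf_l[cols] = itf
    ss_l = np.full(L, -1, dtype=int)
    if ss is not None:
        ss_l[cols] = ss
    ctm_l = np.zeros((L, L), dtype=int)
    if ctm is not None:
        ctm_l[np.ix_(cols, cols)] = ctm
    labels = LabelSet(ss=ss_l, itf=itf_l, ctm=ctm_l, valid=valid)

    # directed edge list with self-loops on residue columns
    if len(graph.edges):
        col_edges = cols[graph.edges]  # [E, 2] in column coords
        src = np.concatenate([col_edges[:, 0], col_edges[:, 1], cols])
        dst = np.concatenate([col_edges[:, 1], col_edges[:, 0], cols])
    else:
        col_edges = np.empty((0, 2), dtype=int)
        src = dst = cols.copy()

    sides = np.full(L, "", dtype=object)
    restypes = np.full(L, "", dtype=object)
    res_sides = cx.side_of()
    for i, res in enumerate(cx.residues):
        sides[cols[i]] = res_sides[i]
        restypes[cols[i]] = res.restype

    return ComplexBatch(
        complex_id=complex_id, tokens=msa.tokens, valid_cols=msa.valid_cols.copy(),
        residue_cols=cols, chain_segments=list(msa.chain_segments),
        gnn_src=src.astype(int), gnn_dst=dst.astype(int),
        labels=labels, sides=np.array(sides, dtype=object),
        restypes=np.array(restypes, dtype=object),
        row_mask=msa.row_mask(),
        col_edges=col_edges.astype(int),
    )
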