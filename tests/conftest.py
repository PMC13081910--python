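"""Shared fixtures: random complexes for geometry oracles, tiny model
configs, and a small synthetic training set reused across training tests."""

from __future__ import annotations

import numpy as np
import pytest

from epigat.mga_model import ModelConfig
from epigat.structure_io import AA_ORDER, ComplexStructure, Residue
from epigat.synthetic import SyntheticSpec, synthetic_batches


def random_complex(rng: np.random.Generator, n_ab: int = 12, n_ag: int = 12,
                   box: float = 18.0, with_light: bool = False) -> ComplexStructure:
    """Random two/three-chain complex with 1-4 atoms per residue, coordinates
    in a box sized so that cross- and intra-chain contacts occur at 10 Å."""

    def chain(cid, n, offset):
        residues = []
        for i in range(n):
            k = int(rng.integers(1, 5))
            coords = rng.uniform(0, box, size=(k, 3)) + offset
            names = ["CA"] + [f"C{chr(ord('B') + j)}" for j in range(k - 1)]
            heavy = np.ones(k, dtype=bool)
            if k > 2 and rng.random() < 0.3:
                names[-1] = "H1"        # occasional hydrogen: heavy-only subset differs
                heavy[-1] = False
            residues.append(Residue(
                chain_id=cid, ordinal=i,
                restype=str(rng.choice(list(AA_ORDER))),
                atom_names=names, coords=coords, is_heavy=heavy))
        return residues

    chains = [("heavy", chain("H", n_ab, np.zeros(3)))]
    if with_light:
        chains.append(("light", chain("L", max(2, n_ab // 2), np.array([box, 0, 0]))))
    chains.append(("antigen", chain("A", n_ag, np.array([box / 2, 4.0, 0]))))
    return ComplexStructure(chains=chains)


def brute_force_edges(cx: ComplexStructure, cutoff: float, atom_subset: str = "all"):
    """O(N² a²) reference for adjacency/contact construction."""
    residues = cx.residues
    edges = []
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            ci = residues[i].heavy_coords if atom_subset == "heavy" else residues[i].coords
            cj = residues[j].heavy_coords if atom_subset == "heavy" else residues[j].coords
            d = np.linalg.norm(ci[:, None, :] - cj[None, :, :], axis=2)
            if d.min() <= cutoff:
                edges.append((i, j))
    return np.array(sorted(edges), dtype=int).reshape(-1, 2)


def brute_force_interface(cx: ComplexStructure, cutoff: float):
    """Reference interface labels: min cross-side heavy-atom distance threshold."""
    residues = cx.residues
    sides = cx.side_of()
    labels = np.zeros(len(residues), dtype=int)
    for i in range(len(residues)):
        for j in range(len(residues)):
            if sides[i] == sides[j]:
                continue
            d = np.linalg.norm(residues[i].heavy_coords[:, None, :]
                               - residues[j].heavy_coords[None, :, :], axis=2)
            if d.min() <= cutoff:
                labels[i] = 1
    return labels


@pytest.fixture(scope="session")
def tiny_cfg() -> ModelConfig:
    return ModelConfig(B=1, M=4, L=64, D=32, H=4, n_msa_blocks=1,
                       n_gnn_layers=1, n_attn_layers=1, dropout=0.0)


@pytest.fixture(scope="session")
def tiny_batches():
    """Eight featurized synthetic complexes (shared; treat as read-only)."""
    return synthetic_batches(8, SyntheticSpec(), seed=101, M=4, L=64)


MINIMAL_PDB = """\
ATOM      1  N   ALA H   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA H   1       1.400   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY H   2       5.000   0.000   0.000  1.00  0.00           C
ATOM      4  CA  SER L   1       0.000   8.000   0.000  1.00  0.00           C
ATOM      5  CA  THR L   2       4.000   8.000   0.000  1.00  0.00           C
ATOM      6  CA  TYR A   1      30.000   0.000   0.000  1.00  0.00           C
ATOM      7  CB  TYR A   1      31.200   0.700   0.000  1.00  0.00           C
ATOM      8  CA  ASN A   2      34.000   0.000   0.000  1.00  0.00           C
ATOM      9  CA  TRP A   3      38.000   0.000   0.000  1.00  0.00           C
HETATM   10  O   HOH A 101      40.000   5.000   0.000  1.00  0.00           O
END
"""
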