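"""Parse antibody–antigen complexes and derive residue-level geometric labels.

A complex is held as a :class:`ComplexStructure`: chains ordered
heavy → light → antigen, each chain a list of residues carrying their atoms.
From it we derive

* a residue adjacency graph (edge iff any atom pair within a cutoff,
  default 10 Å over *all* atoms),
* binary interface labels (residue positive iff any *heavy* atom lies within
  the cutoff of a heavy atom on the opposite side; 10 Å default, 4.5 Å as the
  conventional contact definition),
* a symmetric binary contact map with unit diagonal, and
* an 8-class secondary-structure assignment (from a precomputed label file,
  or a coarse φ/ψ fallback).

Adjacency intentionally uses all atoms while interface labels use heavy atoms
only — the two criteria differ and both are kept, with ``atom_subset``
overrides.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

ROLES = ("heavy", "light", "antigen")

STANDARD_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_AA3 = {v: k for k, v in STANDARD_AA3.items()}
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"  # alphabetical one-letter order

#: default 8-letter secondary-structure alphabet (DSSP-style); configurable.
SS_ALPHABET = "HGIEBTSC"


@dataclass
class AtomRecord:
    chain_id: str
    residue_ordinal: int
    residue_type: str  # one-letter code
    atom_name: str
    is_heavy: bool
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")


@dataclass
class Residue:
    chain_id: str
    ordinal: int
    restype: str  # one-letter
    atom_names: list
    coords: np.ndarray  # [n_atoms, 3]
    is_heavy: np.ndarray  # [n_atoms] bool
    author_id: str = ""  # original residue numbering, metadata only

    @property
    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.is_heavy]


@dataclass
class ComplexStructure:
    """Chains with roles; residues concatenated heavy → light → antigen."""

    chains: list  # list of (role, list[Residue])

    def __post_init__(self):
        seen = [r for r, _ in self.chains if r != "antigen"]
        if len(seen) != len(set(seen)):
            raise ValueError("heavy/light roles must be unique per complex")
        for role, residues in self.chains:
            if role not in ROLES:
                raise ValueError(f"unknown chain role {role!r}")
            for res in residues:
                if not res.is_heavy.any():
                    raise ValueError(
                        f"residue {res.chain_id}:{res.ordinal} has no heavy atom")

    @property
    def residues(self) -> list:
        out = []
        for role in ROLES:
            for r, residues in self.chains:
                if r == role:
                    out.extend(residues)
        return out

    @property
    def n_residues(self) -> int:
        return sum(len(res) for _, res in self.chains)

    @property
    def global_index(self) -> dict:
        return {(res.chain_id, res.ordinal): i for i, res in enumerate(self.residues)}

    def side_of(self) -> np.ndarray:
        """Per-residue side label: 'antibody' or 'antigen', in global order."""
        sides = []
        for role in ROLES:
            for r, residues in self.chains:
                if r == role:
                    sides.extend(["antigen" if role == "antigen" else "antibody"] * len(residues))
        return np.array(sides)

    def roles_per_residue(self) -> np.ndarray:
        out = []
        for role in ROLES:
            for r, residues in self.chains:
                if r == role:
                    out.extend([role] * len(residues))
        return np.array(out)

    def sequence(self, role: str) -> str:
        parts = [ "".join(res.restype for res in residues)
                  for r, residues in self.chains if r == role ]
        return "".join(parts)

    def sequences(self) -> dict:
        return {role: self.sequence(role) for role in ROLES if self.sequence(role)}


@dataclass
class ResidueGraph:
    n_residues: int
    edges: np.ndarray  # [E, 2], undirected, i < j
    cutoff_angstrom: float
    atom_subset: str = "all"

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if self.edges.size:
            if (self.edges[:, 0] >= self.edges[:, 1]).any():
                raise ValueError("edges must be stored once with i < j")
            if self.edges.max() >= self.n_residues:
                raise ValueError("edge index out of range")


@dataclass
class InterfaceDefinition:
    cutoff_angstrom: float = 10.0
    atom_subset: str = "heavy"

    def __post_init__(self):
        if self.cutoff_angstrom <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class LabelSet:
    ss: np.ndarray          # [L] int, -1 where missing/padded
    itf: np.ndarray         # [L] int {0,1}, 0 at padding
    ctm: np.ndarray         # [L, L] int
    valid: np.ndarray       # [L] bool
    ctm_valid: np.ndarray = None  # [L, L] bool

    def __post_init__(self):
        if self.ctm_valid is None:
            self.ctm_valid = np.outer(self.valid, self.valid)
        v = self.ctm_valid
        if not np.array_equal(self.ctm * v, (self.ctm * v).T):
            raise ValueError("contact map must be symmetric on valid positions")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _load_atom_array(path: Path):
    import biotite.structure.io.pdb as pdbio
    import biotite.structure.io.pdbx as pdbxio

    suffix = path.suffix.lower()
    try:
        if suffix in (".cif", ".mmcif", ".pdbx"):
            f = pdbxio.CIFFile.read(str(path))
            return pdbxio.get_structure(f, model=1, altloc="occupancy")
        f = pdbio.PDBFile.read(str(path))
        return pdbio.get_structure(f, model=1, altloc="occupancy")
    except Exception as exc:  # pragma: no cover - passthrough formatting
        raise ValueError(f"could not parse structure file {path}: {exc}") from exc


def parse_structure(path, chain_roles: dict) -> ComplexStructure:
    """Read a PDB/mmCIF file into a :class:`ComplexStructure`.

    Parameters
    ----------
    path : str or Path
        Structure file; format chosen by extension (.pdb vs .cif).
    chain_roles : dict
        Mapping chain id → role in {heavy, light, antigen}.  Multiple chains
        may map to ``antigen``; heavy/light must be unique.  A light chain may
        be absent (single-domain antibodies).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    atoms = _load_atom_array(path)
    present = set(np.unique(atoms.chain_id))
    for cid in chain_roles:
        if cid not in present:
            raise ValueError(f"chain {cid!r} not found in {path.name}; "
                             f"file has chains {sorted(present)}")
    role_order = {"heavy": 0, "light": 1, "antigen": 2}
    ordered = sorted(chain_roles.items(), key=lambda kv: (role_order[kv[1]], kv[0]))

    chains = []
    for cid, role in ordered:
        sel = atoms[atoms.chain_id == cid]
        residues = []
        n_dropped = 0
        # group by (res_id, ins_code) in order of appearance
        keys = list(zip(sel.res_id.tolist(), sel.ins_code.tolist()))
        seen: dict = {}
        for k in keys:
            if k not in seen:
                seen[k] = len(seen)
        for k in seen:
            mask = (sel.res_id == k[0]) & (sel.ins_code == k[1])
            grp = sel[mask]
            res_name = grp.res_name[0]
            if res_name not in STANDARD_AA3:
                n_dropped += 1
                continue
            heavy = np.array([e.upper() not in ("H", "D") for e in grp.element])
            if not heavy.any():
                n_dropped += 1
                continue
            residues.append(Residue(
                chain_id=cid,
                ordinal=len(residues),
                restype=STANDARD_AA3[res_name],
                atom_names=list(grp.atom_name),
                coords=np.asarray(grp.coord, dtype=float),
                is_heavy=heavy,
                author_id=f"{k[0]}{k[1].strip() if isinstance(k[1], str) else ''}",
            ))
        if n_dropped:
            logger.warning("chain %s: dropped %d non-standard residue(s)", cid, n_dropped)
        if not residues:
            raise ValueError(f"chain {cid!r} contains zero standard residues")
        chains.append((role, residues))
    return ComplexStructure(chains=chains)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _atom_table(cx: ComplexStructure, atom_subset: str):
    """Flat coordinate array plus residue index per atom."""
    coords, res_idx = [], []
    for i, res in enumerate(cx.residues):
        c = res.heavy_coords if atom_subset == "heavy" else res.coords
        coords.append(c)
        res_idx.append(np.full(len(c), i))
    return np.concatenate(coords), np.concatenate(res_idx)


def build_adjacency(cx: ComplexStructure, cutoff: float = 10.0,
                    atom_subset: str = "all") -> ResidueGraph:
    """Residue graph: edge iff min inter-atom distance ≤ cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cx.n_residues == 0:
        raise ValueError("empty complex")
    coords, res_idx = _atom_table(cx, atom_subset)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        ri = res_idx[pairs[:, 0]]
        rj = res_idx[pairs[:, 1]]
        keep = ri != rj
        lo = np.minimum(ri[keep], rj[keep])
        hi = np.maximum(ri[keep], rj[keep])
        edges = np.unique(np.stack([lo, hi], axis=1), axis=0)
    else:
        edges = np.empty((0, 2), dtype=int)
    return ResidueGraph(cx.n_residues, edges, cutoff, atom_subset)


def label_interface(cx: ComplexStructure, defn: InterfaceDefinition | None = None) -> np.ndarray:
    """Binary interface flags: antibody positives are paratopes, antigen epitopes."""
    defn = defn or InterfaceDefinition()
    sides = cx.side_of()
    if not ((sides == "antibody").any() and (sides == "antigen").any()):
        raise ValueError("interface labeling needs both an antibody and an antigen side")
    coords, res_idx = _atom_table(cx, defn.atom_subset)
    atom_side = sides[res_idx]
    ab_tree = cKDTree(coords[atom_side == "antibody"])
    ag_tree = cKDTree(coords[atom_side == "antigen"])
    ab_res = res_idx[atom_side == "antibody"]
    ag_res = res_idx[atom_side == "antigen"]
    labels = np.zeros(cx.n_residues, dtype=int)
    hits = ab_tree.query_ball_tree(ag_tree, defn.cutoff_angstrom)
    for a, lst in enumerate(hits):
        if lst:
            labels[ab_res[a]] = 1
            labels[ag_res[np.asarray(lst)]] = 1
    return labels


def build_contact_map(cx: ComplexStructure, cutoff: float = 10.0,
                      atom_subset: str = "all") -> np.ndarray:
    """Dense symmetric contact matrix with unit diagonal (same criterion as adjacency)."""
    graph = build_adjacency(cx, cutoff=cutoff, atom_subset=atom_subset)
    n = cx.n_residues
    ctm = np.eye(n, dtype=int)
    if len(graph.edges):
        ctm[graph.edges[:, 0], graph.edges[:, 1]] = 1
        ctm[graph.edges[:, 1], graph.edges[:, 0]] = 1
    return ctm


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.degrees(np.arctan2(y, x)))


def _backbone(res: Residue):
    out = {}
    for name in ("N", "CA", "C"):
        if name in res.atom_names:
            out[name] = res.coords[res.atom_names.index(name)]
    return out if len(out) == 3 else None


def assign_secondary_structure(cx: ComplexStructure, ss_file=None,
                               alphabet: str = SS_ALPHABET) -> np.ndarray:
    """Per-residue 8-class secondary structure.

    With ``ss_file`` (TSV: chain_id, residue_ordinal, letter) classes are read
    directly and mapped through ``alphabet``.  Without it, a coarse φ/ψ window
    heuristic assigns helix/strand/coil only — supply a precomputed file for
    real assignments.
    """
    n = cx.n_residues
    gidx = cx.global_index
    if ss_file is not None:
        ss = np.full(n, -1, dtype=int)
        rows = 0
        with open(ss_file) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                cid, ordinal, letter = line.split("\t")
                if letter not in alphabet:
                    raise ValueError(f"unknown secondary-structure letter {letter!r}")
                key = (cid, int(ordinal))
                if key not in gidx:
                    raise ValueError(f"ss file names unknown residue {key}")
                ss[gidx[key]] = alphabet.index(letter)
                rows += 1
        if rows != n or (ss < 0).any():
            raise ValueError(f"ss file covers {rows} residues, complex has {n}")
        return ss

    helix, strand, coil = alphabet.index("H"), alphabet.index("E"), alphabet.index("C")
    ss = np.full(n, coil, dtype=int)
    for role, residues in cx.chains:
        for i, res in enumerate(residues):
            if i == 0 or i == len(residues) - 1:
                continue
            prev_bb, bb, next_bb = (_backbone(residues[i - 1]), _backbone(res),
                                    _backbone(residues[i + 1]))
            if not (prev_bb and bb and next_bb):
                continue
            phi = _dihedral(prev_bb["C"], bb["N"], bb["CA"], bb["C"])
            psi = _dihedral(bb["N"], bb["CA"], bb["C"], next_bb["N"])
            g = gidx[(res.chain_id, res.ordinal)]
            if -90 <= phi <= -30 and -77 <= psi <= -17:
                ss[g] = helix
            elif -150 <= phi <= -90 and 90 <= psi <= 150:
                ss[g] = strand
    return ss


def build_backbone_from_dihedrals(n_res: int, phi: float, psi: float,
                                  omega: float = 180.0) -> list:
    """Ideal poly-alanine backbone (N, CA, C per residue) from fixed torsions.

    Standard bond geometry; used for synthetic traces and the φ/ψ heuristic's
    self-test.  Returns a list of ``[3, 3]`` coordinate arrays.
    """
    b_nca, b_cac, b_cn = 1.458, 1.525, 1.329
    a_ncac, a_cacn, a_cnca = 111.2, 116.2, 121.7

    def place(a, b, c, bond, angle, torsion):
        angle, torsion = np.radians(angle), np.radians(torsion)
        bc = c - b
        bc /= np.linalg.norm(bc)
        ab = b - a
        n = np.cross(ab, bc)
        n /= np.linalg.norm(n)
        m = np.cross(n, bc)
        d = np.array([-bond * np.cos(angle),
                      bond * np.sin(angle) * np.cos(torsion),
                      -bond * np.sin(angle) * np.sin(torsion)])
        return c + d[0] * bc + d[1] * m + d[2] * n

    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([b_nca, 0.0, 0.0])
    ang = np.radians(a_ncac)
    C = CA + b_cac * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    coords = [np.stack([N, CA, C])]
    for _ in range(1, n_res):
        Np = place(N, CA, C, b_cn, a_cacn, psi)
        CAp = place(CA, C, Np, b_nca, a_cnca, omega)
        Cp = place(C, Np, CAp, b_cac, a_ncac, phi)
        N, CA, C = Np, CAp, Cp
        coords.append(np.stack([N, CA, C]))
    return coords


# ---------------------------------------------------------------------------
# Text outputs
# ---------------------------------------------------------------------------

def write_manifest(cx: ComplexStructure, path, complex_id: str = ""):
    doc = {
        "complex_id": complex_id,
        "chains": [
            {"role": role, "chain_id": residues[0].chain_id,
             "n_residues": len(residues),
             "sequence": "".join(r.restype for r in residues)}
            for role, residues in cx.chains
        ],
        "n_residues": cx.n_residues,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def write_labels_tsv(cx: ComplexStructure, itf: np.ndarray, ss: np.ndarray, path):
    lines = ["chain_id\tresidue_ordinal\tresidue_type\titf\tss"]
    for i, res in enumerate(cx.residues):
        lines.append(f"{res.chain_id}\t{res.ordinal}\t{res.restype}\t{int(itf[i])}\t{int(ss[i])}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_edges_tsv(graph: ResidueGraph, path):
    lines = [f"# cutoff_angstrom={graph.cutoff_angstrom}\tatom_subset={graph.atom_subset}",
             "i\tj"]
    for i, j in graph.edges:
        lines.append(f"{i}\t{j}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edges_tsv(path) -> ResidueGraph:
    lines = Path(path).read_text().splitlines()
    header = lines[0].lstrip("# ").split("\t")
    cutoff = float(header[0].split("=")[1])
    subset = header[1].split("=")[1]
    edges = [tuple(map(int, ln.split("\t"))) for ln in lines[2:] if ln]
    n = 1 + max((max(e) for e in edges), default=-1)
    return ResidueGraph(n, np.array(edges, dtype=int).reshape(-1, 2), cutoff, subset)
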