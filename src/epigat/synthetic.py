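"""Seeded generator of toy antibody–antigen complexes.

Each complex has Cα-plus-pseudo-side-chain chains built as self-avoiding
random walks, a planted interface patch — ``patch_size`` antigen residues
placed at ``contact_distance`` from chosen antibody residues while every
other cross-side residue stays beyond ``far_distance`` — and per-chain MSAs
whose interface columns are preferentially conserved across rows.  The
interface signal therefore lives both in geometry (cross-side graph edges)
and in sequence statistics (column conservation), and labels are always
derived through the real labeling operations, never asserted directly:
generation retries until ``label_interface`` at 4.5 Å reproduces the planted
set exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .batch import ComplexBatch, make_batch
from .msa_features import TokenVocabulary, select_diverse_rows, tokenize_and_stack
from .structure_io import (AA1_TO_AA3, AA_ORDER, ComplexStructure,
                           InterfaceDefinition, Residue, SS_ALPHABET,
                           build_adjacency, build_contact_map, label_interface,
                           write_labels_tsv, write_manifest)

_CA_STEP = 3.8          # Å between consecutive Cα
_MIN_SEP = 3.6          # Å self-avoidance between non-adjacent Cα


class _PlantingError(RuntimeError):
    """Recoverable geometric failure; generation retries with a fresh stream."""


@dataclass
class SyntheticSpec:
    n_heavy: int = 20
    n_light: int = 10
    n_antigen: int = 30
    patch_size: int = 3
    contact_distance: float = 4.0
    far_distance: float = 25.0
    msa_depth: int = 16
    conservation_strength: float = 0.9
    background_mutation_rate: float = 0.3
    coordinate_noise: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.far_distance <= 10.0:
            raise ValueError("far_distance must exceed the 10 Å labeling cutoff")
        if self.patch_size > min(self.n_heavy, self.n_antigen):
            raise ValueError("patch_size larger than a chain")


@dataclass
class SyntheticComplex:
    cx: ComplexStructure
    itf_contact: np.ndarray       # planted labels at 4.5 Å, global residue order
    ss: np.ndarray                # per-residue 8-class labels
    msas: dict                    # role -> list of aligned sequences (query first)
    planted_pairs: list           # [(ab_global_idx, ag_global_idx)]
    spec: SyntheticSpec


def _walk(rng, n, start, x_min=None):
    """Self-avoiding random walk of Cα positions with fixed step length."""
    pts = [np.asarray(start, dtype=float)]
    while len(pts) < n:
        for _ in range(200):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            cand = pts[-1] + _CA_STEP * d
            if x_min is not None and cand[0] < x_min:
                continue
            if len(pts) > 1:
                prev = np.stack(pts[:-1])
                if np.min(np.linalg.norm(prev - cand, axis=1)) < _MIN_SEP:
                    continue
            pts.append(cand)
            break
        else:
            raise _PlantingError("self-avoiding walk dead-ended")
    return np.stack(pts)


def _make_chain(rng, chain_id, ca, seq):
    residues = []
    for i, pos in enumerate(ca):
        n_side = 1 + int(rng.integers(0, 3))  # 1-3 pseudo side-chain atoms
        names = ["CA"] + [f"C{chr(ord('B') + k)}" for k in range(n_side)]
        coords = [pos]
        for k in range(n_side):
            off = rng.normal(size=3)
            off *= 1.5 / np.linalg.norm(off)
            coords.append(pos + off * (1.0 + 0.4 * k))
        residues.append(Residue(
            chain_id=chain_id, ordinal=i, restype=seq[i],
            atom_names=names, coords=np.stack(coords),
            is_heavy=np.ones(len(names), dtype=bool)))
    return residues


def _spaced_choice(rng, n, k, min_gap=4):
    for _ in range(200):
        picks = np.sort(rng.choice(n, size=k, replace=False))
        if k == 1 or np.min(np.diff(picks)) >= min_gap:
            return picks
    return picks  # fall back to last draw


def generate_complex(spec: SyntheticSpec) -> SyntheticComplex:
    """Build one synthetic complex; deterministic for a given spec/seed."""
    base_rng = np.random.default_rng(spec.seed)
    last_err = None
    for attempt in range(25):
        rng = np.random.default_rng(base_rng.integers(2**31))
        try:
            return _generate_once(spec, rng)
        except _PlantingError as err:
            last_err = err
    raise RuntimeError(
        f"could not plant a consistent interface after 25 attempts "
        f"({last_err}); try a smaller coordinate_noise")


def _generate_once(spec: SyntheticSpec, rng) -> SyntheticComplex:
    seq_h = "".join(rng.choice(list(AA_ORDER), size=spec.n_heavy))
    seq_l = "".join(rng.choice(list(AA_ORDER), size=spec.n_light))
    seq_a = "".join(rng.choice(list(AA_ORDER), size=spec.n_antigen))

    ca_h = _walk(rng, spec.n_heavy, (0.0, 0.0, 0.0))
    res_h = _make_chain(rng, "H", ca_h, seq_h)
    res_l = []
    if spec.n_light:
        ca_l = _walk(rng, spec.n_light, (0.0, 14.0, 0.0))
        res_l = _make_chain(rng, "L", ca_l, seq_l)

    # antigen walk confined beyond far_distance in +x
    x0 = spec.far_distance + 12.0
    ca_a = _walk(rng, spec.n_antigen, (x0, 0.0, 0.0), x_min=spec.far_distance + 6.0)
    res_a = _make_chain(rng, "A", ca_a, seq_a)

    # plant the patch: each chosen antigen residue gets a "reaching" atom at
    # contact_distance from its antibody anchor's Cα.  Contacts among planted
    # residues are harmless (the label set is per-residue), so clearance is
    # only required from the NON-picked antibody residues.
    ab_picks = _spaced_choice(rng, spec.n_heavy, spec.patch_size)
    ag_picks = _spaced_choice(rng, spec.n_antigen, spec.patch_size)
    picked = set(int(a) for a in ab_picks)
    nonpicked = np.concatenate(
        [r.coords for i, r in enumerate(res_h) if i not in picked]
        + [r.coords for r in res_l])
    for ai, gi in zip(ab_picks, ag_picks):
        anchor = ca_h[ai]
        for _ in range(100):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            p = anchor + spec.contact_distance * u          # reaching atom
            q = anchor + (spec.contact_distance + 2.5) * u  # new Cα
            perp = np.cross(u, rng.normal(size=3))
            perp /= np.linalg.norm(perp)
            extra = q + 1.2 * (u + 0.6 * perp) / np.linalg.norm(u + 0.6 * perp)
            cand = np.stack([q, p, extra])
            # 1 Å margin over the 4.5 Å label cutoff absorbs coordinate noise
            if np.min(np.linalg.norm(
                    nonpicked[:, None, :] - cand[None, :, :], axis=2)) > 5.5:
                res_a[gi] = Residue(
                    chain_id="A", ordinal=int(gi), restype=seq_a[gi],
                    atom_names=["CA", "CB", "CG"],
                    coords=np.stack([q, p, extra]),
                    is_heavy=np.ones(3, dtype=bool))
                break
        else:
            raise _PlantingError("no collision-free placement direction")

    chains = [("heavy", res_h)]
    if spec.n_light:
        chains.append(("light", res_l))
    chains.append(("antigen", res_a))
    cx = ComplexStructure(chains=chains)

    if spec.coordinate_noise > 0:
        for res in cx.residues:
            res.coords = res.coords + rng.normal(0, spec.coordinate_noise,
                                                 res.coords.shape)

    # labels always come from the real labeling op; verify the plant
    itf = label_interface(cx, InterfaceDefinition(4.5))
    gidx = cx.global_index
    n_ab = spec.n_heavy + spec.n_light
    planted = np.zeros(cx.n_residues, dtype=int)
    pairs = []
    for ai, gi in zip(ab_picks, ag_picks):
        a = gidx[("H", int(ai))]
        g = gidx[("A", int(gi))]
        planted[a] = planted[g] = 1
        pairs.append((a, g))
    if not np.array_equal(itf, planted):
        raise _PlantingError("labels disagree with planted patch")

    ss = _synthetic_ss(rng, cx)
    msas = generate_msa_for(cx, itf, spec, rng)
    return SyntheticComplex(cx=cx, itf_contact=itf, ss=ss, msas=msas,
                            planted_pairs=pairs, spec=spec)


def _synthetic_ss(rng, cx: ComplexStructure) -> np.ndarray:
    """Run-structured 8-class labels (helix/strand/coil runs of length 3-7)."""
    classes = [SS_ALPHABET.index(c) for c in "HEC"]
    out = []
    for _, residues in cx.chains:
        n = len(residues)
        labels = np.empty(n, dtype=int)
        i = 0
        while i < n:
            run = int(rng.integers(3, 8))
            labels[i:i + run] = classes[int(rng.integers(len(classes)))]
            i += run
        out.append(labels)
    order = {"heavy": 0, "light": 1, "antigen": 2}
    chunks = sorted(zip((r for r, _ in cx.chains), out), key=lambda t: order[t[0]])
    return np.concatenate([c for _, c in chunks])


def generate_msa_for(cx: ComplexStructure, itf: np.ndarray, spec: SyntheticSpec,
                     rng) -> dict:
    """Per-chain alignments with conservation planted on interface columns."""
    msas = {}
    offset = 0
    role_order = [r for r in ("heavy", "light", "antigen") if cx.sequence(r)]
    for role in role_order:
        query = cx.sequence(role)
        n = len(query)
        flags = itf[offset:offset + n].astype(bool)
        offset += n
        conserved = flags & (rng.random(n) < spec.conservation_strength)
        rows = [query]
        for _ in range(spec.msa_depth - 1):
            row = list(query)
            mutate = (~conserved) & (rng.random(n) < spec.background_mutation_rate)
            for j in np.where(mutate)[0]:
                choices = [a for a in AA_ORDER if a != query[j]]
                row[j] = choices[int(rng.integers(len(choices)))]
            rows.append("".join(row))
        msas[role] = rows
    return msas


def generate_msa(cplx: SyntheticComplex, spec: SyntheticSpec | None = None) -> dict:
    """Regenerate the per-chain MSAs for an existing complex (fresh seed stream)."""
    spec = spec or cplx.spec
    rng = np.random.default_rng(spec.seed + 7919)
    return generate_msa_for(cplx.cx, cplx.itf_contact, spec, rng)


# ---------------------------------------------------------------------------
# Batching and on-disk datasets
# ---------------------------------------------------------------------------

def to_batch(sc: SyntheticComplex, M: int = 4, L: int = 64,
             itf_cutoff: float = 4.5, adjacency_cutoff: float = 10.0,
             with_ctm: bool = True, seed: int = 0,
             complex_id: str = "") -> ComplexBatch:
    """Featurize one synthetic complex exactly as the real pipeline would."""
    vocab = TokenVocabulary()
    per_chain = {role: select_diverse_rows(seqs, M=M, seed=seed, vocab=vocab)
                 for role, seqs in sc.msas.items()}
    msa = tokenize_and_stack(per_chain, vocab, M=M, L=L,
                             reference_sequences=sc.cx.sequences())
    graph = build_adjacency(sc.cx, cutoff=adjacency_cutoff)
    itf = (sc.itf_contact if itf_cutoff == 4.5
           else label_interface(sc.cx, InterfaceDefinition(itf_cutoff)))
    ctm = build_contact_map(sc.cx, cutoff=adjacency_cutoff) if with_ctm else None
    return make_batch(sc.cx, msa, graph, itf, ss=sc.ss, ctm=ctm,
                      complex_id=complex_id)


def synthetic_batches(n_complexes: int, spec: SyntheticSpec, seed: int,
                      M: int = 4, L: int = 64, itf_cutoff: float = 4.5) -> list:
    """Generate ``n_complexes`` featurized complexes with per-complex seeds."""
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n_complexes)):
        sub = replace(spec, seed=int(child.generate_state(1)[0] % 2**31))
        sc = generate_complex(sub)
        out.append(to_batch(sc, M=M, L=L, itf_cutoff=itf_cutoff,
                            seed=seed + i, complex_id=f"syn{i:04d}"))
    return out


def write_pdb(cx: ComplexStructure, path):
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    n_atoms = sum(len(r.atom_names) for r in cx.residues)
    arr = struc.AtomArray(n_atoms)
    i = 0
    for res in cx.residues:
        for name, coord in zip(res.atom_names, res.coords):
            arr.chain_id[i] = res.chain_id
            arr.res_id[i] = res.ordinal + 1
            arr.res_name[i] = AA1_TO_AA3[res.restype]
            arr.atom_name[i] = name
            arr.element[i] = name[0]
            arr.coord[i] = coord
            i += 1
    f = pdbio.PDBFile()
    pdbio.set_structure(f, arr)
    f.write(str(path))


def generate_dataset(n_complexes: int, spec: SyntheticSpec, seed: int,
                     out_dir) -> list:
    """Write ``n_complexes`` synthetic complexes to disk in pipeline formats.

    Emits per complex: a PDB file, one a3m per chain, a labels TSV (10 Å
    interface definition) and a manifest; plus a chain-role table covering
    the whole set.  Returns the complex ids.
    """
    if n_complexes < 3:
        raise ValueError("need at least 3 complexes for a train/val/test split")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    ids = []
    role_rows = ["complex_id\tchain_id\trole"]
    for i, child in enumerate(ss.spawn(n_complexes)):
        sub = replace(spec, seed=int(child.generate_state(1)[0] % 2**31))
        sc = generate_complex(sub)
        cid = f"syn{i:04d}"
        ids.append(cid)
        write_pdb(sc.cx, out / f"{cid}.pdb")
        for role, rows in sc.msas.items():
            chain_id = {"heavy": "H", "light": "L", "antigen": "A"}[role]
            lines = []
            for j, s in enumerate(rows):
                lines.append(f">{cid}_{role}_{j}")
                lines.append(s)
            (out / f"{cid}_{role}.a3m").write_text("\n".join(lines) + "\n")
            role_rows.append(f"{cid}\t{chain_id}\t{role}")
        itf10 = label_interface(sc.cx, InterfaceDefinition(10.0))
        write_labels_tsv(sc.cx, itf10, sc.ss, out / f"{cid}.labels.tsv")
        write_manifest(sc.cx, out / f"{cid}.manifest.json", complex_id=cid)
    (out / "chain_roles.tsv").write_text("\n".join(role_rows) + "\n")
    return ids
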