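"""Leakage-aware dataset splitting.

Antibody sequences are embedded (3-mer composition by default), clustered by
average-linkage hierarchical clustering on cosine distance, and whole clusters
are assigned greedily — largest first — to the training side until the
requested fraction is reached.  No cluster ever spans train and test, which is
the point: near-identical antibodies must not appear on both sides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .structure_io import AA_ORDER

_KMER = 3
_KMER_INDEX = {"".join(p): i for i, p in enumerate(product(AA_ORDER, repeat=_KMER))}


@dataclass
class ClusterAssignment:
    cluster_of: dict        # complex_id -> cluster_id
    split_of_cluster: dict  # cluster_id -> "train" | "test"
    achieved_train_fraction: float

    def split_of(self, complex_id) -> str:
        return self.split_of_cluster[self.cluster_of[complex_id]]

    def ids_in(self, split: str) -> list:
        return sorted(c for c in self.cluster_of
                      if self.split_of_cluster[self.cluster_of[c]] == split)


def embed_antibody(seq_heavy: str, seq_light: str | None = None) -> np.ndarray:
    """Concatenated heavy+light 3-mer composition vector (length 2·20³), L2-normalized."""
    if not seq_heavy:
        raise ValueError("heavy-chain sequence must be nonempty")

    def kmer_counts(seq: str) -> np.ndarray:
        v = np.zeros(len(_KMER_INDEX))
        bad = set(seq) - set(AA_ORDER)
        if bad:
            raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")
        for i in range(len(seq) - _KMER + 1):
            v[_KMER_INDEX[seq[i:i + _KMER]]] += 1
        return v

    vec = np.concatenate([kmer_counts(seq_heavy),
                          kmer_counts(seq_light) if seq_light else np.zeros(len(_KMER_INDEX))])
    norm = np.linalg.norm(vec)
    return vec / norm if norm > 0 else vec


def cluster_and_split(embeddings: dict, train_fraction: float = 0.8,
                      distance_threshold: float = 0.5, seed: int = 0) -> ClusterAssignment:
    """Cluster complexes and assign whole clusters to train until the fraction is met.

    ``embeddings``: complex_id → vector.  Deterministic: ids are processed in
    sorted order, clusters largest-first with ties broken by smallest member.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    ids = sorted(embeddings)
    if len(ids) < 2:
        raise ValueError("need at least two complexes to split")
    X = np.stack([embeddings[i] for i in ids])
    dist = pdist(X, metric="cosine")
    Z = linkage(dist, method="average")
    flat = fcluster(Z, t=distance_threshold, criterion="distance")
    clusters: dict = {}
    for cid, c in zip(ids, flat):
        clusters.setdefault(int(c), []).append(cid)
    if len(clusters) == 1:
        raise ValueError("all complexes fall into a single cluster; raise the "
                         "distance threshold resolution or split manually")
    order = sorted(clusters, key=lambda c: (-len(clusters[c]), min(clusters[c])))
    n = len(ids)
    split_of_cluster, assigned = {}, 0
    for c in order:
        if assigned / n < train_fraction:
            split_of_cluster[c] = "train"
            assigned += len(clusters[c])
        else:
            split_of_cluster[c] = "test"
    if assigned == n:  # never leave the test side empty
        last = order[-1]
        split_of_cluster[last] = "test"
        assigned -= len(clusters[last])
    cluster_of = {cid: int(c) for cid, c in zip(ids, flat)}
    return ClusterAssignment(cluster_of, split_of_cluster, assigned / n)


def make_cv_folds(complex_ids, k: int = 5, seed: int = 0) -> list:
    """k disjoint complex-level folds with sizes differing by at most one."""
    ids = sorted(complex_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError("more folds than complexes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = [[] for _ in range(k)]
    for pos, idx in enumerate(perm):
        folds[pos % k].append(ids[idx])
    return [sorted(f) for f in folds]


def write_split_tsv(assignment: ClusterAssignment, path):
    lines = ["complex_id\tcluster_id\tsplit"]
    for cid in sorted(assignment.cluster_of):
        cl = assignment.cluster_of[cid]
        lines.append(f"{cid}\t{cl}\t{assignment.split_of_cluster[cl]}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_folds_json(folds: list, path):
    Path(path).write_text(json.dumps({"folds": folds}, indent=1) + "\n")
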