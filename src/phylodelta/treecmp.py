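"""Quantifying topological differences between trees.

Robinson–Foulds distances on bipartition sets, classical (Torgerson)
multidimensional scaling of tree-distance matrices, and a Fitch-parsimony
score of the binary sample-type character that quantifies how strongly
historical versus modern samples cluster on a tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignment import SampleMetadata
from .trees import PhyloTree, TreeError

__all__ = ["rf_distance", "tree_distance_matrix", "TreeDistanceMatrix",
           "mds_embed", "MDSResult", "type_clustering_score"]


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson–Foulds distance: size of the symmetric difference of the
    non-trivial bipartition sets (rooted inputs are unrooted first)."""
    if set(t1.tip_names()) != set(t2.tip_names()):
        raise TreeError("trees have different tip sets")
    b1 = t1.bipartitions()
    b2 = t2.bipartitions()
    return len(b1 ^ b2)


@dataclass
class TreeDistanceMatrix:
    labels: list[str]
    matrix: np.ndarray


def tree_distance_matrix(trees: Sequence[PhyloTree],
                         labels: Sequence[str] = None) -> TreeDistanceMatrix:
    if labels is None:
        labels = [f"tree{i}" for i in range(len(trees))]
    splits = [t.bipartitions() for t in trees]
    n = len(trees)
    D = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = len(splits[i] ^ splits[j])
    return TreeDistanceMatrix(list(labels), D)


@dataclass
class MDSResult:
    coords: np.ndarray                      # (n, dim)
    eigenvalues: np.ndarray
    deficient: bool                         # fewer positive eigenpairs than dim


def mds_embed(distance_matrix: np.ndarray, dim: int = 2) -> MDSResult:
    """Classical (Torgerson) MDS: double-centre the squared distances and
    keep the top ``dim`` eigenpairs.

    Axes are ordered by eigenvalue and sign-fixed so the first non-zero
    loading of each axis is positive; axes beyond the number of positive
    eigenvalues are zero and flagged.
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, dim))
    n_pos = 0
    for a in range(min(dim, n)):
        if vals[a] > 1e-10:
            coords[:, a] = vecs[:, a] * np.sqrt(vals[a])
            n_pos += 1
    for a in range(dim):
        col = coords[:, a]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, a] = -col
    return MDSResult(coords, vals, deficient=n_pos < dim)


def type_clustering_score(tree: PhyloTree,
                          metadata: dict[str, SampleMetadata]) -> int:
    """Fitch parsimony score of the modern/historical character.

    The minimum number of sample-type changes on the tree: 0 when one type,
    1 when the two types are reciprocally monophyletic, larger the more the
    types interleave.  Lower = stronger sample-type clustering.  The score is
    invariant to rooting.
    """
    untyped = [t for t in tree.tip_names() if t not in metadata]
    if untyped:
        raise TreeError(f"tips without sample type: {untyped}")
    changes = 0
    state: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_tip:
            state[id(node)] = frozenset([metadata[node.name].sample_type])
            continue
        sets = [state[id(c)] for c in node.children]
        inter = frozenset.intersection(*sets)
        if inter:
            state[id(node)] = inter
        else:
            # Fitch on multifurcations: repeatedly intersect, counting a
            # change whenever the running intersection empties
            run = sets[0]
            for s in sets[1:]:
                nxt = run & s
                if nxt:
                    run = nxt
                else:
                    run = run | s
                    changes += 1
            state[id(node)] = run
    return changes
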