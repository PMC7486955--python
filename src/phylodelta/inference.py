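"""Desk-scale maximum-likelihood tree estimation.

A Jukes–Cantor distance matrix (pairwise deletion) seeds a neighbour-joining
starting tree, which is improved by nearest-neighbour-interchange (NNI) hill
climbing with branch-length re-optimisation, and assessed by nonparametric
(within-partition) bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .alignment import ConcatenatedAlignment, PartitionMap
from .likelihood import TreeLikelihood, compile_blocks, \
    optimize_branch_lengths
from .models import PartitionedModel
from .trees import Node, PhyloTree

__all__ = ["jc_distances", "neighbor_joining", "nni_ml_search",
           "bootstrap_support", "BootstrapSet", "estimate_tree"]

DIST_CAP = 5.0


def jc_distances(aln: ConcatenatedAlignment, cap: float = DIST_CAP
                 ) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Pairwise Jukes–Cantor distances with pairwise deletion of missing
    columns.  Pairs with no overlap or with p ≥ 3/4 are capped at ``cap``
    and reported in the flagged list."""
    codes = aln.codes()
    n = aln.n_taxa
    present = codes != 4
    D = np.zeros((n, n))
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            m = int(both.sum())
            if m == 0:
                D[i, j] = D[j, i] = cap
                flagged.append((aln.taxa[i], aln.taxa[j]))
                continue
            p = float((codes[i, both] != codes[j, both]).sum()) / m
            if p >= 0.75:
                D[i, j] = D[j, i] = cap
                flagged.append((aln.taxa[i], aln.taxa[j]))
            else:
                D[i, j] = D[j, i] = -0.75 * np.log1p(-4.0 * p / 3.0)
    return D, flagged


def neighbor_joining(distance_matrix: np.ndarray, labels: Sequence[str]
                     ) -> PhyloTree:
    """Standard neighbour joining (negative branch estimates clamped to 0).

    Taxa are processed in lexicographic label order so the result does not
    depend on the input ordering.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.shape[0] != D.shape[1] or D.shape[0] != len(labels):
        raise ValueError("distance matrix / label size mismatch")
    if np.abs(D - D.T).max() > 1e-9:
        raise ValueError("distance matrix is not symmetric")
    if np.abs(np.diag(D)).max() > 1e-12:
        raise ValueError("distance matrix has non-zero diagonal")
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    labels_sorted = [labels[i] for i in order]
    D = D[np.ix_(order, order)]
    if len(labels) == 2:
        root = Node()
        root.add(Node(labels_sorted[0], D[0, 1] / 2))
        root.add(Node(labels_sorted[1], D[0, 1] / 2))
        return PhyloTree(root, rooted=False)
    if len(labels) == 3:
        root = Node()
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        for name, d in zip(labels_sorted,
                           [(d01 + d02 - d12) / 2, (d01 + d12 - d02) / 2,
                            (d02 + d12 - d01) / 2]):
            root.add(Node(name, max(d, 0.0)))
        return PhyloTree(root, rooted=False)
    tree = _skbio_nj(DistanceMatrix(D, ids=labels_sorted))
    out = PhyloTree.from_newick(str(tree).strip())
    for node in out.postorder():
        if node.parent is not None and node.length < 0:
            node.length = 0.0
    return out.unroot()


# ---------------------------------------------------------------- NNI moves

def _internal_edges(tree: PhyloTree) -> list[int]:
    """Postorder indices of internal (non-root, non-tip) nodes, each
    identifying the edge to its parent."""
    nodes = list(tree.postorder())
    return [i for i, n in enumerate(nodes)
            if n.parent is not None and not n.is_tip]


def _swap(x: Node, y: Node) -> None:
    px, py = x.parent, y.parent
    px.children[px.children.index(x)] = y
    py.children[py.children.index(y)] = x
    x.parent, y.parent = py, px


def _make_nni(tree: PhyloTree, edge_index: int, which: int
              ) -> tuple[PhyloTree, Node]:
    """One NNI rearrangement; returns the rearranged copy and its central
    node (lower end of the rearranged edge)."""
    t = tree.copy()
    nodes = list(t.postorder())
    v = nodes[edge_index]
    u = v.parent
    sib = next(c for c in u.children if c is not v)
    _swap(v.children[which], sib)
    return t, v


def nni_neighbors(tree: PhyloTree, edge_index: int
                  ) -> list[tuple[PhyloTree, Node]]:
    """The two NNI rearrangements around one internal edge."""
    return [_make_nni(tree, edge_index, w) for w in (0, 1)]


def nni_ml_search(start_tree: PhyloTree, pmodel: PartitionedModel,
                  aln: ConcatenatedAlignment, min_improvement: float = 1e-6,
                  opt_tol: float = 1e-3, max_opt_rounds: int = 8,
                  max_iterations: int = 60, max_tries_per_iteration: int = 3
                  ) -> tuple[PhyloTree, list[float]]:
    """NNI hill climbing with branch re-optimisation.

    Each iteration scores both NNI neighbours of every internal edge by
    re-optimising only the rearranged edge (a cheap but reliable proxy),
    then applies the highest-scoring rearrangements in order, confirming
    each with a full branch-length re-optimisation and reverting moves that
    do not genuinely improve the log-likelihood by ``min_improvement``.
    Ties keep the incumbent.  Returns the final tree and the accepted-lnL
    trace.
    """
    if start_tree.n_tips() < 4:
        return start_tree.copy(), []
    current = start_tree.unroot()
    blocks = compile_blocks(pmodel, aln, current.tip_names())
    tl = TreeLikelihood(current, pmodel, aln, blocks=blocks)
    cur_lnl = tl.optimize_branch_lengths(tol=opt_tol,
                                         max_rounds=max_opt_rounds,
                                         xatol=1e-6)
    trace = [cur_lnl]

    def apply_moves(tree, moves):
        cand = tree.copy()
        nodes = list(cand.postorder())
        for ei, which in moves:
            v = nodes[ei]
            u = v.parent
            sib = next(c for c in u.children if c is not v)
            _swap(v.children[which], sib)
        return cand

    def full_opt(tree):
        ctl = TreeLikelihood(tree, pmodel, aln, blocks=blocks)
        return ctl.optimize_branch_lengths(tol=opt_tol,
                                           max_rounds=max_opt_rounds,
                                           xatol=1e-6)

    for _ in range(max_iterations):
        scored = []
        for ei in _internal_edges(current):
            for which in (0, 1):
                cand, central = _make_nni(current, ei, which)
                ctl = TreeLikelihood(cand, pmodel, aln, blocks=blocks)
                score = ctl.score_with_single_edge(central)
                if score > cur_lnl + min_improvement:
                    scored.append((score, ei, which))
        if not scored:
            break
        scored.sort(key=lambda sc: -sc[0])
        # apply the best structurally independent rearrangements together;
        # a swap touches only the children lists of the edge's two nodes
        nodes_cur = list(current.postorder())
        chosen, used = [], set()
        for score, ei, which in scored:
            v = nodes_cur[ei]
            region = {id(v), id(v.parent)}
            if region & used:
                continue
            chosen.append((ei, which))
            used |= region
        accepted = False
        attempts = [chosen]
        if len(chosen) > 1:
            attempts.append([chosen[0]])
        for moves in attempts[:max_tries_per_iteration]:
            cand = apply_moves(current, moves)
            lnl = full_opt(cand)
            if lnl > cur_lnl + min_improvement:
                current, cur_lnl = cand, lnl
                trace.append(cur_lnl)
                accepted = True
                break
        if not accepted:
            break
    return current, trace


# --------------------------------------------------------------- bootstrap

@dataclass
class BootstrapSet:
    replicates: list[PhyloTree]
    B: int
    seed: int


def _resample_columns(partitions: PartitionMap, rng: np.random.Generator
                      ) -> tuple[np.ndarray, PartitionMap]:
    cols = []
    for lid, start, end in partitions.entries:
        cols.append(rng.integers(start, end, size=end - start))
    return np.concatenate(cols), PartitionMap(list(partitions.entries))


def bootstrap_support(aln: ConcatenatedAlignment, pmodel: PartitionedModel,
                      ml_tree: PhyloTree, B: int = 100, seed: int = 0,
                      **search_kwargs) -> tuple[PhyloTree, BootstrapSet]:
    """Felsenstein bootstrap: columns resampled within each partition (locus
    sizes preserved), each replicate analysed by NJ + NNI under the fixed
    model; supports are the percentage of replicates containing each internal
    bipartition of ``ml_tree``."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(B):
        cols, pmap = _resample_columns(aln.partitions, rng)
        rep_aln = ConcatenatedAlignment(list(aln.taxa), aln.matrix[:, cols],
                                        pmap)
        D, _ = jc_distances(rep_aln)
        start = neighbor_joining(D, rep_aln.taxa)
        tree, _ = nni_ml_search(start, pmodel, rep_aln, **search_kwargs)
        reps.append(tree)
    annotated = ml_tree.copy()
    rep_splits = [t.bipartitions() for t in reps]
    all_tips = frozenset(annotated.tip_names())
    anchor = min(all_tips)
    n = len(all_tips)
    below: dict[int, frozenset] = {}
    for node in annotated.postorder():
        if node.is_tip:
            below[id(node)] = frozenset([node.name])
            continue
        s = frozenset().union(*(below[id(c)] for c in node.children))
        below[id(node)] = s
        if node.parent is None:
            continue
        side = s if anchor not in s else all_tips - s
        if 2 <= len(side) <= n - 2:
            node.support = 100.0 * sum(side in rs for rs in rep_splits) / B
    return annotated, BootstrapSet(reps, B, seed)


# ------------------------------------------------------------- convenience

def estimate_tree(aln: ConcatenatedAlignment, pmodel: PartitionedModel,
                  **search_kwargs) -> tuple[PhyloTree, float]:
    """NJ starting tree followed by NNI ML search; returns (tree, lnL)."""
    D, _ = jc_distances(aln)
    start = neighbor_joining(D, aln.taxa)
    tree, trace = nni_ml_search(start, pmodel, aln, **search_kwargs)
    if trace:
        return tree, trace[-1]
    tl = TreeLikelihood(tree.copy(), pmodel, aln)
    return tree, tl.total_log_likelihood()
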