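"""Felsenstein pruning under partitioned reversible models.

Per-site log-likelihoods are computed by postorder pruning over
alignment-column *patterns* (identical columns are collapsed and weighted),
with per-node rescaling against underflow.  Branch lengths are optimised by
coordinate ascent: one postorder ("down") and one preorder ("out") pass per
round give, for every edge, the two conditional partials that make the edge
likelihood a cheap one-dimensional function of its length.

Tip partials follow the standard convention: an unambiguous base is a unit
vector, and N/-/? is all-ones, so an all-missing column contributes exactly
zero log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize as spo

from .alignment import ConcatenatedAlignment, PartitionMap
from .models import (EigenSystem, ModelError, PartitionedModel,
                     SubstitutionModel)
from .trees import PhyloTree

__all__ = ["LikelihoodError", "TreeLikelihood", "compile_blocks",
           "site_log_likelihoods", "optimize_branch_lengths", "fit_models",
           "FitResult", "BRANCH_MIN", "BRANCH_MAX"]

BRANCH_MIN = 1e-8
BRANCH_MAX = 10.0


class LikelihoodError(RuntimeError):
    pass


class _Block:
    """A set of alignment columns sharing one substitution model and rate
    multiplier (merged across partitions when models are shared).  Rows are
    ordered by sorted taxon name, independently of any tree, so compiled
    blocks can be shared across the many candidate trees of a search."""

    __slots__ = ("eig", "freqs", "rates", "multiplier", "patterns", "counts",
                 "columns", "inverse", "tip_partials")

    def __init__(self, model: SubstitutionModel, multiplier: float,
                 codes: np.ndarray, columns: np.ndarray):
        self.eig = EigenSystem.from_model(model)
        self.freqs = model.freqs
        self.rates = model.category_rates()
        self.multiplier = float(multiplier)
        self.columns = columns              # global column indices
        sub = codes[:, columns]             # (n_tips, n_cols)
        pat, inverse = np.unique(sub.T, axis=0, return_inverse=True)
        self.patterns = pat.T               # (n_tips, n_pat)
        self.inverse = inverse
        self.counts = np.bincount(inverse, minlength=self.patterns.shape[1]
                                  ).astype(float)
        # (n_tips, 4, n_pat): unit vector for a base, ones for missing
        n_tips, n_pat = self.patterns.shape
        tp = np.zeros((n_tips, 4, n_pat))
        for s in range(4):
            tp[:, s, :] = (self.patterns == s) | (self.patterns == 4)
        self.tip_partials = tp

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    def scaled_times(self, t: float) -> np.ndarray:
        return t * self.multiplier * self.rates


def compile_blocks(pmodel: PartitionedModel, aln: ConcatenatedAlignment,
                   tip_names: Sequence[str]) -> list[_Block]:
    """Pattern-compress the alignment into model blocks (rows in sorted
    ``tip_names`` order).  The result is tree-independent and reusable for
    every topology over the same taxa, model and alignment."""
    missing = [t for t in tip_names if t not in aln.taxa]
    if missing:
        raise LikelihoodError(f"tree taxa absent from alignment: {missing}")
    unknown = [k for k in pmodel.models if k not in aln.partitions.locus_ids]
    if unknown:
        raise LikelihoodError(f"model for unknown partitions: {unknown}")
    for lid in aln.partitions.locus_ids:
        if lid not in pmodel.models:
            raise LikelihoodError(f"no model for partition {lid!r}")
    order = sorted(tip_names)
    rows = [aln.taxa.index(t) for t in order]
    codes = aln.codes()[rows]
    groups: dict[tuple, list[tuple[int, int]]] = {}
    for lid, start, end in aln.partitions.entries:
        key = (id(pmodel.models[lid]), pmodel.multipliers[lid])
        groups.setdefault(key, []).append((start, end))
    blocks = []
    for (mid, mult), spans in groups.items():
        model = next(pmodel.models[lid] for lid, s, e in aln.partitions.entries
                     if id(pmodel.models[lid]) == mid)
        columns = np.concatenate([np.arange(s, e) for s, e in spans])
        blocks.append(_Block(model, mult, codes, columns))
    return blocks


class TreeLikelihood:
    """Pruning engine bound to one tree, one partitioned model and one
    alignment.  The tree is used in place: callers who need the input
    preserved should pass a copy.  Precompiled ``blocks`` (from
    :func:`compile_blocks`) may be supplied to amortise pattern compression
    across many trees."""

    def __init__(self, tree: PhyloTree, pmodel: PartitionedModel,
                 aln: ConcatenatedAlignment,
                 blocks: Optional[list[_Block]] = None):
        self.tree = tree
        self.aln = aln
        self.pmodel = pmodel
        self.blocks = blocks if blocks is not None else compile_blocks(
            pmodel, aln, tree.tip_names())
        self._index_tree()

    # ------------------------------------------------------------- indexing
    def _index_tree(self) -> None:
        self.nodes = list(self.tree.postorder())
        self.node_index = {id(n): i for i, n in enumerate(self.nodes)}
        order = sorted(self.tree.tip_names())
        tip_pos = {name: i for i, name in enumerate(order)}
        self.tip_row = {id(n): tip_pos[n.name] for n in self.nodes if n.is_tip}

    # ------------------------------------------------------------ the passes
    def _child_term(self, block: _Block, down, scales, node):
        """P(t_child) applied to a child's partial, per category."""
        i = self.node_index[id(node)]
        Ps = block.eig.probs_many(block.scaled_times(node.length))
        if node.is_tip:
            cp = block.tip_partials[self.tip_row[id(node)]]     # (4, n_pat)
            return np.einsum("cij,jp->cip", Ps, cp), 0.0
        return np.einsum("cij,cjp->cip", Ps, down[i]), scales[i]

    def _down_pass(self, block: _Block):
        n = len(self.nodes)
        down: list = [None] * n
        scales: list = [None] * n
        for k, node in enumerate(self.nodes):
            if node.is_tip:
                continue
            prod = None
            sc = np.zeros(block.n_patterns)
            for child in node.children:
                term, child_scale = self._child_term(block, down, scales, child)
                prod = term if prod is None else prod * term
                sc = sc + child_scale
            m = prod.max(axis=(0, 1))
            m = np.where(m > 0, m, 1.0)
            down[k] = prod / m
            scales[k] = sc + np.log(m)
        return down, scales

    def _out_pass(self, block: _Block, down, scales):
        """Partial of everything outside each node's subtree, evaluated at
        the parent end of the node's branch (reversible models only)."""
        n = len(self.nodes)
        ncat = block.rates.size
        out: list = [None] * n
        out_scales: list = [None] * n
        up_node: list = [None] * n
        up_scales: list = [None] * n
        root_i = self.node_index[id(self.tree.root)]
        up_node[root_i] = np.ones((ncat, 4, block.n_patterns))
        up_scales[root_i] = np.zeros(block.n_patterns)
        for node in self.tree.preorder():
            if node.is_tip:
                continue
            k = self.node_index[id(node)]
            terms = []
            for child in node.children:
                terms.append(self._child_term(block, down, scales, child))
            for idx, child in enumerate(node.children):
                ci = self.node_index[id(child)]
                o = up_node[k].copy()
                sc = up_scales[k].copy()
                for jdx, (term, term_scale) in enumerate(terms):
                    if jdx == idx:
                        continue
                    o = o * term
                    sc = sc + term_scale
                m = o.max(axis=(0, 1))
                m = np.where(m > 0, m, 1.0)
                o /= m
                sc = sc + np.log(m)
                out[ci] = o
                out_scales[ci] = sc
                if not child.is_tip:
                    Ps = block.eig.probs_many(block.scaled_times(child.length))
                    up_node[ci] = np.einsum("cij,cjp->cip", Ps, o)
                    up_scales[ci] = sc
        return out, out_scales

    # ---------------------------------------------------------- likelihoods
    def _block_pattern_lnl(self, block: _Block, down, scales) -> np.ndarray:
        root_i = self.node_index[id(self.tree.root)]
        ncat = block.rates.size
        like = np.einsum("i,cip->p", block.freqs, down[root_i]) / ncat
        if np.any(like <= 0):
            bad = int(np.argmin(like))
            raise LikelihoodError(
                f"non-positive site likelihood at pattern {bad} "
                f"(column {int(block.columns[np.nonzero(block.inverse == bad)[0][0]])})")
        lnl = np.log(like) + scales[root_i]
        # an all-missing column has likelihood exactly one; pin it against
        # eigendecomposition round-off
        lnl[(block.patterns == 4).all(axis=0)] = 0.0
        return lnl

    def site_log_likelihoods(self) -> tuple[np.ndarray, float]:
        """Per-site log-likelihood vector (original column order) and total."""
        per_site = np.empty(self.aln.partitions.total_length)
        total = 0.0
        for block in self.blocks:
            down, scales = self._down_pass(block)
            lnl_pat = self._block_pattern_lnl(block, down, scales)
            per_site[block.columns] = lnl_pat[block.inverse]
            total += float(lnl_pat @ block.counts)
        return per_site, total

    def total_log_likelihood(self) -> float:
        total = 0.0
        for block in self.blocks:
            down, scales = self._down_pass(block)
            total += float(self._block_pattern_lnl(block, down, scales)
                           @ block.counts)
        return total

    # ------------------------------------------------- branch optimisation
    def _down_entry(self, block, down, scales, node):
        """(partial, scale) of the subtree below ``node`` for one block."""
        i = self.node_index[id(node)]
        if node.is_tip:
            return block.tip_partials[self.tip_row[id(node)]][None], 0.0
        return down[i], scales[i]

    def _refresh_down(self, state, node) -> None:
        """Recompute one internal node's down partial from its children."""
        for block, down, scales in state:
            prod, sc = None, np.zeros(block.n_patterns)
            for child in node.children:
                term, t_scale = self._child_term(block, down, scales, child)
                prod = term if prod is None else prod * term
                sc = sc + t_scale
            m = prod.max(axis=(0, 1))
            m = np.where(m > 0, m, 1.0)
            i = self.node_index[id(node)]
            down[i] = prod / m
            scales[i] = sc + np.log(m)

    def _optimize_edge(self, state, node, ups, xatol: float = 1e-8,
                       maxiter: int = 60) -> None:
        """Bounded Brent on the branch above ``node``; ``ups`` maps block
        index to the fresh (out partial, out scale) at the parent end."""
        parts = []
        for bi, (block, down, scales) in enumerate(state):
            D, d_scale = self._down_entry(block, down, scales, node)
            up, up_scale = ups[bi]
            piO = block.freqs[None, :, None] * up
            const = up_scale + d_scale
            parts.append((block, piO, D, const, block.rates.size))

        def neg(t: float) -> float:
            total = 0.0
            for block, piO, D, const, ncat in parts:
                Ps = block.eig.probs_many(block.scaled_times(t))
                PD = np.einsum("cij,njp->cip", Ps, D) if D.shape[0] == 1 \
                    else np.einsum("cij,cjp->cip", Ps, D)
                like = np.einsum("cip,cip->p", piO, PD) / ncat
                like = np.maximum(like, 1e-300)
                total += float((np.log(like) + const) @ block.counts)
            return -total

        cur = neg(node.length)
        # search a bracket around the current length first; re-widen to the
        # global bounds only if the optimum presses against the bracket
        lo = max(BRANCH_MIN, node.length / 10.0)
        hi = min(BRANCH_MAX, max(node.length * 10.0, 1e-4))
        res = spo.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                  options={"xatol": xatol, "maxiter": maxiter})
        at_edge = (res.x - lo < 2 * xatol and lo > BRANCH_MIN) or \
                  (hi - res.x < 2 * xatol and hi < BRANCH_MAX)
        if at_edge:
            res = spo.minimize_scalar(neg, bounds=(BRANCH_MIN, BRANCH_MAX),
                                      method="bounded",
                                      options={"xatol": xatol,
                                               "maxiter": maxiter})
        if res.fun < cur:
            node.length = float(np.clip(res.x, BRANCH_MIN, BRANCH_MAX))

    def _sweep(self, state, xatol: float = 1e-8) -> None:
        """One Gauss–Seidel sweep over all edges with partials refreshed as
        the traversal descends (each edge sees fully current partials)."""

        def up_times_siblings(node, parent_ups, siblings):
            ups = []
            for bi, (block, down, scales) in enumerate(state):
                up, up_scale = parent_ups[bi]
                prod, sc = up, up_scale
                first = prod is None
                for sib in siblings:
                    term, t_scale = self._child_term(block, down, scales, sib)
                    if first:
                        prod, sc, first = term, t_scale, False
                    else:
                        prod = prod * term
                        sc = sc + t_scale
                m = prod.max(axis=(0, 1))
                m = np.where(m > 0, m, 1.0)
                ups.append((prod / m, sc + np.log(m)))
            return ups

        def visit(node, ups) -> None:
            # ups: per block, the rest-of-tree partial at the parent end of
            # the branch above ``node``, current for all other edges
            self._optimize_edge(state, node, ups, xatol=xatol)
            if node.is_tip:
                return
            # out partial seen from below the (new) branch above node
            node_ups = []
            for bi, (block, down, scales) in enumerate(state):
                up, up_scale = ups[bi]
                Ps = block.eig.probs_many(block.scaled_times(node.length))
                # P(outside | state at node) = P(t) @ out  (reversibility)
                node_ups.append((np.einsum("cij,cjp->cip", Ps, up), up_scale))
            for child in node.children:
                sibs = [c for c in node.children if c is not child]
                visit(child, up_times_siblings(node, node_ups, sibs))
            self._refresh_down(state, node)

        root = self.tree.root
        ncat_ones = {bi: (None, 0.0) for bi in range(len(state))}
        for child in root.children:
            sibs = [c for c in root.children if c is not child]
            visit(child, up_times_siblings(root, ncat_ones, sibs))
        self._refresh_down(state, root)

    def optimize_branch_lengths(self, tol: float = 1e-6, max_rounds: int = 20,
                                xatol: float = 1e-8) -> float:
        """Coordinate-ascent branch-length optimisation in place.

        Each round is one Gauss–Seidel sweep: edges are optimised one at a
        time against partials that reflect every previously updated branch,
        so each single-edge step is an exact conditional maximisation and
        the total log-likelihood is non-decreasing.  Rounds stop when the
        improvement falls below ``tol``.
        """
        total = self.total_log_likelihood()
        if not np.isfinite(total):
            raise LikelihoodError("non-finite starting likelihood")
        state = [(block, *self._down_pass(block)) for block in self.blocks]
        prev = total
        for _ in range(max_rounds):
            self._sweep(state, xatol=xatol)
            total = 0.0
            for block, down, scales in state:
                total += float(self._block_pattern_lnl(block, down, scales)
                               @ block.counts)
            if total - prev < tol:
                break
            prev = total
        return max(total, prev)

    def score_with_single_edge(self, node, xatol: float = 1e-4) -> float:
        """Optimise only the branch above ``node`` and return the total lnL.

        Used to score NNI candidates cheaply: one down pass plus an up-path
        walk from the root to the edge, then bounded Brent on that edge.
        """
        state = [(block, *self._down_pass(block)) for block in self.blocks]
        path = []
        cur = node
        while cur.parent is not None:
            path.append(cur)
            cur = cur.parent
        path.reverse()                      # root child ... node
        ups = [(None, 0.0)] * len(state)
        for step in path:
            parent = step.parent
            new_ups = []
            for bi, (block, down, scales) in enumerate(state):
                up, up_scale = ups[bi]
                prod, sc, first = up, up_scale, up is None
                for sib in parent.children:
                    if sib is step:
                        continue
                    term, t_scale = self._child_term(block, down, scales, sib)
                    if first:
                        prod, sc, first = term, t_scale, False
                    else:
                        prod = prod * term
                        sc = sc + t_scale
                m = prod.max(axis=(0, 1))
                m = np.where(m > 0, m, 1.0)
                new_ups.append((prod / m, sc + np.log(m)))
            if step is not node:
                moved = []
                for bi, (block, _, _) in enumerate(state):
                    up, up_scale = new_ups[bi]
                    Ps = block.eig.probs_many(block.scaled_times(step.length))
                    moved.append((np.einsum("cij,cjp->cip", Ps, up), up_scale))
                ups = moved
            else:
                ups = new_ups
        self._optimize_edge(state, node, ups, xatol=xatol, maxiter=25)
        # total at the optimised length, via the edge formula
        total = 0.0
        for bi, (block, down, scales) in enumerate(state):
            D, d_scale = self._down_entry(block, down, scales, node)
            up, up_scale = ups[bi]
            Ps = block.eig.probs_many(block.scaled_times(node.length))
            PD = np.einsum("cij,njp->cip", Ps, D) if D.shape[0] == 1 \
                else np.einsum("cij,cjp->cip", Ps, D)
            piO = block.freqs[None, :, None] * up
            like = np.einsum("cip,cip->p", piO, PD) / block.rates.size
            like = np.maximum(like, 1e-300)
            total += float((np.log(like) + up_scale + d_scale) @ block.counts)
        return total

    def optimize_multipliers(self, bounds=(1e-3, 1e3)) -> float:
        """Optimise each block's rate multiplier by bounded scalar search."""
        for block in self.blocks:
            def f(logm: float) -> float:
                block.multiplier = float(np.exp(logm))
                down, scales = self._down_pass(block)
                return -float(self._block_pattern_lnl(block, down, scales)
                              @ block.counts)
            res = spo.minimize_scalar(f, bounds=(np.log(bounds[0]),
                                                 np.log(bounds[1])),
                                      method="bounded",
                                      options={"xatol": 1e-6, "maxiter": 60})
            block.multiplier = float(np.exp(res.x))
        return self.total_log_likelihood()


# ------------------------------------------------------------- entry points

def site_log_likelihoods(tree: PhyloTree, pmodel: PartitionedModel,
                         aln: ConcatenatedAlignment
                         ) -> tuple[np.ndarray, float]:
    """Per-site log-likelihoods by pruning plus their exact total."""
    return TreeLikelihood(tree.copy(), pmodel, aln).site_log_likelihoods()


def optimize_branch_lengths(topology: PhyloTree, pmodel: PartitionedModel,
                            aln: ConcatenatedAlignment, tol: float = 1e-6,
                            max_rounds: int = 20) -> tuple[PhyloTree, float]:
    """Maximum-likelihood branch lengths on a fixed topology.

    Returns a new tree (same topology) and the final total log-likelihood,
    which is never below the starting one.
    """
    tl = TreeLikelihood(topology.copy(), pmodel, aln)
    total = tl.optimize_branch_lengths(tol=tol, max_rounds=max_rounds)
    return tl.tree, total


# ----------------------------------------------------------- model fitting

@dataclass
class FitResult:
    model: PartitionedModel
    bic_table: "object"                     # pandas DataFrame
    tree: PhyloTree                         # lengths rescaled to keep the
                                            # weighted-mean multiplier at 1
    flagged_loci: list = field(default_factory=list)


def _empirical_freqs(codes: np.ndarray) -> np.ndarray:
    counts = np.array([(codes == s).sum() for s in range(4)], dtype=float) + 1.0
    return counts / counts.sum()


def _candidate_models(freqs: np.ndarray):
    """(label, builder(params), n_free_params, x0, bounds) per candidate,
    ordered from simple to complex.  Parameters are log-scale:
    [log multiplier, (log kappa | 5 log exchangeabilities), (log alpha)]."""
    cands = []
    mb = (np.log(1e-3), np.log(1e3))
    kb = (np.log(0.05), np.log(100.0))
    ab = (np.log(0.02), np.log(100.0))

    def jc(x, gamma):
        return SubstitutionModel("JC69",
                                 gamma_shape=np.exp(x[1]) if gamma else None)

    def hky(x, gamma):
        return SubstitutionModel("HKY85", freqs=freqs, kappa=np.exp(x[1]),
                                 gamma_shape=np.exp(x[2]) if gamma else None)

    def gtr(x, gamma):
        ex = np.concatenate([np.exp(x[1:6]), [1.0]])
        return SubstitutionModel("GTR", freqs=freqs, exchangeabilities=ex,
                                 gamma_shape=np.exp(x[6]) if gamma else None)

    for gamma in (False, True):
        suffix = "+G4" if gamma else ""
        extra = ([np.log(0.5)], [ab]) if gamma else ([], [])
        cands.append((f"JC69{suffix}", lambda x, g=gamma: jc(x, g),
                      0 + (1 if gamma else 0),
                      [0.0] + extra[0], [mb] + extra[1]))
        cands.append((f"HKY85{suffix}", lambda x, g=gamma: hky(x, g),
                      1 + (1 if gamma else 0),
                      [0.0, np.log(2.0)] + extra[0], [mb, kb] + extra[1]))
        cands.append((f"GTR{suffix}", lambda x, g=gamma: gtr(x, g),
                      5 + (1 if gamma else 0),
                      [0.0] + [0.0] * 5 + extra[0], [mb] + [kb] * 5 + extra[1]))
    # evaluation order: by complexity, so BIC ties resolve to simpler models
    cands.sort(key=lambda c: c[2])
    return cands


def fit_models(aln: ConcatenatedAlignment, tree: PhyloTree,
               gamma: bool = True, maxiter: int = 60) -> FitResult:
    """Per-locus model selection by BIC over {JC69, HKY85, GTR} x {+/-Γ4}.

    Base frequencies are empirical per locus; the per-locus free parameters
    (rate multiplier, kappa or exchangeabilities, Γ shape) are optimised
    numerically with branch lengths held fixed.  BIC uses the locus length
    as the sample size; ties prefer the simpler model.
    """
    import pandas as pd

    rows = []
    models: dict[str, SubstitutionModel] = {}
    multipliers: dict[str, float] = {}
    flagged = []
    codes_all = aln.codes()
    for lid, start, end in aln.partitions.entries:
        sub = ConcatenatedAlignment(
            list(aln.taxa), aln.matrix[:, start:end],
            PartitionMap([(lid, 0, end - start)]))
        freqs = _empirical_freqs(codes_all[:, start:end])
        L = end - start
        best = None
        for label, build, n_free, x0, bounds in _candidate_models(freqs):
            if not gamma and label.endswith("+G4"):
                continue

            def neg_lnl(x):
                try:
                    model = build(x)
                    pm = PartitionedModel({lid: model},
                                          {lid: float(np.exp(x[0]))})
                    tl = TreeLikelihood(tree.copy(), pm, sub)
                    return -tl.total_log_likelihood()
                except (ModelError, LikelihoodError, FloatingPointError):
                    return 1e12

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = spo.minimize(neg_lnl, np.asarray(x0, float),
                                   method="L-BFGS-B", bounds=bounds,
                                   options={"maxiter": maxiter})
            lnl = -float(res.fun)
            n_params = n_free + 1           # + the rate multiplier
            bic = -2.0 * lnl + n_params * np.log(L)
            converged = bool(res.success) and lnl > -1e11
            rows.append({"locus_id": lid, "model": label, "lnL": lnl,
                         "n_params": n_params, "BIC": bic,
                         "converged": converged})
            if converged and (best is None or bic < best["BIC"] - 1e-9):
                best = {"label": label, "BIC": bic, "x": res.x,
                        "build": build}
        if best is None:                    # nothing converged: simplest family
            flagged.append(lid)
            models[lid] = SubstitutionModel("JC69")
            multipliers[lid] = 1.0
        else:
            models[lid] = best["build"](best["x"])
            multipliers[lid] = float(np.exp(best["x"][0]))

    pmodel = PartitionedModel(models, multipliers)
    scale = pmodel.normalise(aln.partitions.lengths())
    out_tree = tree.copy()
    for node in out_tree.postorder():
        if node.parent is not None:
            node.length *= scale
    table = pd.DataFrame(rows)
    table["selected"] = [
        r["model"] == _selected_label(models[r["locus_id"]])
        for _, r in table.iterrows()]
    return FitResult(pmodel, table, out_tree, flagged)


def _selected_label(m: SubstitutionModel) -> str:
    return m.family + ("+G4" if m.gamma_shape is not None else "")
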