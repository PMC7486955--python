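"""Independent reference implementations used as test oracles.

These deliberately use different algorithms from the package: full
enumeration over internal states for site likelihoods, and edge-removal
flood fill for tree bipartitions.
"""

import itertools

import numpy as np

from phylodelta.models import EigenSystem, rate_matrix


def brute_force_site_lnl(tree, model, taxa, column, multiplier=1.0):
    """Site log-likelihood by summation over all internal-state
    assignments, averaged over Γ categories."""
    es = EigenSystem(rate_matrix(model), model.freqs)
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_tip]
    tip_state = {n.name: column[taxa.index(n.name)] for n in nodes if n.is_tip}
    total = 0.0
    rates = model.category_rates()
    for r in rates:
        P = {id(n): es.probs(n.length * r * multiplier) for n in nodes}
        cat = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            amap = {id(n): a for n, a in zip(internals, assign)}
            pr = model.freqs[amap[id(tree.root)]]
            for n in nodes:
                if n.parent is None:
                    continue
                parent_state = amap[id(n.parent)]
                if n.is_tip:
                    c = tip_state[n.name]
                    pr *= 1.0 if c not in code else P[id(n)][parent_state,
                                                            code[c]]
                else:
                    pr *= P[id(n)][parent_state, amap[id(n)]]
            cat += pr
        total += cat / len(rates)
    return np.log(total)


def floodfill_rf(t1, t2):
    """RF distance via edge-removal flood fill on the tree graph — an
    algorithm independent of the package's postorder subtree-set approach."""

    def splits(tree):
        nodes = list(tree.postorder())
        adj = {id(n): set() for n in nodes}
        by_id = {id(n): n for n in nodes}
        for n in nodes:
            if n.parent is not None:
                adj[id(n)].add(id(n.parent))
                adj[id(n.parent)].add(id(n))
        tips = frozenset(n.name for n in nodes if n.is_tip)
        anchor = min(tips)
        out = set()
        for n in nodes:
            if n.parent is None or n.is_tip:
                continue
            # remove the edge (n, parent) and flood from n
            seen = {id(n)}
            stack = [id(n)]
            blocked = frozenset({(id(n), id(n.parent)),
                                 (id(n.parent), id(n))})
            while stack:
                cur = stack.pop()
                for nb in adj[cur]:
                    if (cur, nb) in blocked or nb in seen:
                        continue
                    seen.add(nb)
                    stack.append(nb)
            side = frozenset(by_id[i].name for i in seen
                             if by_id[i].is_tip)
            side = side if anchor not in side else tips - side
            if 2 <= len(side) <= len(tips) - 2:
                out.add(side)
        return out

    return len(splits(t1) ^ splits(t2))
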