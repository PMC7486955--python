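"""Phylogenetic tree container and topology operations.

A :class:`PhyloTree` is a rooted node structure that also serves as the
working representation of an unrooted tree: an unrooted binary tree is stored
rooted at an internal node with three children.  All likelihood models used
here are time-reversible, so the placement of that root is immaterial.

Newick parsing is delegated to dendropy; writing is a small recursion.
"""

from __future__ import annotations

import io
from typing import Iterator, Optional

import dendropy

__all__ = ["TreeError", "Node", "PhyloTree", "root_with_outgroup"]


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.support: Optional[float] = None
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, n_children={len(self.children)})"


class PhyloTree:
    """Binary tree with branch lengths; tips carry unique taxon labels."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        names = [t.name for t in self.tips()]
        if len(set(names)) != len(names):
            raise TreeError("duplicate tip labels")
        if any(n is None for n in names):
            raise TreeError("unlabelled tip")

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_newick(cls, newick: str, rooted: Optional[bool] = None) -> "PhyloTree":
        try:
            dt = dendropy.Tree.get(data=newick, schema="newick",
                                   preserve_underscores=True,
                                   suppress_internal_node_taxa=True)
        except Exception as err:
            raise TreeError(f"cannot parse newick: {err}") from err

        def convert(dn) -> Node:
            label = dn.taxon.label if dn.taxon is not None else None
            node = Node(name=label, length=dn.edge.length or 0.0)
            if label is None and dn.label is not None:
                try:
                    node.support = float(dn.label)
                except ValueError:
                    pass
            for c in dn.child_nodes():
                node.add(convert(c))
            return node

        root = convert(dt.seed_node)
        if rooted is None:
            rooted = len(root.children) == 2
        return cls(root, rooted=rooted)

    def to_newick(self, lengths: bool = True, supports: bool = False,
                  length_fmt: str = "%.10g") -> str:
        out = io.StringIO()

        def write(node: Node, top: bool) -> None:
            if node.is_tip:
                out.write(node.name)
            else:
                out.write("(")
                for i, c in enumerate(node.children):
                    if i:
                        out.write(",")
                    write(c, False)
                out.write(")")
                if supports and node.support is not None and not top:
                    out.write("%d" % round(node.support))
            if lengths and not top:
                out.write(":" + length_fmt % node.length)

        write(self.root, True)
        out.write(";")
        return out.getvalue()

    # ------------------------------------------------------------ traversal
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    def n_tips(self) -> int:
        return len(self.tips())

    def copy(self) -> "PhyloTree":
        def dup(n: Node) -> Node:
            m = Node(n.name, n.length)
            m.support = n.support
            for c in n.children:
                m.add(dup(c))
            return m

        return PhyloTree(dup(self.root), rooted=self.rooted)

    # --------------------------------------------------------- bipartitions
    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions of the (unrooted sense of the) tree.

        Each internal edge induces a split of the tip set; splits are
        canonicalised as the side *not* containing the lexicographically
        smallest tip, so identical splits from differently rooted trees
        compare equal.
        """
        all_tips = frozenset(self.tip_names())
        anchor = min(all_tips)
        n = len(all_tips)
        splits: set[frozenset] = set()
        below: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_tip:
                below[id(node)] = frozenset([node.name])
            else:
                s = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = s
                if node is self.root:
                    continue
                side = s if anchor not in s else all_tips - s
                if 2 <= len(side) <= n - 2:
                    splits.add(side)
        return splits

    # -------------------------------------------------------------- rooting
    def unroot(self) -> "PhyloTree":
        """Return an unrooted copy (root is a trifurcation, or the tree
        itself for n < 3)."""
        t = self.copy()
        t.rooted = False
        root = t.root
        while len(root.children) == 2:
            # collapse the bifurcating root: merge one internal child up
            a, b = root.children
            keep = a if not a.is_tip else b
            if keep.is_tip:     # two-tip tree; nothing to collapse
                break
            other = b if keep is a else a
            other.length += keep.length
            root.children = [c for c in root.children if c is not keep]
            for c in keep.children:
                root.add(c)
            root = t.root
        return t

    def reroot_at(self, node: Node) -> None:
        """Make ``node`` (internal) the root in place, reversing parent links."""
        if node is self.root:
            return
        path = []
        cur = node
        while cur is not None:
            path.append(cur)
            cur = cur.parent
        old_lengths = [v.length for v in path]
        # path: node ... old_root; reverse each edge along the path
        for child, parent in zip(path, path[1:]):
            parent.children.remove(child)
            child.add(parent)
        # the reversed edge (v_i, v_{i+1}) keeps its length, now stored on
        # v_{i+1} which hangs below v_i
        for i in range(1, len(path)):
            path[i].length = old_lengths[i - 1]
        node.parent = None
        node.length = 0.0
        self.root = node


def root_with_outgroup(tree: PhyloTree, outgroup_taxon: str) -> PhyloTree:
    """Root a tree on the midpoint of the outgroup's pendant edge.

    The ingroup topology is untouched; the result is a rooted binary tree
    whose two children are the outgroup tip and the ingroup clade.
    """
    t = tree.unroot() if tree.rooted else tree.copy()
    tip = next((n for n in t.postorder() if n.is_tip and n.name == outgroup_taxon), None)
    if tip is None:
        raise TreeError(f"outgroup taxon {outgroup_taxon!r} not in tree")
    attach = tip.parent
    if attach is None:
        raise TreeError("cannot root a single-tip tree")
    t.reroot_at(attach)
    # attach now has the outgroup tip among its children; split its pendant edge
    half = tip.length / 2.0
    new_root = Node()
    attach.children.remove(tip)
    ingroup = attach
    new_root.add(tip)
    tip.length = half
    new_root.add(ingroup)
    ingroup.length = half
    ingroup.parent = new_root
    out = PhyloTree(new_root, rooted=True)
    return out
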