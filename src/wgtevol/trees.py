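"""Rooted species trees with a root edge descending from the polyploidy event.

The tree is rooted and binary; every node, including the root, carries the
length of the edge *above* it in units of expected triplicate-to-duplicate
losses (``nu = alpha * t``).  The root edge runs from the polyploidy event to
the first speciation, which is where loss bookkeeping starts.
"""
from __future__ import annotations

import itertools

import dendropy
import numpy as np


class SpeciesTree:
    """Array-backed rooted binary tree.

    Nodes are indexed ``0 .. n_nodes-1``; node 0 is the root.  ``lengths[i]``
    is the length of the edge above node ``i`` (``lengths[0]`` is the root
    edge).  Tip labels appear in ``genomes`` in traversal order; that order
    fixes the genome axis used throughout the pillar HMM.
    """

    def __init__(self, children: list[list[int]], lengths, labels: list[str | None]):
        self.children = [list(c) for c in children]
        self.lengths = np.asarray(lengths, dtype=float).copy()
        self.labels = list(labels)
        self.n_nodes = len(children)
        if self.n_nodes != len(self.lengths) or self.n_nodes != len(self.labels):
            raise ValueError("inconsistent node arrays")
        if np.any(self.lengths < 0):
            raise ValueError("branch lengths must be >= 0")
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        for i, cs in enumerate(self.children):
            if len(cs) not in (0, 2):
                raise ValueError("tree must be binary")
            for c in cs:
                self.parent[c] = i
        self.tips = [i for i in range(self.n_nodes) if not self.children[i]]
        self.genomes = tuple(self.labels[i] for i in self.tips)
        if len(set(self.genomes)) != len(self.genomes) or None in self.genomes:
            raise ValueError("tip labels must be unique and non-empty")
        # postorder: children before parents
        self.postorder: list[int] = []
        stack, seen = [0], set()
        while stack:
            n = stack.pop()
            if n in seen:
                self.postorder.append(n)
                continue
            seen.add(n)
            stack.append(n)
            stack.extend(self.children[n])

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def n_edges(self) -> int:
        return self.n_nodes

    def edge_names(self) -> list[str]:
        """Human-readable branch names: tip label, joined clade labels, or
        ``root`` for the root edge."""
        names = [""] * self.n_nodes
        for n in self.postorder:
            if not self.children[n]:
                names[n] = self.labels[n]
            else:
                names[n] = "(" + "+".join(sorted(
                    names[c].strip("()") for c in self.children[n])) + ")"
        names[0] = "root"
        return names

    def clade(self, node: int) -> frozenset:
        out = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if self.children[n]:
                stack.extend(self.children[n])
            else:
                out.add(self.labels[n])
        return frozenset(out)

    def with_lengths(self, lengths) -> "SpeciesTree":
        return SpeciesTree(self.children, lengths, self.labels)

    # -- construction -------------------------------------------------------------
    @classmethod
    def from_topology(cls, topo, lengths: dict | None = None,
                      default_length: float = 0.1, root_length: float | None = None):
        """Build from a nested-tuple topology such as ``((("a","b"),"c"),"d")``.

        ``lengths`` maps tip labels / frozensets of tip labels (clades) to edge
        lengths; the key ``"root"`` sets the root edge.
        """
        lengths = lengths or {}
        children: list[list[int]] = []
        lens: list[float] = []
        labels: list[str | None] = []

        def build(sub) -> int:
            idx = len(children)
            children.append([])
            lens.append(default_length)
            labels.append(None)
            if isinstance(sub, (tuple, list)):
                kids = [build(s) for s in sub]
                children[idx].extend(kids)
            else:
                labels[idx] = str(sub)
            return idx

        build(topo)
        tree = cls(children, lens, labels)
        for i in range(tree.n_nodes):
            key = tree.labels[i] if not tree.children[i] else tree.clade(i)
            if i == 0 and root_length is not None:
                tree.lengths[0] = root_length
            elif i == 0 and "root" in lengths:
                tree.lengths[0] = lengths["root"]
            elif key in lengths:
                tree.lengths[i] = lengths[key]
        if np.any(tree.lengths < 0):
            raise ValueError("branch lengths must be >= 0")
        return tree

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        try:
            dt = dendropy.Tree.get(data=newick, schema="newick",
                                   suppress_internal_node_taxa=True,
                                   preserve_underscores=True)
        except Exception as exc:
            raise ValueError(f"could not parse newick tree: {exc}") from exc
        children: list[list[int]] = []
        lens: list[float] = []
        labels: list[str | None] = []

        def build(node) -> int:
            idx = len(children)
            children.append([])
            lens.append(node.edge.length if node.edge.length is not None else 0.0)
            labels.append(node.taxon.label if node.taxon is not None else None)
            for ch in node.child_nodes():
                children[idx].append(build(ch))
            return idx

        build(dt.seed_node)
        return cls(children, lens, labels)

    def to_newick(self) -> str:
        def fmt(n: int) -> str:
            if not self.children[n]:
                return f"{self.labels[n]}:{self.lengths[n]:g}"
            inner = ",".join(fmt(c) for c in self.children[n])
            return f"({inner}):{self.lengths[n]:g}"
        return fmt(0) + ";"

    def __repr__(self):
        return f"SpeciesTree({self.to_newick()})"


def enumerate_topologies(tips, constraint: tuple[str, str] | None = None):
    """All distinct rooted binary topologies over ``tips`` as nested tuples.

    With ``constraint`` given as a pair of tip labels, only topologies in
    which that pair forms a cherry (sister tips) are returned; for four tips
    this leaves exactly the three placements of the remaining two.
    """
    tips = [str(t) for t in tips]
    if len(tips) < 3:
        raise ValueError("need at least 3 tips")

    def grow(topos, tip):
        out = []
        for topo in topos:
            # insert on every edge, including above the current root
            out.append((topo, tip))
            out.extend(_insert_within(topo, tip))
        return out

    def _insert_within(sub, tip):
        # insertions on the edge above either child, or deeper down
        if not isinstance(sub, tuple):
            return []
        a, b = sub
        res = [((a, tip), b), (a, (b, tip))]
        res.extend((new_a, b) for new_a in _insert_within(a, tip))
        res.extend((a, new_b) for new_b in _insert_within(b, tip))
        return res

    topos = [tips[0]]
    for tip in tips[1:]:
        topos = grow(topos, tip)

    def canon(sub):
        if not isinstance(sub, tuple):
            return sub
        a, b = canon(sub[0]), canon(sub[1])
        return tuple(sorted((a, b), key=str))

    seen = {}
    for t in topos:
        seen.setdefault(canon(t), t)
    topos = list(seen.values())

    def has_cherry(sub) -> bool:
        if not isinstance(sub, tuple):
            return False
        a, b = sub
        if {a, b} == set(constraint):
            return True
        return has_cherry(a) or has_cherry(b)

    if constraint is not None:
        topos = [t for t in topos if has_cherry(t)]
    return topos


def default_study_tree() -> SpeciesTree:
    """Four-taxon tree shaped like the Brassiceae study system.

    Topology ``(((B_rapa, B_oleracea), C_hispanica), S_alba)`` with a root
    edge long enough to reproduce heavy root-branch fractionation; lengths are
    the synthetic-data defaults (in units of alpha*t), not estimates.
    """
    topo = ((("B_rapa", "B_oleracea"), "C_hispanica"), "S_alba")
    lengths = {
        "root": 0.45,
        "B_rapa": 0.18,
        "B_oleracea": 0.18,
        "C_hispanica": 0.22,
        "S_alba": 0.28,
        frozenset({"B_rapa", "B_oleracea"}): 0.08,
        frozenset({"B_rapa", "B_oleracea", "C_hispanica"}): 0.10,
    }
    return SpeciesTree.from_topology(topo, lengths)
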