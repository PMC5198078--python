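"""Lightweight tree structures for trees of parts.

Unrooted binary trees are adjacency dicts: leaves are integers
``0..n-1`` indexing a taxon-name list, internal nodes are integers
``>= n`` with degree 3.  Rooted trees keep a child map with a degree-2
root.  Newick interchange goes through dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

Adjacency = dict[int, list[int]]


def star_tree(taxa_idx: tuple[int, int, int], internal: int) -> Adjacency:
    """The unique unrooted tree on three taxa."""
    a, b, c = taxa_idx
    return {a: [internal], b: [internal], c: [internal],
            internal: [a, b, c]}


def two_taxon_tree(a: int, b: int) -> Adjacency:
    return {a: [b], b: [a]}


def edges(adj: Adjacency) -> list[tuple[int, int]]:
    """Undirected edge list, each edge once with u < v."""
    return [(u, v) for u in adj for v in adj[u] if u < v]


def add_leaf_on_edge(adj: Adjacency, edge: tuple[int, int], leaf: int,
                     new_internal: int) -> Adjacency:
    """Copy of ``adj`` with ``leaf`` attached mid-edge via a new node."""
    u, v = edge
    out = {k: list(vs) for k, vs in adj.items()}
    out[u][out[u].index(v)] = new_internal
    out[v][out[v].index(u)] = new_internal
    out[new_internal] = [u, v, leaf]
    out[leaf] = [new_internal]
    return out


def leaves(adj: Adjacency, n_taxa: int) -> list[int]:
    return sorted(k for k in adj if k < n_taxa)


def splits(adj: Adjacency, n_taxa: int) -> frozenset[frozenset[int]]:
    """Topology fingerprint: the set of leaf bipartition sides.

    For each edge, the side not containing leaf ``min(leaves)`` is
    recorded; two unrooted binary trees are isomorphic as labeled trees
    iff their split sets are equal.
    """
    ref = min(leaves(adj, n_taxa))
    out = set()
    for u, v in edges(adj):
        side = _leafset_away(adj, v, u, n_taxa)
        if ref in side:
            side = frozenset(l for l in leaves(adj, n_taxa) if l not in side)
        out.add(side)
    return frozenset(out)


def _leafset_away(adj: Adjacency, start: int, block: int,
                  n_taxa: int) -> frozenset[int]:
    """Leaves reachable from ``start`` without crossing into ``block``."""
    seen = {block, start}
    stack = [start]
    found = []
    while stack:
        node = stack.pop()
        if node < n_taxa:
            found.append(node)
        for nxt in adj[node]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return frozenset(found)


def branch_label(adj: Adjacency, edge: tuple[int, int], n_taxa: int,
                 taxa: list[str]) -> str:
    """Deterministic human-readable label for a branch (for tie-breaks)."""
    u, v = edge
    side = sorted(taxa[l] for l in _leafset_away(adj, v, u, n_taxa))
    other = sorted(taxa[l] for l in _leafset_away(adj, u, v, n_taxa))
    small, big = sorted([side, other], key=lambda s: (len(s), s))
    return ",".join(small) + "|" + ",".join(big)


@dataclass(frozen=True)
class UnrootedTree:
    """An unrooted binary tree of parts with its parsimony length."""

    adj: Adjacency = field(hash=False)
    taxa: list[str] = field(hash=False)
    length: int | None = None

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def splits(self) -> frozenset[frozenset[int]]:
        return splits(self.adj, self.n_taxa)

    def canonical_newick(self) -> str:
        """Deterministic newick: rooted for display at the lowest-named
        leaf's branch, children sorted by subtree taxon content."""
        ref = min(range(self.n_taxa), key=lambda i: self.taxa[i])

        def rec(node: int, parent: int) -> tuple[str, str]:
            if node < self.n_taxa:
                return self.taxa[node], self.taxa[node]
            parts = sorted(rec(c, node) for c in self.adj[node] if c != parent)
            key = parts[0][0]
            return key, "(" + ",".join(p[1] for p in parts) + ")"

        if self.n_taxa == 2:
            a, b = sorted(self.taxa)
            return f"({a},{b});"
        _, rest = rec(self.adj[ref][0], ref)
        return f"({self.taxa[ref]},{rest});"

    def __eq__(self, other) -> bool:
        return (isinstance(other, UnrootedTree)
                and self.taxa == other.taxa
                and self.splits() == other.splits())

    def __hash__(self) -> int:
        return hash((tuple(self.taxa), self.splits()))


@dataclass
class RootedTree:
    """A rooted binary tree (degree-2 root), the input to chronologies."""

    children: dict[int, tuple[int, ...]]
    root: int
    taxa: list[str]
    length: int | None = None
    root_branch: str | None = None  # label of the branch the root was pulled to

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def parent_map(self) -> dict[int, int]:
        return {c: p for p, cs in self.children.items() for c in cs}

    def to_newick(self) -> str:
        def rec(node: int) -> str:
            if node not in self.children or not self.children[node]:
                return self.taxa[node]
            inner = ",".join(sorted(rec(c) for c in self.children[node]))
            return f"({inner})"

        return rec(self.root) + ";"

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick",
                                 rooting="force-rooted")
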