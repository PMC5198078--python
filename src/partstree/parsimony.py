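"""Wagner parsimony on ordered multistate characters.

Abundance-derived character states form a linear series, so a change
from state i to state j costs |i - j| (Wagner parsimony).  Tree length
is computed by the Farris interval rule, with a Sankoff dynamic program
as an independent second route; exact searches enumerate or
branch-and-bound over unrooted binary topologies; optimal trees are
rooted a posteriori by the Lundberg method, pulling the root to the
branch where a hypothetical ancestor attaches with the least increase
in length.  Under Weston's generality criterion the ancestor defaults
to the per-character maximum observed state, because in trees of parts
abundant, widespread states are ancestral.
"""

from __future__ import annotations

import numpy as np

from .matrix import CodedMatrix
from . import trees as T
from .trees import RootedTree, UnrootedTree

BIG = np.int64(1 << 40)


# ---------------------------------------------------------------------------
# tree length


def _farris(adj: T.Adjacency, states: np.ndarray) -> int:
    """Wagner length by the Farris interval rule (exact on binary trees).

    ``states[i]`` is the character-state row of leaf ``i``; leaves are
    the degree-1 nodes of ``adj``.
    """
    n_rows = states.shape[0]
    root = next(k for k in adj if k < n_rows and len(adj[k]) == 1)
    if len(adj) == 2:
        other = adj[root][0]
        return int(np.abs(states[root] - states[other]).sum())

    # orient away from the root leaf, then process in reverse (postorder)
    order: list[tuple[int, int]] = [(adj[root][0], root)]
    i = 0
    while i < len(order):
        node, parent = order[i]
        i += 1
        for nxt in adj[node]:
            if nxt != parent and len(adj[nxt]) > 1:
                order.append((nxt, node))
    lo: dict[int, np.ndarray] = {}
    hi: dict[int, np.ndarray] = {}
    cost = np.zeros(states.shape[1], dtype=np.int64)
    for node, parent in reversed(order):
        cl = ch = None
        for child in adj[node]:
            if child == parent:
                continue
            l, h = ((states[child], states[child]) if len(adj[child]) == 1
                    else (lo[child], hi[child]))
            if cl is None:
                cl, ch = l, h
            else:
                ilo = np.maximum(cl, l)
                ihi = np.minimum(ch, h)
                gap = ilo - ihi
                np.maximum(gap, 0, out=gap)
                cost += gap
                cl = np.minimum(ilo, ihi)
                ch = np.maximum(ilo, ihi)
        lo[node] = cl
        hi[node] = ch
    top = adj[root][0]
    s = states[root]
    cost += np.maximum(np.maximum(lo[top] - s, s - hi[top]), 0)
    return int(cost.sum())


def _sankoff(adj: T.Adjacency, states: np.ndarray, n_states: int) -> int:
    """Wagner length by Sankoff DP with linear cost (independent route)."""
    n_rows = states.shape[0]
    n_chars = states.shape[1]
    root = next(k for k in adj if k < n_rows and len(adj[k]) == 1)

    def leaf_vec(leaf: int) -> np.ndarray:
        v = np.full((n_chars, n_states), BIG, dtype=np.int64)
        v[np.arange(n_chars), states[leaf]] = 0
        return v

    def transform(g: np.ndarray) -> np.ndarray:
        # m[i] = min_j g[j] + |i - j|, via forward/backward passes
        m = g.copy()
        for i in range(1, n_states):
            np.minimum(m[:, i], m[:, i - 1] + 1, out=m[:, i])
        for i in range(n_states - 2, -1, -1):
            np.minimum(m[:, i], m[:, i + 1] + 1, out=m[:, i])
        return m

    def cost(node: int, parent: int) -> np.ndarray:
        if len(adj[node]) == 1:
            return leaf_vec(node)
        total = np.zeros((n_chars, n_states), dtype=np.int64)
        for child in adj[node]:
            if child != parent:
                total += transform(cost(child, node))
        return total

    top = transform(cost(adj[root][0], root))
    return int(top[np.arange(n_chars), states[root]].sum())


def _states_for(tree: UnrootedTree, c: CodedMatrix) -> np.ndarray:
    if sorted(tree.taxa) != sorted(c.part_ids):
        raise ValueError("tree leaf set does not match matrix taxa")
    row = {p: i for i, p in enumerate(c.part_ids)}
    return c.states[[row[t] for t in tree.taxa]]


def tree_length(tree: UnrootedTree, c: CodedMatrix,
                method: str = "farris") -> int:
    """Minimum number of ordered state steps implied by the topology."""
    states = _states_for(tree, c)
    if method == "farris":
        return _farris(tree.adj, states)
    if method == "sankoff":
        return _sankoff(tree.adj, states, c.alphabet_size)
    raise ValueError(f"unknown method: {method!r}")


def farris_bound(c: CodedMatrix) -> int:
    """Lower bound on any tree's length: sum of per-character ranges."""
    return int((c.states.max(axis=0) - c.states.min(axis=0)).sum())


# ---------------------------------------------------------------------------
# exact searches


def _all_topologies(n: int):
    """Yield every unrooted binary topology on leaves 0..n-1."""
    if n == 2:
        yield T.two_taxon_tree(0, 1)
        return

    def rec(adj: T.Adjacency, k: int, next_internal: int):
        if k == n:
            yield adj
            return
        for edge in T.edges(adj):
            yield from rec(T.add_leaf_on_edge(adj, edge, k, next_internal),
                           k + 1, next_internal + 1)

    yield from rec(T.star_tree((0, 1, 2), n), 3, n + 1)


def n_topologies(n: int) -> int:
    """(2n-5)!! unrooted binary topologies on n >= 3 leaves."""
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


def exhaustive_search(c: CodedMatrix, max_taxa: int = 9) -> list[UnrootedTree]:
    """All minimal-length unrooted trees by full enumeration.

    Enumerates every (2n-5)!! topology; refuse beyond ``max_taxa``
    (use :func:`branch_and_bound_search` or :func:`heuristic_search`).
    """
    n = c.n_parts
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n > max_taxa:
        raise ValueError(
            f"{n} taxa exceed the enumeration bound ({max_taxa}); "
            "use branch_and_bound_search or heuristic_search")
    best: int | None = None
    keep: list[T.Adjacency] = []
    for adj in _all_topologies(n):
        length = _farris(adj, c.states)
        if best is None or length < best:
            best, keep = length, [adj]
        elif length == best:
            keep.append(adj)
    out = [UnrootedTree(adj=a, taxa=list(c.part_ids), length=best)
           for a in keep]
    return sorted(out, key=UnrootedTree.canonical_newick)


def branch_and_bound_search(c: CodedMatrix) -> list[UnrootedTree]:
    """All minimal trees by depth-first stepwise addition with pruning.

    A partial tree is abandoned when its length plus an admissible
    completion bound (the per-character state range still unspanned by
    the placed taxa) exceeds the best full-tree length found so far.
    Ties are retained, so the result equals :func:`exhaustive_search`.
    """
    n = c.n_parts
    if n < 2:
        raise ValueError("need at least 2 taxa")
    states = c.states
    if n <= 3:
        return exhaustive_search(c)
    gmin = states.min(axis=0)
    gmax = states.max(axis=0)
    best: list[int | None] = [None]
    keep: list[T.Adjacency] = []

    def completion_bound(k: int) -> int:
        placed = states[:k]
        ext = (np.maximum(gmax - placed.max(axis=0), 0)
               + np.maximum(placed.min(axis=0) - gmin, 0))
        return int(ext.sum())

    def rec(adj: T.Adjacency, k: int, next_internal: int) -> None:
        length = _farris(adj, states[:k] if k < n else states)
        if best[0] is not None and length + completion_bound(k) > best[0]:
            return
        if k == n:
            if best[0] is None or length < best[0]:
                best[0] = length
                keep.clear()
            keep.append(adj)
            return
        for edge in T.edges(adj):
            rec(T.add_leaf_on_edge(adj, edge, k, next_internal),
                k + 1, next_internal + 1)

    rec(T.star_tree((0, 1, 2), n), 3, n + 1)
    out = [UnrootedTree(adj=a, taxa=list(c.part_ids), length=best[0])
           for a in keep]
    return sorted(out, key=UnrootedTree.canonical_newick)


# ---------------------------------------------------------------------------
# heuristic search


def _nni_neighbors(adj: T.Adjacency, n_taxa: int):
    for u, v in T.edges(adj):
        if u < n_taxa or v < n_taxa:
            continue
        a, b = [x for x in adj[u] if x != v]
        c, d = [x for x in adj[v] if x != u]
        for swap in (c, d):
            out = {k: list(vs) for k, vs in adj.items()}
            out[u][out[u].index(b)] = swap
            out[v][out[v].index(swap)] = b
            out[b][out[b].index(u)] = v
            out[swap][out[swap].index(v)] = u
            yield out


def _spr_neighbors(adj: T.Adjacency, n_taxa: int):
    for u, v in [(a, b) for a, b in T.edges(adj)] + \
                [(b, a) for a, b in T.edges(adj)]:
        # prune the subtree hanging off v (away from u); u must be internal
        if u < n_taxa:
            continue
        x, y = [w for w in adj[u] if w != v]
        residual = {k: list(vs) for k, vs in adj.items() if k != u}
        sub_nodes = _component(adj, v, u)
        residual_nodes = set(residual) - sub_nodes
        for k in (x, y):
            residual[k][residual[k].index(u)] = x if k == y else y
        if len(residual_nodes) < 2:
            continue
        res_edges = [(a, b) for a, b in T.edges(
            {k: residual[k] for k in residual_nodes}) if True]
        for edge in res_edges:
            if set(edge) == {x, y}:
                continue  # regraft in place = original topology
            out = {k: list(vs) for k, vs in residual.items()}
            for k in sub_nodes:
                out[k] = list(adj[k])
            a, b = edge
            out[a][out[a].index(b)] = u
            out[b][out[b].index(a)] = u
            out[u] = [a, b, v]
            yield out


def _component(adj: T.Adjacency, start: int, block: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for nxt in adj[node]:
            if nxt != block and nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen


def _greedy_addition(order: np.ndarray, states: np.ndarray,
                     n: int) -> T.Adjacency:
    adj = T.star_tree(tuple(int(t) for t in order[:3]), n)
    nxt = n + 1
    for t in order[3:]:
        rows = None
        best_len, best_adj = None, None
        for edge in T.edges(adj):
            cand = T.add_leaf_on_edge(adj, edge, int(t), nxt)
            length = _farris(cand, states)
            if best_len is None or length < best_len:
                best_len, best_adj = length, cand
        adj = best_adj
        nxt += 1
    return adj


def heuristic_search(c: CodedMatrix, n_starts: int = 10,
                     seed: int = 0) -> UnrootedTree:
    """Best tree found by random-addition starts refined by NNI then SPR.

    Deterministic given the seed; the reported length can never fall
    below the true minimum (it is the length of an actual tree).
    """
    n = c.n_parts
    if n < 4:
        return exhaustive_search(c)[0]
    rng = np.random.default_rng(seed)
    states = c.states
    best_len: int | None = None
    best_adj: T.Adjacency | None = None
    best_key: str | None = None
    for _ in range(max(1, n_starts)):
        adj = _greedy_addition(rng.permutation(n), states, n)
        length = _farris(adj, states)
        improved = True
        while improved:
            improved = False
            for gen in (_nni_neighbors, _spr_neighbors):
                for cand in gen(adj, n):
                    cl = _farris(cand, states)
                    if cl < length:
                        adj, length = cand, cl
                        improved = True
                        break
                if improved:
                    break
        key = UnrootedTree(adj=adj, taxa=list(c.part_ids)).canonical_newick()
        if best_len is None or length < best_len or \
                (length == best_len and key < best_key):
            best_len, best_adj, best_key = length, adj, key
    return UnrootedTree(adj=best_adj, taxa=list(c.part_ids), length=best_len)


# ---------------------------------------------------------------------------
# Lundberg rooting


def hypothetical_ancestor(c: CodedMatrix, convention: str = "max",
                          vector: np.ndarray | None = None) -> np.ndarray:
    """Per-character ancestral state vector for a-posteriori rooting.

    ``max`` (default) takes the per-character maximum observed state —
    in trees of parts high abundance is the general, hence ancestral,
    condition; ``min`` and an explicit user vector are also accepted.
    """
    if convention == "max":
        return c.states.max(axis=0)
    if convention == "min":
        return c.states.min(axis=0)
    if convention == "user":
        v = np.asarray(vector, dtype=np.int64)
        if v.shape != (c.n_characters,):
            raise ValueError("ancestor vector length must equal character count")
        return v
    raise ValueError(f"unknown ancestor convention: {convention!r}")


def lundberg_root(tree: UnrootedTree, c: CodedMatrix,
                  ancestor: np.ndarray | None = None) -> RootedTree:
    """Root a tree on the branch where a hypothetical ancestor attaches
    with the minimum increase in Wagner length.

    The ancestor is scored as a temporary extra leaf on every branch in
    turn and is not retained in the rooted tree.  Ties break to the
    lexicographically smallest branch label.  The rooted tree's length
    is the unrooted length plus the minimal increase.
    """
    if ancestor is None:
        ancestor = hypothetical_ancestor(c, "max")
    ancestor = np.asarray(ancestor, dtype=np.int64)
    if ancestor.shape != (c.n_characters,):
        raise ValueError("ancestor states missing for some characters")
    states = _states_for(tree, c)
    n = tree.n_taxa
    base = _farris(tree.adj, states)
    ext_states = np.vstack([states, ancestor[None, :]])
    anc_leaf = n  # sits in the extended state matrix right after the taxa
    top = max(tree.adj) + 1
    offset = top - n  # shift internal ids clear of the ancestor leaf id
    shifted = {k + offset if k >= n else k:
               [v + offset if v >= n else v for v in vs]
               for k, vs in tree.adj.items()}
    best = None
    for u, v in T.edges(tree.adj):
        su = u + offset if u >= n else u
        sv = v + offset if v >= n else v
        cand = T.add_leaf_on_edge(shifted, (su, sv), anc_leaf, max(shifted) + 1)
        increase = _farris(cand, ext_states) - base
        label = T.branch_label(tree.adj, (u, v), n, tree.taxa)
        entry = (increase, label, (u, v))
        if best is None or entry < best:
            best = entry
    increase, label, root_edge = best
    return _root_on_edge(tree, root_edge, base + increase, label)


def _root_on_edge(tree: UnrootedTree, edge: tuple[int, int],
                  rooted_length: int, label: str) -> RootedTree:
    u, v = edge
    root = max(tree.adj) + 1
    children: dict[int, tuple[int, ...]] = {root: (u, v)}

    def orient(node: int, parent: int) -> None:
        kids = tuple(w for w in tree.adj[node] if w != parent)
        if kids:
            children[node] = kids
            for k in kids:
                orient(k, node)

    orient(u, v)
    orient(v, u)
    return RootedTree(children=children, root=root, taxa=list(tree.taxa),
                      length=rooted_length, root_branch=label)


__all__ = [
    "tree_length", "farris_bound", "exhaustive_search",
    "branch_and_bound_search", "heuristic_search", "lundberg_root",
    "hypothetical_ancestor", "n_topologies",
]
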