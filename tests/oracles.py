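"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's DP/search code paths: tree
lengths come from enumerating every internal state assignment,
alignment scores from enumerating every monotone matching, and relic
components from pairwise union-find.
"""

from itertools import combinations

import numpy as np

from partstree.align import ScoringScheme


def brute_tree_length(adj: dict, states: np.ndarray) -> int:
    """Min over all internal-node state assignments of the Wagner cost."""
    n_rows = states.shape[0]
    internals = [k for k in adj if len(adj[k]) > 1]
    edges = [(u, v) for u in adj for v in adj[u] if u < v]
    total = 0
    for c in range(states.shape[1]):
        col = states[:, c]
        lo, hi = int(col.min()), int(col.max())
        if not internals:
            total += sum(abs(int(col[u]) - int(col[v])) for u, v in edges)
            continue
        axes = [np.arange(lo, hi + 1)] * len(internals)
        grids = np.meshgrid(*axes, indexing="ij")
        assign = {node: g.ravel() for node, g in zip(internals, grids)}
        cost = np.zeros(grids[0].size, dtype=np.int64)
        for u, v in edges:
            vu = assign[u] if u in assign else int(col[u])
            vv = assign[v] if v in assign else int(col[v])
            cost += np.abs(vu - vv)
        total += int(cost.min())
    return total


def brute_align_score(query: str, target: str, s: ScoringScheme) -> int:
    """Max over all monotone matchings, scoring internal gaps affinely
    and end gaps free (a gap run counts as internal for a sequence when
    residues of that sequence flank it on both sides)."""
    q = query.upper().replace("U", "T")
    t = target.upper().replace("U", "T")
    n, m = len(q), len(t)
    o, e = s.gap_open, s.gap_extend

    def gap(length: int) -> int:
        return o + e * length if length > 0 else 0

    best = 0  # the empty alignment
    for k in range(1, min(n, m) + 1):
        for qi in combinations(range(n), k):
            for tj in combinations(range(m), k):
                sc = 0
                for a, b in zip(qi, tj):
                    sc += s.match if q[a] == t[b] else s.mismatch
                for (a, b), (a2, b2) in zip(zip(qi, tj),
                                            zip(qi[1:], tj[1:])):
                    sc += gap(a2 - a - 1) + gap(b2 - b - 1)
                pre_q, pre_t = qi[0], tj[0]
                if pre_q and pre_t:
                    sc += gap(min(pre_q, pre_t))
                post_q, post_t = n - 1 - qi[-1], m - 1 - tj[-1]
                if post_q and post_t:
                    sc += gap(min(post_q, post_t))
                best = max(best, sc)
    return best


def brute_overlap_components(intervals: list[tuple[int, int]],
                             min_overlap: int = 1) -> list[frozenset[int]]:
    """Connected components of the pairwise interval-overlap graph."""
    n = len(intervals)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            if min(e1, e2) - max(s1, s2) + 1 >= min_overlap:
                parent[find(i)] = find(j)
    comps: dict[int, set[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return sorted((frozenset(v) for v in comps.values()),
                  key=lambda c: min(intervals[i][0] for i in c))
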