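"""Pairwise global DNA alignment without end-gap penalties.

The scan for tRNA-derived segments in rRNA needs alignments that are
global in the tRNA query but may land anywhere in the much longer rRNA
target, so gaps touching either sequence's ends are free while internal
gaps pay an affine penalty.  The dynamic program is Gotoh's three-state
recursion with zero-initialized boundaries and the optimum taken over
the last row and column; rows are vectorized over the target, with the
within-row affine gap state resolved by a prefix-maximum scan.

U and T are treated as identical; IUPAC ambiguity codes are accepted
and scored as mismatches; anything else is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    njit = None

NEG = -1e15  # effectively -infinity, safe under addition

_BASES = "ACGT"
_AMBIG = "RYSWKMBDHVN"
_SENTINEL = "!"  # hard-mask character; can never align profitably
_CODE = {b: i for i, b in enumerate(_BASES)}
_CODE.update({b: 4 + i for i, b in enumerate(_AMBIG)})
_CODE["U"] = _CODE["T"]
_CODE[_SENTINEL] = 4 + len(_AMBIG)
_NCODES = 4 + len(_AMBIG) + 1


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch and affine gap scores (gap of length L costs
    gap_open + gap_extend * L)."""

    match: int = 5
    mismatch: int = -4
    gap_open: int = -12
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("mismatch and gap penalties must be <= 0")

    def matrix(self) -> np.ndarray:
        m = np.full((_NCODES, _NCODES), float(self.mismatch))
        for i in range(4):
            m[i, i] = float(self.match)
        m[_CODE[_SENTINEL], :] = NEG / 1000
        m[:, _CODE[_SENTINEL]] = NEG / 1000
        return m


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to integer codes (U folded onto T)."""
    if not seq:
        raise ValueError("empty sequence")
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-IUPAC nucleotide symbol: {exc.args[0]!r}") from exc


@dataclass
class AlignmentResult:
    """One optimal free-end-gap alignment.

    ``ops`` runs from alignment start to end; each element is
    ``("M", i, j)`` for query position i aligned to target position j,
    ``("D", 0, j)`` for target position j inside an internal query gap,
    or ``("I", i, 0)`` for query position i inside an internal target
    gap (positions 1-based).  Free end gaps are not part of the trace.
    """

    score: int
    query_interval: tuple[int, int] | None
    target_interval: tuple[int, int] | None
    ops: list[tuple[str, int, int]] = field(default_factory=list)


def score_from_trace(query: str, target: str, ops: list[tuple[str, int, int]],
                     scheme: ScoringScheme) -> int:
    """Recompute an alignment's score from its trace (oracle for hits)."""
    q = encode(query)
    t = encode(target)
    sub = scheme.matrix()
    total = 0.0
    run: str | None = None
    for op, i, j in ops:
        if op == "M":
            total += sub[q[i - 1], t[j - 1]]
            run = None
        else:
            if op != run:
                total += scheme.gap_open
                run = op
            total += scheme.gap_extend
    return int(round(total))


def _dp_rows(q: np.ndarray, t: np.ndarray, sub: np.ndarray,
             scheme: ScoringScheme, keep: bool):
    """Row-wise Gotoh DP; returns final score and (optionally) matrices."""
    n, m = len(q), len(t)
    o, e = float(scheme.gap_open), float(scheme.gap_extend)
    H_prev = np.zeros(m + 1)
    M_prev = np.full(m + 1, NEG)
    Ix_prev = np.full(m + 1, NEG)
    Iy_prev = np.full(m + 1, NEG)
    js = np.arange(m + 1) * e
    if keep:
        Ms = np.full((n + 1, m + 1), NEG)
        Ixs = np.full((n + 1, m + 1), NEG)
        Iys = np.full((n + 1, m + 1), NEG)
    best = 0.0
    last_row = None
    for i in range(1, n + 1):
        M = np.full(m + 1, NEG)
        M[1:] = sub[q[i - 1], t] + H_prev[:-1]
        Iy = np.full(m + 1, NEG)
        Iy[1:] = np.maximum(np.maximum(M_prev[1:] + o, Ix_prev[1:] + o),
                            Iy_prev[1:]) + e
        # Ix[j] = max(max(M, Iy)[j-1] + o, Ix[j-1]) + e  via prefix max
        opened = np.maximum(M, Iy) + o + e
        w = np.full(m + 1, NEG)
        w[1:] = opened[:-1] - js[1:]
        Ix = np.maximum.accumulate(w) + js
        Ix[0] = NEG
        H = np.maximum(np.maximum(M, Ix), Iy)
        H[0] = 0.0
        if keep:
            Ms[i], Ixs[i], Iys[i] = M, Ix, Iy
        best = max(best, float(H[m]))
        M_prev, Ix_prev, Iy_prev, H_prev = M, Ix, Iy, H
        last_row = H
    if n >= 1:
        best = max(best, float(last_row[1:].max(initial=NEG)))
    if keep:
        return best, Ms, Ixs, Iys
    return best, None, None, None


def _score_kernel_py(q, t, sub, o, e):  # pragma: no cover - numba source
    n, m = q.shape[0], t.shape[0]
    H_prev = np.zeros(m + 1)
    M_prev = np.full(m + 1, NEG)
    Ix_prev = np.full(m + 1, NEG)
    Iy_prev = np.full(m + 1, NEG)
    M = np.full(m + 1, NEG)
    Ix = np.full(m + 1, NEG)
    Iy = np.full(m + 1, NEG)
    H = np.zeros(m + 1)
    best = 0.0
    for i in range(1, n + 1):
        srow = sub[q[i - 1]]
        mj = NEG  # M[j-1]
        ixj = NEG  # Ix[j-1]
        iyj = NEG  # Iy[j-1]
        hj = H_prev[0]  # H_prev[j-1]
        for j in range(1, m + 1):
            mv = srow[t[j - 1]] + hj
            hj = H_prev[j]
            a = M_prev[j] + o
            b = Ix_prev[j] + o
            c = Iy_prev[j]
            iyv = (a if a >= b and a >= c else (b if b >= c else c)) + e
            a = mj + o
            b = iyj + o
            c = ixj
            ixv = (a if a >= b and a >= c else (b if b >= c else c)) + e
            h = mv
            if ixv > h:
                h = ixv
            if iyv > h:
                h = iyv
            M[j] = mv
            Ix[j] = ixv
            Iy[j] = iyv
            H[j] = h
            mj, ixj, iyj = mv, ixv, iyv
        if H[m] > best:
            best = H[m]
        M_prev, M = M, M_prev
        Ix_prev, Ix = Ix, Ix_prev
        Iy_prev, Iy = Iy, Iy_prev
        H_prev, H = H, H_prev
    for j in range(1, m + 1):
        if H_prev[j] > best:
            best = H_prev[j]
    return best


_score_kernel = njit(cache=False)(_score_kernel_py) if njit else _score_kernel_py


def semiglobal_score(query: str, target: str,
                     s: ScoringScheme | None = None) -> int:
    """Optimal free-end-gap alignment score only (fast path)."""
    s = s or ScoringScheme()
    best = _score_kernel(encode(query), encode(target), s.matrix(),
                         float(s.gap_open), float(s.gap_extend))
    return int(round(best))


def semiglobal_align(query: str, target: str,
                     s: ScoringScheme | None = None) -> AlignmentResult:
    """Optimal free-end-gap alignment with one optimal trace.

    Ties break deterministically: the alignment end is the first
    maximal cell scanning the last row (left to right, states M, then
    query-gap, then target-gap) and then the last column; during
    traceback the diagonal is preferred, then the query-gap state, then
    the target-gap state.
    """
    s = s or ScoringScheme()
    q = encode(query)
    t = encode(target)
    n, m = len(q), len(t)
    best, Ms, Ixs, Iys = _dp_rows(q, t, s.matrix(), s, True)
    score = int(round(best))
    if score <= 0:
        # the empty alignment (all residues in free end gaps) scores 0
        return AlignmentResult(score=0, query_interval=None,
                               target_interval=None, ops=[])

    mats = {"M": Ms, "D": Ixs, "I": Iys}
    end = None
    for j in range(1, m + 1):
        for st in ("M", "D", "I"):
            if mats[st][n, j] == best:
                end = (st, n, j)
                break
        if end:
            break
    if end is None:
        for i in range(1, n + 1):
            for st in ("M", "D", "I"):
                if mats[st][i, m] == best:
                    end = (st, i, m)
                    break
            if end:
                break
    o, e = float(s.gap_open), float(s.gap_extend)
    ops: list[tuple[str, int, int]] = []
    st, i, j = end
    while True:
        if st == "M":
            ops.append(("M", i, j))
            i, j = i - 1, j - 1
            if i == 0 or j == 0:
                break
            vals = (Ms[i, j], Ixs[i, j], Iys[i, j])
            st = "MDI"[vals.index(max(vals))]  # first max: M, then D, then I
        elif st == "D":  # gap in query, consumed target j
            ops.append(("D", 0, j))
            cur = Ixs[i, j]
            j -= 1
            if j == 0:
                break
            if cur == Ms[i, j] + o + e:
                st = "M"
            elif cur == Ixs[i, j] + e:
                st = "D"
            else:
                st = "I"
        else:  # gap in target, consumed query i
            ops.append(("I", i, 0))
            cur = Iys[i, j]
            i -= 1
            if i == 0:
                break
            if cur == Ms[i, j] + o + e:
                st = "M"
            elif cur == Ixs[i, j] + o + e:
                st = "D"
            else:
                st = "I"
    ops.reverse()
    pairs = [(i, j) for op, i, j in ops if op == "M"]
    if not pairs:
        return AlignmentResult(score=max(score, 0), query_interval=None,
                               target_interval=None, ops=[])
    qi = (pairs[0][0], pairs[-1][0])
    ti = (pairs[0][1], pairs[-1][1])
    return AlignmentResult(score=score, query_interval=qi,
                           target_interval=ti, ops=ops)


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")
    return seq.translate(comp)[::-1]
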