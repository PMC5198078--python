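"""Iterative scan for tRNA-derived segments (relic candidates) in rRNA.

Each query is aligned to the target with free end gaps, the best hit's
target interval is hard-masked with a sentinel that can never align,
and the scan repeats, producing a per-query list of non-overlapping
hits.  Hits from different queries may still overlap, which is what the
downstream relic merge exploits.  Hit acceptance uses an empirical
permutation null: the query is mononucleotide-shuffled and realigned;
by default hits are kept while the empirical p-value stays at or below
0.01 under 200 shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import (AlignmentResult, ScoringScheme, _SENTINEL,
                    semiglobal_align, semiglobal_score)


@dataclass
class Significance:
    zscore: float | None  # None when the shuffle null has zero variance
    pvalue: float
    n_shuffles: int
    shuffle_mean: float
    shuffle_sd: float


@dataclass
class HomologyHit:
    """A significance-filtered alignment of a query inside the target
    (coordinates 1-based inclusive)."""

    query_id: str
    target_id: str
    start: int
    end: int
    score: int
    zscore: float | None
    pvalue: float
    query_start: int
    query_end: int
    ops: list[tuple[str, int, int]]

    @property
    def target_interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _query_parts(query) -> tuple[str, str]:
    if isinstance(query, (tuple, list)) and len(query) == 2:
        return str(query[0]), str(query[1])
    return str(query.id), str(query.sequence)


def mononucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    letters = list(seq)
    rng.shuffle(letters)
    return "".join(letters)


def score_significance(query: str, target: str, s: ScoringScheme,
                       observed: int, n_shuffles: int = 200,
                       seed: int = 0) -> Significance:
    """Permutation z-score and empirical p for an observed score.

    p = (1 + #{shuffled >= observed}) / (n_shuffles + 1); the z-score is
    flagged undefined (None) when the shuffle scores have zero variance.
    """
    if n_shuffles < 20:
        raise ValueError("need at least 20 shuffles")
    rng = np.random.default_rng(seed)
    scores = np.array([
        semiglobal_score(mononucleotide_shuffle(query, rng), target, s)
        for _ in range(n_shuffles)], dtype=float)
    mean = float(scores.mean())
    sd = float(scores.std(ddof=0))
    z = (observed - mean) / sd if sd > 0 else None
    p = (1 + int((scores >= observed).sum())) / (n_shuffles + 1)
    return Significance(zscore=z, pvalue=p, n_shuffles=n_shuffles,
                        shuffle_mean=mean, shuffle_sd=sd)


def scan_nonoverlapping(query, target: str,
                        s: ScoringScheme | None = None,
                        max_hits: int = 10,
                        target_id: str = "target",
                        p_threshold: float = 0.01,
                        n_shuffles: int = 200,
                        seed: int = 0) -> list[HomologyHit]:
    """Non-overlapping hits of one query in a target, best first.

    Stops when max_hits is reached, the alignment score drops to zero,
    or the permutation p-value exceeds the threshold.  Returned target
    intervals are pairwise disjoint by construction (hard masking).
    """
    s = s or ScoringScheme()
    qid, qseq = _query_parts(query)
    work = list(target)
    hits: list[HomologyHit] = []
    for it in range(max_hits):
        res: AlignmentResult = semiglobal_align(qseq, "".join(work), s)
        if res.score <= 0 or res.target_interval is None:
            break
        sig = score_significance(qseq, "".join(work), s, res.score,
                                 n_shuffles=n_shuffles, seed=seed + it)
        if sig.pvalue > p_threshold:
            break
        start, end = res.target_interval
        hits.append(HomologyHit(
            query_id=qid, target_id=target_id, start=start, end=end,
            score=res.score, zscore=sig.zscore, pvalue=sig.pvalue,
            query_start=res.query_interval[0],
            query_end=res.query_interval[1], ops=res.ops))
        for pos in range(start - 1, end):
            work[pos] = _SENTINEL
    return sorted(hits, key=lambda h: (-h.score, h.start))


def scan_queries(queries, target: str, s: ScoringScheme | None = None,
                 max_hits: int = 10, target_id: str = "target",
                 p_threshold: float = 0.01, n_shuffles: int = 200,
                 seed: int = 0) -> list[HomologyHit]:
    """Scan every query independently against the same (unmasked) target."""
    out: list[HomologyHit] = []
    for k, query in enumerate(queries):
        out.extend(scan_nonoverlapping(
            query, target, s, max_hits=max_hits, target_id=target_id,
            p_threshold=p_threshold, n_shuffles=n_shuffles,
            seed=seed + 1000 * (k + 1)))
    return out
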