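"""Relic assembly and rRNA helix-age projection.

Overlapping tRNA-to-rRNA homology hits (from any query) are merged into
*relics* — connected components of the interval-overlap graph.  Each
relic is projected onto the rRNA helix-age map and annotated with the
minimum nd among the helices it spans: relics sitting in old ribosomal
real estate (the SSU ratchet at nd 0-0.04, the hinges at 0.09-0.26, the
PTC at 0.28-0.30) mark tRNA building blocks recruited early in
ribosomal accretion.  Pairing each relic's age with the age of the tRNA
that produced the hit gives the tRNA/rRNA coevolution table and its
rank correlation.

All coordinates here are 1-based inclusive; BED interchange converts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scan import HomologyHit

#: Named old-region age bands (nd ranges) of the ribosomal accretion map.
DEFAULT_AGE_BANDS: dict[str, tuple[float, float]] = {
    "ratchet": (0.00, 0.04),
    "hinges": (0.09, 0.26),
    "ptc": (0.28, 0.30),
}

#: Relics at or below this nd sit in old ribosomal segments (the upper
#: bound of the PTC band).
DEFAULT_OLD_CUTOFF = 0.30


@dataclass
class HelixMap:
    """Helix intervals of an rRNA with their relative ages (nd)."""

    target_id: str
    intervals: list[tuple[int, int, str, float]]  # start, end, id, nd

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals)
        for start, end, hid, nd in ivs:
            if start > end or start < 1:
                raise ValueError(f"bad helix interval {hid}: [{start}, {end}]")
            if not 0.0 <= nd <= 1.0:
                raise ValueError(f"helix {hid} nd outside [0, 1]: {nd}")
        for (s1, e1, h1, _), (s2, e2, h2, _) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"helices {h1} and {h2} overlap")
        self.intervals = ivs

    @property
    def length_covered(self) -> int:
        return sum(e - s + 1 for s, e, _, _ in self.intervals)

    def tiles(self, target_length: int) -> bool:
        """True when the helices cover 1..target_length without holes."""
        pos = 1
        for s, e, _, _ in self.intervals:
            if s != pos:
                return False
            pos = e + 1
        return pos == target_length + 1

    def overlapping(self, start: int, end: int) -> list[tuple[int, int, str, float]]:
        return [(s, e, h, nd) for s, e, h, nd in self.intervals
                if s <= end and start <= e]


@dataclass
class Relic:
    """Union of mutually overlapping homology hits on one rRNA."""

    start: int
    end: int
    member_hits: list[HomologyHit]
    oldest_nd: float | None = None
    projection: list[tuple[str, float]] = field(default_factory=list)

    @property
    def target_interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def member_query_ids(self) -> list[str]:
        return [h.query_id for h in self.member_hits]


def build_relics(hits: list[HomologyHit], min_overlap: int = 1) -> list[Relic]:
    """Merge hits (across queries) into relics by strict interval overlap.

    Two hits belong to the same relic when their intervals share at
    least ``min_overlap`` positions, directly or through a chain of
    overlapping members; abutting intervals do not merge.  Relics are
    returned sorted by start, each spanning the union of its members.
    """
    if not hits:
        return []
    targets = {h.target_id for h in hits}
    if len(targets) > 1:
        raise ValueError(f"hits span multiple targets: {sorted(targets)}")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    ordered = sorted(hits, key=lambda h: (h.start, h.end))
    relics: list[Relic] = []
    cur = [ordered[0]]
    cur_end = ordered[0].end
    for h in ordered[1:]:
        if min(cur_end, h.end) - h.start + 1 >= min_overlap:
            cur.append(h)
            cur_end = max(cur_end, h.end)
        else:
            relics.append(Relic(start=min(x.start for x in cur), end=cur_end,
                                member_hits=cur))
            cur = [h]
            cur_end = h.end
    relics.append(Relic(start=min(x.start for x in cur), end=cur_end,
                        member_hits=cur))
    return relics


def project_oldest_helix(relic: Relic, hmap: HelixMap) -> Relic:
    """Annotate a relic with every helix it intersects and the minimum nd.

    Helices partially overlapping the relic count fully (no pro-rating).
    A relic reaching outside the map's coverage is a gap error.
    """
    spans = hmap.overlapping(relic.start, relic.end)
    covered = 0
    for s, e, _, _ in spans:
        covered += min(e, relic.end) - max(s, relic.start) + 1
    if covered != relic.end - relic.start + 1:
        raise ValueError(
            f"relic [{relic.start}, {relic.end}] falls in a gap of the "
            f"helix map for {hmap.target_id!r}")
    relic.projection = [(h, nd) for _, _, h, nd in spans]
    relic.oldest_nd = min(nd for _, nd in relic.projection)
    return relic


def _metadata(queries) -> dict[str, tuple[str, int, float]]:
    meta = {}
    for q in queries:
        meta[str(q.id)] = (str(q.isoacceptor), int(q.group), float(q.nd_trna))
    return meta


def coevolution_table(relics: list[Relic], queries,
                      old_cutoff: float = DEFAULT_OLD_CUTOFF,
                      level: str = "hit") -> pd.DataFrame:
    """Pair tRNA ages with the age of the rRNA segment holding each hit.

    ``level='hit'`` emits one row per (hit, relic) membership;
    ``level='relic'`` one row per (relic, distinct query).  Rows are
    flagged ``old_segment`` when the relic's oldest helix nd is at or
    below the cutoff.  Every member hit's query must carry metadata.
    """
    if level not in ("hit", "relic"):
        raise ValueError(f"unknown level: {level!r}")
    meta = _metadata(queries)
    rows = []
    for k, r in enumerate(relics):
        if r.oldest_nd is None:
            raise ValueError("relics must be projected before tabulation")
        members = r.member_hits
        if level == "relic":
            seen, uniq = set(), []
            for h in members:
                if h.query_id not in seen:
                    seen.add(h.query_id)
                    uniq.append(h)
            members = uniq
        for h in members:
            if h.query_id not in meta:
                raise KeyError(f"no metadata for query {h.query_id!r}")
            iso, group, nd_trna = meta[h.query_id]
            rows.append({
                "relic": k, "query_id": h.query_id, "isoacceptor": iso,
                "group": group, "nd_trna": nd_trna,
                "oldest_nd": r.oldest_nd,
                "old_segment": r.oldest_nd <= old_cutoff,
                "hit_start": h.start, "hit_end": h.end, "score": h.score,
            })
    cols = ["relic", "query_id", "isoacceptor", "group", "nd_trna",
            "oldest_nd", "old_segment", "hit_start", "hit_end", "score"]
    return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float | None
    pvalue: float | None
    n: int
    note: str = ""


def coevolution_correlation(table: pd.DataFrame, restrict_old: bool = False,
                            n_permutations: int = 999,
                            seed: int = 0) -> CorrelationResult:
    """Spearman correlation between tRNA age and relic-segment age.

    The p-value is a two-sided label permutation test (>= 999 shuffles
    of the relic-age column).  A constant column makes the correlation
    undefined; that is reported explicitly, never as a silent NaN.
    """
    if n_permutations < 999:
        raise ValueError("need at least 999 permutations")
    sub = table[table["old_segment"]] if restrict_old else table
    if len(sub) < 3:
        raise ValueError("need at least 3 rows for a correlation")
    x = sub["nd_trna"].to_numpy(dtype=float)
    y = sub["oldest_nd"].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(rho=None, pvalue=None, n=len(sub),
                                 note="undefined: constant ranks")
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = float(stats.spearmanr(x, rng.permutation(y)).statistic)
        if abs(perm) >= abs(rho):
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return CorrelationResult(rho=rho, pvalue=p, n=len(sub))


def band_of(nd: float, bands: dict[str, tuple[float, float]] | None = None,
            old_cutoff: float = DEFAULT_OLD_CUTOFF) -> str:
    """Name of the age band containing nd ('old' / 'young' outside them)."""
    bands = DEFAULT_AGE_BANDS if bands is None else bands
    for name, (lo, hi) in bands.items():
        if lo <= nd <= hi:
            return name
    return "old" if nd <= old_cutoff else "young"


def isoacceptor_census(relics: list[Relic], queries,
                       bands: dict[str, tuple[float, float]] | None = None,
                       old_cutoff: float = DEFAULT_OLD_CUTOFF) -> pd.DataFrame:
    """Hit counts per isoacceptor, aminoacylation group, and age band.

    One count per member hit of every relic; the band is the named nd
    band containing the relic's oldest helix age.
    """
    meta = _metadata(queries)
    rows = []
    for r in relics:
        for h in r.member_hits:
            if h.query_id not in meta:
                raise KeyError(f"no metadata for query {h.query_id!r}")
            iso, group, _ = meta[h.query_id]
            band = (band_of(r.oldest_nd, bands, old_cutoff)
                    if r.oldest_nd is not None else "unprojected")
            rows.append({"isoacceptor": iso, "group": group, "band": band})
    if not rows:
        return pd.DataFrame(columns=["isoacceptor", "group", "band", "n_hits"])
    df = pd.DataFrame(rows)
    out = (df.groupby(["isoacceptor", "group", "band"], as_index=False)
             .size().rename(columns={"size": "n_hits"}))
    return out.sort_values(["isoacceptor", "group", "band"],
                           ignore_index=True)
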