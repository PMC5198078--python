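"""Synthetic study inputs with recorded ground truth.

The real censuses behind trees of parts (domain abundances across
hundreds of proteomes) and the curated rRNA/tRNA sequence sets are not
bundled, so every pipeline input can be generated here with a known
truth record: abundance matrices whose rows carry a recoverable
accretion signal (older parts more abundant and more widespread),
rRNA-like sequences with mutated tRNA copies planted at recorded
coordinates, helix-age maps placing old ages over planted positions,
and tRNA metadata.  All generators are deterministic given their seed.

What is emulated is the *polarizable signal*, not the statistical fine
structure of real data: background base composition is uniform,
insertions replace background (coordinates stay exact), and no
secondary structure or tree-based sequence evolution is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import AbundanceMatrix
from .projection import DEFAULT_AGE_BANDS, HelixMap

_AMINO_ACIDS = ["Leu", "Ser", "Val", "Pro", "Ala", "Met", "Ile", "Phe",
                "Lys", "Tyr", "Thr", "Gly", "Glu", "Asp", "Arg", "Gln",
                "Asn", "His", "Cys", "Trp"]


@dataclass(frozen=True)
class AccretionTruth:
    """Ground-truth accretion order behind a simulated census.

    ``taxon_order[0]`` is the oldest part; ``birth_time`` maps each part
    to 1 - (intended nd), so it decreases strictly with rank.
    """

    taxon_order: tuple[str, ...]
    birth_time: dict[str, float]

    def __post_init__(self) -> None:
        bt = [self.birth_time[t] for t in self.taxon_order]
        if any(not 0.0 <= b <= 1.0 for b in bt):
            raise ValueError("birth times must lie in [0, 1]")
        if any(b1 <= b2 for b1, b2 in zip(bt, bt[1:])):
            raise ValueError("birth_time must strictly decrease with rank")

    def rank_of(self, taxon: str) -> int:
        return self.taxon_order.index(taxon)


@dataclass(frozen=True)
class PlantedRelicTruth:
    """Where a mutated tRNA copy was planted (1-based inclusive)."""

    query_id: str
    start: int
    end: int
    divergence: float


@dataclass(frozen=True)
class TRNAQuery:
    """A tRNA sequence with the metadata the coevolution analysis needs:
    isoacceptor (amino-acid label), aminoacylation group (1 and 2 hold
    the old editing specificities, 3 the young ones) and relative age."""

    id: str
    sequence: str
    isoacceptor: str
    group: int
    nd_trna: float

    def __post_init__(self) -> None:
        if self.group not in (1, 2, 3):
            raise ValueError("group must be 1, 2 or 3")
        if not 0.0 <= self.nd_trna <= 1.0:
            raise ValueError("nd_trna must lie in [0, 1]")
        if not self.sequence:
            raise ValueError("empty tRNA sequence")


# ---------------------------------------------------------------------------
# abundance census


def simulate_abundance_matrix(n_parts: int, n_proteomes: int,
                              growth_rate: float, loss_prob: float,
                              noise_sd: float, seed: int,
                              base_count: int = 100,
                              ) -> tuple[AbundanceMatrix, AccretionTruth]:
    """Census with a planted accretion order.

    A part of rank r (rank 0 = oldest) gets intended nd = r/(n_parts-1)
    and birth_time = 1 - nd.  Its expected abundance per proteome is
    base_count * exp(growth_rate * birth_time) — parts that have been
    around longer accumulated more copies — multiplied by lognormal
    noise (sd of the underlying normal = noise_sd) and zeroed
    independently per proteome with probability loss_prob * nd, so
    younger parts are both rarer and less widespread.  A row that would
    be lost everywhere keeps its first-proteome count (census rows are
    parts that exist somewhere).
    """
    if n_parts < 4:
        raise ValueError("need at least 4 parts")
    if n_proteomes < 1:
        raise ValueError("need at least 1 proteome")
    if not 0.0 <= loss_prob <= 1.0:
        raise ValueError("loss_prob must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    width = len(str(n_parts - 1))
    parts = [f"P{r:0{width}d}" for r in range(n_parts)]
    proteomes = [f"G{c}" for c in range(n_proteomes)]
    nd = np.arange(n_parts) / (n_parts - 1)
    birth = 1.0 - nd
    expected = base_count * np.exp(growth_rate * birth)
    noise = (np.exp(rng.normal(0.0, noise_sd, size=(n_parts, n_proteomes)))
             if noise_sd > 0 else np.ones((n_parts, n_proteomes)))
    counts = np.floor(expected[:, None] * noise + 0.5).astype(np.int64)
    np.maximum(counts, 1, out=counts)  # a part present in a proteome has >= 1 copy
    if loss_prob > 0:
        lost = rng.random((n_parts, n_proteomes)) < (loss_prob * nd)[:, None]
        kept = counts.copy()
        counts[lost] = 0
        dead = counts.sum(axis=1) == 0
        counts[dead, 0] = kept[dead, 0]
    truth = AccretionTruth(taxon_order=tuple(parts),
                           birth_time=dict(zip(parts, birth)))
    return AbundanceMatrix(part_ids=parts, proteome_ids=proteomes,
                           counts=counts), truth


# ---------------------------------------------------------------------------
# tRNA queries


def simulate_trna_queries(n: int, seed: int,
                          length_range: tuple[int, int] = (70, 95),
                          specs: list[dict] | None = None,
                          ) -> list[TRNAQuery]:
    """Random tRNA-like queries with metadata.

    ``specs`` may fix per-query isoacceptor / group / nd_trna (missing
    fields are filled); by default isoacceptors cycle through the amino
    acids, groups cycle 1, 2, 3 and nd_trna spreads evenly over [0, 1].
    Sequences are uniform-random nucleotides (cloverleaf folding is not
    simulated) in the given length range, written in the T alphabet.
    """
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError("bad length range")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        spec = dict(specs[i]) if specs else {}
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        iso = spec.get("isoacceptor", _AMINO_ACIDS[i % len(_AMINO_ACIDS)])
        group = spec.get("group", i % 3 + 1)
        nd = spec.get("nd_trna", i / max(n - 1, 1))
        out.append(TRNAQuery(id=spec.get("id", f"tRNA-{iso}-{i}"),
                             sequence=spec.get("sequence", seq),
                             isoacceptor=iso, group=group, nd_trna=nd))
    return out


# ---------------------------------------------------------------------------
# rRNA with planted relics


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    if divergence == 0:
        return seq
    bases = "ACGT"
    out = list(seq)
    hit = rng.random(len(seq)) < divergence
    for k in np.flatnonzero(hit):
        choices = [b for b in bases if b != out[k]]
        out[k] = choices[int(rng.integers(3))]
    return "".join(out)


def simulate_rrna_with_relics(queries: list[TRNAQuery], target_length: int,
                              n_insertions_per_query: int, divergence: float,
                              seed: int,
                              ) -> tuple[str, list[PlantedRelicTruth]]:
    """Random-background rRNA-like sequence with planted tRNA copies.

    Each query is copied ``n_insertions_per_query`` times, point-mutated
    at the stated per-position divergence, and written over the uniform
    ACGT background at non-overlapping recorded positions (insertions
    replace background, so truth coordinates are exact).  Queries given
    in the U alphabet are planted in their T rendering.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    if n_insertions_per_query < 0:
        raise ValueError("n_insertions_per_query must be >= 0")
    inserts = [q for q in queries for _ in range(n_insertions_per_query)]
    total = sum(len(q.sequence) for q in inserts)
    if total >= target_length:
        raise ValueError(
            f"insufficient room: {total} nt of insertions in a "
            f"{target_length} nt target")
    rng = np.random.default_rng(seed)
    background = rng.choice(list("ACGT"), size=target_length)
    order = rng.permutation(len(inserts))
    free = target_length - total
    gaps = rng.multinomial(free, np.full(len(inserts) + 1,
                                         1.0 / (len(inserts) + 1)))
    seq = background.copy()
    truths: list[PlantedRelicTruth] = []
    pos = 0
    for slot, idx in enumerate(order):
        q = inserts[idx]
        pos += int(gaps[slot])
        copy = _mutate(q.sequence.upper().replace("U", "T"), divergence, rng)
        seq[pos:pos + len(copy)] = list(copy)
        truths.append(PlantedRelicTruth(query_id=q.id, start=pos + 1,
                                        end=pos + len(copy),
                                        divergence=divergence))
        pos += len(copy)
    truths.sort(key=lambda t: t.start)
    return "".join(seq), truths


# ---------------------------------------------------------------------------
# helix-age map


def simulate_helix_map(target_length: int,
                       relic_truths: list[PlantedRelicTruth],
                       old_fraction: float, seed: int,
                       bands: dict[str, tuple[float, float]] | None = None,
                       young_range: tuple[float, float] = (0.3, 1.0),
                       helix_length: int = 50,
                       target_id: str = "rRNA",
                       ) -> HelixMap:
    """Contiguous helix tiling of the target with planted old ages.

    The target is cut at planted-relic boundaries; a fraction
    ``old_fraction`` of the relic blocks receives nd drawn from the
    named old bands (ratchet / hinges / PTC by default), everything else
    from Uniform(young_range).  Non-relic stretches are tiled into
    helices of about ``helix_length`` nt.  Every position of the target
    belongs to exactly one helix.
    """
    if not 0.0 <= old_fraction <= 1.0:
        raise ValueError("old_fraction must lie in [0, 1]")
    bands = DEFAULT_AGE_BANDS if bands is None else bands
    rng = np.random.default_rng(seed)
    blocks = _merged_blocks(relic_truths, target_length)
    n_old = int(round(old_fraction * len(blocks)))
    old_idx = set(rng.choice(len(blocks), size=n_old, replace=False)
                  ) if blocks else set()
    band_list = list(bands.values())
    intervals: list[tuple[int, int, str, float]] = []
    pos = 1
    hid = 0

    def young() -> float:
        return float(rng.uniform(*young_range))

    def add(start: int, end: int, nd: float) -> None:
        nonlocal hid
        hid += 1
        intervals.append((start, end, f"H{hid:03d}", nd))

    for k, (bs, be) in enumerate(blocks):
        while pos < bs:  # tile the gap before this relic block
            end = min(bs - 1, pos + helix_length - 1)
            add(pos, end, young())
            pos = end + 1
        if k in old_idx:
            lo, hi = band_list[int(rng.integers(len(band_list)))]
            nd = float(rng.uniform(lo, hi))
        else:
            nd = young()
        add(bs, be, nd)
        pos = be + 1
    while pos <= target_length:
        end = min(target_length, pos + helix_length - 1)
        add(pos, end, young())
        pos = end + 1
    hmap = HelixMap(target_id=target_id, intervals=intervals)
    if not hmap.tiles(target_length):
        raise ValueError("helix intervals do not tile the target")
    return hmap


def _merged_blocks(truths: list[PlantedRelicTruth],
                   target_length: int) -> list[tuple[int, int]]:
    ivs = sorted((t.start, t.end) for t in truths)
    for s, e in ivs:
        if s < 1 or e > target_length or s > e:
            raise ValueError(f"planted interval [{s}, {e}] outside target")
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged
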