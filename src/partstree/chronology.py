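"""Node-distance chronologies and the molecular clock of folds.

A rooted, comb-like tree of parts is converted into a relative
chronology by counting bifurcations from the root toward the leaves.
Each taxon's *node distance* (nd) is its bifurcation rank rescaled to
[0, 1], where nd = 0 is the most basal (oldest) taxon and nd = 1 the
most recent.  Because nd correlates with geological time for parts tied
to the rock record, a linear clock converts nd into age in billions of
years (Gy): by default the scale is anchored at 3.8 Gy (nd = 0) and
reaches 0 Gy (nd = 1), so age = 3.8 x (1 - nd).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import RootedTree


@dataclass(frozen=True)
class ClockModel:
    """Linear molecular clock: age_gy = origin_gy * (1 - nd)."""

    origin_gy: float = 3.8

    def __post_init__(self) -> None:
        if self.origin_gy <= 0:
            raise ValueError("origin_gy must be positive")

    def age(self, nd: float) -> float:
        return self.origin_gy * (1.0 - nd)


@dataclass
class Chronology:
    """Per-taxon node distances and (optionally) clock ages.

    ``table`` columns: taxon, rank, nd, age_gy, transferred_from.
    """

    table: pd.DataFrame
    clock: ClockModel | None = None

    COLUMNS = ["taxon", "rank", "nd", "age_gy", "transferred_from"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"chronology table missing columns: {missing}")
        nd = self.table["nd"].to_numpy(dtype=float)
        if np.any((nd < 0) | (nd > 1)):
            raise ValueError("nd must lie in [0, 1]")

    def nd_of(self, taxon: str) -> float:
        rows = self.table[self.table["taxon"] == taxon]
        if rows.empty:
            raise KeyError(f"unknown taxon: {taxon!r}")
        return float(rows["nd"].iloc[0])

    def age_of(self, taxon: str) -> float:
        rows = self.table[self.table["taxon"] == taxon]
        if rows.empty:
            raise KeyError(f"unknown taxon: {taxon!r}")
        return float(rows["age_gy"].iloc[0])


def render_age(age_gy: float) -> str:
    """One-decimal Gy rendering used in reports (e.g. 3.724 -> '3.7')."""
    return f"{age_gy:.1f}"


def node_distances(tree: RootedTree) -> Chronology:
    """Backward-count bifurcations from leaves to the root.

    A taxon's rank is the number of non-root internal nodes on its
    root-to-leaf path (the root itself is rank 0); nd = rank/max_rank.
    When every taxon sits at the same rank, all nd are 0.
    """
    if tree.n_taxa < 2:
        raise ValueError("chronology needs at least 2 taxa")
    parent = tree.parent_map()
    leaves = [n for n in parent if n not in tree.children
              or not tree.children[n]]
    ranks = {}
    for leaf in leaves:
        rank, node = 0, parent[leaf]
        while node != tree.root:
            rank += 1
            node = parent[node]
        ranks[tree.taxa[leaf]] = rank
    max_rank = max(ranks.values())
    rows = [{"taxon": t, "rank": r,
             "nd": r / max_rank if max_rank > 0 else 0.0,
             "age_gy": np.nan, "transferred_from": None}
            for t, r in sorted(ranks.items(), key=lambda kv: (kv[1], kv[0]))]
    return Chronology(table=pd.DataFrame(rows, columns=Chronology.COLUMNS))


def clock_ages(chron: Chronology, clock: ClockModel | None = None) -> Chronology:
    """Attach linear-clock ages in Gy to a node-distance chronology."""
    clock = clock or ClockModel()
    table = chron.table.copy()
    table["age_gy"] = [clock.age(nd) for nd in table["nd"]]
    return Chronology(table=table, clock=clock)


def transfer_age(chron: Chronology, source_id: str,
                 interactor_id: str) -> Chronology:
    """Give an interacting molecule the age of its partner.

    The age of an RNA molecule is taken to be the age of its
    protein-RNA interaction, so the interactor receives the source's nd
    and age verbatim, flagged as transferred.  Transferring a second
    time from a source of a different age is an error, never a silent
    average; repeating the same transfer is a no-op.
    """
    src = chron.table[chron.table["taxon"] == source_id]
    if src.empty:
        raise KeyError(f"unknown source taxon: {source_id!r}")
    src = src.iloc[0]
    existing = chron.table[chron.table["taxon"] == interactor_id]
    if not existing.empty:
        prev = existing.iloc[0]
        if prev["nd"] == src["nd"] and prev["transferred_from"] == source_id:
            return chron
        raise ValueError(
            f"conflicting age transfer to {interactor_id!r}: already has "
            f"nd={prev['nd']} (from {prev['transferred_from']}), refusing "
            f"to overwrite with nd={src['nd']} from {source_id!r}")
    row = {"taxon": interactor_id, "rank": src["rank"], "nd": src["nd"],
           "age_gy": src["age_gy"], "transferred_from": source_id}
    table = pd.concat([chron.table, pd.DataFrame([row])], ignore_index=True)
    return Chronology(table=table, clock=chron.clock)


def summarize_chronologies(chrons: list[Chronology]) -> pd.DataFrame:
    """Per-taxon nd mean and range across equally parsimonious trees."""
    if not chrons:
        raise ValueError("no chronologies to summarize")
    frames = [c.table[["taxon", "nd"]] for c in chrons]
    cat = pd.concat(frames)
    out = cat.groupby("taxon")["nd"].agg(nd_mean="mean", nd_min="min",
                                         nd_max="max").reset_index()
    out["n_trees"] = len(chrons)
    return out
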