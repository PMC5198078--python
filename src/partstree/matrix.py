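"""Containers for parts-by-proteomes census matrices.

A census matrix counts how many times each molecular part (a protein
structural domain, an RNA substructure, ...) occurs in each proteome.
Rows are the taxa of a "tree of parts"; columns are the phylogenetic
characters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _check_ids(ids: list[str], what: str) -> None:
    if len(ids) != len(set(ids)):
        raise ValueError(f"duplicate {what} ids")
    if any(not i for i in ids):
        raise ValueError(f"empty {what} id")


@dataclass
class AbundanceMatrix:
    """Non-negative integer counts of parts (rows) across proteomes (columns).

    Parameters
    ----------
    part_ids : row labels, the taxa of the tree of parts.
    proteome_ids : column labels, the phylogenetic characters.
    counts : integer array of shape (n_parts, n_proteomes), all >= 0,
        with at least one non-zero cell per part.
    """

    part_ids: list[str]
    proteome_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        if self.counts.shape != (len(self.part_ids), len(self.proteome_ids)):
            raise ValueError("counts shape does not match id lists")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("negative counts are not allowed")
        if np.any(self.counts.sum(axis=1) == 0):
            raise ValueError("every part needs at least one non-zero cell")
        _check_ids(self.part_ids, "part")
        _check_ids(self.proteome_ids, "proteome")

    @property
    def n_parts(self) -> int:
        return len(self.part_ids)

    @property
    def n_proteomes(self) -> int:
        return len(self.proteome_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.part_ids,
                            columns=self.proteome_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceMatrix":
        return cls(part_ids=[str(i) for i in df.index],
                   proteome_ids=[str(c) for c in df.columns],
                   counts=df.to_numpy())


@dataclass
class CodedMatrix:
    """Linearly ordered multistate characters derived from abundance.

    States run 0..alphabet_size-1 and are rendered alphanumerically
    (0-9 then A, B, ...) for interchange with parsimony software.
    """

    part_ids: list[str]
    proteome_ids: list[str]
    states: np.ndarray = field(repr=False)
    alphabet_size: int = 24

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.shape != (len(self.part_ids), len(self.proteome_ids)):
            raise ValueError("states shape does not match id lists")
        if not 2 <= self.alphabet_size <= 36:
            raise ValueError("alphabet_size must be in [2, 36]")
        if np.any(self.states < 0) or np.any(self.states > self.alphabet_size - 1):
            raise ValueError("states out of 0..alphabet_size-1 range")
        _check_ids(self.part_ids, "part")
        _check_ids(self.proteome_ids, "proteome")

    @property
    def n_parts(self) -> int:
        return len(self.part_ids)

    @property
    def n_characters(self) -> int:
        return len(self.proteome_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.states, index=self.part_ids,
                            columns=self.proteome_ids)
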