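"""Encoding abundance censuses into ordered multistate characters.

Raw occurrence counts span several orders of magnitude, so they are
rescaled column-wise (per proteome) into a small linearly ordered state
alphabet before parsimony analysis.  The default is a logarithmic
transform into 24 states, rendered alphanumerically as 0-9 then A-N; a
linear transform and full coarse-graining to presence/absence are also
provided.
"""

from __future__ import annotations

import numpy as np

from .matrix import AbundanceMatrix, CodedMatrix

_ALPHANUM = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round is banker's rounding; the coding contract is half-up
    return np.floor(x + 0.5).astype(np.int64)


def code_abundance(m: AbundanceMatrix, alphabet_size: int = 24,
                   scheme: str = "log") -> CodedMatrix:
    """Rescale each proteome column into states 0..alphabet_size-1.

    ``log``: state = round((S-1) * ln(a+1) / ln(a_max+1)), clamped to at
    least 1 for non-zero counts so that presence/absence survives the
    transform (occurrence is a quotient of the log coding); ``linear``:
    state = round((S-1) * a / a_max).  Zero abundance always codes to
    state 0, the per-column maximum to S-1, and coding is monotone in
    abundance within a column.  A column whose maximum is zero codes to
    all zeros.
    """
    if not 2 <= alphabet_size <= 36:
        raise ValueError("alphabet_size must be in [2, 36]")
    if scheme not in ("log", "linear"):
        raise ValueError(f"unknown coding scheme: {scheme!r}")
    a = m.counts.astype(np.float64)
    col_max = a.max(axis=0)
    safe_max = np.where(col_max > 0, col_max, 1.0)
    if scheme == "log":
        frac = np.log1p(a) / np.log1p(safe_max)
    else:
        frac = a / safe_max
    frac = np.where(col_max > 0, frac, 0.0)
    states = _round_half_up((alphabet_size - 1) * frac)
    if scheme == "log":
        states = np.where(m.counts > 0, np.maximum(states, 1), states)
    return CodedMatrix(part_ids=list(m.part_ids),
                       proteome_ids=list(m.proteome_ids),
                       states=states, alphabet_size=alphabet_size)


def coarse_grain_occurrence(m: AbundanceMatrix) -> CodedMatrix:
    """Reduce abundance to presence/absence (a binary 0/1 matrix)."""
    return CodedMatrix(part_ids=list(m.part_ids),
                       proteome_ids=list(m.proteome_ids),
                       states=(m.counts > 0).astype(np.int64),
                       alphabet_size=2)


def render_alphanumeric(c: CodedMatrix) -> list[str]:
    """Render each taxon's states as a string of 0-9 then A-Z symbols."""
    if c.alphabet_size > 36:
        raise ValueError("alphanumeric rendering supports at most 36 states")
    return ["".join(_ALPHANUM[s] for s in row) for row in c.states]


def parse_alphanumeric(rows: list[str], part_ids: list[str],
                       proteome_ids: list[str],
                       alphabet_size: int = 24) -> CodedMatrix:
    """Inverse of :func:`render_alphanumeric`."""
    states = np.array([[_ALPHANUM.index(ch) for ch in row] for row in rows],
                      dtype=np.int64)
    return CodedMatrix(part_ids=part_ids, proteome_ids=proteome_ids,
                       states=states, alphabet_size=alphabet_size)
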