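"""Pairwise global sequence alignment (dynamic programming) and
alignment assessment."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .sequence import Sequence

__all__ = [
    "Alignment",
    "align_global",
    "percent_identity",
    "read_substitution_matrix",
]

GAP = "-"


@dataclass
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float
    path: List[Tuple[Optional[int], Optional[int]]]
    # path entries are (i, j) residue indices; None marks a gap on that side

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")

    def to_fasta(self, header_a: str = "a", header_b: str = "b") -> str:
        return f">{header_a}\n{self.aligned_a}\n>{header_b}\n{self.aligned_b}\n"


def _score_fn(match, mismatch, matrix):
    if matrix is not None:
        def score(x: str, y: str) -> float:
            return matrix[(x, y)]
        return score
    return lambda x, y: match if x == y else mismatch


def align_global(
    a: Union[Sequence, str],
    b: Union[Sequence, str],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
    matrix: Optional[Dict[Tuple[str, str], float]] = None,
) -> Alignment:
    """Needleman-Wunsch global alignment with a linear gap penalty.

    Traceback is deterministic: on score ties, diagonal beats up beats
    left.  ``matrix`` (a symmetric substitution table keyed by letter
    pairs) overrides match/mismatch when given.
    """
    sa = a.letters if isinstance(a, Sequence) else a
    sb = b.letters if isinstance(b, Sequence) else b
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    if gap > 0:
        raise ValueError("gap penalty must be <= 0")
    score = _score_fn(match, mismatch, matrix)
    n, m = len(sa), len(sb)
    S = np.zeros((n + 1, m + 1))
    S[:, 0] = gap * np.arange(n + 1)
    S[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            S[i, j] = max(
                S[i - 1, j - 1] + score(sa[i - 1], sb[j - 1]),
                S[i - 1, j] + gap,
                S[i, j - 1] + gap,
            )
    # traceback with diagonal > up > left priority on ties
    out_a: List[str] = []
    out_b: List[str] = []
    path: List[Tuple[Optional[int], Optional[int]]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and S[i, j] == S[i - 1, j - 1] + score(sa[i - 1], sb[j - 1])
        ):
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            path.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif i > 0 and S[i, j] == S[i - 1, j] + gap:
            out_a.append(sa[i - 1])
            out_b.append(GAP)
            path.append((i - 1, None))
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(sb[j - 1])
            path.append((None, j - 1))
            j -= 1
    return Alignment(
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=float(S[n, m]),
        path=list(reversed(path)),
    )


def percent_identity(al: Alignment) -> float:
    """100 * matches / columns, excluding double-gap columns."""
    columns = 0
    matches = 0
    for x, y in zip(al.aligned_a, al.aligned_b):
        if x == GAP and y == GAP:
            continue
        columns += 1
        if x == y and x != GAP:
            matches += 1
    if columns == 0:
        raise ValueError("empty alignment")
    return 100.0 * matches / columns


def read_substitution_matrix(path: Union[str, Path]) -> Dict[Tuple[str, str], float]:
    """Whitespace table with a header row and a leading letter per row."""
    lines = [
        l for l in Path(path).read_text().splitlines() if l.strip() and not l.startswith("#")
    ]
    header = lines[0].split()
    table: Dict[Tuple[str, str], float] = {}
    for line in lines[1:]:
        toks = line.split()
        row = toks[0]
        for col, val in zip(header, toks[1:]):
            table[(row, col)] = float(val)
    return table
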