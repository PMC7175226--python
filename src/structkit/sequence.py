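"""Sequences, FASTA I/O and sequence profiles."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence as Seq, Union

import numpy as np

from .core_model import Structure, is_polymer_residue, three_to_one

__all__ = [
    "Sequence",
    "SequenceProfile",
    "structure_to_sequences",
    "read_fasta",
    "write_fasta",
    "profile_from_msa",
    "profile_to_tsv",
]

AMINO_ACID_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")
GAP_CHARS = frozenset("-.")


@dataclass
class Sequence:
    header: str
    letters: str

    def __len__(self) -> int:
        return len(self.letters)

    def ungapped(self) -> str:
        return "".join(c for c in self.letters if c not in GAP_CHARS)


def structure_to_sequences(structure: Structure) -> List[Sequence]:
    """One sequence per chain containing polymer residues, in chain order.

    Hetero-only chains (e.g. a lone ligand) are omitted.  The header is
    ``structure_id|chain_id``.  The result depends only on residue
    identity, so a CA-only structure yields the same sequences as its
    all-atom parent.
    """
    out: List[Sequence] = []
    for chain in structure.chains:
        letters = "".join(
            three_to_one(r.res_name) for r in chain.residues if is_polymer_residue(r)
        )
        if letters:
            out.append(Sequence(header=f"{structure.id}|{chain.chain_id}", letters=letters))
    return out


def read_fasta(path: Union[str, Path]) -> List[Sequence]:
    sequences: List[Sequence] = []
    header = None
    body: List[str] = []

    def flush():
        if header is None:
            return
        letters = "".join(body)
        if not letters:
            raise ValueError(f"FASTA record {header!r} has an empty sequence body")
        sequences.append(Sequence(header=header, letters=letters))

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            body = []
        else:
            if header is None:
                raise ValueError("sequence data before the first FASTA header")
            body.append(line)
    flush()
    return sequences


def write_fasta(sequences: Seq[Sequence], path: Union[str, Path], width: int = 80) -> None:
    lines: List[str] = []
    for s in sequences:
        lines.append(f">{s.header}")
        for i in range(0, len(s.letters), width):
            lines.append(s.letters[i : i + width])
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class SequenceProfile:
    """Per-column symbol frequency matrix of an MSA (columns sum to 1)."""

    columns: np.ndarray  # (L, A)
    alphabet: tuple

    def __len__(self) -> int:
        return self.columns.shape[0]


def profile_from_msa(
    sequences: Seq[Sequence],
    pseudocount: float = 0.0,
    alphabet: Seq[str] = AMINO_ACID_ALPHABET,
) -> SequenceProfile:
    """Column frequencies with additive smoothing.

    freq(a) = (count_a + pseudocount) / (n_non_gap + A * pseudocount);
    gaps (and symbols outside the alphabet, e.g. 'X') reduce the
    effective count rather than being alphabet symbols.  An all-gap
    column with zero pseudocount falls back to uniform.
    """
    if not sequences:
        raise ValueError("at least one sequence is required")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    length = len(sequences[0].letters)
    for s in sequences:
        if len(s.letters) != length:
            raise ValueError(
                f"unequal sequence lengths: {s.header!r} has {len(s.letters)}, "
                f"expected {length}"
            )
    alphabet = tuple(alphabet)
    index = {a: i for i, a in enumerate(alphabet)}
    A = len(alphabet)
    columns = np.zeros((length, A), dtype=float)
    for col in range(length):
        counts = np.zeros(A)
        n_non_gap = 0
        for s in sequences:
            ch = s.letters[col].upper()
            if ch not in index:
                continue
            n_non_gap += 1
            counts[index[ch]] += 1
        denom = n_non_gap + A * pseudocount
        if denom <= 0:
            columns[col] = 1.0 / A
        else:
            columns[col] = (counts + pseudocount) / denom
    return SequenceProfile(columns=columns, alphabet=alphabet)


def profile_to_tsv(profile: SequenceProfile) -> str:
    lines = ["\t".join(profile.alphabet)]
    for row in profile.columns:
        lines.append("\t".join(f"{v:.6f}" for v in row))
    return "\n".join(lines) + "\n"
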