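"""In-memory hierarchy for macromolecular structures.

The aggregation mirrors the usual crystallographic decomposition:
``Structure`` holds ordered ``Chain`` objects, each chain an ordered list
of ``Residue`` objects, each residue an ordered list of ``PdbAtom``
records.  Ordering always follows the source file; residue identity
within a chain is the ``(res_seq, i_code)`` pair exactly as numbered in
the file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Tuple

import numpy as np

__all__ = [
    "Vec3",
    "PdbAtom",
    "Residue",
    "Chain",
    "Structure",
    "MonomerInfo",
    "MONOMERS",
    "AROMATIC_RESIDUES",
    "iter_atoms",
    "ca_trace",
    "three_to_one",
    "is_ca_atom",
    "is_polymer_residue",
]


@dataclass
class Vec3:
    """A 3-vector in Ångström with the elementary vector algebra."""

    x: float
    y: float
    z: float

    def __add__(self, other: "Vec3") -> "Vec3":
        return Vec3(self.x + other.x, self.y + other.y, self.z + other.z)

    def __sub__(self, other: "Vec3") -> "Vec3":
        return Vec3(self.x - other.x, self.y - other.y, self.z - other.z)

    def __mul__(self, s: float) -> "Vec3":
        return Vec3(self.x * s, self.y * s, self.z * s)

    __rmul__ = __mul__

    def __neg__(self) -> "Vec3":
        return Vec3(-self.x, -self.y, -self.z)

    def dot(self, other: "Vec3") -> float:
        return self.x * other.x + self.y * other.y + self.z * other.z

    def cross(self, other: "Vec3") -> "Vec3":
        return Vec3(
            self.y * other.z - self.z * other.y,
            self.z * other.x - self.x * other.z,
            self.x * other.y - self.y * other.x,
        )

    def norm(self) -> float:
        return math.sqrt(self.dot(self))

    def __iter__(self) -> Iterator[float]:
        yield self.x
        yield self.y
        yield self.z

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a) -> "Vec3":
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclass
class PdbAtom:
    """One atom record.

    ``name`` keeps the raw 4-character PDB atom-name field (e.g. ``" CA "``)
    so that round trips preserve alignment; use :meth:`stripped_name` for
    comparisons.
    """

    serial: int
    name: str
    pos: Vec3
    alt_loc: str = " "
    element: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def stripped_name(self) -> str:
        return self.name.strip()


@dataclass
class Residue:
    res_name: str
    res_seq: int
    i_code: str = " "
    atoms: List[PdbAtom] = field(default_factory=list)

    def find_atom(self, name: str) -> Optional[PdbAtom]:
        """First atom whose stripped name equals ``name`` (stripped)."""
        want = name.strip()
        for a in self.atoms:
            if a.stripped_name() == want:
                return a
        return None

    @property
    def is_hetero(self) -> bool:
        return bool(self.atoms) and all(a.is_hetero for a in self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class Chain:
    chain_id: str
    residues: List[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)


@dataclass
class Structure:
    id: str = ""
    model_no: int = 1
    chains: List[Chain] = field(default_factory=list)

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)

    def chain(self, chain_id: str) -> Optional[Chain]:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def residues(self) -> Iterator[Tuple[Chain, Residue]]:
        for c in self.chains:
            for r in c.residues:
                yield c, r

    @property
    def atom_count(self) -> int:
        return sum(len(r) for c in self.chains for r in c.residues)


@dataclass(frozen=True)
class MonomerInfo:
    code3: str
    code1: str
    is_aromatic: bool = False
    # ring atoms listed in order around the ring; empty when not aromatic
    ring_atom_names: Tuple[str, ...] = ()


_AA = [
    ("ALA", "A"), ("ARG", "R"), ("ASN", "N"), ("ASP", "D"), ("CYS", "C"),
    ("GLN", "Q"), ("GLU", "E"), ("GLY", "G"), ("ILE", "I"), ("LEU", "L"),
    ("LYS", "K"), ("MET", "M"), ("PRO", "P"), ("SER", "S"), ("THR", "T"),
    ("VAL", "V"),
]

# TRP uses its six-membered benzene ring, HIS its five-membered ring:
# one well-defined plane per residue.
_AROMATIC = {
    "PHE": ("F", ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")),
    "TYR": ("Y", ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")),
    "TRP": ("W", ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")),
    "HIS": ("H", ("CG", "ND1", "CE1", "NE2", "CD2")),
}

MONOMERS = {c3: MonomerInfo(c3, c1) for c3, c1 in _AA}
MONOMERS.update(
    {c3: MonomerInfo(c3, c1, True, ring) for c3, (c1, ring) in _AROMATIC.items()}
)

AROMATIC_RESIDUES = frozenset(_AROMATIC)

_NUCLEOTIDES = frozenset({"DA", "DC", "DG", "DT", "A", "C", "G", "U"})


def three_to_one(code3: str) -> str:
    """Standard IUPAC 3-letter → 1-letter amino-acid code; unknown → ``'X'``."""
    info = MONOMERS.get(code3.strip().upper())
    return info.code1 if info is not None else "X"


def monomer_info(code3: str) -> MonomerInfo:
    """Lookup with fallback: unknown codes keep code3 verbatim, code1 'X'."""
    code3 = code3.strip().upper()
    return MONOMERS.get(code3, MonomerInfo(code3, "X"))


def is_ca_atom(atom: PdbAtom) -> bool:
    """Alpha-carbon test with calcium disambiguation.

    True iff the name strips to ``CA`` and the element field is carbon or
    blank — a calcium ion (element ``CA``) is never an alpha carbon.
    """
    if atom.stripped_name() != "CA":
        return False
    el = atom.element.strip().upper()
    return el in ("C", "")


def is_polymer_residue(residue: Residue) -> bool:
    """Polymer test: known monomer code, or presence of an alpha carbon
    (tolerates modified residues)."""
    code = residue.res_name.strip().upper()
    if code in MONOMERS or code in _NUCLEOTIDES:
        return True
    return any(is_ca_atom(a) for a in residue.atoms)


def iter_atoms(structure: Structure) -> Iterator[Tuple[Chain, Residue, PdbAtom]]:
    """Yield ``(chain, residue, atom)`` triples in file order."""
    for chain in structure.chains:
        for residue in chain.residues:
            for atom in residue.atoms:
                yield chain, residue, atom


def ca_trace(structure: Structure) -> List[Vec3]:
    """One point per residue possessing a true alpha carbon, in order."""
    trace: List[Vec3] = []
    for _, residue in structure.residues():
        for atom in residue.atoms:
            if is_ca_atom(atom):
                trace.append(atom.pos)
                break
    return trace
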