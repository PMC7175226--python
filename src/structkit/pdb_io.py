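"""Fixed-column PDB reading and writing with pluggable line filters.

Filters are predicates over raw 80-column text lines, applied *before*
parsing, so rejected records are never materialized.  Multi-model files
take a fast path: the first model is parsed in full and, as long as the
following models are chemically identical (same atom count and the same
sequence of (name, resName, chainID) tuples), they are built by cloning
the first model's topology and swapping in coordinates, occupancy and
B-factor only.
"""

from __future__ import annotations

import gzip
import warnings
from copy import deepcopy
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, List, Optional, Sequence, Tuple, Union

from .core_model import Chain, PdbAtom, Residue, Structure, Vec3

__all__ = [
    "PdbParseError",
    "NoAtomsError",
    "LineFilter",
    "is_atom_filter",
    "is_hetero_filter",
    "is_ca_filter",
    "atom_name_filter",
    "chain_filter",
    "residue_name_filter",
    "parse_atom_line",
    "read_structures",
    "write_pdb",
    "PdbReader",
]


class PdbParseError(ValueError):
    """Malformed PDB content; message names the column span and line."""


class NoAtomsError(PdbParseError):
    """No atom records survived filtering."""


class LineFilter:
    """A pure predicate over a raw PDB line, composable with ``&``, ``|``, ``~``."""

    def __init__(self, predicate: Callable[[str], bool], name: str = "filter"):
        self._predicate = predicate
        self.name = name

    def __call__(self, line: str) -> bool:
        return bool(self._predicate(line))

    def __and__(self, other: "LineFilter") -> "LineFilter":
        return LineFilter(lambda l: self(l) and other(l), f"({self.name} & {other.name})")

    def __or__(self, other: "LineFilter") -> "LineFilter":
        return LineFilter(lambda l: self(l) or other(l), f"({self.name} | {other.name})")

    def __invert__(self) -> "LineFilter":
        return LineFilter(lambda l: not self(l), f"~{self.name}")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"LineFilter({self.name})"


def _pad(line: str) -> str:
    """Right-pad to 80 columns; common truncated-line dialect."""
    line = line.rstrip("\r\n")
    return line.ljust(80) if len(line) < 80 else line


def is_atom_filter() -> LineFilter:
    return LineFilter(lambda l: l.startswith("ATOM  "), "is_atom")


def is_hetero_filter() -> LineFilter:
    return LineFilter(lambda l: l.startswith("HETATM"), "is_hetero")


def is_ca_filter() -> LineFilter:
    """Accept only ATOM lines whose atom name strips to CA and whose
    element field is not calcium."""

    def pred(line: str) -> bool:
        if not line.startswith("ATOM  "):
            return False
        line = _pad(line)
        if line[12:16].strip() != "CA":
            return False
        return line[76:78].strip().upper() in ("C", "")

    return LineFilter(pred, "is_ca")


def atom_name_filter(*names: str) -> LineFilter:
    want = {n.strip() for n in names}
    return LineFilter(
        lambda l: _pad(l)[12:16].strip() in want, f"atom_name{sorted(want)}"
    )


def chain_filter(*chain_ids: str) -> LineFilter:
    want = set(chain_ids)
    return LineFilter(lambda l: _pad(l)[21] in want, f"chain{sorted(want)}")


def residue_name_filter(*res_names: str) -> LineFilter:
    want = {n.strip().upper() for n in res_names}
    return LineFilter(
        lambda l: _pad(l)[17:20].strip().upper() in want, f"res_name{sorted(want)}"
    )


def _fixed_float(line: str, lo: int, hi: int, lineno: Optional[int], default=None) -> float:
    text = line[lo:hi]
    if not text.strip():
        if default is not None:
            return default
        raise PdbParseError(
            f"blank numeric field in columns {lo + 1}-{hi}"
            + (f" on line {lineno}" if lineno else "")
        )
    try:
        return float(text)
    except ValueError:
        raise PdbParseError(
            f"malformed numeric field {text!r} in columns {lo + 1}-{hi}"
            + (f" on line {lineno}" if lineno else "")
        ) from None


def _fixed_int(line: str, lo: int, hi: int, lineno: Optional[int]) -> int:
    text = line[lo:hi]
    try:
        return int(text)
    except ValueError:
        raise PdbParseError(
            f"malformed integer field {text!r} in columns {lo + 1}-{hi}"
            + (f" on line {lineno}" if lineno else "")
        ) from None


@dataclass(frozen=True)
class AtomRecord:
    """A parsed ATOM/HETATM line: the atom plus its residue/chain identity."""

    atom: PdbAtom
    chain_id: str
    res_name: str
    res_seq: int
    i_code: str


def parse_atom_line(line: str, lineno: Optional[int] = None) -> AtomRecord:
    """Parse one ATOM/HETATM record by wwPDB v3.3 fixed columns."""
    if not (line.startswith("ATOM  ") or line.startswith("HETATM")):
        raise PdbParseError(
            f"not an ATOM/HETATM record" + (f" on line {lineno}" if lineno else "")
        )
    line = _pad(line)
    atom = PdbAtom(
        serial=_fixed_int(line, 6, 11, lineno),
        name=line[12:16],
        alt_loc=line[16],
        pos=Vec3(
            _fixed_float(line, 30, 38, lineno),
            _fixed_float(line, 38, 46, lineno),
            _fixed_float(line, 46, 54, lineno),
        ),
        occupancy=_fixed_float(line, 54, 60, lineno, default=1.0),
        b_factor=_fixed_float(line, 60, 66, lineno, default=0.0),
        element=line[76:78].strip(),
        is_hetero=line.startswith("HETATM"),
    )
    return AtomRecord(
        atom=atom,
        chain_id=line[21],
        res_name=line[17:20].strip(),
        res_seq=_fixed_int(line, 22, 26, lineno),
        i_code=line[26],
    )


def _open_text(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _split_models(lines: Iterable[str]) -> List[List[Tuple[int, str]]]:
    """Group (lineno, line) pairs into MODEL blocks; one block if no MODEL."""
    models: List[List[Tuple[int, str]]] = []
    current: List[Tuple[int, str]] = []
    seen_model = False
    for lineno, raw in enumerate(lines, start=1):
        rec = raw[:6]
        if rec == "MODEL ":
            if seen_model and current:
                models.append(current)
                current = []
            seen_model = True
        elif rec == "ENDMDL":
            models.append(current)
            current = []
        else:
            current.append((lineno, raw))
    if current or not models:
        models.append(current)
    # drop trailing blocks with no atom records (e.g. only END)
    def has_atoms(block):
        return any(l.startswith(("ATOM  ", "HETATM")) for _, l in block)

    kept = [m for m in models if has_atoms(m)]
    return kept if kept else models[:1]


def _accept(line: str, filters: Sequence[LineFilter]) -> bool:
    return all(f(line) for f in filters)


def _build_structure(
    records: List[AtomRecord],
    struct_id: str,
    model_no: int,
    keep_alt_locs: bool,
) -> Structure:
    structure = Structure(id=struct_id, model_no=model_no)
    chains: dict = {}
    for rec in records:
        chain = chains.get(rec.chain_id)
        if chain is None:
            chain = Chain(chain_id=rec.chain_id)
            chains[rec.chain_id] = chain
            structure.chains.append(chain)
        key = (rec.res_seq, rec.i_code)
        if chain.residues and (
            chain.residues[-1].res_seq,
            chain.residues[-1].i_code,
        ) == key:
            residue = chain.residues[-1]
        else:
            residue = next(
                (r for r in chain.residues if (r.res_seq, r.i_code) == key), None
            )
            if residue is None:
                residue = Residue(
                    res_name=rec.res_name, res_seq=rec.res_seq, i_code=rec.i_code
                )
                chain.residues.append(residue)
        if not keep_alt_locs and rec.atom.alt_loc not in (" ", ""):
            # keep only the first-encountered alt-loc per (residue, atom name)
            if any(
                a.stripped_name() == rec.atom.stripped_name() for a in residue.atoms
            ):
                continue
        residue.atoms.append(rec.atom)
    return structure


def _model_records(
    block: List[Tuple[int, str]],
    filters: Sequence[LineFilter],
    keep_hetero: bool,
) -> List[AtomRecord]:
    records = []
    for lineno, raw in block:
        if not raw.startswith(("ATOM  ", "HETATM")):
            continue
        if not keep_hetero and raw.startswith("HETATM"):
            continue
        if not _accept(raw, filters):
            continue
        records.append(parse_atom_line(raw, lineno))
    return records


def _topology_signature(records: List[AtomRecord]) -> List[Tuple[str, str, str]]:
    return [(r.atom.name, r.res_name, r.chain_id) for r in records]


def read_structures(
    path: Union[str, Path],
    filters: Sequence[LineFilter] = (),
    keep_hetero: bool = True,
    keep_alt_locs: bool = False,
    fast_path: bool = True,
) -> List[Structure]:
    """Read a PDB file into one :class:`Structure` per model.

    Parameters
    ----------
    filters:
        Line filters ANDed together; rejected lines are never parsed.
    keep_hetero:
        When False, HETATM records are skipped.
    keep_alt_locs:
        When False (default), only the first alternate location per
        (residue, atom name) is kept.
    fast_path:
        Reuse model-1 topology for chemically identical later models,
        swapping only coordinates, occupancy and B-factor.  Models that
        fail the identity check fall back to a full parse with a warning.
    """
    path = Path(path)
    with _open_text(path) as fh:
        blocks = _split_models(fh)

    struct_id = path.name
    for suffix in (".gz", ".pdb", ".ent"):
        if struct_id.endswith(suffix):
            struct_id = struct_id[: -len(suffix)]

    first_records = _model_records(blocks[0], filters, keep_hetero)
    if not first_records:
        raise NoAtomsError(f"no atoms selected from {path}")
    first = _build_structure(first_records, struct_id, 1, keep_alt_locs)
    structures = [first]
    first_sig = _topology_signature(first_records) if fast_path else None

    for model_no, block in enumerate(blocks[1:], start=2):
        records = _model_records(block, filters, keep_hetero)
        if fast_path and _topology_signature(records) == first_sig:
            clone = deepcopy(first)
            clone.model_no = model_no
            i = 0
            for chain in clone.chains:
                for residue in chain.residues:
                    for atom in residue.atoms:
                        rec = records[i]
                        atom.pos = rec.atom.pos
                        atom.occupancy = rec.atom.occupancy
                        atom.b_factor = rec.atom.b_factor
                        i += 1
            structures.append(clone)
        else:
            if fast_path:
                warnings.warn(
                    f"model {model_no} of {path.name} is not chemically identical "
                    f"to model 1; falling back to a full parse",
                    stacklevel=2,
                )
            structures.append(
                _build_structure(records, struct_id, model_no, keep_alt_locs)
            )
    return structures


class PdbReader:
    """Object-style wrapper around :func:`read_structures`."""

    def __init__(
        self,
        filters: Sequence[LineFilter] = (),
        keep_hetero: bool = True,
        keep_alt_locs: bool = False,
        fast_path: bool = True,
    ):
        self.filters = list(filters)
        self.keep_hetero = keep_hetero
        self.keep_alt_locs = keep_alt_locs
        self.fast_path = fast_path
        self.model_count = 0

    def read(self, path: Union[str, Path]) -> List[Structure]:
        structures = read_structures(
            path,
            filters=self.filters,
            keep_hetero=self.keep_hetero,
            keep_alt_locs=self.keep_alt_locs,
            fast_path=self.fast_path,
        )
        self.model_count = len(structures)
        return structures


def _format_atom_line(
    atom: PdbAtom, res: Residue, chain: Chain
) -> str:
    for v in (atom.pos.x, atom.pos.y, atom.pos.z):
        if abs(v) >= 10000.0:
            raise ValueError(
                f"coordinate {v} exceeds the %8.3f PDB field width"
            )
    record = "HETATM" if atom.is_hetero else "ATOM  "
    name = atom.name if len(atom.name) == 4 else _format_atom_name(atom.name, atom.element)
    return (
        f"{record}{atom.serial % 100000:5d} {name}{atom.alt_loc or ' '}"
        f"{res.res_name:>3s} {chain.chain_id}{res.res_seq:4d}{res.i_code or ' '}   "
        f"{atom.pos.x:8.3f}{atom.pos.y:8.3f}{atom.pos.z:8.3f}"
        f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}          "
        f"{atom.element:>2s}"
    )


def _format_atom_name(name: str, element: str) -> str:
    """PDB alignment: single-letter elements start in column 14."""
    name = name.strip()
    if len(name) >= 4:
        return name[:4]
    if len(element.strip()) == 1 or (not element.strip() and len(name) < 4):
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(
    structures: Union[Structure, Sequence[Structure]],
    path: Union[str, Path],
) -> None:
    """Write fixed-column PDB; multiple structures become MODEL blocks."""
    if isinstance(structures, Structure):
        structures = [structures]
    structures = list(structures)
    if not structures:
        raise ValueError("no structures to write")
    multi = len(structures) > 1
    lines: List[str] = []
    for i, structure in enumerate(structures, start=1):
        if multi:
            lines.append(f"MODEL {i:>8d}")
        for chain in structure.chains:
            for residue in chain.residues:
                for atom in residue.atoms:
                    lines.append(_format_atom_line(atom, residue, chain))
            lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
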