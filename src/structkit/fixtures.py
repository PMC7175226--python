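"""Deterministic synthetic-structure generators with known ground truth.

Everything here is seeded and reproducible: the same spec and seed give
byte-identical output files.  PDB text is emitted by a *local* formatter
(independent of :mod:`structkit.pdb_io`) so the generators double as an
oracle for the reader and writer.  Each file generator can also write a
machine-readable JSON sidecar with the ground truth used by tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence as Seq, Tuple, Union

import numpy as np

from .core_model import Chain, MONOMERS, PdbAtom, Residue, Structure, Vec3, three_to_one

__all__ = [
    "FixtureSpec",
    "build_backbone",
    "make_trajectory",
    "make_aromatic_pair",
    "make_protein_structure",
    "make_two_basin_ensemble",
    "random_rotation",
    "write_raw_pdb",
]

# idealized backbone internal coordinates (Å / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic PDB fixture."""

    seed: int = 0
    n_residues: int = 8
    n_chains: int = 1
    n_models: int = 1
    phi_psi: Optional[List[Tuple[float, float]]] = None
    sigma: float = 0.0
    with_ligand: bool = False
    with_calcium: bool = False
    with_alt_locs: bool = False


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Internal-coordinate (NeRF) placement of atom D from A-B-C."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + bc * d[0] + m * d[1] + n * d[2]


_ONE_TO_THREE = {info.code1: c3 for c3, info in MONOMERS.items()}


def _res_names(sequence, n: int) -> List[str]:
    if sequence is None:
        return ["ALA"] * n
    if isinstance(sequence, str):
        return [_ONE_TO_THREE.get(ch.upper(), "ALA") for ch in sequence]
    return [str(s).upper() for s in sequence]


def build_backbone(
    phi_psi_targets: Seq[Tuple[float, float]],
    sequence=None,
    chain_id: str = "A",
    structure_id: str = "backbone",
) -> Structure:
    """Poly-alanine backbone (N, CA, C per residue) chained so that the
    measured phi/psi dihedrals reproduce the targets exactly.

    ``phi_psi_targets[i]`` gives (phi, psi) for residue ``i``; phi of the
    first and psi of the last residue have no geometric effect.
    """
    targets = list(phi_psi_targets)
    n = len(targets)
    if n < 1:
        raise ValueError("at least one residue is required")
    names = _res_names(sequence, n)
    if len(names) != n:
        raise ValueError("sequence length must match the number of targets")

    coords: List[Dict[str, np.ndarray]] = []
    N0 = np.array([0.0, 0.0, 0.0])
    CA0 = np.array([BOND_N_CA, 0.0, 0.0])
    dummy = np.array([0.0, 1.0, 0.0])  # reference for the first placement
    C0 = _place_atom(dummy, N0, CA0, BOND_CA_C, ANGLE_N_CA_C, targets[0][0])
    coords.append({"N": N0, "CA": CA0, "C": C0})
    for i in range(1, n):
        prev = coords[i - 1]
        Ni = _place_atom(
            prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, targets[i - 1][1]
        )
        CAi = _place_atom(prev["CA"], prev["C"], Ni, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        Ci = _place_atom(prev["C"], Ni, CAi, BOND_CA_C, ANGLE_N_CA_C, targets[i][0])
        coords.append({"N": Ni, "CA": CAi, "C": Ci})

    chain = Chain(chain_id=chain_id)
    serial = 1
    for i, res_coords in enumerate(coords):
        residue = Residue(res_name=names[i], res_seq=i + 1)
        for atom_name, element in (("N", "N"), ("CA", "C"), ("C", "C")):
            residue.atoms.append(
                PdbAtom(
                    serial=serial,
                    name=f" {atom_name:<3s}",
                    pos=Vec3.from_array(res_coords[atom_name]),
                    element=element,
                )
            )
            serial += 1
        chain.residues.append(residue)
    return Structure(id=structure_id, model_no=1, chains=[chain])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via a random unit quaternion)."""
    q = rng.normal(size=4)
    q = q / np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _structure_coords(structure: Structure) -> np.ndarray:
    return np.array(
        [a.pos.to_array() for c in structure.chains for r in c.residues for a in r.atoms]
    )


def _with_coords(structure: Structure, coords: np.ndarray, model_no: int) -> Structure:
    from copy import deepcopy

    clone = deepcopy(structure)
    clone.model_no = model_no
    i = 0
    for chain in clone.chains:
        for residue in chain.residues:
            for atom in residue.atoms:
                atom.pos = Vec3.from_array(coords[i])
                i += 1
    return clone


def make_trajectory(
    base: Structure,
    n_models: int,
    mode: str = "rigid",
    sigma: float = 0.0,
    seed: int = 0,
    path: Optional[Union[str, Path]] = None,
    round_coords: bool = True,
) -> Tuple[List[Structure], List[np.ndarray]]:
    """Multi-model ensemble from a base structure.

    ``mode='rigid'`` applies a random rotation+translation per model
    (all pairwise crmsd stay 0 when sigma == 0); ``mode='noise'`` adds
    isotropic Gaussian noise of the given sigma.  Model 1 is the base.
    Returns the structures and the ground-truth coordinate arrays; when
    ``path`` is given the trajectory is also written as a multi-model
    PDB file with a ``<path>.truth.json`` sidecar.
    """
    if mode not in ("rigid", "noise"):
        raise ValueError(f"unknown trajectory mode {mode!r}")
    rng = np.random.default_rng(seed)
    base_coords = _structure_coords(base)
    first = np.round(base_coords, 3) if round_coords else base_coords.copy()
    coords_per_model = [first]
    for _ in range(1, n_models):
        c = base_coords.copy()
        if mode == "rigid":
            R = random_rotation(rng)
            t = rng.uniform(-20, 20, size=3)
            c = c @ R.T + t
        if sigma > 0:
            c = c + rng.normal(scale=sigma, size=c.shape)
        if round_coords:
            c = np.round(c, 3)  # PDB file precision
        coords_per_model.append(c)
    structures = [
        _with_coords(base, coords_per_model[k], k + 1) for k in range(n_models)
    ]
    if path is not None:
        write_raw_pdb(structures, path)
        sidecar = Path(str(path) + ".truth.json")
        sidecar.write_text(
            json.dumps(
                {
                    "n_models": n_models,
                    "mode": mode,
                    "sigma": sigma,
                    "seed": seed,
                    "coords": [c.tolist() for c in coords_per_model],
                }
            )
        )
    return structures, coords_per_model


def make_two_basin_ensemble(
    n_per_basin: int,
    n_residues: int = 10,
    sigma: float = 0.05,
    seed: int = 0,
) -> Tuple[List[Structure], List[int]]:
    """Ensemble drawn from two well-separated conformational basins
    (helix vs extended) with small coordinate noise; returns structures
    and the ground-truth basin label per model."""
    rng = np.random.default_rng(seed)
    helix = build_backbone([(-57.0, -47.0)] * n_residues, structure_id="helix")
    extended = build_backbone([(180.0, 180.0)] * n_residues, structure_id="extended")
    structures: List[Structure] = []
    labels: List[int] = []
    model_no = 1
    for label, base in ((0, helix), (1, extended)):
        base_coords = _structure_coords(base)
        for _ in range(n_per_basin):
            c = base_coords + rng.normal(scale=sigma, size=base_coords.shape)
            s = _with_coords(base, np.round(c, 3), model_no)
            s.id = f"{base.id}_{model_no}"
            structures.append(s)
            labels.append(label)
            model_no += 1
    return structures, labels


_PHE_RING = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
RING_CC = 1.39  # aromatic carbon-carbon bond length


def _hexagon(center: np.ndarray, normal: np.ndarray, spin_deg: float = 0.0) -> np.ndarray:
    """Regular hexagon of circumradius equal to the aromatic C-C bond."""
    normal = normal / np.linalg.norm(normal)
    # orthonormal in-plane basis
    seed_vec = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed_vec, normal)) > 0.9:
        seed_vec = np.array([0.0, 1.0, 0.0])
    u = seed_vec - np.dot(seed_vec, normal) * normal
    u = u / np.linalg.norm(u)
    v = np.cross(normal, u)
    spin = math.radians(spin_deg)
    pts = []
    for k in range(6):
        theta = spin + k * math.pi / 3.0
        pts.append(center + RING_CC * (math.cos(theta) * u + math.sin(theta) * v))
    return np.array(pts)


def make_aromatic_pair(
    distance: float,
    plane_angle: float,
    offset: float,
    spin_b: float = 0.0,
    structure_id: str = "aromatic_pair",
) -> Structure:
    """Two PHE rings engineered so that the stacking descriptor of the
    pair is exactly ``(distance, plane_angle, offset)``.

    Ring A lies in the xy-plane at the origin; ring B's centroid sits at
    lateral offset ``offset`` and centroid distance ``distance``, its
    plane tilted by ``plane_angle`` degrees.
    """
    if not 0 <= plane_angle <= 90:
        raise ValueError("plane_angle must be in [0, 90] degrees")
    if offset > distance:
        raise ValueError("offset cannot exceed the centroid distance")
    h = math.sqrt(max(distance * distance - offset * offset, 0.0))
    center_a = np.zeros(3)
    normal_a = np.array([0.0, 0.0, 1.0])
    center_b = np.array([offset, 0.0, h])
    ang = math.radians(plane_angle)
    normal_b = np.array([0.0, math.sin(ang), math.cos(ang)])

    chain = Chain(chain_id="A")
    serial = 1
    for res_seq, (center, normal, spin) in enumerate(
        ((center_a, normal_a, 0.0), (center_b, normal_b, spin_b)), start=1
    ):
        residue = Residue(res_name="PHE", res_seq=res_seq)
        ring = _hexagon(center, normal, spin)
        for name, xyz in zip(_PHE_RING, ring):
            residue.atoms.append(
                PdbAtom(
                    serial=serial,
                    name=f" {name:<3s}",
                    pos=Vec3.from_array(xyz),
                    element="C",
                )
            )
            serial += 1
        chain.residues.append(residue)
    return Structure(id=structure_id, model_no=1, chains=[chain])


def make_protein_structure(
    spec: FixtureSpec,
) -> Tuple[Structure, Dict]:
    """Random multi-chain protein-like structure for parser fixtures.

    Residues carry N, CA, C, O, CB atoms with seeded random coordinates
    (rounded to PDB precision); optional HETATM ligand, a calcium ion
    (atom name ``CA``, element ``CA`` — must never be mistaken for an
    alpha carbon) and alternate locations.  Returns the structure and a
    ground-truth dict (sequences, counts, coordinates).
    """
    rng = np.random.default_rng(spec.seed)
    aa_codes = sorted(MONOMERS)
    structure = Structure(id=f"fix{spec.seed}", model_no=1)
    # n_atoms counts every emitted record; n_atoms_kept excludes the
    # non-first alternate locations a default reader drops
    truth: Dict = {
        "sequences": {},
        "n_ca": 0,
        "n_atoms": 0,
        "n_atoms_kept": 0,
        "coords": [],
    }
    serial = 1
    for ci in range(spec.n_chains):
        chain_id = chr(ord("A") + ci)
        chain = Chain(chain_id=chain_id)
        seq_letters = []
        for ri in range(spec.n_residues):
            res_name = aa_codes[int(rng.integers(len(aa_codes)))]
            seq_letters.append(three_to_one(res_name))
            residue = Residue(res_name=res_name, res_seq=ri + 1)
            for atom_name, element in (
                ("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"),
            ):
                if res_name == "GLY" and atom_name == "CB":
                    continue
                xyz = np.round(rng.uniform(-50, 50, size=3), 3)
                residue.atoms.append(
                    PdbAtom(
                        serial=serial,
                        name=f" {atom_name:<3s}",
                        pos=Vec3.from_array(xyz),
                        element=element,
                        occupancy=1.0,
                        b_factor=round(float(rng.uniform(0, 99)), 2),
                    )
                )
                truth["n_atoms"] += 1
                truth["n_atoms_kept"] += 1
                if atom_name == "CA":
                    truth["n_ca"] += 1
                truth["coords"].append(residue.atoms[-1].pos.to_array().tolist())
                serial += 1
            if spec.with_alt_locs and ri == 0:
                # second conformer of the last atom; readers keep the first
                alt = PdbAtom(
                    serial=serial,
                    name=residue.atoms[-1].name,
                    pos=Vec3.from_array(np.round(rng.uniform(-50, 50, 3), 3)),
                    alt_loc="B",
                    element=residue.atoms[-1].element,
                    occupancy=0.5,
                )
                residue.atoms[-1].alt_loc = "A"
                residue.atoms.append(alt)
                truth["n_atoms"] += 1
                truth["coords"].append(alt.pos.to_array().tolist())
                serial += 1
            chain.residues.append(residue)
        structure.chains.append(chain)
        truth["sequences"][chain_id] = "".join(seq_letters)
    if spec.with_ligand:
        lig_chain = Chain(chain_id="L")
        residue = Residue(res_name="LIG", res_seq=1)
        for atom_name, element in (("C1", "C"), ("O1", "O")):
            xyz = np.round(rng.uniform(-50, 50, size=3), 3)
            residue.atoms.append(
                PdbAtom(
                    serial=serial,
                    name=f" {atom_name:<3s}",
                    pos=Vec3.from_array(xyz),
                    element=element,
                    is_hetero=True,
                )
            )
            truth["n_atoms"] += 1
            truth["n_atoms_kept"] += 1
            truth["coords"].append(xyz.tolist())
            serial += 1
        lig_chain.residues.append(residue)
        structure.chains.append(lig_chain)
    if spec.with_calcium:
        ion_chain = Chain(chain_id="M")
        residue = Residue(res_name="CA", res_seq=1)
        xyz = np.round(rng.uniform(-50, 50, size=3), 3)
        residue.atoms.append(
            PdbAtom(
                serial=serial,
                name="CA  ",
                pos=Vec3.from_array(xyz),
                element="CA",
                is_hetero=True,
            )
        )
        truth["n_atoms"] += 1
        truth["n_atoms_kept"] += 1
        truth["coords"].append(xyz.tolist())
        ion_chain.residues.append(residue)
        structure.chains.append(ion_chain)
    return structure, truth


def _raw_atom_line(atom: PdbAtom, residue: Residue, chain: Chain) -> str:
    record = "HETATM" if atom.is_hetero else "ATOM  "
    return (
        f"{record}{atom.serial % 100000:5d} {atom.name:<4.4s}{atom.alt_loc or ' '}"
        f"{residue.res_name:>3.3s} {chain.chain_id}{residue.res_seq:4d}"
        f"{residue.i_code or ' '}   "
        f"{atom.pos.x:8.3f}{atom.pos.y:8.3f}{atom.pos.z:8.3f}"
        f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}          {atom.element:>2.2s}"
    )


def write_raw_pdb(
    structures: Union[Structure, Seq[Structure]],
    path: Union[str, Path],
) -> None:
    """Independent PDB emitter (oracle for the I/O layer, not built on it)."""
    if isinstance(structures, Structure):
        structures = [structures]
    structures = list(structures)
    lines: List[str] = []
    multi = len(structures) > 1
    for k, structure in enumerate(structures, start=1):
        if multi:
            lines.append(f"MODEL {k:>8d}")
        for chain in structure.chains:
            for residue in chain.residues:
                for atom in residue.atoms:
                    lines.append(_raw_atom_line(atom, residue, chain))
            lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def spec_to_json(spec: FixtureSpec) -> str:
    return json.dumps(asdict(spec))
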