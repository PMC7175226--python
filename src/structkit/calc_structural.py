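"""Geometry engine: superposition/crmsd, backbone dihedrals with
Ramachandran classes, residue contact maps and aromatic-ring frames."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .core_model import (
    AROMATIC_RESIDUES,
    Chain,
    Residue,
    Structure,
    Vec3,
    ca_trace,
    is_polymer_residue,
    monomer_info,
)

__all__ = [
    "SuperpositionResult",
    "RamachandranRecord",
    "ContactMap",
    "RingFrame",
    "StackingDescriptor",
    "dihedral",
    "phi_psi",
    "kabsch_superpose",
    "crmsd_ca",
    "pairwise_crmsd_matrix",
    "contact_map",
    "ring_frame",
    "stacking_pairs",
]

GLYCINE = "Glycine"
PROLINE = "Proline"
PRE_PROLINE = "Pre-Proline"
GENERAL = "General"


def _as_points(points) -> np.ndarray:
    if isinstance(points, np.ndarray):
        arr = np.asarray(points, dtype=float)
    else:
        arr = np.array(
            [p.to_array() if isinstance(p, Vec3) else np.asarray(p, float) for p in points],
            dtype=float,
        )
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected an (n, 3) point set")
    return arr


def dihedral(a, b, c, d) -> float:
    """Signed torsion angle in degrees, in (−180, 180], IUPAC convention."""
    a, b, c, d = (p.to_array() if isinstance(p, Vec3) else np.asarray(p, float) for p in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12:
        raise ValueError("zero-length central bond")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / nb2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    angle = -math.degrees(math.atan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return angle


@dataclass
class RamachandranRecord:
    chain_id: str
    res_seq: int
    res_name: str
    phi: Optional[float]
    psi: Optional[float]
    klass: str


def _classify(res_name: str, next_res_name: Optional[str]) -> str:
    # residue identity outranks pre-proline context
    if res_name == "GLY":
        return GLYCINE
    if res_name == "PRO":
        return PROLINE
    if next_res_name == "PRO":
        return PRE_PROLINE
    return GENERAL


def phi_psi(chain: Chain) -> List[RamachandranRecord]:
    """Backbone phi/psi per polymer residue with 4-way class labels.

    phi_i = dihedral(C_{i-1}, N_i, CA_i, C_i);
    psi_i = dihedral(N_i, CA_i, C_i, N_{i+1}).
    Chain-terminal or backbone-incomplete residues get ``None`` angles.
    """
    residues = [r for r in chain.residues if is_polymer_residue(r)]
    records: List[RamachandranRecord] = []
    backbone = []
    for r in residues:
        backbone.append({n: r.find_atom(n) for n in ("N", "CA", "C")})
    for i, r in enumerate(residues):
        bb = backbone[i]
        phi = psi = None
        missing = [n for n, a in bb.items() if a is None]
        if missing:
            warnings.warn(
                f"residue {r.res_name} {r.res_seq}{r.i_code.strip()} in chain "
                f"{chain.chain_id!r} lacks backbone atoms {missing}; "
                f"angles undefined",
                stacklevel=2,
            )
        else:
            if i > 0 and backbone[i - 1]["C"] is not None:
                phi = dihedral(
                    backbone[i - 1]["C"].pos, bb["N"].pos, bb["CA"].pos, bb["C"].pos
                )
            if i + 1 < len(residues) and backbone[i + 1]["N"] is not None:
                psi = dihedral(
                    bb["N"].pos, bb["CA"].pos, bb["C"].pos, backbone[i + 1]["N"].pos
                )
        next_name = residues[i + 1].res_name.strip().upper() if i + 1 < len(residues) else None
        records.append(
            RamachandranRecord(
                chain_id=chain.chain_id,
                res_seq=r.res_seq,
                res_name=r.res_name,
                phi=phi,
                psi=psi,
                klass=_classify(r.res_name.strip().upper(), next_name),
            )
        )
    return records


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, orthonormal, det = +1
    translation: np.ndarray  # applied after rotation
    crmsd: float

    def transform(self, points) -> np.ndarray:
        return _as_points(points) @ self.rotation.T + self.translation


def kabsch_superpose(mobile, reference) -> SuperpositionResult:
    """Optimal rigid-body superposition (SVD, reflection-corrected).

    Returns the rotation/translation mapping *mobile* onto *reference*
    and the minimized coordinate RMSD.
    """
    P = _as_points(mobile)
    Q = _as_points(reference)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in size: {P.shape[0]} vs {Q.shape[0]}")
    if P.shape[0] < 3:
        raise ValueError("at least 3 points are required")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = P0 @ R.T
    crmsd = float(np.sqrt(np.mean(np.sum((moved - Q0) ** 2, axis=1))))
    t = qc - pc @ R.T
    return SuperpositionResult(rotation=R, translation=t, crmsd=crmsd)


def crmsd_ca(structure_a: Structure, structure_b: Structure) -> float:
    """crmsd over the alpha-carbon traces of two structures."""
    ta = ca_trace(structure_a)
    tb = ca_trace(structure_b)
    if len(ta) != len(tb):
        raise ValueError(
            f"CA trace lengths differ: {len(ta)} ({structure_a.id}) vs "
            f"{len(tb)} ({structure_b.id})"
        )
    return kabsch_superpose(ta, tb).crmsd


def pairwise_crmsd_matrix(ensemble: Sequence[Structure]):
    """All-pairs crmsd over an ensemble; symmetric with zero diagonal.

    The result is independent of evaluation order; each (i, j) entry is a
    self-contained superposition, so entries may be computed in any
    partitioning (parallel-safe contract).
    """
    from .clustering import DistanceMatrix

    traces = []
    for idx, s in enumerate(ensemble):
        traces.append(_as_points(ca_trace(s)))
    if not traces:
        raise ValueError("empty ensemble")
    n0 = traces[0].shape[0]
    for idx, t in enumerate(traces):
        if t.shape[0] != n0:
            raise ValueError(
                f"model {idx} ({ensemble[idx].id!r}) has CA trace length "
                f"{t.shape[0]}, expected {n0}"
            )
    n = len(traces)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            v = kabsch_superpose(traces[i], traces[j]).crmsd
            values[i, j] = values[j, i] = v
    labels = [s.id or str(i) for i, s in enumerate(ensemble)]
    return DistanceMatrix(values=values, labels=labels)


@dataclass
class ContactMap:
    """Counts, over models, of residue pairs in contact (strict ``< cutoff``)."""

    pairs: Dict[Tuple[int, int], int]
    cutoff: float
    n_models: int
    labels: List[Tuple[str, int, str, str]] = field(default_factory=list)
    # labels[i] = (chain_id, res_seq, i_code, res_name) for internal index i

    def count(self, i: int, j: int) -> int:
        if i == j:
            return 0
        key = (min(i, j), max(i, j))
        return self.pairs.get(key, 0)


def _residue_index(structure: Structure):
    labels = []
    entries = []  # (chain position, residue)
    for ci, chain in enumerate(structure.chains):
        for residue in chain.residues:
            labels.append(
                (chain.chain_id, residue.res_seq, residue.i_code, residue.res_name)
            )
            entries.append((ci, residue))
    return labels, entries


def contact_map(
    structures: Sequence[Structure],
    cutoff: float,
    mode: str = "CA",
    min_seq_sep: int = 2,
) -> ContactMap:
    """Aggregate residue-residue contacts across models.

    ``mode='CA'`` measures alpha-carbon distance (residues without a CA
    are skipped); ``mode='any-atom'`` uses the minimum inter-atomic
    distance.  Intra-chain pairs closer than ``min_seq_sep`` in sequence
    are excluded (set 0 to disable).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if mode not in ("CA", "any-atom"):
        raise ValueError(f"unknown contact mode {mode!r}")
    structures = list(structures)
    if not structures:
        raise ValueError("no structures given")
    labels, _ = _residue_index(structures[0])
    counts: Dict[Tuple[int, int], int] = {}
    for structure in structures:
        _, entries = _residue_index(structure)
        n = len(entries)
        if mode == "CA":
            reps = []
            for idx, (ci, res) in enumerate(entries):
                a = res.find_atom("CA")
                reps.append(None if a is None else a.pos.to_array())
            for i in range(n):
                if reps[i] is None:
                    continue
                for j in range(i + 1, n):
                    if reps[j] is None:
                        continue
                    if _excluded(entries, i, j, min_seq_sep):
                        continue
                    if np.linalg.norm(reps[i] - reps[j]) < cutoff:
                        key = (i, j)
                        counts[key] = counts.get(key, 0) + 1
        else:
            coords = [
                np.array([a.pos.to_array() for a in res.atoms]) for _, res in entries
            ]
            for i in range(n):
                for j in range(i + 1, n):
                    if _excluded(entries, i, j, min_seq_sep):
                        continue
                    if coords[i].size == 0 or coords[j].size == 0:
                        continue
                    if cdist(coords[i], coords[j]).min() < cutoff:
                        key = (i, j)
                        counts[key] = counts.get(key, 0) + 1
    return ContactMap(
        pairs=counts, cutoff=cutoff, n_models=len(structures), labels=labels
    )


def _excluded(entries, i: int, j: int, min_seq_sep: int) -> bool:
    ci, _ = entries[i]
    cj, _ = entries[j]
    return ci == cj and abs(i - j) < min_seq_sep


def contact_map_to_tsv(cmap: ContactMap) -> str:
    lines = ["#chain_i\tres_i\tchain_j\tres_j\tcount"]
    for (i, j), count in sorted(cmap.pairs.items()):
        ci, si, _, _ = cmap.labels[i]
        cj, sj, _, _ = cmap.labels[j]
        lines.append(f"{ci}\t{si}\t{cj}\t{sj}\t{count}")
    return "\n".join(lines) + "\n"


@dataclass
class RingFrame:
    """Right-handed orthonormal frame of an aromatic ring.

    ``z_axis`` is the unit normal of the least-squares ring plane;
    ``x_axis`` the in-plane direction towards the first ring atom;
    ``origin`` the ring-atom centroid.
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    res_name: str
    res_seq: int
    chain_id: str = ""


def ring_frame(residue: Residue, chain_id: str = "") -> RingFrame:
    info = monomer_info(residue.res_name)
    if not info.is_aromatic:
        raise ValueError(f"{residue.res_name} is not an aromatic residue")
    atoms = []
    missing = []
    for name in info.ring_atom_names:
        a = residue.find_atom(name)
        if a is None:
            missing.append(name)
        else:
            atoms.append(a.pos.to_array())
    if missing:
        raise ValueError(
            f"{residue.res_name} {residue.res_seq}: missing ring atoms {missing}"
        )
    coords = np.array(atoms)
    origin = coords.mean(axis=0)
    centered = coords - origin
    # least-squares plane normal = singular vector of the smallest singular value
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    z = Vt[2]
    # deterministic sign: align with the ring's winding direction
    winding = np.cross(centered[0], centered[1])
    if np.dot(z, winding) < 0:
        z = -z
    x = centered[0] - np.dot(centered[0], z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        raise ValueError("degenerate ring geometry: first ring atom on the normal")
    x = x / nx
    y = np.cross(z, x)
    return RingFrame(
        origin=origin,
        x_axis=x,
        y_axis=y,
        z_axis=z,
        res_name=residue.res_name,
        res_seq=residue.res_seq,
        chain_id=chain_id,
    )


@dataclass
class StackingDescriptor:
    ring_a: Tuple[str, int, str]  # (chain_id, res_seq, res_name)
    ring_b: Tuple[str, int, str]
    centroid_distance: float
    plane_angle: float  # degrees in [0, 90]
    lateral_offset: float


def stacking_pairs(structure: Structure, cutoff: float = 6.5) -> List[StackingDescriptor]:
    """Descriptors for every aromatic ring pair with centroids closer than
    ``cutoff``: centroid distance, inter-plane angle (normal-flip
    invariant) and lateral offset in the first ring's plane."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frames: List[RingFrame] = []
    for chain in structure.chains:
        for residue in chain.residues:
            if residue.res_name.strip().upper() in AROMATIC_RESIDUES:
                try:
                    frames.append(ring_frame(residue, chain.chain_id))
                except ValueError:
                    continue  # incomplete ring: skip, not an error at scan level
    out: List[StackingDescriptor] = []
    for i in range(len(frames)):
        for j in range(i + 1, len(frames)):
            fa, fb = frames[i], frames[j]
            d = fb.origin - fa.origin
            dist = float(np.linalg.norm(d))
            if dist >= cutoff:
                continue
            cosang = abs(float(np.dot(fa.z_axis, fb.z_axis)))
            angle = math.degrees(math.acos(min(1.0, cosang)))
            lateral = float(np.linalg.norm(d - np.dot(d, fa.z_axis) * fa.z_axis))
            out.append(
                StackingDescriptor(
                    ring_a=(fa.chain_id, fa.res_seq, fa.res_name),
                    ring_b=(fb.chain_id, fb.res_seq, fb.res_name),
                    centroid_distance=dist,
                    plane_angle=angle,
                    lateral_offset=lateral,
                )
            )
    return out


def ramachandran_to_tsv(records: Sequence[RamachandranRecord]) -> str:
    lines = ["#chain\tres_seq\tres_name\tphi\tpsi\tclass"]
    for r in records:
        phi = "NA" if r.phi is None else f"{r.phi:.3f}"
        psi = "NA" if r.psi is None else f"{r.psi:.3f}"
        lines.append(f"{r.chain_id}\t{r.res_seq}\t{r.res_name}\t{phi}\t{psi}\t{r.klass}")
    return "\n".join(lines) + "\n"


def stacking_to_tsv(descriptors: Sequence[StackingDescriptor]) -> str:
    lines = ["#chain_a\tres_a\tname_a\tchain_b\tres_b\tname_b\tdistance\tplane_angle\toffset"]
    for d in descriptors:
        ca_, sa, na = d.ring_a
        cb, sb, nb = d.ring_b
        lines.append(
            f"{ca_}\t{sa}\t{na}\t{cb}\t{sb}\t{nb}\t"
            f"{d.centroid_distance:.4f}\t{d.plane_angle:.4f}\t{d.lateral_offset:.4f}"
        )
    return "\n".join(lines) + "\n"
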