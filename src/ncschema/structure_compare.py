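"""Rigid-body superposition and polar-contact geometry.

Superposition is the least-squares optimal rotation/translation (Kabsch) of
paired atom sets, used to compare a chimera's fold with its parents.
Polar contacts are donor/acceptor heavy-atom (N/O) pairs below a distance
cutoff — a hydrogen-bond proxy that needs no hydrogen positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import ParentStructure, _element_of


@dataclass
class SuperpositionResult:
    rotation: np.ndarray       # 3x3, det +1
    translation: np.ndarray    # 3-vector, Å
    rmsd: float                # Å, over the paired atoms after transform
    n_atoms: int
    atom_selection: str

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "rmsd": self.rmsd,
            "n_atoms": self.n_atoms,
            "atom_selection": self.atom_selection,
        }


@dataclass
class PolarContact:
    donor: str      # "RES68:OD1" style identifier
    acceptor: str
    distance: float


def _paired_coords(mobile: ParentStructure, reference: ParentStructure,
                   pairing: list[tuple[int, int]], atoms: str = "CA"
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of the selected atom for each paired residue (1-based indices)."""
    mob, ref = [], []
    for i_mob, i_ref in pairing:
        try:
            a = mobile.residues[i_mob - 1].atom(atoms)
            b = reference.residues[i_ref - 1].atom(atoms)
        except KeyError:
            continue  # residue lacks the selected atom (e.g. truncated side chain)
        mob.append(a[1:])
        ref.append(b[1:])
    return np.asarray(mob, float), np.asarray(ref, float)


def superpose(mobile: ParentStructure, reference: ParentStructure,
              pairing: list[tuple[int, int]], atoms: str = "CA") -> SuperpositionResult:
    """Kabsch superposition of ``mobile`` onto ``reference`` over paired residues.

    ``pairing`` lists (mobile_residue_index, reference_residue_index) pairs,
    1-based in structure order; ``atoms`` names the atom taken from each
    residue (Cα by default). Raises on fewer than 3 usable pairs or on a
    degenerate (collinear) point set.
    """
    mob, ref = _paired_coords(mobile, reference, pairing, atoms)
    if len(mob) < 3:
        raise ValueError(f"need >= 3 paired atoms, found {len(mob)}")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2 or np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) atom set; rotation is not determined")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - R @ mob.mean(axis=0)
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               n_atoms=len(mob), atom_selection=atoms)


def apply_transform(structure: ParentStructure, result: SuperpositionResult) -> ParentStructure:
    """Return a copy of the structure with the superposition applied."""
    from .structure_io import ParentStructure as PS, ResidueRecord
    R, t = result.rotation, result.translation
    new_residues = []
    for res in structure.residues:
        atoms = tuple(
            (name, *(R @ np.array([x, y, z]) + t))
            for name, x, y, z in res.heavy_atoms
        )
        new_residues.append(ResidueRecord(res.chain_id, res.residue_number,
                                          res.residue_name, atoms))
    return PS(parent_id=structure.parent_id, source=structure.source,
              residues=new_residues)


def _polar_atoms(structure: ParentStructure, residue_index: int):
    res = structure.residues[residue_index - 1]
    for name, x, y, z in res.heavy_atoms:
        if _element_of(name) in ("N", "O"):
            yield f"{res.residue_name}{res.residue_number}:{name}", np.array([x, y, z])


def polar_contacts(structure: ParentStructure,
                   residue_queries: list[tuple[int, int]],
                   cutoff: float = 3.5) -> list[PolarContact]:
    """N/O atom pairs below ``cutoff`` between queried residue pairs.

    ``residue_queries`` lists (residue_index_a, residue_index_b) pairs,
    1-based in structure order. A plain distance criterion (no angle term)
    is used, since the models carry no hydrogens.
    """
    n = len(structure.residues)
    out: list[PolarContact] = []
    for ia, ib in residue_queries:
        for idx in (ia, ib):
            if not 1 <= idx <= n:
                raise ValueError(f"unknown residue index {idx} (structure has {n})")
        for name_a, xyz_a in _polar_atoms(structure, ia):
            for name_b, xyz_b in _polar_atoms(structure, ib):
                d = float(np.linalg.norm(xyz_a - xyz_b))
                if d < cutoff:
                    out.append(PolarContact(donor=name_a, acceptor=name_b, distance=d))
    out.sort(key=lambda c: c.distance)
    return out


def write_polar_report(contacts: list[PolarContact], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("donor\tacceptor\tdistance_A\n")
        for c in contacts:
            fh.write(f"{c.donor}\t{c.acceptor}\t{c.distance:.3f}\n")
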