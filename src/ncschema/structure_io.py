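"""Structure and alignment input.

Reads the two parent structures (PDB or mmCIF, via gemmi), reads their
pairwise sequence alignment (FASTA or Clustal, via Bio.AlignIO), and builds
the residue-to-alignment-column mapping every downstream stage uses.

Conventions: alignment columns are 1-based; residue indices within a parent
are 1-based in structure order (chain, then author residue number).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gemmi
from Bio import AlignIO

GAP = "-"

#: Standard one-letter codes accepted in alignment rows.
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ResidueRecord:
    """One standard amino-acid residue with its heavy atoms.

    ``heavy_atoms`` holds ``(atom_name, x, y, z)`` tuples in Å; hydrogens are
    never stored.
    """

    chain_id: str
    residue_number: int
    residue_name: str
    heavy_atoms: tuple[tuple[str, float, float, float], ...]

    @property
    def one_letter(self) -> str:
        return _three_to_one(self.residue_name)

    def atom(self, name: str) -> tuple[str, float, float, float]:
        for a in self.heavy_atoms:
            if a[0] == name:
                return a
        raise KeyError(f"atom {name!r} not in residue {self.residue_name}{self.residue_number}")


@dataclass
class ParentStructure:
    """An ordered list of residues of one parent's catalytic domain."""

    parent_id: str
    source: str
    residues: list[ResidueRecord]

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ParentAlignment:
    """A pairwise alignment of the two parent sequences.

    ``conserved_mask[c]`` is True when both rows carry the identical residue
    at column ``c`` (0-based internally); any gap makes a column
    non-conserved.
    """

    parent1_row: str
    parent2_row: str

    def __post_init__(self) -> None:
        if len(self.parent1_row) != len(self.parent2_row):
            raise ValueError(
                f"alignment rows differ in length: {len(self.parent1_row)} vs {len(self.parent2_row)}"
            )
        self.parent1_row = self.parent1_row.upper()
        self.parent2_row = self.parent2_row.upper()
        for row in (self.parent1_row, self.parent2_row):
            bad = set(row) - AMINO_ACIDS - {GAP}
            if bad:
                raise ValueError(f"non-amino-acid symbols in alignment row: {sorted(bad)}")

    @property
    def columns(self) -> int:
        return len(self.parent1_row)

    @property
    def conserved_mask(self) -> list[bool]:
        return [
            a != GAP and b != GAP and a == b
            for a, b in zip(self.parent1_row, self.parent2_row)
        ]

    def nonconserved_columns(self) -> list[int]:
        """1-based columns where the parents are not identical."""
        return [c + 1 for c, cons in enumerate(self.conserved_mask) if not cons]

    def row(self, which: int) -> str:
        if which == 1:
            return self.parent1_row
        if which == 2:
            return self.parent2_row
        raise ValueError("parent selector must be 1 or 2")

    def ungapped(self, which: int) -> str:
        return self.row(which).replace(GAP, "")


@dataclass
class ColumnMap:
    """Mapping alignment column (1-based) -> residue index (1-based) for one parent."""

    which: int
    column_to_residue: dict[int, int]
    residue_to_column: dict[int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.residue_to_column = {r: c for c, r in self.column_to_residue.items()}

    def residue_at(self, column: int) -> int | None:
        return self.column_to_residue.get(column)

    def column_of(self, residue_index: int) -> int:
        return self.residue_to_column[residue_index]


# gemmi knows the tabulated residues; this covers the common modified ones
# (MSE selenomethionine etc.) that should map back to a parent amino acid.
_MODIFIED_PARENT = {"MSE": "MET", "SEC": "CYS", "MLY": "LYS", "CSO": "CYS", "PTR": "TYR",
                    "SEP": "SER", "TPO": "THR", "HYP": "PRO"}


def _three_to_one(name: str) -> str:
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_standard() and info.is_amino_acid():
        return gemmi.find_tabulated_residue(name).one_letter_code.upper()
    parent = _MODIFIED_PARENT.get(name.upper())
    if parent:
        return gemmi.find_tabulated_residue(parent).one_letter_code.upper()
    raise ValueError(f"not a standard amino acid: {name}")


def _is_standard_aa(name: str) -> bool:
    try:
        code = _three_to_one(name)
    except ValueError:
        return False
    return code in AMINO_ACIDS


def load_structure(path: str | Path, chain_selector: str | None = None,
                   parent_id: str = "P") -> ParentStructure:
    """Read one chain of a PDB/mmCIF file as a :class:`ParentStructure`.

    Keeps standard amino-acid residues only (waters, ions, buffer molecules
    and other hetero groups are dropped), strips hydrogens, and resolves
    alternate locations to the highest-occupancy conformer (ties broken by
    altloc label order). Modified residues with a tabulated parent amino acid
    (e.g. MSE) are kept under their own name but translate to the parent's
    one-letter code; anything else is excluded with a warning.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unparseable structure file {path}: {exc}") from None
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    st.setup_entities()
    model = st[0]
    chains = {ch.name for ch in model}
    if chain_selector is None:
        chain_selector = model[0].name
    if chain_selector not in chains:
        raise ValueError(f"chain {chain_selector!r} not in {path} (has {sorted(chains)})")

    residues: list[ResidueRecord] = []
    for res in model[chain_selector]:
        if res.is_water():
            continue
        if not _is_standard_aa(res.name):
            if res.het_flag == "A":  # polymer residue we cannot translate
                warnings.warn(f"excluding non-standard residue {res.name} {res.seqid.num}")
            continue
        atoms = _select_heavy_atoms(res)
        if atoms:
            residues.append(ResidueRecord(chain_selector, res.seqid.num, res.name, tuple(atoms)))
    if not residues:
        raise ValueError(f"zero standard residues in chain {chain_selector} of {path}")
    residues.sort(key=lambda r: (r.chain_id, r.residue_number))
    return ParentStructure(parent_id=parent_id, source=str(path), residues=residues)


def _select_heavy_atoms(res: gemmi.Residue) -> list[tuple[str, float, float, float]]:
    # group altloc conformers per atom name, keep highest occupancy
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in res:
        if atom.is_hydrogen():
            continue
        by_name.setdefault(atom.name, []).append(atom)
    out = []
    for name, group in by_name.items():
        best = sorted(group, key=lambda a: (-a.occ, a.altloc))[0]
        pos = best.pos
        out.append((name, pos.x, pos.y, pos.z))
    return out


def write_structure(structure: ParentStructure, path: str | Path) -> None:
    """Write a ParentStructure as plain single-chain PDB text."""
    st = gemmi.Structure()
    st.name = structure.parent_id
    model = gemmi.Model("1")
    chain = gemmi.Chain(structure.residues[0].chain_id if structure.residues else "A")
    for rec in structure.residues:
        res = gemmi.Residue()
        res.name = rec.residue_name
        res.seqid = gemmi.SeqId(rec.residue_number, " ")
        for name, x, y, z in rec.heavy_atoms:
            atom = gemmi.Atom()
            atom.name = name
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            atom.element = gemmi.Element(_element_of(name))
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def _element_of(atom_name: str) -> str:
    """Element of a standard amino-acid heavy atom from its PDB name."""
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def load_alignment(path: str | Path) -> ParentAlignment:
    """Read a two-row pairwise alignment (FASTA or Clustal)."""
    path = Path(path)
    fmt = _sniff_alignment_format(path)
    aln = AlignIO.read(str(path), fmt)
    if len(aln) != 2:
        raise ValueError(f"expected exactly 2 aligned sequences, found {len(aln)}")
    return ParentAlignment(str(aln[0].seq), str(aln[1].seq))


def _sniff_alignment_format(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        return "fasta"
    if first.upper().startswith("CLUSTAL"):
        return "clustal"
    raise ValueError(f"unrecognized alignment format in {path}")


def map_columns(alignment: ParentAlignment, parent: ParentStructure, which: int) -> ColumnMap:
    """Map each alignment column to the parent's residue index (1-based).

    The ungapped alignment row must equal the parent's structure-derived
    sequence; the first mismatch is reported by position.
    """
    row = alignment.row(which)
    seq = parent.sequence
    ungapped = row.replace(GAP, "")
    if ungapped != seq:
        n = min(len(ungapped), len(seq))
        pos = next((i + 1 for i in range(n) if ungapped[i] != seq[i]), n + 1)
        raise ValueError(
            f"alignment row {which} does not match structure {parent.parent_id} sequence: "
            f"first difference at residue position {pos} "
            f"(row has {ungapped[pos - 1] if pos <= len(ungapped) else 'end'!r}, "
            f"structure has {seq[pos - 1] if pos <= len(seq) else 'end'!r})"
        )
    mapping: dict[int, int] = {}
    residue_index = 0
    for col, symbol in enumerate(row, start=1):
        if symbol != GAP:
            residue_index += 1
            mapping[col] = residue_index
    return ColumnMap(which=which, column_to_residue=mapping)


def write_column_report(alignment: ParentAlignment, map1: ColumnMap, map2: ColumnMap,
                        path: str | Path) -> None:
    """TSV report: column, parent1_residue, parent2_residue, conserved."""
    mask = alignment.conserved_mask
    with open(path, "w") as fh:
        fh.write("column\tparent1_residue\tparent2_residue\tconserved\n")
        for col in range(1, alignment.columns + 1):
            r1 = map1.residue_at(col)
            r2 = map2.residue_at(col)
            fh.write(f"{col}\t{r1 if r1 else '.'}\t{r2 if r2 else '.'}\t"
                     f"{int(mask[col - 1])}\n")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
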