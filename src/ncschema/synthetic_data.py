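"""Synthetic parents, alignments and simulated stability assays.

Generates a pair of toy parent structures that share a compact backbone (so
a nontrivial contact map exists) but differ in residue identity at a chosen
fraction of positions, together with a planted block design and per-block
temperature contributions. Stability measurements are then simulated from
the additive-block model plus homoscedastic Gaussian noise — the statistical
structure the downstream regression assumes. Geometry is deliberately
minimal: a lattice-coil backbone with small pseudo side chains, not
physically realistic protein structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .block_design import BlockAssignment, _canonical_labels
from .chimera_library import Code
from .stability_model import StabilityRecord
from .structure_io import (ParentAlignment, ParentStructure, ResidueRecord,
                           write_fasta, write_structure)

AA3 = {"A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
       "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
       "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
       "W": "TRP", "Y": "TYR"}
AA1 = sorted(AA3)

# pseudo side-chain atom names per residue, drawn 1..4 of these
_SIDE_NAMES = ("CB", "CG", "OD1", "ND2")

CA_SPACING = 3.8  # Å, consecutive-residue spacing on the lattice coil


@dataclass
class SyntheticWorld:
    seed: int
    n_residues: int
    conservation_fraction: float
    parent1: ParentStructure
    parent2: ParentStructure
    alignment: ParentAlignment
    true_assignment: BlockAssignment
    true_deltas: np.ndarray   # °C per block, P1-inherited effect
    baseline: float           # °C, the P2 trait value
    noise_sd: float           # °C


def _lattice_coil(n: int) -> np.ndarray:
    """Cα positions snaking through a compact cubic lattice, spacing 3.8 Å."""
    side = int(np.ceil(n ** (1 / 3)))
    coords = []
    for layer in range(side):
        for row in range(side):
            cols = range(side) if row % 2 == 0 else range(side - 1, -1, -1)
            for col in cols:
                coords.append((col, row, layer))
                if len(coords) == n:
                    return np.asarray(coords, float) * CA_SPACING
    return np.asarray(coords[:n], float) * CA_SPACING


def _make_residues(sequence: str, ca: np.ndarray, rng: np.random.Generator,
                   chain_id: str = "A") -> list[ResidueRecord]:
    residues = []
    for i, letter in enumerate(sequence):
        atoms = [("CA", *ca[i])]
        n_side = int(rng.integers(1, 5))
        for name in _SIDE_NAMES[:n_side]:
            offset = rng.uniform(-1.5, 1.5, size=3)
            atoms.append((name, *(ca[i] + offset)))
        residues.append(ResidueRecord(chain_id, i + 1, AA3[letter], tuple(atoms)))
    return residues


def generate_toy_parents(n_residues: int = 60, conservation_fraction: float = 0.5,
                         seed: int = 0, k: int = 4, delta_range: float = 6.0,
                         baseline: float = 72.0, noise_sd: float = 1.0) -> SyntheticWorld:
    """Two gapless toy parents sharing a compact backbone, plus planted truth.

    ``conservation_fraction`` of the positions carry the identical residue in
    both parents; the rest differ. Non-conserved columns are chunked into k
    planted blocks (contiguous in column order), each with a true additive
    temperature contribution drawn uniformly from ±``delta_range`` °C.
    """
    if not 10 <= n_residues <= 500:
        raise ValueError("n_residues must be in [10, 500]")
    if not 0 < conservation_fraction < 1:
        raise ValueError("conservation_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_cons = round(conservation_fraction * n_residues)
    n_var = n_residues - n_cons
    if n_var < k:
        raise ValueError(f"only {n_var} non-conserved positions for k={k} blocks")

    conserved_positions = set(rng.choice(n_residues, size=n_cons, replace=False).tolist())
    seq1 = [AA1[int(rng.integers(20))] for _ in range(n_residues)]
    seq2 = list(seq1)
    for i in range(n_residues):
        if i not in conserved_positions:
            alternatives = [a for a in AA1 if a != seq1[i]]
            seq2[i] = alternatives[int(rng.integers(19))]

    ca = _lattice_coil(n_residues)
    # parents share all coordinates; only identities differ
    residues1 = _make_residues("".join(seq1), ca, rng)
    residues2 = [ResidueRecord(r.chain_id, r.residue_number, AA3[seq2[i]], r.heavy_atoms)
                 for i, r in enumerate(residues1)]

    p1 = ParentStructure(parent_id="P1", source=f"synthetic(seed={seed})", residues=residues1)
    p2 = ParentStructure(parent_id="P2", source=f"synthetic(seed={seed})", residues=residues2)
    alignment = ParentAlignment("".join(seq1), "".join(seq2))

    nc_cols = alignment.nonconserved_columns()
    chunks = np.array_split(np.asarray(nc_cols), k)
    raw = {int(col): b for b, chunk in enumerate(chunks) for col in chunk}
    assignment = BlockAssignment(k=k, column_to_block=_canonical_labels(raw, k))

    true_deltas = rng.uniform(-delta_range, delta_range, size=k)
    return SyntheticWorld(
        seed=seed, n_residues=n_residues, conservation_fraction=conservation_fraction,
        parent1=p1, parent2=p2, alignment=alignment, true_assignment=assignment,
        true_deltas=true_deltas, baseline=baseline, noise_sd=noise_sd,
    )


def true_trait(world: SyntheticWorld, code: Code) -> float:
    """Noise-free trait value of a code under the planted additive model."""
    return float(world.baseline
                 + sum(d for d, c in zip(world.true_deltas, code) if c == 1))


def simulate_stability(world: SyntheticWorld, codes: list[Code],
                       noise_sd: float | None = None,
                       seed: int | None = None) -> list[StabilityRecord]:
    """Simulated assay: additive block model plus Gaussian noise."""
    sd = world.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(world.seed if seed is None else seed)
    records = []
    for i, code in enumerate(codes):
        value = true_trait(world, code) + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        records.append(StabilityRecord(name=f"S{i}", code=tuple(code),
                                       t50=value, ta50=value))
    return records


def random_recombination_graph(n_nodes: int, seed: int, edge_prob: float = 0.35):
    """A random weighted graph shaped like a recombination graph.

    Nodes are column indices, edge weights are drawn from {0.5, 1.0} — the
    two values breakable contacts can carry. Used to exercise the
    partitioner against enumeration on arbitrary topologies.
    """
    import networkx as nx
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(range(1, n_nodes + 1))
    for i in range(1, n_nodes + 1):
        for j in range(i + 1, n_nodes + 1):
            if rng.random() < edge_prob:
                w = 1.0 if rng.random() < 0.5 else 0.5
                g.add_edge(i, j, weight=w, provenance="P1+P2" if w == 1.0 else "P1")
    return g


def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Write the world as standard PDB + FASTA + a parameter JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_structure(world.parent1, outdir / "parent1.pdb")
    write_structure(world.parent2, outdir / "parent2.pdb")
    write_fasta([("P1", world.alignment.parent1_row),
                 ("P2", world.alignment.parent2_row)], outdir / "alignment.fasta")
    params = {
        "seed": world.seed,
        "n_residues": world.n_residues,
        "conservation_fraction": world.conservation_fraction,
        "k": world.true_assignment.k,
        "true_deltas": world.true_deltas.tolist(),
        "baseline": world.baseline,
        "noise_sd": world.noise_sd,
    }
    (outdir / "world.json").write_text(json.dumps(params, indent=2))
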