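"""Residue contact maps and the weighted recombination graph.

Two residues are in contact when any pair of their heavy atoms is closer
than a cutoff (default 4.5 Å, strict inequality). Per-parent contacts are
lifted to alignment columns and merged: a contact between two non-conserved
columns becomes a breakable edge weighted 1.0 if both parents share it and
0.5 if only one does. Contacts touching a conserved column are not breakable
by two-parent recombination and carry no edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ColumnMap, ParentAlignment, ParentStructure

DEFAULT_CUTOFF = 4.5


@dataclass
class ContactMap:
    parent_id: str
    cutoff: float
    contacts: set[tuple[int, int]] = field(default_factory=set)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.contacts

    def __len__(self) -> int:
        return len(self.contacts)


def compute_contacts(structure: ParentStructure, cutoff: float = DEFAULT_CUTOFF) -> ContactMap:
    """All residue pairs with minimum heavy-atom distance strictly below cutoff.

    Uses a k-d tree over every heavy atom, so it scales near-linearly with
    atom count while matching the all-pairs definition exactly.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(structure) == 0:
        raise ValueError("empty structure")
    coords = []
    owner = []
    for idx, res in enumerate(structure.residues, start=1):
        for _, x, y, z in res.heavy_atoms:
            coords.append((x, y, z))
            owner.append(idx)
    xyz = np.asarray(coords)
    owner_arr = np.asarray(owner)
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    contacts: set[tuple[int, int]] = set()
    if len(pairs):
        ri = owner_arr[pairs[:, 0]]
        rj = owner_arr[pairs[:, 1]]
        # query_pairs uses <=; enforce the strict inequality
        d = np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]], axis=1)
        keep = (ri != rj) & (d < cutoff)
        lo = np.minimum(ri[keep], rj[keep])
        hi = np.maximum(ri[keep], rj[keep])
        contacts = set(zip(lo.tolist(), hi.tolist()))
    return ContactMap(parent_id=structure.parent_id, cutoff=cutoff, contacts=contacts)


def contacts_brute_force(structure: ParentStructure, cutoff: float = DEFAULT_CUTOFF) -> ContactMap:
    """Reference O(n²) implementation used as the test oracle."""
    n = len(structure)
    atom_sets = [np.array([[x, y, z] for _, x, y, z in r.heavy_atoms]) for r in structure.residues]
    contacts = set()
    for i in range(n):
        for j in range(i + 1, n):
            diff = atom_sets[i][:, None, :] - atom_sets[j][None, :, :]
            if np.min(np.linalg.norm(diff, axis=-1)) < cutoff:
                contacts.add((i + 1, j + 1))
    return ContactMap(parent_id=structure.parent_id, cutoff=cutoff, contacts=contacts)


def build_recombination_graph(cmap1: ContactMap, cmap2: ContactMap,
                              alignment: ParentAlignment,
                              map1: ColumnMap, map2: ColumnMap,
                              include_adjacent: bool = True) -> nx.Graph:
    """Merge the two parents' contact maps into the weighted breakable graph.

    Nodes are the non-conserved alignment columns (1-based). An edge joins
    two non-conserved columns when at least one parent has the residue
    contact there; its weight is 1.0 when both parents do, 0.5 otherwise.
    ``include_adjacent=False`` drops edges between sequence-adjacent columns.
    """
    conserved = alignment.conserved_mask
    g = nx.Graph()
    g.add_nodes_from(alignment.nonconserved_columns())

    lifted: dict[tuple[int, int], list[str]] = {}
    for cmap, colmap, label in ((cmap1, map1, "P1"), (cmap2, map2, "P2")):
        for (ri, rj) in cmap.contacts:
            try:
                ci = colmap.column_of(ri)
                cj = colmap.column_of(rj)
            except KeyError:
                raise ValueError(
                    f"contact ({ri},{rj}) of {cmap.parent_id} references a residue "
                    "absent from the column map"
                ) from None
            pair = (min(ci, cj), max(ci, cj))
            lifted.setdefault(pair, []).append(label)

    for (ci, cj), parents in lifted.items():
        if conserved[ci - 1] or conserved[cj - 1]:
            continue  # a conserved endpoint: the contact survives any chimera
        if not include_adjacent and cj - ci == 1:
            continue
        weight = 1.0 if len(set(parents)) == 2 else 0.5
        g.add_edge(ci, cj, weight=weight, provenance="+".join(sorted(set(parents))))
    return g


def total_weight(graph: nx.Graph) -> float:
    return float(sum(d["weight"] for _, _, d in graph.edges(data=True)))


def write_edge_list(graph: nx.Graph, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("col_i\tcol_j\tweight\tprovenance\n")
        for i, j, d in sorted(graph.edges(data=True)):
            fh.write(f"{i}\t{j}\t{d['weight']}\t{d['provenance']}\n")
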