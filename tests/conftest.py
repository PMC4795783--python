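import networkx as nx
import pytest

from ncschema import synthetic_data as sd


@pytest.fixture(scope="session")
def world():
    """Default synthetic world shared by read-only tests."""
    return sd.generate_toy_parents(n_residues=60, conservation_fraction=0.5, seed=7)


@pytest.fixture()
def toy_graph():
    """Two weight-1.0 triangles joined by a single 0.5 bridge (columns 1-6)."""
    g = nx.Graph()
    g.add_nodes_from(range(1, 7))
    for tri in ((1, 2, 3), (4, 5, 6)):
        for i in range(3):
            for j in range(i + 1, 3):
                g.add_edge(tri[i], tri[j], weight=1.0, provenance="P1+P2")
    g.add_edge(3, 4, weight=0.5, provenance="P1")
    return g


def make_pdb(path, residues):
    """Write a minimal PDB file; residues = [(resname, [(atom, elem, x, y, z), ...]), ...]."""
    lines = []
    serial = 1
    for resnum, (resname, atoms) in enumerate(residues, start=1):
        for atom, elem, x, y, z in atoms:
            name_field = atom if len(atom) == 4 else f" {atom:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name_field} {resname:>3s} A{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elem:>2s}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
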