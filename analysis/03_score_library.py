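#!/usr/bin/env python
"""Enumerate and score the full chimera library of the designed blocks.

Rebuilds the design of 02_design_blocks.py, enumerates all 2^k chimeras
with their SCHEMA energy E and mutation count m, assembles their sequences,
and picks an informative 8-chimera subset (mutually distant codes under an
E ceiling) of the kind one would send for synthesis.
"""

import json
from pathlib import Path

import numpy as np

from ncschema import block_design as bd
from ncschema import chimera_library as cl
from ncschema import contact_graph as cg
from ncschema import structure_io as sio

ROOT = Path(__file__).resolve().parents[1] / "results"
WORLD = ROOT / "world"
OUT = ROOT / "library"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    p1 = sio.load_structure(WORLD / "parent1.pdb", "A", "P1")
    p2 = sio.load_structure(WORLD / "parent2.pdb", "A", "P2")
    aln = sio.load_alignment(WORLD / "alignment.fasta")
    map1 = sio.map_columns(aln, p1, 1)
    map2 = sio.map_columns(aln, p2, 2)
    graph = cg.build_recombination_graph(
        cg.compute_contacts(p1), cg.compute_contacts(p2), aln, map1, map2)
    k = json.loads((WORLD / "world.json").read_text())["k"]
    assignment = bd.partition_blocks(graph, k=k, seed=0, restarts=20)

    library = cl.enumerate_library(assignment, graph, aln)
    cl.write_library_csv(library, str(OUT / "library.csv"))
    sio.write_fasta(((c.name, cl.assemble_sequence(c.code, assignment, aln))
                     for c in library.chimeras), OUT / "library.fasta")
    energies = [c.E for c in library.chimeras]
    print(f"library: {len(library)} chimeras, E in [{min(energies)}, {max(energies)}], "
          f"mean {np.mean(energies):.3f}")

    ceiling = float(np.percentile(energies, 60))
    n_pick = min(8, 2 ** k - 2)
    subset = cl.select_informative_subset(library, n_pick, ceiling)
    cl.write_library_csv(library, str(OUT / "subset.csv"), subset)
    print(f"informative subset (n={n_pick}, E <= {ceiling:.2f}): "
          f"{[''.join(map(str, c.code)) for c in subset]} -> {OUT}")


if __name__ == "__main__":
    main()
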