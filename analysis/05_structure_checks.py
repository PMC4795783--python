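#!/usr/bin/env python
"""Geometric checks: superposition of the two parents and polar contacts.

Superposes the synthetic parents over their Cα atoms (they share a backbone,
so the RMSD should be numerically zero — the invariant the comparison of a
solved chimera structure against its parents relies on) and reports
short-range N/O polar contacts within the more stable parent.
"""

import json
from pathlib import Path

from ncschema import structure_compare as sc
from ncschema import structure_io as sio

ROOT = Path(__file__).resolve().parents[1] / "results"
WORLD = ROOT / "world"
OUT = ROOT / "structures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    p1 = sio.load_structure(WORLD / "parent1.pdb", "A", "P1")
    p2 = sio.load_structure(WORLD / "parent2.pdb", "A", "P2")

    pairing = [(i, i) for i in range(1, min(len(p1), len(p2)) + 1)]
    result = sc.superpose(p2, p1, pairing, atoms="CA")
    (OUT / "superposition.json").write_text(json.dumps(result.to_dict(), indent=2))
    print(f"P2 onto P1: rmsd {result.rmsd:.3e} A over {result.n_atoms} CA atoms")

    queries = [(i, j) for i in range(1, len(p1) + 1)
               for j in range(i + 2, min(i + 6, len(p1) + 1))]
    contacts = sc.polar_contacts(p1, queries, cutoff=3.5)
    sc.write_polar_report(contacts, str(OUT / "polar_contacts.tsv"))
    print(f"{len(contacts)} N/O polar contacts < 3.5 A between residues 2-5 apart"
          f" -> {OUT}")
    for c in contacts[:5]:
        print(f"  {c.donor} ... {c.acceptor}  {c.distance:.2f} A")


if __name__ == "__main__":
    main()
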