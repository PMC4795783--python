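#!/usr/bin/env python
"""Generate the synthetic study system: two toy parents sharing a fold.

Writes a 60-residue pair of parent structures (identical backbone, 50% of
positions differing in identity), their gapless alignment, and the planted
4-block truth (per-block temperature contributions, baseline, noise level)
under results/world/.
"""

from pathlib import Path

from ncschema.synthetic_data import generate_toy_parents, write_world

OUT = Path(__file__).resolve().parents[1] / "results" / "world"


def main() -> None:
    world = generate_toy_parents(n_residues=60, conservation_fraction=0.5, seed=7, k=4)
    write_world(world, OUT)
    n_var = len(world.alignment.nonconserved_columns())
    print(f"synthetic world: {world.n_residues} residues, "
          f"{n_var} non-conserved columns, planted k={world.true_assignment.k}")
    print(f"true block deltas (degC): {[round(float(d), 2) for d in world.true_deltas]}")
    print(f"baseline {world.baseline} degC, noise sd {world.noise_sd} degC -> {OUT}")


if __name__ == "__main__":
    main()
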