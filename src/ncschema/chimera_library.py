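"""Chimeras: SCHEMA energy E, mutation count m, sequence assembly, subsets.

A chimera over a k-block design is a length-k parent-choice code (digits 1
or 2, block order A, B, C, ...). Its SCHEMA energy E is the total weight of
recombination-graph edges whose two endpoint blocks are taken from different
parents; m is the number of non-conserved columns at which it differs from
the closer parent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx

from .block_design import BlockAssignment
from .structure_io import GAP, ParentAlignment

Code = tuple[int, ...]


@dataclass(frozen=True)
class Chimera:
    name: str
    code: Code
    E: float
    m: int


@dataclass
class ChimeraLibrary:
    assignment: BlockAssignment
    chimeras: list[Chimera]

    def __post_init__(self) -> None:
        codes = [c.code for c in self.chimeras]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate chimera codes in library")

    def __len__(self) -> int:
        return len(self.chimeras)


def _validate_code(code: Code, k: int) -> None:
    if len(code) != k:
        raise ValueError(f"code length {len(code)} != k={k}")
    if any(c not in (1, 2) for c in code):
        raise ValueError(f"code symbols must be 1 or 2, got {code}")


def parse_code(text: str) -> Code:
    """Parse a Table-1-style code string like '1 1 2 2 1 2 1 1' or '11221211'."""
    digits = [int(ch) for ch in text if ch in "12"]
    if not digits:
        raise ValueError(f"no code digits in {text!r}")
    return tuple(digits)


def chimera_energy(code: Code, assignment: BlockAssignment, graph: nx.Graph) -> float:
    """Weighted count of contacts broken by this parent-choice code."""
    _validate_code(code, assignment.k)
    labels = assignment.labels
    choice = {lab: code[i] for i, lab in enumerate(labels)}
    e = 0.0
    for u, v, d in graph.edges(data=True):
        if choice[assignment.label_of(u)] != choice[assignment.label_of(v)]:
            e += d["weight"]
    return e


def chimera_mutations(code: Code, assignment: BlockAssignment,
                      alignment: ParentAlignment) -> int:
    """Amino-acid differences from the closest parent over non-conserved columns.

    Every non-conserved column differs between the parents, so the distance
    to a parent is the total size of the blocks taken from the other parent.
    """
    _validate_code(code, assignment.k)
    sizes = assignment.block_sizes()
    labels = assignment.labels
    to_p1 = sum(sizes[lab] for i, lab in enumerate(labels) if code[i] == 2)
    to_p2 = sum(sizes[lab] for i, lab in enumerate(labels) if code[i] == 1)
    return min(to_p1, to_p2)


def assemble_sequence(code: Code, assignment: BlockAssignment,
                      alignment: ParentAlignment) -> str:
    """Chimera amino-acid sequence implied by a parent-choice code.

    Conserved columns emit the shared residue; a non-conserved column emits
    the residue of the parent chosen for its block, and emits nothing when
    that parent has a gap there.
    """
    _validate_code(code, assignment.k)
    labels = assignment.labels
    choice = {lab: code[i] for i, lab in enumerate(labels)}
    mask = alignment.conserved_mask
    out = []
    for col in range(1, alignment.columns + 1):
        if mask[col - 1]:
            out.append(alignment.parent1_row[col - 1])
        else:
            parent = choice[assignment.label_of(col)]
            res = alignment.row(parent)[col - 1]
            if res != GAP:
                out.append(res)
    return "".join(out)


def enumerate_library(assignment: BlockAssignment, graph: nx.Graph,
                      alignment: ParentAlignment) -> ChimeraLibrary:
    """All 2^k chimeras of a design, scored for E and m."""
    k = assignment.k
    chimeras = []
    for idx, bits in enumerate(itertools.product((1, 2), repeat=k)):
        code = tuple(bits)
        chimeras.append(Chimera(
            name=f"X{idx:0{max(3, k // 3)}d}",
            code=code,
            E=chimera_energy(code, assignment, graph),
            m=chimera_mutations(code, assignment, alignment),
        ))
    return ChimeraLibrary(assignment=assignment, chimeras=chimeras)


def _min_pairwise_hamming(codes: list[Code]) -> int:
    return min(sum(a != b for a, b in zip(c1, c2))
               for c1, c2 in itertools.combinations(codes, 2))


def select_informative_subset(library: ChimeraLibrary, n: int,
                              E_ceiling: float) -> list[Chimera]:
    """Greedy pick of n chimeras that are mutually distant yet low-disruption.

    Candidates are non-parent chimeras with E ≤ E_ceiling. Picks greedily,
    maximizing the minimum pairwise code Hamming distance among the chosen
    set plus both parents; ties go to lower E, then lexicographic code.
    """
    k = library.assignment.k
    parents = [tuple([1] * k), tuple([2] * k)]
    candidates = [c for c in library.chimeras
                  if c.code not in parents and c.E <= E_ceiling]
    if n > len(library):
        raise ValueError(f"requested {n} > library size {len(library)}")
    if n >= len(library):
        return list(library.chimeras)
    if len(candidates) < n:
        raise ValueError(
            f"infeasible: only {len(candidates)} non-parent chimeras have E <= {E_ceiling}")
    chosen: list[Chimera] = []
    while len(chosen) < n:
        pool = [c for c in candidates if c not in chosen]
        scored = []
        for c in pool:
            codes = parents + [x.code for x in chosen] + [c.code]
            scored.append((-_min_pairwise_hamming(codes), c.E, c.code, c))
        scored.sort(key=lambda t: t[:3])
        chosen.append(scored[0][3])
    return chosen


def write_library_csv(library: ChimeraLibrary, path: str,
                      chimeras: list[Chimera] | None = None) -> None:
    rows = chimeras if chimeras is not None else library.chimeras
    with open(path, "w") as fh:
        fh.write("name," + ",".join(f"block_{lab}" for lab in library.assignment.labels)
                 + ",E,m\n")
        for c in rows:
            fh.write(f"{c.name}," + ",".join(map(str, c.code)) + f",{c.E},{c.m}\n")
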