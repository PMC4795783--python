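"""Noncontiguous block design by weighted graph partitioning.

The recombination graph's non-conserved columns are split into k blocks so
that the total weight of inter-block edges (the cut) is small. For a
two-parent library every inter-block edge is broken in exactly half of the
2^k chimeras, so the library mean SCHEMA energy is ⟨E⟩ = cut/2 — minimizing
the cut minimizes ⟨E⟩.

The partitioner is a multi-restart recursive bisection with Kernighan–Lin
refinement and a final single-node move pass, a stand-in for the external
hMETIS package used historically for this problem. An exhaustive enumerator
is provided as the optimality oracle for small graphs.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .structure_io import ParentAlignment

SHARED = "shared"


@dataclass
class BlockAssignment:
    """column -> block label for every non-conserved alignment column."""

    k: int
    column_to_block: dict[int, str]

    def __post_init__(self) -> None:
        labels = set(self.column_to_block.values())
        if len(labels) != self.k:
            raise ValueError(f"expected {self.k} non-empty blocks, found {len(labels)}")

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.column_to_block.values()))

    def blocks(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {lab: [] for lab in self.labels}
        for col, lab in sorted(self.column_to_block.items()):
            out[lab].append(col)
        return out

    def block_sizes(self) -> dict[str, int]:
        return {lab: len(cols) for lab, cols in self.blocks().items()}

    def label_of(self, column: int) -> str:
        """Block label of a column; conserved columns report ``shared``."""
        return self.column_to_block.get(column, SHARED)


@dataclass
class DesignSummary:
    mean_E: float
    mean_m: float
    cut_weight: float
    block_sizes: dict[str, int]


def _size_targets(n: int, k: int) -> list[int]:
    base, rem = divmod(n, k)
    return [base + 1] * rem + [base] * (k - rem)


def _check_balance(sizes, n, k, tol) -> bool:
    lo, hi = (1 - tol) * n / k, (1 + tol) * n / k
    return all(lo <= s <= hi for s in sizes)


def _cut_weight(graph: nx.Graph, labels: dict[int, str]) -> float:
    return float(sum(d["weight"] for u, v, d in graph.edges(data=True)
                     if labels[u] != labels[v]))


def _canonical_labels(assignment: dict[int, int | str], k: int) -> dict[int, str]:
    """Relabel blocks A, B, ... in order of each block's smallest column."""
    firsts: dict[int | str, int] = {}
    for col in sorted(assignment):
        firsts.setdefault(assignment[col], col)
    order = sorted(firsts, key=firsts.get)
    rename = {old: string.ascii_uppercase[i] for i, old in enumerate(order)}
    return {col: rename[b] for col, b in assignment.items()}


def _swap_refine(graph: nx.Graph, part_a: set[int], part_b: set[int],
                 max_passes: int = 20) -> None:
    """Kernighan–Lin-style refinement by pairwise swaps, sizes held fixed.

    Repeatedly applies the best cut-reducing swap of one node from each side
    until no improving swap exists. Swaps keep both part sizes exactly as
    given, so uneven splits (needed for odd k) stay valid.
    """
    side = {v: 0 for v in part_a}
    side.update({v: 1 for v in part_b})

    def d_value(v: int) -> float:  # external minus internal cost
        ext = int_ = 0.0
        for _, u, d in graph.edges(v, data=True):
            if u not in side:
                continue
            if side[u] == side[v]:
                int_ += d["weight"]
            else:
                ext += d["weight"]
        return ext - int_

    for _ in range(max_passes):
        best_gain, best_pair = 1e-12, None
        dvals = {v: d_value(v) for v in side}
        for u in part_a:
            for v in part_b:
                w_uv = graph[u][v]["weight"] if graph.has_edge(u, v) else 0.0
                gain = dvals[u] + dvals[v] - 2 * w_uv
                if gain > best_gain:
                    best_gain, best_pair = gain, (u, v)
        if best_pair is None:
            return
        u, v = best_pair
        part_a.remove(u); part_a.add(v)
        part_b.remove(v); part_b.add(u)
        side[u], side[v] = 1, 0


def _bisect(graph: nx.Graph, nodes: list[int], n_left: int,
            rng: np.random.Generator) -> tuple[list[int], list[int]]:
    """Split ``nodes`` into parts of size (n_left, rest) with small cut."""
    perm = list(nodes)
    rng.shuffle(perm)
    part_a, part_b = set(perm[:n_left]), set(perm[n_left:])
    if not part_b:
        return sorted(part_a), []
    _swap_refine(graph, part_a, part_b)
    return sorted(part_a), sorted(part_b)


def _recursive_partition(graph: nx.Graph, nodes: list[int], k: int,
                         rng: np.random.Generator) -> dict[int, int]:
    if k == 1:
        return {v: 0 for v in nodes}
    targets = _size_targets(len(nodes), k)
    k_left = k // 2
    n_left = sum(targets[:k_left])
    left, right = _bisect(graph, nodes, n_left, rng)
    out = _recursive_partition(graph, left, k_left, rng)
    shift = max(out.values(), default=-1) + 1
    for v, b in _recursive_partition(graph, right, k - k_left, rng).items():
        out[v] = b + shift
    return out


def _move_refine(graph: nx.Graph, labels: dict[int, int], k: int, tol: float,
                 max_passes: int = 20) -> dict[int, int]:
    """k-way refinement: greedy single-node moves, then pairwise swaps.

    Single moves obey the balance bounds; swaps trade one node between two
    blocks, so they always keep sizes and can escape move-local optima.
    """
    n = graph.number_of_nodes()
    sizes = {b: 0 for b in range(k)}
    for b in labels.values():
        sizes[b] += 1
    lo = (1 - tol) * n / k
    hi = (1 + tol) * n / k

    def affinity(v: int, block: int) -> float:
        return sum(d["weight"] for _, u, d in graph.edges(v, data=True)
                   if labels[u] == block)

    nodes = sorted(graph.nodes)
    for _ in range(max_passes):
        improved = False
        for v in nodes:
            here = labels[v]
            best_b, best_gain = here, affinity(v, here)
            for b in {labels[u] for u in graph.neighbors(v)} - {here}:
                if sizes[here] - 1 < lo or sizes[b] + 1 > hi:
                    continue
                gain = affinity(v, b)
                if gain > best_gain + 1e-12:
                    best_b, best_gain = b, gain
            if best_b != here:
                labels[v] = best_b
                sizes[here] -= 1
                sizes[best_b] += 1
                improved = True
        if improved:
            continue
        # no single move helps: try the best balance-preserving swap
        best_swap, best_gain = None, 1e-12
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                bu, bv = labels[u], labels[v]
                if bu == bv:
                    continue
                w_uv = graph[u][v]["weight"] if graph.has_edge(u, v) else 0.0
                gain = (affinity(u, bv) - affinity(u, bu)
                        + affinity(v, bu) - affinity(v, bv) - 2 * w_uv)
                if gain > best_gain:
                    best_gain, best_swap = gain, (u, v)
        if best_swap is None:
            break
        u, v = best_swap
        labels[u], labels[v] = labels[v], labels[u]
    return labels


def partition_blocks(graph: nx.Graph, k: int, balance_tolerance: float = 0.3,
                     seed: int = 0, restarts: int = 20) -> BlockAssignment:
    """k-way minimum-cut partition of the recombination graph.

    Runs ``restarts`` independent recursive bisections (each refined by
    Kernighan–Lin and then by greedy node moves) and keeps the smallest cut;
    ties go to the lexicographically smallest canonical label vector.
    Deterministic for a given seed.
    """
    n = graph.number_of_nodes()
    if n < k:
        raise ValueError(f"cannot split {n} nodes into {k} blocks")
    if not 0 <= balance_tolerance < 1:
        raise ValueError("balance_tolerance must be in [0, 1)")
    if not _check_balance(_size_targets(n, k), n, k, balance_tolerance):
        raise ValueError("infeasible balance constraint for this n and k")
    nodes = sorted(graph.nodes)
    rng = np.random.default_rng(seed)
    best: tuple[float, tuple[str, ...], dict[int, str]] | None = None
    for _ in range(max(1, restarts)):
        raw = _recursive_partition(graph, nodes, k, rng)
        raw = _move_refine(graph, raw, k, balance_tolerance)
        sizes = list(np.bincount([raw[v] for v in nodes], minlength=k))
        if not _check_balance(sizes, n, k, balance_tolerance) or min(sizes) == 0:
            continue
        labels = _canonical_labels(raw, k)
        cut = _cut_weight(graph, labels)
        key = (cut, tuple(labels[v] for v in nodes))
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], labels)
    if best is None:
        raise ValueError("no balanced partition found; relax balance_tolerance")
    return BlockAssignment(k=k, column_to_block=best[2])


def exhaustive_partition(graph: nx.Graph, k: int,
                         balance_tolerance: float = 0.3) -> BlockAssignment:
    """Globally minimum-cut balanced k-partition by enumeration (n ≤ 14)."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n > 14:
        raise ValueError("exhaustive enumeration limited to 14 nodes")
    if n < k:
        raise ValueError(f"cannot split {n} nodes into {k} blocks")
    edges = [(nodes.index(u), nodes.index(v), d["weight"])
             for u, v, d in graph.edges(data=True)]
    lo = (1 - balance_tolerance) * n / k
    hi = (1 + balance_tolerance) * n / k

    best_cut = np.inf
    best_assign: list[int] | None = None
    # restricted-growth strings: canonical set partitions into exactly k blocks
    def rec(i: int, assign: list[int], used: int, sizes: list[int]) -> None:
        nonlocal best_cut, best_assign
        if i == n:
            if used == k and all(lo <= s <= hi for s in sizes[:k]):
                cut = sum(w for a, b, w in edges if assign[a] != assign[b])
                key = (cut, tuple(assign))
                if key < (best_cut, tuple(best_assign or [k + 1])):
                    best_cut, best_assign = cut, list(assign)
            return
        if used + (n - i) < k:  # cannot open enough blocks anymore
            return
        for b in range(min(used + 1, k)):
            if sizes[b] + 1 > hi:
                continue
            assign.append(b)
            sizes[b] += 1
            rec(i + 1, assign, max(used, b + 1), sizes)
            sizes[b] -= 1
            assign.pop()

    rec(0, [], 0, [0] * k)
    if best_assign is None:
        raise ValueError("no balanced partition exists under this tolerance")
    labels = _canonical_labels({nodes[i]: best_assign[i] for i in range(n)}, k)
    return BlockAssignment(k=k, column_to_block=labels)


def cut_weight(graph: nx.Graph, assignment: BlockAssignment) -> float:
    return _cut_weight(graph, assignment.column_to_block)


def summarize_design(assignment: BlockAssignment, graph: nx.Graph,
                     alignment: ParentAlignment) -> DesignSummary:
    """Library-average ⟨E⟩ and ⟨m⟩ of a block design.

    ⟨E⟩ uses the two-parent closed form cut/2. ⟨m⟩ enumerates all 2^k codes:
    a chimera's distance to a parent is the total size of the blocks taken
    from the other parent (every non-conserved column differs between the
    parents by definition), and m is the distance to the closer parent.
    """
    cut = cut_weight(graph, assignment)
    labels = assignment.labels
    sizes = np.array([assignment.block_sizes()[lab] for lab in labels], float)
    k = assignment.k
    codes = (np.arange(2 ** k)[:, None] >> np.arange(k)) & 1  # 1 = block from P1
    m_to_p1 = (1 - codes) @ sizes
    m_to_p2 = codes @ sizes
    mean_m = float(np.minimum(m_to_p1, m_to_p2).mean())
    return DesignSummary(mean_E=cut / 2.0, mean_m=mean_m, cut_weight=cut,
                         block_sizes=assignment.block_sizes())


def random_balanced_partition(graph: nx.Graph, k: int, rng: np.random.Generator) -> BlockAssignment:
    """A uniformly random partition with near-equal block sizes (baseline)."""
    nodes = sorted(graph.nodes)
    perm = list(nodes)
    rng.shuffle(perm)
    targets = _size_targets(len(nodes), k)
    assign: dict[int, int] = {}
    pos = 0
    for b, t in enumerate(targets):
        for v in perm[pos:pos + t]:
            assign[v] = b
        pos += t
    return BlockAssignment(k=k, column_to_block=_canonical_labels(assign, k))


def write_assignment(assignment: BlockAssignment, alignment: ParentAlignment,
                     map1, map2, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("column\tparent1_residue\tparent2_residue\tblock_label\n")
        for col in range(1, alignment.columns + 1):
            r1 = map1.residue_at(col)
            r2 = map2.residue_at(col)
            fh.write(f"{col}\t{r1 if r1 else '.'}\t{r2 if r2 else '.'}\t"
                     f"{assignment.label_of(col)}\n")
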