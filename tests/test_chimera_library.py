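"""Chimera scoring (E, m), sequence assembly and subset selection."""

import itertools

import numpy as np
import pytest

from ncschema import block_design as bd
from ncschema import chimera_library as cl
from ncschema import structure_io as sio
from ncschema.synthetic_data import random_recombination_graph


@pytest.fixture()
def design(toy_graph):
    """k=2 assignment on the two-triangle graph, with a matching alignment."""
    assignment = bd.partition_blocks(toy_graph, k=2, seed=0)
    n_cols = 8  # columns 7,8 conserved
    row1 = list("AAAAAAAA")
    row2 = list("GGGGGGAA")
    aln = sio.ParentAlignment("".join(row1), "".join(row2))
    return assignment, toy_graph, aln


class TestChimeraEnergy:
    def test_parents_have_zero_energy(self, design):
        assignment, graph, _ = design
        assert cl.chimera_energy((1, 1), assignment, graph) == 0.0
        assert cl.chimera_energy((2, 2), assignment, graph) == 0.0

    def test_crossing_the_bridge_costs_its_weight(self, design):
        assignment, graph, _ = design
        assert cl.chimera_energy((1, 2), assignment, graph) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_edge_scan_oracle(self, seed):
        g = random_recombination_graph(10, seed=300 + seed)
        a = bd.partition_blocks(g, k=3, seed=seed)
        rng = np.random.default_rng(seed)
        code = tuple(rng.choice([1, 2], size=3).tolist())
        choice = {lab: code[i] for i, lab in enumerate(a.labels)}
        expected = sum(d["weight"] for u, v, d in g.edges(data=True)
                       if choice[a.label_of(u)] != choice[a.label_of(v)])
        assert cl.chimera_energy(code, a, g) == pytest.approx(expected)

    def test_complement_symmetry(self, design):
        assignment, graph, _ = design
        for code in itertools.product((1, 2), repeat=2):
            comp = tuple(3 - c for c in code)
            assert (cl.chimera_energy(code, assignment, graph)
                    == cl.chimera_energy(comp, assignment, graph))

    def test_bad_code_rejected(self, design):
        assignment, graph, _ = design
        with pytest.raises(ValueError, match="1 or 2"):
            cl.chimera_energy((1, 3), assignment, graph)


class TestChimeraMutations:
    def test_parents_have_zero_m(self, design):
        assignment, _, aln = design
        assert cl.chimera_mutations((1, 1), assignment, aln) == 0
        assert cl.chimera_mutations((2, 2), assignment, aln) == 0

    def test_single_swapped_block_counts_its_columns(self, design):
        assignment, _, aln = design
        sizes = assignment.block_sizes()
        m = cl.chimera_mutations((2, 1), assignment, aln)
        assert m == min(sizes["A"], sizes["B"] )  # closest parent: min of swap sizes

    def test_complement_symmetry(self, design):
        assignment, _, aln = design
        for code in itertools.product((1, 2), repeat=2):
            comp = tuple(3 - c for c in code)
            assert (cl.chimera_mutations(code, assignment, aln)
                    == cl.chimera_mutations(comp, assignment, aln))

    def test_column_count_oracle(self):
        """m equals a per-column diff against the closer parent's sequence."""
        g = random_recombination_graph(9, seed=17)
        row1 = "".join("A" for _ in range(11))
        row2 = "".join("G" if c + 1 in g.nodes else "A" for c in range(11))
        aln = sio.ParentAlignment(row1, row2)
        a = bd.partition_blocks(g, k=3, seed=2)
        for code in itertools.product((1, 2), repeat=3):
            seq = cl.assemble_sequence(code, a, aln)
            d1 = sum(x != y for x, y in zip(seq, row1))
            d2 = sum(x != y for x, y in zip(seq, row2))
            assert cl.chimera_mutations(code, a, aln) == min(d1, d2)


class TestAssembleSequence:
    def test_all_parent_codes_reproduce_parents(self, design):
        assignment, _, aln = design
        assert cl.assemble_sequence((1, 1), assignment, aln) == aln.ungapped(1)
        assert cl.assemble_sequence((2, 2), assignment, aln) == aln.ungapped(2)

    def test_swapped_block_differs_exactly_there(self, design):
        assignment, _, aln = design
        seq = cl.assemble_sequence((2, 1), assignment, aln)
        block_a_cols = set(assignment.blocks()["A"])
        for col in range(1, aln.columns + 1):
            expect = aln.parent2_row[col - 1] if col in block_a_cols else aln.parent1_row[col - 1]
            assert seq[col - 1] == expect

    def test_gap_handling_bounds_length(self):
        # parent 2 has a gap at column 2: choosing P2 there shortens the chimera
        aln = sio.ParentAlignment("AGA", "A-G")
        a = bd.BlockAssignment(k=2, column_to_block={2: "A", 3: "B"})
        lengths = {len(cl.assemble_sequence(code, a, aln))
                   for code in itertools.product((1, 2), repeat=2)}
        assert min(lengths) >= len(aln.ungapped(2))
        assert max(lengths) <= len(aln.ungapped(1))


class TestEnumerateLibrary:
    def test_size_and_uniqueness(self, design):
        assignment, graph, aln = design
        lib = cl.enumerate_library(assignment, graph, aln)
        assert len(lib) == 4
        assert len({c.code for c in lib.chimeras}) == 4

    def test_mean_E_ties_to_design_summary(self, design):
        assignment, graph, aln = design
        lib = cl.enumerate_library(assignment, graph, aln)
        summary = bd.summarize_design(assignment, graph, aln)
        assert np.mean([c.E for c in lib.chimeras]) == pytest.approx(summary.mean_E)


class TestSelectInformativeSubset:
    def _library(self, k=3, seed=4):
        g = random_recombination_graph(12, seed=seed)
        aln_row2 = "".join("G" if c + 1 in g.nodes else "A" for c in range(14))
        aln = sio.ParentAlignment("A" * 14, aln_row2)
        a = bd.partition_blocks(g, k=k, seed=0)
        return cl.enumerate_library(a, g, aln)

    def test_full_request_returns_everything(self):
        lib = self._library()
        assert cl.select_informative_subset(lib, len(lib), np.inf) == lib.chimeras

    def test_infeasible_ceiling(self):
        lib = self._library()
        nonparent_min_E = min(c.E for c in lib.chimeras if 0 < c.E)
        with pytest.raises(ValueError, match="infeasible"):
            cl.select_informative_subset(lib, 3, E_ceiling=nonparent_min_E - 0.25)

    def test_greedy_matches_exhaustive_for_pairs(self):
        """For n=2 the greedy min-pairwise-Hamming equals the exhaustive optimum."""
        lib = self._library()
        chosen = cl.select_informative_subset(lib, 2, np.inf)
        k = lib.assignment.k
        parents = [tuple([1] * k), tuple([2] * k)]
        pool = [c for c in lib.chimeras if c.code not in parents]

        def min_ham(pair):
            codes = parents + [c.code for c in pair]
            return min(sum(a != b for a, b in zip(x, y))
                       for x, y in itertools.combinations(codes, 2))

        best = max(min_ham(p) for p in itertools.combinations(pool, 2))
        assert min_ham(chosen) == best

    def test_ceiling_respected(self):
        lib = self._library()
        ceiling = float(np.median([c.E for c in lib.chimeras]))
        chosen = cl.select_informative_subset(lib, 2, ceiling)
        assert all(c.E <= ceiling for c in chosen)


def test_parse_code_formats():
    assert cl.parse_code("1 1 2 2 1 2 1 1") == (1, 1, 2, 2, 1, 2, 1, 1)
    assert cl.parse_code("11221211") == (1, 1, 2, 2, 1, 2, 1, 1)
    with pytest.raises(ValueError):
        cl.parse_code("no digits")
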