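"""Graph container, edge-list I/O, degree-pair partitions and fixture generators."""

import pytest

from banhatti import (
    EdgePartition,
    GraphValidationError,
    MolecularGraph,
    PartitionError,
    nbo2_partition,
    partition_to_graph,
    random_bounded_degree_graph,
    read_edge_list,
    read_partition_csv,
    validate_handshake,
    write_edge_list,
    write_partition_csv,
)


def triangle():
    return MolecularGraph.from_edges([("a", "b"), ("b", "c"), ("c", "a")])


def star4():
    return MolecularGraph.from_edges([("hub", f"leaf{i}") for i in range(4)])


class TestEdgeListIO:
    def test_path_graph_degrees(self, tmp_path):
        f = tmp_path / "g.edges"
        f.write_text("a b\nb c  # a comment\n# full comment line\n")
        g = read_edge_list(f)
        assert g.degrees() == {"a": 1, "b": 2, "c": 1}
        assert g.num_edges == 2

    def test_duplicate_lines_are_parallel_edges(self, tmp_path):
        f = tmp_path / "g.edges"
        f.write_text("a b\na b\n")
        g = read_edge_list(f)
        assert g.num_edges == 2
        assert g.degree("a") == 2
        assert not g.is_simple()

    def test_self_loop_rejected_with_line_number(self, tmp_path):
        f = tmp_path / "bad.edges"
        f.write_text("a b\na a\n")
        with pytest.raises(GraphValidationError, match=r":2:"):
            read_edge_list(f)

    def test_malformed_line_names_line_number(self, tmp_path):
        f = tmp_path / "bad.edges"
        f.write_text("a b\na b c\n")
        with pytest.raises(GraphValidationError, match=r":2:.*two vertex tokens"):
            read_edge_list(f)

    def test_round_trip(self, tmp_path):
        g = triangle()
        f = tmp_path / "tri.edges"
        write_edge_list(g, f)
        assert read_edge_list(f).edges == g.edges


class TestPartitionCSV:
    def test_round_trip(self, tmp_path, nbo2_22):
        f = tmp_path / "p.csv"
        write_partition_csv(nbo2_22, f)
        assert read_partition_csv(f) == nbo2_22

    def test_bad_header(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text("x,y,z\n1,2,3\n")
        with pytest.raises(PartitionError, match="header"):
            read_partition_csv(f)


class TestEdgePartition:
    def test_pairs_canonicalized_min_max(self):
        p = EdgePartition({(4, 3): 2, (3, 4): 1})
        assert dict(p.items()) == {(3, 4): 3}

    def test_negative_count_rejected(self):
        with pytest.raises(PartitionError):
            EdgePartition({(2, 3): -1})

    def test_zero_classes_dropped_by_canonical(self):
        p = EdgePartition({(2, 3): 5, (4, 4): 0})
        assert (4, 4) in p.classes
        assert (4, 4) not in p.canonical().classes
        assert p == p.canonical()  # equality ignores zero classes


class TestDegreePairPartition:
    def test_triangle(self):
        assert triangle().degree_pair_partition() == EdgePartition({(2, 2): 3})

    def test_star(self):
        assert star4().degree_pair_partition() == EdgePartition({(1, 4): 4})

    def test_sum_identity_against_edge_enumeration(self, random_fixture):
        """Partition-weighted degree sums must equal per-edge enumeration."""
        g = random_fixture
        part = g.degree_pair_partition()
        assert part.edge_total == g.num_edges
        via_part = sum(c * (d1 + d2) for (d1, d2), c in part.items())
        via_edges = sum(g.degree(u) + g.degree(v) for u, v in g.edges)
        assert via_part == via_edges

    def test_invariant_under_relabeling(self, random_fixture):
        mapping = {v: f"x{i}" for i, v in enumerate(reversed(random_fixture.vertices))}
        relabeled = random_fixture.relabeled(mapping)
        assert relabeled.degree_pair_partition() == random_fixture.degree_pair_partition()


class TestHandshake:
    def test_path_of_three(self):
        g = MolecularGraph.from_edges([("a", "b"), ("b", "c")])
        rep = validate_handshake(g)
        assert rep.passed and rep.degree_sum == 4 and rep.twice_edges == 4

    def test_nbo2_22_degree_classes_vs_88_edges(self):
        # 8 atoms of valency 2, 40 of valency 3, 10 of valency 4 vs 88 bonds
        assert 8 * 2 + 40 * 3 + 10 * 4 == 2 * nbo2_partition(2, 2).edge_total == 176


class TestPartitionToGraph:
    def test_single_edge(self):
        g = partition_to_graph(EdgePartition({(1, 1): 1}), seed=0)
        assert g.num_edges == 1 and sorted(g.degrees().values()) == [1, 1]

    def test_two_regular_class(self):
        g = partition_to_graph(EdgePartition({(2, 2): 3}), seed=1)
        assert g.degree_pair_partition() == EdgePartition({(2, 2): 3})
        assert set(g.degrees().values()) == {2}

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_nbo2_11_round_trip_under_seed_sweep(self, seed):
        target = nbo2_partition(1, 1)
        g = partition_to_graph(target, seed=seed)
        assert g.degree_pair_partition() == target
        assert g.num_edges == 28
        assert validate_handshake(g).passed

    def test_nbo2_22_fixture_round_trips_through_edge_list(self, tmp_path, nbo2_22):
        g = partition_to_graph(nbo2_22, seed=3)
        f = tmp_path / "nbo2_22.edges"
        write_edge_list(g, f)
        assert read_edge_list(f).degree_pair_partition() == nbo2_22

    def test_infeasible_odd_stubs(self):
        # one (2,3) edge leaves a lone degree-2 stub: no graph exists
        with pytest.raises(PartitionError, match="infeasible"):
            partition_to_graph(EdgePartition({(2, 3): 1}), seed=0)

    def test_empty_partition_rejected(self):
        with pytest.raises(PartitionError):
            partition_to_graph(EdgePartition({}), seed=0)


class TestRandomBoundedDegreeGraph:
    def test_deterministic_for_fixed_seed(self):
        a = random_bounded_degree_graph(60, 4, 7)
        b = random_bounded_degree_graph(60, 4, 7)
        assert a.edges == b.edges

    def test_tiny_case_at_most_one_edge(self):
        assert random_bounded_degree_graph(2, 1, 5).num_edges <= 1

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_degree_bound_and_handshake(self, seed):
        g = random_bounded_degree_graph(60, 4, seed)
        assert max(g.degrees().values()) <= 4
        assert g.is_simple()
        assert validate_handshake(g).passed


def test_mol_reader_heavy_atom_degrees(tmp_path):
    """MDL MOL bond block -> heavy-atom connection counts (H suppressed)."""
    rdkit = pytest.importorskip("rdkit")  # noqa: F841
    # propan-2-ol heavy-atom skeleton: C-C(-O)-C
    mol = "\n".join([
        "isopropanol", "  test", "",
        "  4  3  0  0  0  0  0  0  0  0999 V2000",
        "    0.0000    0.0000    0.0000 C   0  0",
        "    1.0000    0.0000    0.0000 C   0  0",
        "    2.0000    0.0000    0.0000 C   0  0",
        "    1.0000    1.0000    0.0000 O   0  0",
        "  1  2  1  0", "  2  3  1  0", "  2  4  1  0",
        "M  END", "",
    ])
    f = tmp_path / "mol.mol"
    f.write_text(mol)
    from banhatti import read_mol

    g = read_mol(f)
    assert g.num_edges == 3
    assert g.degree_pair_partition() == EdgePartition({(1, 3): 3})
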