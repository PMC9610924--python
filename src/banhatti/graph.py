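"""Molecular-graph data model and degree-pair edge partitions.

Every descriptor in this package is a linear functional of the *degree-pair
edge partition* of a graph: the grouping of edges by the unordered pair of
endpoint degrees (atom valencies).  This module provides the graph container,
the partition container, plain-text I/O for both, and two fixture generators —
a configuration-model realizer that builds a graph with a prescribed partition,
and a seeded bounded-degree random graph.

Vertices are opaque strings.  Parallel edges are allowed (the configuration
model may need them); self-loops are always rejected.  No geometry, element
types or bond orders are modelled: all quantities downstream depend only on
endpoint degrees.
"""

from __future__ import annotations

import csv
import random
from collections.abc import Hashable, Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

__all__ = [
    "GraphValidationError",
    "PartitionError",
    "RealizationError",
    "MolecularGraph",
    "EdgePartition",
    "HandshakeReport",
    "read_edge_list",
    "write_edge_list",
    "read_partition_csv",
    "write_partition_csv",
    "read_mol",
    "degree_pair_partition",
    "validate_handshake",
    "partition_to_graph",
    "random_bounded_degree_graph",
]


class GraphValidationError(ValueError):
    """A graph or an edge-list file violates the data model."""


class PartitionError(ValueError):
    """An edge partition is malformed or infeasible."""


class RealizationError(RuntimeError):
    """No graph realizing the requested partition was found in the attempt budget."""


class MolecularGraph:
    """Undirected multigraph of atoms (opaque string IDs) and bonds.

    Thin wrapper around :class:`networkx.MultiGraph` that enforces the
    no-self-loop invariant and exposes the degree bookkeeping the descriptor
    layer needs.
    """

    def __init__(self) -> None:
        self._g = nx.MultiGraph()

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[Hashable, Hashable]]) -> "MolecularGraph":
        graph = cls()
        for u, v in edges:
            graph.add_edge(u, v)
        return graph

    def add_vertex(self, v: Hashable) -> None:
        self._g.add_node(str(v))

    def add_edge(self, u: Hashable, v: Hashable) -> None:
        u, v = str(u), str(v)
        if u == v:
            raise GraphValidationError(f"self-loop rejected: ({u!r}, {v!r})")
        self._g.add_edge(u, v)

    @property
    def vertices(self) -> list[str]:
        return sorted(self._g.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Edge multiset as a list of sorted vertex pairs."""
        return sorted(tuple(sorted((u, v))) for u, v, _ in self._g.edges(keys=True))

    @property
    def num_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def num_edges(self) -> int:
        return self._g.number_of_edges()

    def degree(self, v: Hashable) -> int:
        return self._g.degree(str(v))

    def degrees(self) -> dict[str, int]:
        return {v: self._g.degree(v) for v in self._g.nodes}

    def is_simple(self) -> bool:
        """True if no parallel edges are present."""
        return len(set(self.edges)) == self.num_edges

    def relabeled(self, mapping: Mapping[str, str]) -> "MolecularGraph":
        out = MolecularGraph()
        out._g = nx.relabel_nodes(self._g, dict(mapping), copy=True)
        return out

    def degree_pair_partition(self) -> "EdgePartition":
        counts: dict[tuple[int, int], int] = {}
        for u, v, _ in self._g.edges(keys=True):
            pair = tuple(sorted((self._g.degree(u), self._g.degree(v))))
            counts[pair] = counts.get(pair, 0) + 1
        return EdgePartition(counts)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MolecularGraph(|V|={self.num_vertices}, |E|={self.num_edges})"


@dataclass(frozen=True)
class EdgePartition:
    """Map from unordered endpoint-degree pair ``(d1 <= d2)`` to an edge count.

    The central computational object: every index and entropy downstream is a
    sum of ``count * f(d1, d2)`` over the classes stored here.  Pairs are
    canonicalized as ``(min, max)``; zero-count classes are permitted but
    dropped by :meth:`canonical`.
    """

    classes: Mapping[tuple[int, int], int]

    def __post_init__(self) -> None:
        norm: dict[tuple[int, int], int] = {}
        for (d1, d2), count in dict(self.classes).items():
            d1, d2 = int(d1), int(d2)
            count = int(count)
            if d1 < 1 or d2 < 1:
                raise PartitionError(f"degrees must be positive, got ({d1},{d2})")
            if count < 0:
                raise PartitionError(f"negative count {count} for class ({d1},{d2})")
            key = (min(d1, d2), max(d1, d2))
            norm[key] = norm.get(key, 0) + count
        object.__setattr__(self, "classes", norm)

    @property
    def edge_total(self) -> int:
        return sum(self.classes.values())

    def items(self) -> list[tuple[tuple[int, int], int]]:
        return sorted(self.classes.items())

    def canonical(self) -> "EdgePartition":
        """Drop zero-count classes."""
        return EdgePartition({k: c for k, c in self.classes.items() if c > 0})

    def scaled(self, k: int) -> "EdgePartition":
        if k < 0:
            raise PartitionError("scale factor must be non-negative")
        return EdgePartition({pair: c * k for pair, c in self.classes.items()})

    def merged(self, other: "EdgePartition") -> "EdgePartition":
        out = dict(self.classes)
        for pair, c in other.classes.items():
            out[pair] = out.get(pair, 0) + c
        return EdgePartition(out)

    def degree_endpoint_counts(self) -> dict[int, int]:
        """Endpoint slots per degree: degree d appears once per incidence."""
        slots: dict[int, int] = {}
        for (d1, d2), c in self.classes.items():
            slots[d1] = slots.get(d1, 0) + c
            slots[d2] = slots.get(d2, 0) + c
        return slots

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EdgePartition):
            return NotImplemented
        return self.canonical().classes == other.canonical().classes

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.canonical().classes.items())))


@dataclass(frozen=True)
class HandshakeReport:
    """Both sides of the handshake identity sum(deg) = 2|E| for one graph."""

    degree_sum: int
    twice_edges: int

    @property
    def passed(self) -> bool:
        return self.degree_sum == self.twice_edges


def read_edge_list(path: str | Path) -> MolecularGraph:
    """Read a UTF-8 edge-list file: one edge per line, two whitespace-separated
    vertex tokens, ``#`` starts a comment.  Duplicate lines create parallel
    edges (multiset semantics)."""
    graph = MolecularGraph()
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise GraphValidationError(
                    f"{path}:{lineno}: expected two vertex tokens, got {len(tokens)}: {raw.strip()!r}"
                )
            try:
                graph.add_edge(*tokens)
            except GraphValidationError as exc:
                raise GraphValidationError(f"{path}:{lineno}: {exc}") from exc
    return graph


def write_edge_list(graph: MolecularGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for u, v in graph.edges:
            handle.write(f"{u} {v}\n")


def read_partition_csv(path: str | Path) -> EdgePartition:
    """Read a partition CSV with header ``d1,d2,count``."""
    counts: dict[tuple[int, int], int] = {}
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        expected = {"d1", "d2", "count"}
        if reader.fieldnames is None or not expected.issubset(reader.fieldnames):
            raise PartitionError(f"{path}: expected header d1,d2,count")
        for row in reader:
            pair = (int(row["d1"]), int(row["d2"]))
            counts[tuple(sorted(pair))] = counts.get(tuple(sorted(pair)), 0) + int(row["count"])
    return EdgePartition(counts)


def write_partition_csv(partition: EdgePartition, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["d1", "d2", "count"])
        for (d1, d2), count in partition.items():
            writer.writerow([d1, d2, count])


def read_mol(path: str | Path) -> MolecularGraph:
    """Read an MDL MOL/SDF connection table (first record) into a graph.

    Degrees are heavy-atom connection counts from the bond block: hydrogens
    are suppressed and bond orders ignored.  Requires rdkit.
    """
    from rdkit import Chem  # local import: optional dependency

    mol = Chem.MolFromMolFile(str(path), sanitize=False, removeHs=True)
    if mol is None:
        raise GraphValidationError(f"{path}: not a parseable MOL/SDF connection table")
    graph = MolecularGraph()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 1:
            graph.add_vertex(f"a{atom.GetIdx()}")
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() == 1 or b.GetAtomicNum() == 1:
            continue
        graph.add_edge(f"a{a.GetIdx()}", f"a{b.GetIdx()}")
    return graph


def degree_pair_partition(graph: MolecularGraph) -> EdgePartition:
    """Group every edge by its unordered endpoint-degree pair."""
    return graph.degree_pair_partition()


def validate_handshake(graph: MolecularGraph) -> HandshakeReport:
    """Certify the handshake lemma sum(deg) = 2|E| on a concrete graph."""
    return HandshakeReport(
        degree_sum=sum(graph.degrees().values()),
        twice_edges=2 * graph.num_edges,
    )


def partition_to_graph(
    partition: EdgePartition,
    seed: int,
    max_attempts: int = 1000,
) -> MolecularGraph:
    """Realize a degree-pair partition as a concrete graph, or fail detectably.

    Uses a configuration-model-style pairing constrained to the requested
    degree pairs: the endpoint-slot count of each degree d must be divisible
    by d (fixing the number of degree-d vertices), then each edge of class
    (d1, d2) consumes one free stub on a degree-d1 vertex and one on a
    distinct degree-d2 vertex.  Degrees are exact by construction, so a
    successful pairing round-trips the partition exactly; the only stochastic
    failure mode is a forced self-loop, retried up to ``max_attempts``.

    Raises
    ------
    PartitionError
        If the partition is empty or the stub counts are not divisible
        (no graph with these degree pairs exists).
    RealizationError
        If the attempt budget is exhausted without a self-loop-free pairing.
    """
    partition = partition.canonical()
    if partition.edge_total == 0:
        raise PartitionError("cannot realize an empty partition")

    slots = partition.degree_endpoint_counts()
    vertex_counts: dict[int, int] = {}
    for d, n_slots in sorted(slots.items()):
        if n_slots % d != 0:
            raise PartitionError(
                f"infeasible partition: {n_slots} endpoint slots of degree {d} "
                f"not divisible by {d}"
            )
        vertex_counts[d] = n_slots // d

    edges: list[tuple[int, int]] = []
    for (d1, d2), count in partition.items():
        edges.extend([(d1, d2)] * count)

    rng = random.Random(seed)
    for _ in range(max_attempts):
        # free stubs per degree: vertex name repeated (capacity) times
        stubs = {
            d: [f"d{d}_{i}" for i in range(n) for _ in range(d)]
            for d, n in vertex_counts.items()
        }
        for pool in stubs.values():
            rng.shuffle(pool)
        rng.shuffle(edges)

        graph = MolecularGraph()
        for d, n in vertex_counts.items():
            for i in range(n):
                graph.add_vertex(f"d{d}_{i}")

        ok = True
        for d1, d2 in edges:
            u = stubs[d1].pop()
            pool = stubs[d2]
            if pool and pool[-1] != u:
                v = pool.pop()
            else:
                candidates = [i for i, w in enumerate(pool) if w != u]
                if not candidates:
                    ok = False  # forced self-loop; retry whole pairing
                    break
                v = pool.pop(rng.choice(candidates))
            graph.add_edge(u, v)
        if ok:
            return graph

    raise RealizationError(
        f"no self-loop-free realization found in {max_attempts} attempts (seed={seed})"
    )


def random_bounded_degree_graph(n: int, dmax: int, seed: int) -> MolecularGraph:
    """Seeded simple graph on ``n`` vertices with all degrees in [0, dmax].

    Fixture generator for oracle property tests; for a fixed seed the result
    is identical across calls.
    """
    if n < 2:
        raise GraphValidationError("need at least 2 vertices")
    if dmax < 1:
        raise GraphValidationError("dmax must be >= 1")
    rng = random.Random(seed)
    graph = MolecularGraph()
    names = [f"v{i}" for i in range(n)]
    for name in names:
        graph.add_vertex(name)
    present: set[tuple[str, str]] = set()
    for _ in range(2 * n * dmax):
        u, v = rng.sample(names, 2)
        key = tuple(sorted((u, v)))
        if key in present:
            continue
        if graph.degree(u) >= dmax or graph.degree(v) >= dmax:
            continue
        graph.add_edge(u, v)
        present.add(key)
    return graph
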