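"""The TSP reduction of the k-breakpoint-median problem.

Given k genomes on the same n genes, build a complete graph whose minimum
weight Hamilton cycle decodes to a breakpoint median:

* unsigned — one vertex per gene; for each gene pair let ``v(xy)`` count
  the input genomes in which x and y are adjacent, and weight the edge
  ``w(xy) = k - v(xy)``.  A Hamilton cycle is a circular genome M, and its
  weight is exactly the median sum ``sum_i d(M, A_i)``.
* signed — one vertex per gene *extremity* (2n vertices).  The n intra-gene
  tail-head edges are structurally forced into every tour, so each
  extremity picks up exactly one additional *adjacency* edge and the tour
  alternates gene edges with adjacency edges.  Adjacency edges carry
  ``w = k - v`` on extremity pairs; forced edges carry no weight and are
  excluded from the tour weight, which again equals the median sum.

Extremity vertices are encoded as integers: gene g has tail ``2(g-1)`` and
head ``2(g-1)+1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

from .genomes import (
    Extremity,
    Genome,
    GenomeError,
    SignedGenome,
    UnsignedGenome,
    adjacencies,
)

__all__ = [
    "MedianInstance",
    "WeightedMedianGraph",
    "build_median_graph",
    "tour_weight",
    "decode_tour",
    "verify_tour_median_identity",
    "write_tsplib",
    "ext_tail",
    "ext_head",
    "ext_gene",
]


def ext_tail(gene: int) -> int:
    return 2 * (gene - 1)


def ext_head(gene: int) -> int:
    return 2 * (gene - 1) + 1


def ext_gene(vertex: int) -> int:
    return vertex // 2 + 1


def _ext_to_vertex(e: Extremity) -> int:
    return ext_head(e.gene) if e.end == "head" else ext_tail(e.gene)


@dataclass(frozen=True)
class MedianInstance:
    """k >= 3 genomes sharing gene count and signedness."""

    genomes: tuple[Genome, ...]

    def __init__(self, genomes: Sequence[Genome]):
        genomes = tuple(genomes)
        if len(genomes) < 3:
            raise GenomeError(f"a median instance needs k >= 3 genomes, got {len(genomes)}")
        first = genomes[0]
        for g in genomes[1:]:
            if g.n != first.n or g.signed != first.signed:
                raise GenomeError("all genomes must share n and signedness")
        object.__setattr__(self, "genomes", genomes)

    @property
    def k(self) -> int:
        return len(self.genomes)

    @property
    def n(self) -> int:
        return self.genomes[0].n

    @property
    def signed(self) -> bool:
        return self.genomes[0].signed


@dataclass(frozen=True)
class WeightedMedianGraph:
    """Median TSP graph; ``v`` is sparse, w(xy) = k - v.get(xy, 0)."""

    n: int
    k: int
    signed: bool
    v: dict[tuple[int, int], int] = field(compare=False)

    @property
    def num_vertices(self) -> int:
        return 2 * self.n if self.signed else self.n

    def vertices(self) -> range:
        return range(1, self.n + 1) if not self.signed else range(2 * self.n)

    def is_forced(self, x: int, y: int) -> bool:
        """Intra-gene tail-head edge (signed graphs only)."""
        return self.signed and x // 2 == y // 2 and x != y

    def v_count(self, x: int, y: int) -> int:
        return self.v.get((x, y) if x < y else (y, x), 0)

    def weight(self, x: int, y: int) -> int:
        if self.is_forced(x, y):
            return 0
        return self.k - self.v_count(x, y)


def build_median_graph(instance: MedianInstance) -> WeightedMedianGraph:
    """Accumulate adjacency counts v(xy) over the inputs."""
    v: dict[tuple[int, int], int] = {}
    for genome in instance.genomes:
        for pair in adjacencies(genome).pairs:
            elems = sorted(pair) if not instance.signed else sorted(
                _ext_to_vertex(e) for e in pair
            )
            key = (elems[0], elems[1])
            v[key] = v.get(key, 0) + 1
    return WeightedMedianGraph(
        n=instance.n, k=instance.k, signed=instance.signed, v=v
    )


def _tour_edges(tour: Sequence[int]) -> list[tuple[int, int]]:
    m = len(tour)
    return [(tour[i], tour[(i + 1) % m]) for i in range(m)]


def _validate_tour(tour: Sequence[int], graph: WeightedMedianGraph) -> None:
    expected = set(graph.vertices())
    if len(tour) != len(expected) or set(tour) != expected:
        raise ValueError("tour must visit every vertex exactly once")
    if graph.signed:
        forced_positions = [
            i % 2 for i, (x, y) in enumerate(_tour_edges(tour)) if graph.is_forced(x, y)
        ]
        if len(forced_positions) != graph.n or len(set(forced_positions)) != 1:
            raise ValueError(
                "signed tour must alternate forced tail-head edges with adjacency edges"
            )


def tour_weight(tour: Sequence[int], graph: WeightedMedianGraph) -> int:
    """Total w over the tour's adjacency edges (forced edges weigh nothing)."""
    _validate_tour(tour, graph)
    return sum(
        graph.weight(x, y) for x, y in _tour_edges(tour) if not graph.is_forced(x, y)
    )


def decode_tour(tour: Sequence[int], graph: WeightedMedianGraph) -> Genome:
    """Read the genome off a Hamilton tour of the median graph."""
    _validate_tour(tour, graph)
    if not graph.signed:
        return UnsignedGenome(tour)
    tour = list(tour)
    if not graph.is_forced(tour[0], tour[1]):
        tour = tour[1:] + tour[:1]
    order = []
    for i in range(0, len(tour), 2):
        x = tour[i]
        g = ext_gene(x)
        order.append(g if x == ext_tail(g) else -g)  # entered via tail => forward
    return SignedGenome(order)


def verify_tour_median_identity(
    tour: Sequence[int], graph: WeightedMedianGraph, instance: MedianInstance
) -> tuple[int, int]:
    """Return (tour weight, median sum of the decoded genome); they are equal.

    The exact integer identity ``sum_e w(e) = sum_i d(M, A_i)`` is the
    correctness core of the reduction; callers may assert equality.
    """
    from .genomes import breakpoint_distance

    weight = tour_weight(tour, graph)
    genome = decode_tour(tour, graph)
    median_sum = sum(breakpoint_distance(genome, a) for a in instance.genomes)
    return weight, median_sum


def write_tsplib(graph: WeightedMedianGraph, path: Union[str, Path], name: str = "median") -> None:
    """Export the median graph as a TSPLIB EXPLICIT full-matrix instance.

    Signed graphs list the forced intra-gene edges in FIXED_EDGES_SECTION
    (TSPLIB vertices are 1-indexed).
    """
    nv = graph.num_vertices
    verts = list(graph.vertices())
    lines = [
        f"NAME: {name}",
        "TYPE: TSP",
        f"COMMENT: breakpoint median graph (k={graph.k}, signed={graph.signed})",
        f"DIMENSION: {nv}",
        "EDGE_WEIGHT_TYPE: EXPLICIT",
        "EDGE_WEIGHT_FORMAT: FULL_MATRIX",
        "EDGE_WEIGHT_SECTION",
    ]
    for x in verts:
        row = [0 if x == y else graph.weight(x, y) for y in verts]
        lines.append(" ".join(str(w) for w in row))
    if graph.signed:
        lines.append("FIXED_EDGES_SECTION")
        for g in range(1, graph.n + 1):
            lines.append(f"{ext_tail(g) + 1} {ext_head(g) + 1}")
        lines.append("-1")
    lines.append("EOF")
    Path(path).write_text("\n".join(lines) + "\n")
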