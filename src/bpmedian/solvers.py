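"""Breakpoint median solvers.

Three routes of increasing scale:

* ``solve_median_bruteforce`` — exhaustive enumeration of all circular
  genomes (unsigned n <= 8, signed n <= 5); returns *every* optimal median.
  This is the validation oracle for the other solvers.
* ``held_karp_min_weight`` — classic dynamic program over vertex subsets
  for the unsigned median graph (n <= 13); an independent exact cross-check
  for the integer-programming route.
* ``solve_median_tsp`` — the production solver.  ``mode="exact"`` solves an
  integer program with lazily separated subtour-elimination cuts and
  returns a certified optimum; ``mode="heuristic"`` runs greedy
  construction plus 2-opt local search and reports a combinatorial lower
  bound (``certified`` only when the bound is met).

Exact solver formulation.  Minimizing the tour weight ``sum (k - v)`` over
Hamilton cycles is equivalent to maximizing ``sum v`` over the tour's
edges, and only edges present in at least one input (the *support*, at most
kn edges) have v > 0.  The IP therefore selects support edges forming a
vertex-disjoint union of paths (degree <= 2; degree <= 1 per extremity in
the signed case, where the n intra-gene edges are structurally forced) with
cycles other than a full Hamilton cycle excluded by lazily added cuts.  A
maximum-v selection always extends to a Hamilton cycle using only
zero-v edges (at a maximum, any endpoint pair joining two components must
have v = 0, else adding it would improve the selection), so the completed
tour has weight exactly ``k*n - max sum v`` — the certified median sum.

Sampling alternative optima.  Each solve applies a seed-derived random
ordering of the edge variables and an infinitesimal integer perturbation of
the objective (total perturbation below one true-objective unit, so the
optimum set is preserved while ties are broken at random), and the
path-joining completion is itself randomized.  Varying the seed therefore
walks the optimum set, mirroring seed-varied runs of an external TSP
solver.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .genomes import (
    Genome,
    SignedGenome,
    UnsignedGenome,
    breakpoint_distance,
    normalized_distance,
)
from .median_graph import (
    MedianInstance,
    WeightedMedianGraph,
    build_median_graph,
    decode_tour,
    ext_head,
    ext_tail,
)

__all__ = [
    "MedianSolution",
    "SolutionClassification",
    "SolverBudgetError",
    "solve_median_bruteforce",
    "held_karp_min_weight",
    "solve_median_tsp",
    "sample_medians",
    "classify_median",
    "mean_pairwise_distance",
    "heuristic_lower_bound",
]

BRUTEFORCE_MAX_UNSIGNED = 8
BRUTEFORCE_MAX_SIGNED = 5
HELD_KARP_MAX = 13

_SCALE = 1 << 20  # true-objective unit for the tie-breaking perturbation


class SolverBudgetError(RuntimeError):
    """Exact solve exceeded its cut-iteration budget; never a silent fallback."""


@dataclass(frozen=True)
class MedianSolution:
    """A median genome with its certificate and sampling provenance."""

    genome: Genome
    median_sum: int
    per_input_distances: tuple[int, ...]
    certified: bool
    seed: Optional[int] = None
    lower_bound: Optional[int] = None

    def __post_init__(self):
        if self.median_sum != sum(self.per_input_distances):
            raise ValueError("median_sum must equal the sum of per-input distances")


@dataclass(frozen=True)
class SolutionClassification:
    """Corner/middle verdict for one median solution."""

    label: Literal["corner", "middle"]
    corner_index: Optional[int]  # 0-based input index; None for middle
    nearest_input_distance: float
    near_corner: bool  # nearest_input_distance < eps


def _solution_from_genome(
    genome: Genome,
    instance: MedianInstance,
    certified: bool,
    seed: Optional[int] = None,
    lower_bound: Optional[int] = None,
) -> MedianSolution:
    dists = tuple(breakpoint_distance(genome, a) for a in instance.genomes)
    return MedianSolution(
        genome=genome,
        median_sum=sum(dists),
        per_input_distances=dists,
        certified=certified,
        seed=seed,
        lower_bound=lower_bound,
    )


# ---------------------------------------------------------------------------
# brute force oracle


def _all_unsigned_genomes(n: int):
    # fix gene 1 first and half the directions via second < last: one
    # representative per rotation/reflection class, (n-1)!/2 genomes
    for rest in itertools.permutations(range(2, n + 1)):
        if rest[0] < rest[-1]:
            yield UnsignedGenome((1,) + rest)


def _all_signed_genomes(n: int):
    seen = set()
    for rest in itertools.permutations(range(2, n + 1)):
        for signs in itertools.product((1, -1), repeat=n):
            order = tuple(s * g for s, g in zip(signs, (1,) + rest))
            genome = SignedGenome(order)
            if genome.order not in seen:
                seen.add(genome.order)
                yield genome


def solve_median_bruteforce(instance: MedianInstance) -> list[MedianSolution]:
    """Enumerate every genome; return all medians (small n only)."""
    n, signed = instance.n, instance.signed
    if signed and n > BRUTEFORCE_MAX_SIGNED:
        raise ValueError(f"signed brute force limited to n <= {BRUTEFORCE_MAX_SIGNED}")
    if not signed and n > BRUTEFORCE_MAX_UNSIGNED:
        raise ValueError(f"unsigned brute force limited to n <= {BRUTEFORCE_MAX_UNSIGNED}")
    candidates = _all_signed_genomes(n) if signed else _all_unsigned_genomes(n)
    best_sum = None
    best: list[MedianSolution] = []
    for genome in candidates:
        dists = tuple(breakpoint_distance(genome, a) for a in instance.genomes)
        s = sum(dists)
        if best_sum is None or s < best_sum:
            best_sum = s
            best = []
        if s == best_sum:
            best.append(
                MedianSolution(
                    genome=genome,
                    median_sum=s,
                    per_input_distances=dists,
                    certified=True,
                )
            )
    return best


# ---------------------------------------------------------------------------
# Held-Karp dynamic program (unsigned cross-check)


def held_karp_min_weight(graph: WeightedMedianGraph) -> int:
    """Exact minimum tour weight by subset DP; unsigned, n <= 13."""
    if graph.signed:
        raise ValueError("Held-Karp cross-check implemented for unsigned graphs only")
    n = graph.n
    if n > HELD_KARP_MAX:
        raise ValueError(f"Held-Karp limited to n <= {HELD_KARP_MAX}")
    # vertices 1..n; fix vertex 1 as tour start; DP over subsets of 2..n
    others = list(range(2, n + 1))
    m = len(others)
    w = [[graph.weight(x, y) if x != y else 0 for y in range(n + 1)] for x in range(n + 1)]
    INF = float("inf")
    dp = [[INF] * m for _ in range(1 << m)]
    for j, vj in enumerate(others):
        dp[1 << j][j] = w[1][vj]
    for mask in range(1 << m):
        row = dp[mask]
        for j in range(m):
            cur = row[j]
            if cur is INF or not (mask >> j) & 1:
                continue
            vj = others[j]
            for l in range(m):
                if (mask >> l) & 1:
                    continue
                nxt = mask | (1 << l)
                cand = cur + w[vj][others[l]]
                if cand < dp[nxt][l]:
                    dp[nxt][l] = cand
    full = (1 << m) - 1
    return int(min(dp[full][j] + w[others[j]][1] for j in range(m)))


# ---------------------------------------------------------------------------
# exact IP solver with lazy subtour cuts


def _support_edges(graph: WeightedMedianGraph) -> list[tuple[int, int, int]]:
    return [(x, y, v) for (x, y), v in graph.v.items()]


def _components(adj: dict[int, list[int]], vertices) -> list[list[int]]:
    seen: set[int] = set()
    comps = []
    for v0 in vertices:
        if v0 in seen:
            continue
        stack, comp = [v0], []
        seen.add(v0)
        while stack:
            u = stack.pop()
            comp.append(u)
            for w in adj.get(u, ()):  # noqa: B909 - static adjacency
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        comps.append(comp)
    return comps


def _solve_packing(
    graph: WeightedMedianGraph,
    rng: np.random.Generator,
    max_cut_rounds: int = 200,
    extra_constraints=None,
) -> tuple[list[tuple[int, int]], int]:
    """Maximum-v path packing on the support graph; returns (edges, sum v).

    ``extra_constraints`` is an optional callable ``(edges, ne) -> list of
    LinearConstraint`` for restricted searches (e.g. solutions forced to
    share many adjacencies with one input).
    """
    edges = _support_edges(graph)
    rng.shuffle(edges)  # seed-derived variable ordering (relabeling surrogate)
    ne = len(edges)
    n = graph.n
    pert = max(1, _SCALE // (n + 1))
    coeffs = np.array(
        [v * _SCALE + int(rng.integers(pert)) for _, _, v in edges], dtype=float
    )
    verts = list(graph.vertices())
    vidx = {v: i for i, v in enumerate(verts)}
    rows, cols = [], []
    for e, (x, y, _) in enumerate(edges):
        rows.extend((vidx[x], vidx[y]))
        cols.extend((e, e))
    a_deg = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(verts), ne)
    )
    cap = 1.0 if graph.signed else 2.0
    constraints = [LinearConstraint(a_deg, 0, cap)]
    if extra_constraints is not None:
        constraints.extend(extra_constraints(edges, ne))
    integrality = np.ones(ne)
    for _ in range(max_cut_rounds):
        res = milp(
            c=-coeffs,
            constraints=constraints,
            integrality=integrality,
            bounds=Bounds(0, 1),
        )
        if res.status != 0:
            raise SolverBudgetError(f"IP solve failed: {res.message}")
        x = np.round(res.x).astype(int)
        chosen = [(edges[e][0], edges[e][1]) for e in range(ne) if x[e]]
        bad_cycles = _short_cycles(graph, chosen)
        if not bad_cycles:
            total_v = sum(edges[e][2] for e in range(ne) if x[e])
            return chosen, total_v
        for cycle_vertices in bad_cycles:
            s = set(cycle_vertices)
            in_s = [e for e, (ex, ey, _) in enumerate(edges) if ex in s and ey in s]
            limit = (len(s) // 2 if graph.signed else len(s)) - 1
            row = csr_matrix(
                (np.ones(len(in_s)), (np.zeros(len(in_s)), in_s)), shape=(1, ne)
            )
            constraints.append(LinearConstraint(row, 0, limit))
    raise SolverBudgetError("subtour-cut budget exceeded in exact mode")


def _short_cycles(
    graph: WeightedMedianGraph, chosen: list[tuple[int, int]]
) -> list[list[int]]:
    """Cycle components (other than a full Hamilton cycle) of the selection.

    Signed graphs include the forced intra-gene edges when tracing
    components, so cycles alternate gene and adjacency edges.
    """
    adj: dict[int, list[int]] = {}
    for x, y in chosen:
        adj.setdefault(x, []).append(y)
        adj.setdefault(y, []).append(x)
    if graph.signed:
        for g in range(1, graph.n + 1):
            adj.setdefault(ext_tail(g), []).append(ext_head(g))
            adj.setdefault(ext_head(g), []).append(ext_tail(g))
    nv = graph.num_vertices
    cycles = []
    for comp in _components(adj, list(graph.vertices())):
        if len(comp) == nv:
            continue  # spanning component: either the Hamilton cycle or a full path
        if all(len(adj.get(u, ())) == 2 for u in comp):
            cycles.append(comp)
    return cycles


def _complete_to_tour(
    graph: WeightedMedianGraph,
    chosen: list[tuple[int, int]],
    rng: np.random.Generator,
) -> list[int]:
    """Join the selected paths into a Hamilton tour in random order."""
    adj: dict[int, list[int]] = {v: [] for v in graph.vertices()}
    for x, y in chosen:
        adj[x].append(y)
        adj[y].append(x)
    if graph.signed:
        for g in range(1, graph.n + 1):
            adj[ext_tail(g)].append(ext_head(g))
            adj[ext_head(g)].append(ext_tail(g))
    paths: list[list[int]] = []
    visited: set[int] = set()
    # trace each path component from an endpoint (degree < 2)
    for v0 in graph.vertices():
        if v0 in visited or len(adj[v0]) >= 2:
            continue
        seq = [v0]
        visited.add(v0)
        prev, cur = None, v0
        while True:
            nxts = [u for u in adj[cur] if u != prev]
            if not nxts:
                break
            prev, cur = cur, nxts[0]
            seq.append(cur)
            visited.add(cur)
        paths.append(seq)
    if not paths:
        # single spanning cycle: the selection already is a Hamilton tour
        tour = [next(iter(graph.vertices()))]
        visited = {tour[0]}
        while len(tour) < graph.num_vertices:
            nxt = [u for u in adj[tour[-1]] if u not in visited][0]
            tour.append(nxt)
            visited.add(nxt)
        return tour
    order = rng.permutation(len(paths))
    tour = []
    for i in order:
        seq = paths[i]
        if rng.integers(2):
            seq = seq[::-1]
        tour.extend(seq)
    return tour


def heuristic_lower_bound(graph: WeightedMedianGraph) -> int:
    """Degree-relaxation bound: tour weight >= k*n - floor(best attainable sum v).

    Each vertex can host at most two tour edges (one adjacency edge per
    extremity when signed), and every edge is counted at both endpoints.
    """
    best_at: dict[int, list[int]] = {}
    for (x, y), v in graph.v.items():
        best_at.setdefault(x, []).append(v)
        best_at.setdefault(y, []).append(v)
    cap = 1 if graph.signed else 2
    total = 0
    for vals in best_at.values():
        vals.sort(reverse=True)
        total += sum(vals[:cap])
    return graph.k * graph.n - total // 2


def _heuristic_tour(
    graph: WeightedMedianGraph, rng: np.random.Generator, two_opt_rounds: int = 8
) -> list[int]:
    """Greedy nearest-neighbour construction plus 2-opt improvement."""
    n = graph.n
    if not graph.signed:
        start = int(rng.integers(1, n + 1))
        remaining = set(graph.vertices()) - {start}
        tour = [start]
        while remaining:
            cur = tour[-1]
            nxt = min(remaining, key=lambda y: (graph.weight(cur, y), rng.random()))
            tour.append(nxt)
            remaining.remove(nxt)
        order = tour
        for _ in range(two_opt_rounds):
            improved = False
            for i in range(n - 1):
                for j in range(i + 2, n if i > 0 else n - 1):
                    a, b = order[i], order[i + 1]
                    c, d = order[j], order[(j + 1) % n]
                    delta = (
                        graph.weight(a, c) + graph.weight(b, d)
                        - graph.weight(a, b) - graph.weight(c, d)
                    )
                    if delta < 0:
                        order[i + 1 : j + 1] = order[i + 1 : j + 1][::-1]
                        improved = True
            if not improved:
                break
        return order
    # signed: greedy over oriented genes, then 2-opt as signed reversals
    start_gene = int(rng.integers(1, n + 1))
    signed_order = [start_gene]
    remaining = set(range(1, n + 1)) - {start_gene}
    while remaining:
        g = signed_order[-1]
        trail = ext_head(abs(g)) if g > 0 else ext_tail(abs(g))
        cands = []
        for h in remaining:
            cands.append((graph.weight(trail, ext_tail(h)), rng.random(), h))
            cands.append((graph.weight(trail, ext_head(h)), rng.random(), -h))
        _, _, pick = min(cands)
        signed_order.append(pick)
        remaining.remove(abs(pick))

    def adj_w(g: int, h: int) -> int:
        trail = ext_head(abs(g)) if g > 0 else ext_tail(abs(g))
        lead = ext_tail(abs(h)) if h > 0 else ext_head(abs(h))
        return graph.weight(trail, lead)

    for _ in range(two_opt_rounds):
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                # reverse (and flip) the segment order[i+1..j]
                a, b = signed_order[i], signed_order[i + 1]
                c, d = signed_order[j], signed_order[(j + 1) % n]
                delta = adj_w(a, -c) + adj_w(-b, d) - adj_w(a, b) - adj_w(c, d)
                if delta < 0:
                    seg = [-g for g in reversed(signed_order[i + 1 : j + 1])]
                    signed_order[i + 1 : j + 1] = seg
                    improved = True
        if not improved:
            break
    tour = []
    for g in signed_order:
        if g > 0:
            tour.extend((ext_tail(g), ext_head(g)))
        else:
            tour.extend((ext_head(-g), ext_tail(-g)))
    return tour


def solve_median_tsp(
    instance: MedianInstance,
    seed: int = 0,
    mode: Literal["exact", "heuristic"] = "exact",
) -> MedianSolution:
    """Solve the k-median via the TSP reduction.

    Exact mode returns a certified optimum; varying ``seed`` re-samples the
    optimum set.  Heuristic mode is uncertified unless its tour meets the
    combinatorial lower bound.
    """
    graph = build_median_graph(instance)
    rng = np.random.default_rng(seed)
    if mode == "exact":
        chosen, total_v = _solve_packing(graph, rng)
        tour = _complete_to_tour(graph, chosen, rng)
        genome = decode_tour(tour, graph)
        sol = _solution_from_genome(
            genome,
            instance,
            certified=True,
            seed=seed,
            lower_bound=graph.k * graph.n - total_v,
        )
        # the completed tour must achieve the IP optimum exactly
        assert sol.median_sum == graph.k * graph.n - total_v
        return sol
    if mode != "heuristic":
        raise ValueError(f"unknown mode {mode!r}")
    tour = _heuristic_tour(graph, rng)
    genome = decode_tour(tour, graph)
    lb = heuristic_lower_bound(graph)
    sol = _solution_from_genome(
        genome, instance, certified=False, seed=seed, lower_bound=lb
    )
    if sol.median_sum == lb:
        sol = _solution_from_genome(
            genome, instance, certified=True, seed=seed, lower_bound=lb
        )
    return sol


def sample_medians(
    instance: MedianInstance,
    m: int,
    base_seed: int = 0,
    mode: Literal["exact", "heuristic"] = "exact",
) -> list[MedianSolution]:
    """m seed-varied solves; duplicates permitted (optima may coincide)."""
    if m < 1:
        raise ValueError("m must be at least 1")
    child_seeds = np.random.SeedSequence(base_seed).generate_state(m) >> 1
    return [
        solve_median_tsp(instance, seed=int(s), mode=mode) for s in child_seeds
    ]


def classify_median(
    solution: MedianSolution,
    instance: MedianInstance,
    eps: float = 0.1,
    tau: float = 0.05,
) -> SolutionClassification:
    """Corner/middle verdict by the normalized spread of per-input distances.

    MIDDLE when (max_i d - min_i d)/n <= tau (approximately equidistant);
    otherwise CORNER at the nearest input (smallest index on ties).
    """
    if not (0 < eps < 1) or not (0 < tau < 1):
        raise ValueError("eps and tau must lie in (0, 1)")
    n = instance.n
    dists = solution.per_input_distances
    lo, hi = min(dists), max(dists)
    nearest = lo / n
    if (hi - lo) / n <= tau:
        return SolutionClassification("middle", None, nearest, nearest < eps)
    idx = dists.index(lo)
    return SolutionClassification("corner", idx, nearest, nearest < eps)


def mean_pairwise_distance(solutions: Sequence[MedianSolution]) -> float:
    """Mean normalized breakpoint distance over all unordered solution pairs."""
    if not solutions:
        raise ValueError("at least one solution required")
    if len(solutions) == 1:
        return 0.0
    total, count = 0.0, 0
    for a, b in itertools.combinations(solutions, 2):
        total += normalized_distance(a.genome, b.genome)
        count += 1
    return total / count
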