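"""Median solvers: brute-force oracle, Held-Karp cross-check, IP solver, sampling."""

import numpy as np
import pytest
from scipy import stats

from bpmedian import (
    MedianInstance,
    UnsignedGenome,
    breakpoint_distance,
    build_median_graph,
    classify_median,
    held_karp_min_weight,
    identity_genome,
    mean_pairwise_distance,
    sample_medians,
    solve_median_bruteforce,
    solve_median_tsp,
    swap_randomize,
    uniform_random_genome,
)
from bpmedian.solvers import MedianSolution, heuristic_lower_bound

from conftest import random_instance


class TestBruteForce:
    def test_identical_inputs_unique_zero(self):
        g = UnsignedGenome((1, 2, 3, 4, 5))
        sols = solve_median_bruteforce(MedianInstance([g, g, g]))
        assert len(sols) == 1
        assert sols[0].genome == g
        assert sols[0].median_sum == 0

    def test_two_coinciding_inputs(self, rng):
        a = uniform_random_genome(6, False, rng)
        c = uniform_random_genome(6, False, rng)
        sols = solve_median_bruteforce(MedianInstance([a, a, c]))
        assert sols[0].median_sum == breakpoint_distance(a, c)
        assert any(s.genome == a for s in sols)

    def test_size_limits(self, rng):
        with pytest.raises(ValueError):
            solve_median_bruteforce(random_instance(9, 3, False, rng))
        with pytest.raises(ValueError):
            solve_median_bruteforce(random_instance(6, 3, True, rng))


class TestHeldKarp:
    def test_matches_bruteforce(self, rng):
        for _ in range(15):
            n = int(rng.integers(5, 8))
            inst = random_instance(n, 3, False, rng)
            graph = build_median_graph(inst)
            assert held_karp_min_weight(graph) == solve_median_bruteforce(inst)[0].median_sum

    def test_signed_unsupported(self, rng):
        with pytest.raises(ValueError):
            held_karp_min_weight(build_median_graph(random_instance(4, 3, True, rng)))


class TestExactSolver:
    def test_identical_inputs(self):
        g = identity_genome(12)
        sol = solve_median_tsp(MedianInstance([g, g, g]))
        assert sol.median_sum == 0
        assert sol.genome == g
        assert sol.certified

    def test_two_coinciding_inputs_hit_lower_bound(self, rng):
        a = uniform_random_genome(10, False, rng)
        c = uniform_random_genome(10, False, rng)
        sol = solve_median_tsp(MedianInstance([a, a, c]))
        assert sol.median_sum == breakpoint_distance(a, c)

    def test_oracle_equivalence_unsigned(self, rng):
        """The IP route attains the brute-force minimum on every instance."""
        for trial in range(51):
            n = 5 + trial % 3  # n in {5, 6, 7}
            inst = random_instance(n, 3, False, rng)
            sol = solve_median_tsp(inst, seed=int(rng.integers(2**31)))
            assert sol.median_sum == solve_median_bruteforce(inst)[0].median_sum
            assert sol.certified

    def test_oracle_equivalence_signed(self, rng):
        for trial in range(21):
            n = 4 + trial % 2  # n in {4, 5}
            inst = random_instance(n, 3, True, rng)
            sol = solve_median_tsp(inst, seed=int(rng.integers(2**31)))
            assert sol.median_sum == solve_median_bruteforce(inst)[0].median_sum

    def test_held_karp_cross_check_midsize(self, rng):
        for _ in range(5):
            inst = random_instance(11, 3, False, rng)
            sol = solve_median_tsp(inst, seed=7)
            assert sol.median_sum == held_karp_min_weight(build_median_graph(inst))

    def test_upper_bound_every_input_is_candidate(self, rng):
        for signed in (False, True):
            inst = random_instance(12, 4, signed, rng)
            sol = solve_median_tsp(inst)
            best_input = min(
                sum(breakpoint_distance(a, b) for b in inst.genomes)
                for a in inst.genomes
            )
            assert sol.median_sum <= best_input

    def test_solution_invariants(self, rng):
        inst = random_instance(20, 3, False, rng)
        sol = solve_median_tsp(inst, seed=3)
        assert sol.median_sum == sum(sol.per_input_distances)
        assert sol.lower_bound == sol.median_sum  # exact mode is certified


class TestHeuristicSolver:
    def test_identical_inputs_certified(self):
        g = identity_genome(30)
        sol = solve_median_tsp(MedianInstance([g, g, g]), mode="heuristic")
        assert sol.median_sum == 0
        assert sol.certified

    def test_bounded_by_lower_bound(self, rng):
        for signed in (False, True):
            inst = random_instance(30, 3, signed, rng)
            sol = solve_median_tsp(inst, mode="heuristic", seed=5)
            lb = heuristic_lower_bound(build_median_graph(inst))
            assert sol.median_sum >= lb
            assert sol.lower_bound == lb

    def test_close_to_exact_on_moderate_instance(self, rng):
        ident = identity_genome(40)
        genomes = [swap_randomize(ident, 40, rng) for _ in range(3)]
        inst = MedianInstance(genomes)
        exact = solve_median_tsp(inst, mode="exact").median_sum
        heur = solve_median_tsp(inst, mode="heuristic", seed=2).median_sum
        assert heur >= exact
        assert heur - exact <= 0.15 * inst.n


class TestSampling:
    def test_singleton(self, rng):
        inst = random_instance(8, 3, False, rng)
        sols = sample_medians(inst, 1, base_seed=4)
        assert len(sols) == 1

    def test_identical_inputs_unique_optimum(self):
        g = identity_genome(10)
        sols = sample_medians(MedianInstance([g, g, g]), 5, base_seed=1)
        assert all(s.genome == g for s in sols)
        assert mean_pairwise_distance(sols) == 0.0

    def test_all_samples_optimal_and_diverse(self, rng):
        """Every sampled sum is the brute-force minimum; distinct optima appear."""
        found_diverse = 0
        for _ in range(10):
            inst = random_instance(7, 3, False, rng)
            bf = solve_median_bruteforce(inst)
            sols = sample_medians(inst, 20, base_seed=int(rng.integers(2**31)))
            assert all(s.median_sum == bf[0].median_sum for s in sols)
            if len(bf) >= 2 and len({s.genome.order for s in sols}) >= 2:
                found_diverse += 1
        assert found_diverse >= 1

    def test_corner_exchangeability(self, rng):
        """Sampled optima spread over the corners with no input-order bias."""
        counts = [0, 0, 0]
        ident = identity_genome(60)
        for _ in range(8):
            genomes = [swap_randomize(ident, 180, rng) for _ in range(3)]
            inst = MedianInstance(genomes)
            sols = sample_medians(inst, 10, base_seed=int(rng.integers(2**31)))
            for sol in sols:
                c = classify_median(sol, inst)
                if c.label == "corner":
                    counts[c.corner_index] += 1
        _, p = stats.chisquare(counts)
        assert p > 0.01


def _uniform_optimal_medians(graph, n_samples, rng):
    """Independent oracle: count minimum-weight tours with a Held-Karp DP
    and sample uniformly from the full optimum set by backward tracing.

    Every circular genome corresponds to exactly two tours rooted at vertex
    1 (the two reading directions), so uniform over tours is uniform over
    optimal median genomes.  Unsigned only, small n.
    """
    from bpmedian import decode_tour

    n = graph.n
    others = list(range(2, n + 1))
    m = len(others)
    w = [[graph.weight(x, y) if x != y else 0 for y in range(n + 1)] for x in range(n + 1)]
    INF = float("inf")
    dp = [[INF] * m for _ in range(1 << m)]
    cnt = [[0] * m for _ in range(1 << m)]
    for j, vj in enumerate(others):
        dp[1 << j][j] = w[1][vj]
        cnt[1 << j][j] = 1
    for mask in range(1 << m):
        for j in range(m):
            if dp[mask][j] == INF or not (mask >> j) & 1:
                continue
            for l in range(m):
                if (mask >> l) & 1:
                    continue
                nxt = mask | (1 << l)
                cand = dp[mask][j] + w[others[j]][others[l]]
                if cand < dp[nxt][l]:
                    dp[nxt][l] = cand
                    cnt[nxt][l] = cnt[mask][j]
                elif cand == dp[nxt][l]:
                    cnt[nxt][l] += cnt[mask][j]
    full = (1 << m) - 1
    best = min(dp[full][j] + w[others[j]][1] for j in range(m))
    ends = [(j, cnt[full][j]) for j in range(m) if dp[full][j] + w[others[j]][1] == best]
    total = sum(c for _, c in ends)
    genomes = []
    for _ in range(n_samples):
        r = int(rng.integers(total))
        acc = 0
        for j, c in ends:
            acc += c
            if r < acc:
                break
        mask, tour = full, [others[j]]
        while mask != (1 << j):
            pm = mask & ~(1 << j)
            cands = [
                (l, cnt[pm][l])
                for l in range(m)
                if (pm >> l) & 1 and dp[pm][l] + w[others[l]][others[j]] == dp[mask][j]
            ]
            tot = sum(c for _, c in cands)
            r2 = int(rng.integers(tot))
            acc = 0
            for l, c in cands:
                acc += c
                if r2 < acc:
                    break
            tour.append(others[l])
            mask, j = pm, l
        tour.append(1)
        genomes.append(decode_tour(tour, graph))
    return best, genomes


class TestOptimumSetStructure:
    def test_corner_constrained_solutions_attain_the_optimum(self, rng):
        """On heavily scrambled k=3 instances, tours forced to keep >= 80% of
        one input's adjacencies still reach the unconstrained optimum — the
        optimum set contains corner-type solutions."""
        from scipy.optimize import LinearConstraint
        from scipy.sparse import csr_matrix

        from bpmedian import adjacencies, build_median_graph, identity_genome
        from bpmedian.solvers import _solve_packing

        for _ in range(2):
            n = 60
            ident = identity_genome(n)
            genomes = [swap_randomize(ident, 3 * n, rng) for _ in range(3)]
            inst = MedianInstance(genomes)
            graph = build_median_graph(inst)
            a1 = {tuple(sorted(p)) for p in adjacencies(genomes[0]).pairs}
            _, free_v = _solve_packing(graph, np.random.default_rng(1))

            def keep_a1(edges, ne):
                idx = [e for e, (x, y, _) in enumerate(edges) if (x, y) in a1]
                row = csr_matrix(
                    (np.ones(len(idx)), (np.zeros(len(idx)), idx)), shape=(1, ne)
                )
                return [LinearConstraint(row, int(0.8 * n), n)]

            _, corner_v = _solve_packing(
                graph, np.random.default_rng(2), extra_constraints=keep_a1
            )
            assert corner_v == free_v


class TestSamplerUnbiasedness:
    def test_matches_uniform_enumeration_of_optimum_set(self, rng):
        """Seed-varied solves reproduce the uniform optimum-set statistics.

        The counting DP samples exactly uniformly over all optimal medians;
        the production sampler's nearest-input-distance profile must agree.
        """
        from bpmedian import build_median_graph, identity_genome, swap_randomize

        diffs = []
        for _ in range(4):
            n = 12
            ident = identity_genome(n)
            genomes = [swap_randomize(ident, 3 * n, rng) for _ in range(3)]
            inst = MedianInstance(genomes)
            graph = build_median_graph(inst)
            best, uniform = _uniform_optimal_medians(graph, 25, rng)
            sols = sample_medians(inst, 25, base_seed=int(rng.integers(2**31)))
            assert all(s.median_sum == best for s in sols)
            near_u = np.mean(
                [min(breakpoint_distance(g, a) for a in genomes) / n for g in uniform]
            )
            near_s = np.mean(
                [min(s.per_input_distances) / n for s in sols]
            )
            diffs.append(near_s - near_u)
        assert abs(np.mean(diffs)) < 0.08


class TestClassification:
    def test_input_itself_is_its_corner(self, rng):
        inst = random_instance(50, 3, False, rng)
        a1 = inst.genomes[0]
        dists = tuple(breakpoint_distance(a1, g) for g in inst.genomes)
        sol = MedianSolution(a1, sum(dists), dists, certified=True)
        c = classify_median(sol, inst)
        assert c.label == "corner"
        assert c.corner_index == 0
        assert c.nearest_input_distance == 0.0
        assert c.near_corner

    def test_middle_by_small_spread(self, rng):
        inst = random_instance(100, 3, False, rng)
        g = uniform_random_genome(100, False, rng)
        sol = MedianSolution(g, 181, (60, 61, 60), certified=False)
        assert classify_median(sol, inst, tau=0.05).label == "middle"

    def test_corner_by_large_spread(self, rng):
        inst = random_instance(100, 3, False, rng)
        g = uniform_random_genome(100, False, rng)
        sol = MedianSolution(g, 196, (5, 95, 96), certified=False)
        c = classify_median(sol, inst, tau=0.05)
        assert c.label == "corner"
        assert c.corner_index == 0

    def test_parameter_validation(self, rng):
        inst = random_instance(10, 3, False, rng)
        sol = solve_median_tsp(inst)
        with pytest.raises(ValueError):
            classify_median(sol, inst, tau=0.0)


class TestMeanPairwiseDistance:
    def test_single_solution_zero(self, rng):
        inst = random_instance(8, 3, False, rng)
        assert mean_pairwise_distance([solve_median_tsp(inst)]) == 0.0

    def test_two_solutions(self, rng):
        inst = random_instance(8, 3, False, rng)
        sols = sample_medians(inst, 2, base_seed=11)
        expected = breakpoint_distance(sols[0].genome, sols[1].genome) / 8
        assert mean_pairwise_distance(sols) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_pairwise_distance([])
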