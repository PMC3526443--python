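# Methods

## Genome model

A genome is a single circular chromosome carrying genes 1..n exactly once,
n ≥ 3 (below three genes the adjacency structure degenerates: fewer than
three distinct neighbour pairs exist). In the unsigned model only the
cyclic order matters; in the signed model each gene carries an orientation
and contributes two extremities (tail, head), traversed tail→head when the
gene reads forward. Rotations, and reflections (reversing the circle and,
when signed, flipping every orientation), describe the same genome; all
genome objects canonicalize on construction, so equality and hashing are
circular-equivalence semantics. The canonical linearization starts at gene
1 (read forward in the signed case — exactly one reading direction shows
gene 1 forward, making the choice unique and O(n)); the unsigned case
breaks the reflection tie lexicographically.

Adjacencies are unordered pairs: gene pairs when unsigned, extremity pairs
when signed (trailing extremity of one gene joined to the leading extremity
of the next). The extremity encoding makes the identification of an
adjacency *gh* with its reflected form −h −g automatic. The breakpoint
distance is d(A, B) = n − adj(A, B), an exact integer; normalization by n
happens only at reporting time. d is a metric on canonical forms, bounded
by n, and the ε-neighbourhood of A is the set of genomes with d/n < ε
(strict inequality).

A note on counting signed genomes: one sometimes counts 2ⁿ(n−1)! signed
circular sequences without quotienting by reflection. Since adjacency sets
— and hence every distance this package computes — are reflection
invariant, we canonicalize up to reflection throughout; uniform sampling is
unaffected because every equivalence class has equal-size linear fiber.

## Synthetic genomes

The experiments run entirely on synthetic inputs, generated three ways:

* **identity genome** — the circle 1, 2, …, n (all orientations +).
* **swap randomization** — repeatedly pick two distinct positions
  uniformly and exchange their genes; in the signed case the orientation of
  each swapped gene is re-drawn uniformly (a re-draw may restore the old
  sign). One swap touches at most four adjacencies, so it moves the
  breakpoint distance by at most 4; swap counts are stated per 100 genes
  (converted as round(s·n/100)) so different n are comparable. This
  scrambler is intentionally model-agnostic — it is *not* an inversion /
  transposition / DCJ model and makes no biological claim; it is simply a
  graded source of randomness.
* **uniform random genome** — a uniform linear permutation read circularly
  (uniform over circular classes since all classes have equal-size linear
  fibers), with uniform orientations when signed.

RNG contract: every generator consumes draws from a caller-supplied
`numpy.random.Generator` in the documented order (positions, then signs),
so any trajectory is replayable from its seed. Experiment drivers derive
one `SeedSequence` per (design point, replicate) from the master seed with
fixed spawn keys, so no randomness is shared across design points.

For two independent uniform genomes, the number of shared adjacencies is
asymptotically Poisson: parameter 2 unsigned (each of the n adjacencies of
A appears in B with probability 2/(n−1)) and 1/2 signed (the orientation
constraint suppresses matches by a factor 4). Consequently E d/n → 1 in
both models — two random genomes are essentially maximally distant. The
test suite checks both parameters and the 12-class uniformity of the n = 5
sampler by chi-square.

What the generator does *not* emulate: real gene orders evolve by
structured rearrangements (inversions dominate), have unequal gene content,
duplications, and rearrangement hotspots. Passing tests establish the
combinatorial and statistical claims about the model, not about any
organism's genomes.

## The median solver

### Reduction

For k inputs on n genes, the median graph has one vertex per gene (per
extremity when signed; 2n vertices with the n intra-gene tail–head edges
structurally forced into every tour, which makes tours alternate gene edges
and adjacency edges). With v(xy) the number of inputs containing adjacency
xy and w(xy) = k − v(xy), every Hamilton tour satisfies the exact integer
identity: tour weight (forced edges excluded) = Σᵢ d(M, Aᵢ) for the decoded
genome M. A minimum-weight tour is therefore a median. The identity is
property-tested on thousands of random tours and is the backbone of the
optimality certificates.

### Exact solve

Minimizing Σ (k − v) over tours is equivalent to maximizing Σ v, and v > 0
only on the *support* — edges present in at least one input, at most kn of
them. The integer program therefore works on the support subgraph only:
binary edge indicators, degree ≤ 2 per gene vertex (≤ 1 adjacency edge per
extremity when signed), and lazily separated cuts that exclude any cycle
other than a full Hamilton cycle (for a detected cycle component S, at most
|S| − 1 support edges may be chosen inside S). The solver is HiGHS through
`scipy.optimize.milp`; cut rounds repeat until the incumbent selection is
cycle-free or spanning, with an explicit failure (never a silent fallback)
if the round budget is exhausted.

An optimal selection is a vertex-disjoint family of paths (or a full
Hamilton cycle) maximizing Σ v. It always completes to a Hamilton tour of
weight exactly kn − max Σ v: at a maximum, any edge joining endpoints of
two different components must have v = 0 — otherwise adding it would be a
feasible improvement — so the random path-joining step cannot change the
objective. The completed tour's weight is asserted against the IP optimum
on every solve, and the solver is oracle-verified against exhaustive
enumeration (unsigned n ≤ 8, signed n ≤ 5; every optimum found) and an
independent Held–Karp subset dynamic program (n ≤ 13).

This support-graph formulation, rather than an IP over all n(n−1)/2
complete-graph edges, is what makes certified n = 100 solves take a
fraction of a second — tens of thousands of times fewer binary variables
at saturation — and it is exact, not a relaxation.

### Sampling alternative optima

Medians of scrambled genomes are massively non-unique. To sample the
optimum set, each solve (i) shuffles the edge-variable order with a
seed-derived permutation, (ii) adds an infinitesimal integer perturbation
to the objective — each support edge gets a uniform tie-break bonus below
⌊SCALE/(n+1)⌋ with SCALE = 2²⁰ per true unit, so the total perturbation
over any n-edge selection stays below one true unit and the optimum set is
preserved exactly — and (iii) joins the resulting paths in random order and
orientation. Varying the seed walks the optimum set.

Whether such seed-varied sampling is *uniform* over the optimum set cannot
be taken for granted. The test suite validates it directly at n = 12: a
counting Held–Karp dynamic program enumerates the number of minimum-weight
tours and samples exactly uniformly from them by backward tracing, and the
production sampler's nearest-input-distance profile matches the uniform
one. Corner exchangeability (no bias toward any input's corner) is checked
by chi-square.

### Heuristic mode

For instances beyond the exact solver's comfort, `mode="heuristic"` runs
nearest-neighbour construction (on oriented genes in the signed case) plus
2-opt improvement (segment reversal with sign flip when signed), and
reports a combinatorial lower bound: Σ v over any tour is at most half the
per-vertex sum of the two best incident v values (one best per extremity
when signed). Solutions are marked certified only when they meet the
bound; uncertified results are never used in acceptance statistics.

### Corner/middle classification

A solution is MIDDLE when its per-input distances are nearly equal —
normalized spread (maxᵢ d − minᵢ d)/n ≤ τ — and otherwise CORNER(i) for the
nearest input i (smallest index on ties, for determinism). Defaults
τ = 0.05 and neighbourhood radius ε = 0.1, both configurable: no published
numeric criterion exists, and these separate the ~0.6 inter-corner distance
regime from near-zero by a wide margin. Degenerate instances with all
inputs identical classify as MIDDLE (spread 0) by the rule; the census
driver treats this as a pinned edge case, not a scientific statement.

## Experiments

* **Randomization trajectory** — k identity copies scrambled by s swaps per
  100 genes for s on a grid (default 0–300 in steps of 25), exact medians,
  m sampled optima per instance. Tracks normalized median sum (rises to
  ≈ k − 1; slightly below at moderate n) and mean pairwise solution
  distance (rises to ≈ 0.6 for k = 3, below the (k−1)/k bound). Solver
  failures mark records invalid rather than dropping them.
* **Corner/middle census** — fixed heavy scrambling (300 swaps per 100
  genes), sweep over n, m optima per instance; reports the middle fraction
  and mean nearest-input distance.
* **Higher k** — the same trajectory machinery for k > 3; saturated sums
  approach k − 1 and distances stay below (k − 1)/k.

Desk-scale defaults: n = 20–100, 5 replicates, m = 10 sampled optima (20
for the census), saturation window 150–300 swaps per 100 genes. These
sizes keep every recorded point certified-optimal while the full suite and
the acceptance script each run in minutes; the asymptotic claims are about
trends that are already visible at these sizes. All reported statistics
come from the CSV records; plots are decorative.

## Known limitations and an honest caveat

* Single circular chromosomes with equal gene content only; no inversion /
  DCJ medians; no tree inference.
* Exact solving is comfortable to n of a few hundred on scrambled
  instances; thousands of genes require the heuristic mode, which gives
  bounds, not certificates.
* The corner-seeking conjecture — that as n grows, optimal medians
  concentrate in ever-smaller normalized neighbourhoods of the inputs, with
  the middle solutions a vanishing minority — is *asymptotic*, and this
  package's certified experiments do not observe its finite-n signature
  under uniform optimum sampling. At the sizes the census probes (n up to
  100), corner-type solutions do attain the optimum (the suite verifies
  that corner-constrained re-solves tie with the unconstrained optimum),
  but the uniform measure over the optimum set — validated against
  exhaustive and counting-DP enumeration at small n — puts most mass on
  mixed solutions whose nearest-input distance *rises* with n toward
  (k−1)/k, and the middle fraction rises with it.
  The corresponding trend test is therefore expected to fail under this
  package's sampling design, and is retained as an honest probe: observing
  the opposite trend requires either much larger n or an optimum sampler
  biased toward corners, and deliberately biasing the sampler would make
  the census circular. Seed-sampling of external branch-and-cut solvers
  has no uniformity guarantee either — a caveat inherited by any
  experiment of this kind.
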