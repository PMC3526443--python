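"""Simulation drivers: randomization trajectories and corner/middle censuses.

The basic experiment scrambles k copies of the identity genome with an
increasing number of random gene-position swaps (expressed as swaps per 100
genes so different n are comparable), solves the breakpoint median exactly,
samples m alternative optima per instance, and tracks

* the normalized median sum  (sum_i d(M, A_i) / n  -> k - 1 as genomes
  randomize, observed slightly below the asymptote at moderate n),
* the mean normalized distance between alternative solutions
  (-> below (k-1)/k; about 0.6 for k = 3), and
* how the solutions split between the "corners" (near one input) and the
  "middle" (approximately equidistant from all inputs).

The corner/middle census fixes a heavy randomization level (300 swaps per
100 genes) and sweeps n, tracking the middle fraction and the distance to
the nearest input — the two statistics the corner-seeking conjecture makes
predictions about.

Randomness: one master seed per experiment; per-replicate and per-genome
streams are spawned from ``numpy.random.SeedSequence(seed)`` children in
documented order (replicate-major, then genome, then the solver's sampling
seed), so no stream is shared between design points.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .median_graph import MedianInstance
from .solvers import (
    classify_median,
    mean_pairwise_distance,
    sample_medians,
)
from .synthetic import identity_genome, swap_randomize, swaps_for_rate

__all__ = [
    "TrajectoryRecord",
    "CornerCensus",
    "randomization_trajectory",
    "higher_k_trajectory",
    "corner_middle_experiment",
    "summarize_and_export",
    "read_records",
    "saturation_summary",
]

CENSUS_SWAPS_PER_100 = 300.0  # heavy-randomization level of the census design


@dataclass(frozen=True)
class TrajectoryRecord:
    """Statistics of one (swap level, replicate) design point."""

    n: int
    k: int
    signed: bool
    swaps_per_100: float
    replicate: int
    normalized_median_sum: float
    mean_solution_distance: float
    corner_counts: tuple[int, ...]
    middle_count: int
    m_solutions: int
    valid: bool = True

    def __post_init__(self):
        if self.valid and sum(self.corner_counts) + self.middle_count != self.m_solutions:
            raise ValueError("corner counts and middle count must sum to m_solutions")


@dataclass(frozen=True)
class CornerCensus:
    """Corner/middle census at one genome size."""

    n: int
    k: int
    signed: bool
    solutions_per_instance: int
    reps: int
    middle_fraction: float
    mean_nearest_input_distance: float

    def __post_init__(self):
        if not 0 <= self.middle_fraction <= 1:
            raise ValueError("middle_fraction must lie in [0, 1]")


def _spawn_rngs(seed_seq: np.random.SeedSequence, count: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in seed_seq.spawn(count)]


def _solver_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] >> 1)


def _instance_stats(
    instance: MedianInstance,
    m_solutions: int,
    solver_seed: int,
    tau: float,
    mode: str,
) -> tuple[float, float, list[int], int, list[float]]:
    solutions = sample_medians(instance, m_solutions, base_seed=solver_seed, mode=mode)
    norm_sum = float(np.mean([s.median_sum for s in solutions])) / instance.n
    mean_dist = mean_pairwise_distance(solutions)
    corner_counts = [0] * instance.k
    middle = 0
    nearest = []
    for sol in solutions:
        c = classify_median(sol, instance, tau=tau)
        nearest.append(c.nearest_input_distance)
        if c.label == "middle":
            middle += 1
        else:
            corner_counts[c.corner_index] += 1
    return norm_sum, mean_dist, corner_counts, middle, nearest


def randomization_trajectory(
    n: int,
    k: int = 3,
    signed: bool = False,
    max_swaps_per_100: float = 300.0,
    step: float = 25.0,
    reps: int = 5,
    m_solutions: int = 10,
    seed: int = 0,
    tau: float = 0.05,
    mode: str = "exact",
    swap_levels: Optional[Sequence[float]] = None,
) -> list[TrajectoryRecord]:
    """Median statistics along a progressive-randomization sweep.

    At each swap level s (in swaps per 100 genes) and each replicate, k
    genomes are generated by applying ``round(s*n/100)`` random swaps to the
    identity genome (independent streams), m optimal medians are sampled,
    and summary statistics are recorded.  A solver failure marks the record
    ``valid=False`` rather than dropping it.
    """
    if swap_levels is None:
        swap_levels = list(np.arange(0.0, max_swaps_per_100 + 1e-9, step))
    records = []
    for level_idx, s in enumerate(swap_levels):
        # one seed sequence per (level, replicate); within it, k genome
        # streams by spawning plus the solver's sampling seed
        for rep in range(reps):
            rep_seq = np.random.SeedSequence(
                entropy=seed, spawn_key=(level_idx, rep)
            )
            genome_rngs = _spawn_rngs(rep_seq, k)
            swaps = swaps_for_rate(s, n)
            genomes = [
                swap_randomize(identity_genome(n, signed), swaps, g_rng)
                for g_rng in genome_rngs
            ]
            instance = MedianInstance(genomes)
            try:
                norm_sum, mean_dist, corners, middle, _ = _instance_stats(
                    instance, m_solutions, _solver_seed(rep_seq), tau, mode
                )
            except Exception:
                records.append(
                    TrajectoryRecord(
                        n=n, k=k, signed=signed, swaps_per_100=float(s),
                        replicate=rep, normalized_median_sum=float("nan"),
                        mean_solution_distance=float("nan"),
                        corner_counts=tuple([0] * k), middle_count=0,
                        m_solutions=0, valid=False,
                    )
                )
                continue
            records.append(
                TrajectoryRecord(
                    n=n, k=k, signed=signed, swaps_per_100=float(s),
                    replicate=rep, normalized_median_sum=norm_sum,
                    mean_solution_distance=mean_dist,
                    corner_counts=tuple(corners), middle_count=middle,
                    m_solutions=m_solutions,
                )
            )
    return records


def higher_k_trajectory(
    n: int,
    k_values: Sequence[int],
    signed: bool = False,
    max_swaps_per_100: float = 300.0,
    step: float = 25.0,
    reps: int = 5,
    m_solutions: int = 10,
    seed: int = 0,
    **kwargs,
) -> list[TrajectoryRecord]:
    """Trajectories for several k; saturated statistics approach sum -> k-1
    and inter-solution distance -> (k-1)/k from below, more slowly as k grows."""
    records = []
    for i, k in enumerate(k_values):
        if k < 3:
            raise ValueError("k must be at least 3")
        records.extend(
            randomization_trajectory(
                n=n, k=k, signed=signed, max_swaps_per_100=max_swaps_per_100,
                step=step, reps=reps, m_solutions=m_solutions,
                seed=seed + 7919 * i, **kwargs,
            )
        )
    return records


def corner_middle_experiment(
    n_values: Sequence[int],
    k: int = 3,
    signed: bool = False,
    m_solutions: int = 50,
    reps: int = 5,
    seed: int = 0,
    tau: float = 0.05,
    swaps_per_100: float = CENSUS_SWAPS_PER_100,
    mode: str = "exact",
) -> list[CornerCensus]:
    """Corner/middle census across genome sizes at heavy randomization.

    Inputs are identity genomes scrambled by ``swaps_per_100`` (default 300)
    swaps per 100 genes so that almost no adjacencies survive.  Per n, the
    fraction of sampled medians classified as "middle" and the mean
    normalized distance from each median to its nearest input are averaged
    over replicates.  The corner-seeking conjecture predicts both shrink as
    n grows; what a given optimum-sampling scheme actually shows at
    accessible sizes is discussed in the methods notes.
    """
    censuses = []
    for n_idx, n in enumerate(n_values):
        middle_total, count = 0, 0
        nearest_all: list[float] = []
        for rep in range(reps):
            rep_seq = np.random.SeedSequence(
                entropy=seed, spawn_key=(1000 + n_idx, rep)
            )
            genome_rngs = _spawn_rngs(rep_seq, k)
            swaps = swaps_for_rate(swaps_per_100, n)
            genomes = [
                swap_randomize(identity_genome(n, signed), swaps, g_rng)
                for g_rng in genome_rngs
            ]
            instance = MedianInstance(genomes)
            _, _, _, middle, nearest = _instance_stats(
                instance, m_solutions, _solver_seed(rep_seq), tau, mode
            )
            middle_total += middle
            count += m_solutions
            nearest_all.extend(nearest)
        censuses.append(
            CornerCensus(
                n=n, k=k, signed=signed, solutions_per_instance=m_solutions,
                reps=reps, middle_fraction=middle_total / count,
                mean_nearest_input_distance=float(np.mean(nearest_all)),
            )
        )
    return censuses


# ---------------------------------------------------------------------------
# aggregation and export


def saturation_summary(
    records: Sequence[TrajectoryRecord], min_swaps_per_100: float = 150.0
) -> dict[str, float]:
    """Mean saturated statistics over records at or beyond the given level."""
    sat = [
        r for r in records
        if r.valid and r.swaps_per_100 >= min_swaps_per_100
    ]
    if not sat:
        raise ValueError("no valid records in the saturation window")
    return {
        "mean_normalized_median_sum": float(
            np.mean([r.normalized_median_sum for r in sat])
        ),
        "mean_solution_distance": float(
            np.mean([r.mean_solution_distance for r in sat])
        ),
        "records": len(sat),
    }


_LIST_FIELDS = ("corner_counts",)


def summarize_and_export(
    records: Sequence[Union[TrajectoryRecord, CornerCensus]],
    path: Union[str, Path],
    config: Optional[dict] = None,
) -> pd.DataFrame:
    """Write records to ``<path>.csv`` with a ``<path>.config.json`` sidecar.

    The CSV round-trips exactly through :func:`read_records`.
    """
    if not records:
        raise ValueError("no records to export")
    kinds = {type(r) for r in records}
    if len(kinds) > 1:
        raise ValueError("records must be homogeneous")
    rows = []
    for r in records:
        row = asdict(r)
        for f in _LIST_FIELDS:
            if f in row:
                row[f] = json.dumps(list(row[f]))
        rows.append(row)
    df = pd.DataFrame(rows)
    path = Path(path)
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path.with_suffix(".csv"), index=False, float_format="%.17g")
    sidecar = {
        "record_type": kinds.pop().__name__,
        "config": config or {},
    }
    path.with_suffix(".config.json").write_text(json.dumps(sidecar, indent=2))
    return df


def plot_trajectory(records: Sequence[TrajectoryRecord], path: Union[str, Path]) -> None:
    """Decorative trajectory plot (median sum and solution distance vs swaps).

    All quantitative reporting goes through the CSV records; this is a
    convenience visualization only.  Requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    valid = [r for r in records if r.valid]
    if not valid:
        raise ValueError("no valid records to plot")
    levels = sorted({r.swaps_per_100 for r in valid})
    mean_sum = [
        np.mean([r.normalized_median_sum for r in valid if r.swaps_per_100 == s])
        for s in levels
    ]
    mean_dist = [
        np.mean([r.mean_solution_distance for r in valid if r.swaps_per_100 == s])
        for s in levels
    ]
    k = valid[0].k
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax1.plot(levels, mean_sum, "o-")
    ax1.axhline(k - 1, ls="--", c="gray", label=f"asymptote {k - 1}")
    ax1.set_xlabel("swaps per 100 genes")
    ax1.set_ylabel("normalized median sum")
    ax1.legend()
    ax2.plot(levels, mean_dist, "o-")
    ax2.axhline((k - 1) / k, ls="--", c="gray", label=f"asymptote {(k - 1)}/{k}")
    ax2.set_xlabel("swaps per 100 genes")
    ax2.set_ylabel("mean solution distance")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def read_records(path: Union[str, Path]) -> list[Union[TrajectoryRecord, CornerCensus]]:
    """Read back records written by :func:`summarize_and_export`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".config.json").read_text())
    cls = {"TrajectoryRecord": TrajectoryRecord, "CornerCensus": CornerCensus}[
        sidecar["record_type"]
    ]
    df = pd.read_csv(path.with_suffix(".csv"), float_precision="round_trip")
    records = []
    for row in df.to_dict(orient="records"):
        if "corner_counts" in row:
            row["corner_counts"] = tuple(json.loads(row["corner_counts"]))
        records.append(cls(**row))
    return records
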