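"""Seeded simulation protocols: minimum-cohort estimation, the
false-positive sensitivity experiment, and iterative multi-pathway
discovery.

The central experimental quantity is the *empirical minimum cohort size*:
the smallest patient count m on a grid m_i = i·step at which a discovery
procedure returns exactly the planted driver pathway in more than a target
fraction x of replicate datasets.  For the recurrence test this estimate,
written m_{R,x}(s(q)), depends on the supplied passenger-probability
estimate s(q); for the weight-maximizing greedy search, m_{G,x} needs no
such estimate at all.  Success is strict: the output set must equal the
planted pathway exactly — partial recovery counts as failure.

Every protocol is driven by a single seed through a spawned seed tree, so
a (config, seed) pair reproduces the experiment bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matrix import GeneSet, MutationMatrix
from .models import (
    DePModelParams,
    DpModelParams,
    simulate_dep,
    simulate_dgp,
    simulate_dgp_counts,
)
from .recurrence import BONFERRONI, rmg_test_counts
from .search import SearchResult, greedy_unknown_k, greedy_weight, pair_swap_init

__all__ = [
    "MinPatientGrid",
    "MinPatientResult",
    "FalsePositiveResult",
    "estimate_min_patients_rmg",
    "estimate_min_patients_greedy",
    "false_positive_experiment",
    "iterative_discovery",
]

DGP = "dgp"
DEP = "dep"


@dataclass(frozen=True)
class MinPatientGrid:
    """Configuration of a minimum-cohort estimation run.

    The patient grid is m_i = i·m_step for 1 ≤ i ≤ m_points, with
    ``replicates`` independent datasets per grid point.  ``q_est`` (the
    estimate s(q) handed to the recurrence test) and ``alpha`` are only
    consulted by the recurrence-test protocol.
    """

    model: str
    n: int
    k: int
    q: float
    m_step: int
    m_points: int
    replicates: int
    target: float = 0.99
    q_est: float | None = None
    alpha: float = 0.005
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in (DGP, DEP):
            raise ValueError(f"model must be '{DGP}' or '{DEP}', got {self.model!r}")
        if self.m_step < 1 or self.m_points < 1 or self.replicates < 1:
            raise ValueError("m_step, m_points and replicates must be positive")
        if not (0.0 < self.target < 1.0):
            raise ValueError(f"target must lie in (0, 1), got {self.target!r}")

    @property
    def grid(self) -> list[int]:
        return [i * self.m_step for i in range(1, self.m_points + 1)]


@dataclass(frozen=True)
class MinPatientResult:
    """Estimate plus the full success curve (m, successes, replicates)."""

    estimate: int | None
    reached: bool
    curve: tuple[tuple[int, int, int], ...]
    target: float

    def success_fractions(self) -> list[tuple[int, float]]:
        return [(m, s / r) for m, s, r in self.curve]

    def standard_errors(self) -> list[tuple[int, float]]:
        """Binomial standard error of each point's success fraction."""
        out = []
        for m, s, r in self.curve:
            p = s / r
            out.append((m, float(np.sqrt(p * (1 - p) / r))))
        return out


def _first_exceeding(
    curve: list[tuple[int, int, int]], target: float
) -> tuple[int | None, bool]:
    # first grid point whose success fraction strictly exceeds the target;
    # later dips are recorded in the curve but do not move the estimate
    for m, s, r in curve:
        if s / r > target:
            return m, True
    return None, False


def estimate_min_patients_rmg(grid: MinPatientGrid) -> MinPatientResult:
    """Empirical m_{R,x}(s(q)): minimum cohort for the recurrence test to
    report exactly the planted pathway with probability > x.

    D>P only (the equal-frequency model defeats the test at any cohort
    size).  Datasets are reduced to per-gene counts — all the test ever
    reads — so grid points at n = 10000 stay cheap.
    """
    if grid.model != DGP:
        raise ValueError("the recurrence-test protocol is defined for the D>P model")
    q_est = grid.q_est if grid.q_est is not None else grid.q
    root = np.random.SeedSequence(grid.seed)
    curve: list[tuple[int, int, int]] = []
    for m, child in zip(grid.grid, root.spawn(grid.m_points)):
        successes = 0
        for rep_seed in child.spawn(grid.replicates):
            rng = np.random.default_rng(rep_seed)
            params = DpModelParams(n=grid.n, k=grid.k, q=grid.q, m=m)
            d_counts, p_counts = simulate_dgp_counts(params, rng)
            counts = np.concatenate([d_counts, p_counts])
            outcome = rmg_test_counts(counts, m, q_est, grid.alpha, BONFERRONI)
            mask = outcome.reported_mask
            if mask[: grid.k].all() and not mask[grid.k :].any():
                successes += 1
        curve.append((m, successes, grid.replicates))
    estimate, reached = _first_exceeding(curve, grid.target)
    return MinPatientResult(estimate, reached, tuple(curve), grid.target)


def estimate_min_patients_greedy(
    grid: MinPatientGrid,
    *,
    use_pair_swap_init: bool = False,
    restarts: int = 1,
) -> MinPatientResult:
    """Empirical m_{G,x}: minimum cohort for the greedy weight maximizer to
    return exactly the planted pathway with probability > x.

    Works under either model and needs no estimate of q.  One greedy run
    per dataset by default (``restarts`` enables a best-of-R protocol);
    ``use_pair_swap_init`` switches on the double-swap initializer built
    for the equal-frequency model.
    """
    root = np.random.SeedSequence(grid.seed)
    curve: list[tuple[int, int, int]] = []
    for m, child in zip(grid.grid, root.spawn(grid.m_points)):
        successes = 0
        for rep_seed in child.spawn(grid.replicates):
            streams = rep_seed.spawn(restarts + 1)
            sim_seed = np.random.default_rng(streams[0])
            if grid.model == DGP:
                dataset = simulate_dgp(
                    DpModelParams(
                        n=grid.n,
                        k=grid.k,
                        q=grid.q,
                        m=m,
                        seed=int(sim_seed.integers(2**31)),
                    )
                )
            else:
                dataset = simulate_dep(
                    DePModelParams(
                        n=grid.n,
                        k=grid.k,
                        q=grid.q,
                        m=m,
                        seed=int(sim_seed.integers(2**31)),
                    )
                )
            truth = set(dataset.driver_set)
            hit = False
            for search_seed in streams[1:]:
                init = None
                if use_pair_swap_init:
                    init = pair_swap_init(dataset.matrix, grid.k, seed=search_seed)
                res = greedy_weight(dataset.matrix, grid.k, seed=search_seed, init=init)
                if set(res.best_set) == truth:
                    hit = True
                    break
            if hit:
                successes += 1
        curve.append((m, successes, grid.replicates))
    estimate, reached = _first_exceeding(curve, grid.target)
    return MinPatientResult(estimate, reached, tuple(curve), grid.target)


@dataclass(frozen=True)
class FalsePositiveResult:
    """Fraction of replicate datasets whose report contains any non-driver
    gene, under a (possibly misspecified) passenger-probability estimate."""

    fraction: float
    n_with_false_positive: int
    replicates: int
    q_est: float


def false_positive_experiment(
    n: int,
    k: int,
    q: float,
    m: int,
    s_factor: float,
    replicates: int,
    alpha: float,
    seed: int | None = None,
    correction: str = BONFERRONI,
) -> FalsePositiveResult:
    """Sensitivity of the recurrence test to underestimating q.

    Simulates D>P cohorts (count-level sampling) and runs the test with the
    estimate s(q) = s_factor·q.  With s_factor = 1 the Bonferroni guarantee
    caps the fraction of datasets reporting any non-driver gene at α; with
    s_factor < 1 every passenger gene's null is too optimistic and false
    positives appear at a rate that grows sharply as the estimate drops.
    """
    if s_factor <= 0:
        raise ValueError(f"s_factor must be positive, got {s_factor!r}")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates!r}")
    q_est = s_factor * q
    root = np.random.SeedSequence(seed)
    hits = 0
    params = DpModelParams(n=n, k=k, q=q, m=m)
    for rep_seed in root.spawn(replicates):
        rng = np.random.default_rng(rep_seed)
        d_counts, p_counts = simulate_dgp_counts(params, rng)
        counts = np.concatenate([d_counts, p_counts])
        outcome = rmg_test_counts(counts, m, q_est, alpha, correction)
        if outcome.reported_mask[k:].any():
            hits += 1
    return FalsePositiveResult(
        fraction=hits / replicates,
        n_with_false_positive=hits,
        replicates=replicates,
        q_est=q_est,
    )


def iterative_discovery(
    matrix: MutationMatrix,
    k: int | None = None,
    k_max: int | None = None,
    *,
    max_rounds: int | None = None,
    min_weight: int | None = None,
    seed: int | None = None,
) -> list[SearchResult]:
    """Discover multiple disjoint pathways by iterative removal.

    Repeatedly runs the weight search (fixed k, or best over sizes up to
    ``k_max``) and deletes the found genes' columns before searching again.
    Stops when fewer genes than the requested size remain, when
    ``max_rounds`` rounds have run, or when the best weight found falls
    below ``min_weight`` (that sub-threshold set is not returned).
    """
    if (k is None) == (k_max is None):
        raise ValueError("provide exactly one of k or k_max")
    size = k if k is not None else k_max
    assert size is not None
    if size < 2:
        raise ValueError("pathway size must be >= 2")
    root = np.random.SeedSequence(seed)
    results: list[SearchResult] = []
    current = matrix
    round_no = 0
    while True:
        if max_rounds is not None and round_no >= max_rounds:
            break
        if current is None or current.n < size:
            break
        child = root.spawn(1)[0]
        if k is not None:
            res = greedy_weight(current, k, seed=child)
        else:
            res = greedy_unknown_k(current, k_max, seed=int(child.generate_state(1)[0] % 2**31))
        if min_weight is not None and res.best_weight < min_weight:
            break
        results.append(res)
        round_no += 1
        remaining = [g for g in current.gene_ids if g not in set(res.best_set)]
        if len(remaining) == 0:
            break
        current = current.subset_genes(remaining)
    return results
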