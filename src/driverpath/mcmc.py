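"""Metropolis sampling over size-k gene sets, targeting Π(M) ∝ e^{c·W(M)}.

The chain's state space is the collection of all size-k gene sets.  One
step proposes replacing a uniformly chosen member v of the current set with
a gene w drawn uniformly from *all* genes, accepting with probability
min[1, e^{c·(W(M∖{v}∪{w}) − W(M))}].  When the proposed w already belongs
to the current set the move would shrink it, so the chain simply holds in
place that iteration; such self-loops do not alter the stationary law.
The proposal kernel is symmetric (probability 1/(nk) for each ordered
swap), so the chain is reversible with unique stationary distribution
Π(M) = e^{cW(M)} / Σ_R e^{cW(R)}.

Under the planted generative models, at cohort sizes where the weight
landscape has concentrated, the chain climbs to the planted pathway in
O(nk·log k) steps for any c > 0; the default iteration budget
⌈2kn·ln(2kn)⌉ comes from the coupon-collector count of driver-acquiring
swaps.  Small instances can be checked exactly against the enumerated
stationary distribution and transition matrix provided here.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .matrix import GeneSet, MutationMatrix

__all__ = [
    "McmcConfig",
    "McmcTrace",
    "default_iterations",
    "mcmc_step",
    "mcmc_run",
    "stationary_distribution",
    "transition_matrix",
]


def default_iterations(n: int, k: int, burn_in: int = 0) -> int:
    """Default chain length ⌈2kn·ln(2kn)⌉ + burn_in (coupon-collector
    budget for acquiring all k driver genes)."""
    return int(math.ceil(2 * k * n * math.log(2 * k * n))) + burn_in


@dataclass(frozen=True)
class McmcConfig:
    """Sampler configuration.

    ``c`` is the inverse-temperature coefficient of the target
    Π(M) ∝ e^{cW(M)}: larger c concentrates mass on high-weight sets
    (convergence to the planted pathway holds for any c > 0 under the
    generative models); c < 1/k additionally lies in the provably
    rapidly-mixing regime for arbitrary matrices.  ``iterations=None``
    resolves to :func:`default_iterations` at run time.
    """

    k: int
    c: float = 1.0
    iterations: int | None = None
    burn_in: int = 0
    thin: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if not self.c > 0:
            raise ValueError(f"c must be positive, got {self.c}")
        if self.burn_in < 0:
            raise ValueError(f"burn_in must be >= 0, got {self.burn_in}")
        if self.thin < 1:
            raise ValueError(f"thin must be >= 1, got {self.thin}")
        if self.iterations is not None and self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")


@dataclass
class McmcTrace:
    """Sampler output: post-burn-in state frequencies (states are sorted
    label tuples), the full per-iteration weight series, and the final
    state."""

    frequencies: Counter
    weights: np.ndarray
    final_state: GeneSet
    n_samples: int
    config: McmcConfig = field(repr=False, default=None)

    def top_sets(self, limit: int = 10) -> list[tuple[GeneSet, int]]:
        return self.frequencies.most_common(limit)

    def empirical_distribution(self) -> dict[GeneSet, float]:
        total = sum(self.frequencies.values())
        return {s: c / total for s, c in self.frequencies.items()}


def _delta_weight(
    B: np.ndarray, colsum: np.ndarray, mult: np.ndarray, v: int, w: int
) -> int:
    """ΔW for swapping member v out and outside gene w in, from the cached
    per-patient multiplicity of the current set.  O(m) per step; equals the
    full recomputation 2Δ|Γ(M)| − Δ(Σ|Γ(g)|) exactly."""
    col_v = B[:, v]
    lost = int(np.count_nonzero(col_v & (mult == 1)))
    gained = int(np.count_nonzero(B[:, w] & ((mult - col_v) == 0)))
    return 2 * (gained - lost) - int(colsum[w] - colsum[v])


def mcmc_step(
    state: GeneSet,
    matrix: MutationMatrix,
    config: McmcConfig,
    rng: np.random.Generator,
) -> GeneSet:
    """One Metropolis transition from the given state (label interface).

    Draw order: proposal gene w (uniform over all genes), outgoing member v
    (uniform over the state), then — only for well-formed proposals — the
    acceptance uniform.  Returns the next state as a sorted label tuple.
    """
    idx = matrix.gene_indices(state)
    if len(idx) != config.k:
        raise ValueError(f"state has size {len(idx)}, expected k={config.k}")
    B = matrix.boolean_entries
    colsum = matrix.column_sums
    mult = matrix.multiplicity(idx)
    w = int(rng.integers(matrix.n))
    v = int(idx[rng.integers(config.k)])
    if w in set(int(j) for j in idx):
        return tuple(sorted(state, key=matrix.gene_index))
    delta = _delta_weight(B, colsum, mult, v, w)
    if delta >= 0 or rng.random() < math.exp(config.c * delta):
        new = sorted(j for j in idx if j != v) + [w]
        return tuple(matrix.gene_ids[j] for j in sorted(new))
    return tuple(sorted(state, key=matrix.gene_index))


def mcmc_run(matrix: MutationMatrix, config: McmcConfig) -> McmcTrace:
    """Run the chain from a uniformly random size-k start.

    Records the state every ``thin`` iterations once past ``burn_in``, plus
    the weight after every iteration.  Fully deterministic given the seed.
    """
    n, k = matrix.n, config.k
    if k > n:
        raise ValueError(f"k={k} exceeds gene count n={n}")
    iterations = (
        config.iterations
        if config.iterations is not None
        else default_iterations(n, k, config.burn_in)
    )
    rng = np.random.default_rng(config.seed)
    B = matrix.boolean_entries
    colsum = matrix.column_sums

    cur = np.sort(rng.choice(n, size=k, replace=False))
    in_set = set(int(j) for j in cur)
    members = list(int(j) for j in cur)
    mult = matrix.multiplicity(cur)
    w_cur = 2 * int(np.count_nonzero(mult)) - int(colsum[cur].sum())

    weights = np.empty(iterations, dtype=np.int64)
    freq: Counter = Counter()
    n_samples = 0
    c = config.c
    for t in range(iterations):
        w = int(rng.integers(n))
        pos = int(rng.integers(k))
        v = members[pos]
        if w not in in_set:
            delta = _delta_weight(B, colsum, mult, v, w)
            if delta >= 0 or rng.random() < math.exp(c * delta):
                members[pos] = w
                in_set.remove(v)
                in_set.add(w)
                mult = mult - B[:, v] + B[:, w]
                w_cur += delta
        weights[t] = w_cur
        if t >= config.burn_in and (t - config.burn_in) % config.thin == 0:
            freq[tuple(matrix.gene_ids[j] for j in sorted(in_set))] += 1
            n_samples += 1

    final = tuple(matrix.gene_ids[j] for j in sorted(in_set))
    return McmcTrace(
        frequencies=freq,
        weights=weights,
        final_state=final,
        n_samples=n_samples,
        config=config,
    )


# ---------------------------------------------------------------------------
# Exact small-instance machinery
# ---------------------------------------------------------------------------

def _states(matrix: MutationMatrix, k: int) -> list[tuple[int, ...]]:
    return list(itertools.combinations(range(matrix.n), k))


def stationary_distribution(
    matrix: MutationMatrix, k: int, c: float, cap: int = 200_000
) -> dict[GeneSet, float]:
    """Exact Π(M) = e^{cW(M)} / Σ_R e^{cW(R)} by full enumeration.

    Weights are shifted by their maximum before exponentiating so the
    partition sum never overflows.  Refuses above ``cap`` states.
    """
    if math.comb(matrix.n, k) > cap:
        raise ValueError("state space too large to enumerate")
    states = _states(matrix, k)
    w = np.array(
        [matrix.weight_by_index(np.array(s, dtype=np.intp)) for s in states],
        dtype=np.float64,
    )
    expw = np.exp(c * (w - w.max()))
    probs = expw / expw.sum()
    return {
        tuple(matrix.gene_ids[j] for j in s): float(p) for s, p in zip(states, probs)
    }


def transition_matrix(
    matrix: MutationMatrix, k: int, c: float, cap: int = 5_000
) -> tuple[list[GeneSet], np.ndarray]:
    """Exact one-step transition matrix of the sampler by enumeration.

    State j is reachable from state i ≠ j iff they differ in exactly one
    gene; the move is proposed with probability 1/(nk) and accepted with
    min[1, e^{cΔW}].  The diagonal absorbs everything else (rejections and
    the w∈M self-loops).  Returns (states, P) with rows summing to 1.
    """
    if math.comb(matrix.n, k) > cap:
        raise ValueError("state space too large to enumerate")
    states = _states(matrix, k)
    index = {s: i for i, s in enumerate(states)}
    wts = {
        s: matrix.weight_by_index(np.array(s, dtype=np.intp)) for s in states
    }
    S = len(states)
    P = np.zeros((S, S), dtype=np.float64)
    n = matrix.n
    for s in states:
        i = index[s]
        for v in s:
            for w in range(n):
                if w in s:
                    continue
                t = tuple(sorted(set(s) - {v} | {w}))
                accept = min(1.0, math.exp(c * (wts[t] - wts[s])))
                P[i, index[t]] += accept / (n * k)
        P[i, i] = 1.0 - P[i].sum() + P[i, i]
    return [tuple(matrix.gene_ids[j] for j in s) for s in states], P
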