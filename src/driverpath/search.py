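"""Maximum-weight gene-set search: greedy local search, pair-swap
initialization for the equal-frequency regime, unknown-k wrapping, an
exhaustive oracle, and theoretical cohort-size bounds.

The optimization target is the coverage/exclusivity weight
W(M) = 2|Γ(M)| − Σ_{g∈M}|Γ(g)| over gene sets M of a fixed size k.  Finding
the global maximum is NP-hard for arbitrary matrices, but under the planted
generative models the weight landscape is benign once the cohort is large
enough: every swap that trades a passenger for a missing driver gene raises
the expected weight by Ω(m/k), so simple local search succeeds with high
probability.

The greedy search repeatedly scans the current set's members; for each
member it finds the best single-gene replacement from outside the set and
applies it when it *strictly* increases W, stopping at a fixed point.  In
the D=P model a start containing zero driver genes is a (shallow) trap, so
a one-shot best-pair double swap is offered as an initializer: it is enough
to inject at least one driver gene into the start set, after which
single-gene swaps take over.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .matrix import GeneSet, MutationMatrix, as_gene_set

__all__ = [
    "SearchResult",
    "ExhaustiveResult",
    "greedy_weight",
    "pair_swap_init",
    "greedy_unknown_k",
    "exhaustive_max_weight",
    "min_patients_greedy_dgp",
    "min_patients_greedy_dep",
]

_NEG = np.iinfo(np.int64).min


@dataclass(frozen=True)
class SearchResult:
    """Outcome of one local search run.

    ``best_set`` is reported in gene-index order; ``iterations`` counts full
    passes over the set's members and ``swaps`` the accepted replacements.
    """

    best_set: GeneSet
    best_weight: int
    iterations: int
    swaps: int
    initial_set: GeneSet
    seed: object = None


@dataclass(frozen=True)
class ExhaustiveResult:
    """All maximum-weight size-k sets (the argmax may not be unique)."""

    best_sets: tuple[GeneSet, ...]
    best_weight: int
    n_evaluated: int


def _random_init(matrix: MutationMatrix, k: int, rng: np.random.Generator) -> np.ndarray:
    return np.sort(rng.choice(matrix.n, size=k, replace=False))


def _labels(matrix: MutationMatrix, idx: np.ndarray) -> GeneSet:
    return tuple(matrix.gene_ids[j] for j in np.sort(idx))


def greedy_weight(
    matrix: MutationMatrix,
    k: int,
    seed=None,
    init: GeneSet | None = None,
    max_passes: int | None = None,
) -> SearchResult:
    """Greedy local search for a maximum-weight set of size k.

    Starting from ``init`` (or k uniformly random columns), repeatedly: for
    each member gene g of the current set, find the replacement
    g* = argmax_{g′∉M} W(M∖{g}∪{g′}) (ties broken toward the lowest column
    index) and swap g for g* iff that strictly increases W.  Passes repeat
    until one completes with no swap; each pass evaluates O(nk) candidate
    sets.  Deterministic given seed/init.

    A pass cap of k·n (overridable) guards termination; since every accepted
    swap strictly increases the integer-valued W ≤ m, the cap is never hit
    in practice and exceeding it raises ``RuntimeError``.
    """
    n, m = matrix.n, matrix.m
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    if init is not None:
        cur = np.sort(matrix.gene_indices(init))
        if len(cur) != k:
            raise ValueError(f"init has size {len(cur)}, expected k={k}")
    else:
        cur = _random_init(matrix, k, rng)
    initial_labels = _labels(matrix, cur)

    B = matrix.boolean_entries
    colsum = matrix.column_sums
    in_set = np.zeros(n, dtype=bool)
    in_set[cur] = True
    mult = matrix.multiplicity(cur)
    sum_supports = int(colsum[cur].sum())
    w_cur = 2 * int(np.count_nonzero(mult)) - sum_supports

    cap = max_passes if max_passes is not None else k * n
    passes = 0
    swaps = 0
    while True:
        passes += 1
        if passes > cap:
            raise RuntimeError(f"greedy search exceeded the pass cap ({cap})")
        changed = False
        for g in sorted(np.flatnonzero(in_set)):
            mult_r = mult - B[:, g]
            cov_r = int(np.count_nonzero(mult_r))
            zeros = (mult_r == 0).astype(np.int64)
            gains = zeros @ B  # per-candidate newly covered patients
            w_new = 2 * (cov_r + gains) - (sum_supports - colsum[g] + colsum)
            w_new[in_set] = _NEG  # candidates come from G ∖ M only
            g_star = int(np.argmax(w_new))  # first max = lowest index
            if w_new[g_star] > w_cur:
                in_set[g] = False
                in_set[g_star] = True
                mult = mult_r + B[:, g_star]
                sum_supports += int(colsum[g_star] - colsum[g])
                w_cur = int(w_new[g_star])
                swaps += 1
                changed = True
        if not changed:
            break

    final = np.flatnonzero(in_set)
    return SearchResult(
        best_set=_labels(matrix, final),
        best_weight=w_cur,
        iterations=passes,
        swaps=swaps,
        initial_set=initial_labels,
        seed=seed,
    )


def pair_swap_init(
    matrix: MutationMatrix,
    k: int,
    seed=None,
    init: GeneSet | None = None,
) -> GeneSet:
    """Initial set for the equal-frequency (D=P) regime.

    Takes a start set of size k (random if not given), removes its first two
    members (by column index), and scans *all* pairs (g₃, g₄) of outside
    genes for the one maximizing the weight after the double swap; the swap
    is applied only if it strictly improves W.  Under the D=P model with
    enough patients this guarantees the returned start contains at least one
    driver gene, which is all the single-swap greedy needs to finish the
    job.  Costs O(n²) weight evaluations.

    With fewer than two outside genes (n < k + 2) the double swap is
    impossible; a random start is returned with a warning.
    """
    n = matrix.n
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    if init is not None:
        cur = np.sort(matrix.gene_indices(init))
        if len(cur) != k:
            raise ValueError(f"init has size {len(cur)}, expected k={k}")
    else:
        cur = _random_init(matrix, k, rng)
    if n < k + 2:
        warnings.warn(
            "pair-swap initialization needs n >= k + 2 outside genes; "
            "returning a random initial set",
            stacklevel=2,
        )
        return _labels(matrix, cur)

    B = matrix.boolean_entries
    colsum = matrix.column_sums
    g1, g2 = int(cur[0]), int(cur[1])
    mult = matrix.multiplicity(cur)
    sum_supports = int(colsum[cur].sum())
    w_cur = 2 * int(np.count_nonzero(mult)) - sum_supports

    mult_r = mult - B[:, g1].astype(np.int64) - B[:, g2].astype(np.int64)
    cov_r = int(np.count_nonzero(mult_r))
    zeros = mult_r == 0
    outside = np.flatnonzero(~np.isin(np.arange(n), cur))
    Bz = B[zeros][:, outside].astype(np.int64)  # rows: uncovered patients
    single = Bz.sum(axis=0)                     # |Γ(g) ∩ Z| per candidate
    pair_int = Bz.T @ Bz                        # |Γ(g_i) ∩ Γ(g_j) ∩ Z|
    base_sum = sum_supports - int(colsum[g1]) - int(colsum[g2])

    # W for the double swap (i, j): union gain = single_i + single_j − pair_int
    gain = single[:, None] + single[None, :] - pair_int
    w_pair = 2 * (cov_r + gain) - (base_sum + colsum[outside][:, None] + colsum[outside][None, :])
    np.fill_diagonal(w_pair, _NEG)  # g3 ≠ g4
    flat = int(np.argmax(w_pair))
    i, j = divmod(flat, len(outside))
    if w_pair[i, j] > w_cur:
        new = np.sort(
            np.concatenate([cur[2:], [outside[i], outside[j]]])
        )
        return _labels(matrix, new)
    return _labels(matrix, cur)


def greedy_unknown_k(matrix: MutationMatrix, k_max: int, seed=None) -> SearchResult:
    """Search without knowing the pathway size: run the greedy for every
    2 ≤ k ≤ k_max and return the best set of any size, ties going to the
    smaller k.  Sound because, at cohort sizes meeting the model bounds,
    the planted pathway outweighs every other set of every size."""
    if k_max < 2:
        raise ValueError(f"k_max must be >= 2, got {k_max}")
    if k_max > matrix.n:
        raise ValueError(f"k_max={k_max} exceeds gene count n={matrix.n}")
    children = np.random.SeedSequence(seed).spawn(k_max - 1)
    best: SearchResult | None = None
    for k, child in zip(range(2, k_max + 1), children):
        res = greedy_weight(matrix, k, seed=child)
        if best is None or res.best_weight > best.best_weight:
            best = res
    assert best is not None
    return best


def exhaustive_max_weight(
    matrix: MutationMatrix, k: int, cap: int = 2_000_000
) -> ExhaustiveResult:
    """Brute-force oracle: enumerate every size-k set and return the full
    collection of maximum-weight sets.  Refuses when C(n, k) exceeds
    ``cap``; meant for small instances and for validating the heuristics."""
    n = matrix.n
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n, got k={k}, n={n}")
    total = math.comb(n, k)
    if total > cap:
        raise ValueError(
            f"C({n},{k}) = {total} exceeds the enumeration cap ({cap}); "
            "use the greedy or MCMC search instead"
        )
    B = matrix.boolean_entries
    colsum = matrix.column_sums
    best_w = None
    best: list[GeneSet] = []
    for combo in itertools.combinations(range(n), k):
        idx = np.array(combo, dtype=np.intp)
        cov = int(np.count_nonzero(B[:, idx].any(axis=1)))
        w = 2 * cov - int(colsum[idx].sum())
        if best_w is None or w > best_w:
            best_w = w
            best = [tuple(matrix.gene_ids[j] for j in combo)]
        elif w == best_w:
            best.append(tuple(matrix.gene_ids[j] for j in combo))
    assert best_w is not None
    return ExhaustiveResult(best_sets=tuple(best), best_weight=best_w, n_evaluated=total)


def min_patients_greedy_dgp(k: int, n: int, eps: float) -> int:
    """Cohort-size bound m ≥ 8k³(k+ε)·ln n under which, in the D>P model
    with q ≤ 1/(4k), the weight of every size-k set concentrates tightly
    enough that (a) the planted pathway is the unique global maximum and
    (b) the greedy search finds it, each with failure probability ≤ 1/n^ε.
    A worst-case bound: empirical cohort sizes are orders of magnitude
    smaller."""
    if not (isinstance(k, (int, np.integer)) and k >= 2):
        raise ValueError(f"k must be an integer >= 2, got {k!r}")
    if not (isinstance(n, (int, np.integer)) and n >= 2):
        raise ValueError(f"n must be an integer >= 2, got {n!r}")
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps!r}")
    return int(math.ceil(8.0 * k**3 * (k + eps) * math.log(n)))


def min_patients_greedy_dep(k: int, n: int, eps: float, q: float) -> int:
    """Cohort-size bound for the equal-frequency (D=P) model:

        m ≥ k³(k+ε)·ln n / (2·((1−q)^k + (1/k)·((k−1)/k)^k)²),

    derived from the per-driver expected-weight increment of that model.
    The published rendering of this bound is typographically ambiguous, so
    the adopted reading is isolated here; treat the output as an
    order-of-magnitude figure only.  When passenger mutations are rare
    (q ≈ 1/k, and (1−q)^k ≥ ((k−1)/k)^k / 2) it is of the same order as
    :func:`min_patients_greedy_dgp`."""
    if not (isinstance(k, (int, np.integer)) and k >= 2):
        raise ValueError(f"k must be an integer >= 2, got {k!r}")
    if not (isinstance(n, (int, np.integer)) and n >= 2):
        raise ValueError(f"n must be an integer >= 2, got {n!r}")
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps!r}")
    if not (1.0 / k <= q < 1.0):
        raise ValueError(f"D=P bound requires 1/k <= q < 1, got q={q!r}, k={k!r}")
    increment = (1.0 - q) ** k + ((k - 1) / k) ** k / k
    bound = k**3 * (k + eps) * math.log(n) / (2.0 * increment**2)
    return int(math.ceil(bound))
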