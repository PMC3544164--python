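"""Generative models of somatic mutation matrices with one planted driver pathway.

Both models share the same skeleton: a cohort of m patients is screened over
n genes, of which a hidden subset D of size k is the *driver pathway*.  In
every patient exactly one gene of D, chosen uniformly at random, carries the
driver mutation; passenger mutations fall independently on genes with a
per-gene, per-patient probability q.  The models differ in the marginal
mutation frequency of the driver genes:

* **D>P model** — besides the forced driver entry, every other entry of the
  row (driver columns included) is Bernoulli(q).  A driver gene is then
  mutated with probability 1/k + (1−1/k)q > q, so drivers are marginally
  *more* frequent than passengers and a recurrence test can find them given
  enough patients.

* **D=P model** — the non-assigned driver entries are instead Bernoulli(r)
  with r = (qk−1)/(k−1), which requires q ≥ 1/k and makes every gene's
  marginal mutation probability exactly q (since 1/k + (1−1/k)r = q).
  Driver and passenger column counts are then identically distributed, so no
  single-gene frequency test can separate them — only the joint
  coverage/exclusivity structure can.

Randomness is consumed in a documented, fixed order (per-patient driver
assignments first, then the Bernoulli field row-major), so a given parameter
set and seed reproduces the same dataset bit-for-bit on any platform.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matrix import GeneSet, MutationMatrix

__all__ = [
    "DpModelParams",
    "DePModelParams",
    "SimulatedDataset",
    "LowPassengerRegimeWarning",
    "exclusive_rate_r",
    "simulate_dgp",
    "simulate_dep",
    "simulate_dgp_counts",
    "expected_weight_dgp",
]


class LowPassengerRegimeWarning(UserWarning):
    """The concentration analysis assumes q ≤ 1/(4k); simulation outside this
    regime is legitimate but the theoretical guarantees need not hold."""


def _validate_common(n: int, k: int, q: float, m: int) -> None:
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if not (isinstance(k, (int, np.integer)) and 2 <= k <= n):
        raise ValueError(f"k must satisfy 2 <= k <= n, got k={k!r}, n={n!r}")
    if not (0.0 <= q < 1.0):
        raise ValueError(f"q must lie in [0, 1), got {q!r}")
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise ValueError(f"m must be a positive integer, got {m!r}")


@dataclass(frozen=True)
class DpModelParams:
    """Parameters of the D>P model.

    Attributes
    ----------
    n, k, q, m
        Gene count, driver-pathway size, passenger mutation probability per
        gene per patient, and patient count.
    seed
        RNG seed; ``None`` draws fresh entropy.
    """

    n: int
    k: int
    q: float
    m: int
    seed: int | None = None

    def __post_init__(self) -> None:
        _validate_common(self.n, self.k, self.q, self.m)
        if not self.in_low_passenger_regime:
            warnings.warn(
                f"q={self.q} exceeds 1/(4k)={1 / (4 * self.k):.4g}; the "
                "weight-concentration guarantees assume q <= 1/(4k)",
                LowPassengerRegimeWarning,
                stacklevel=2,
            )

    @property
    def in_low_passenger_regime(self) -> bool:
        """Advisory flag: whether q ≤ 1/(4k), the regime the theory assumes."""
        return self.q <= 1.0 / (4 * self.k)


@dataclass(frozen=True)
class DePModelParams:
    """Parameters of the D=P model.  Requires q ≥ 1/k so that the
    within-pathway rate r = (qk−1)/(k−1) is a proper probability."""

    n: int
    k: int
    q: float
    m: int
    seed: int | None = None

    def __post_init__(self) -> None:
        _validate_common(self.n, self.k, self.q, self.m)
        if self.q < 1.0 / self.k:
            raise ValueError(
                f"D=P model requires q >= 1/k (got q={self.q}, 1/k={1 / self.k:.4g})"
            )

    @property
    def r(self) -> float:
        return exclusive_rate_r(self)


@dataclass(frozen=True)
class SimulatedDataset:
    """A simulated matrix together with its planted ground truth.

    ``driver_set`` lists the k planted driver genes; ``driver_assignment``
    gives, per patient (aligned with ``matrix.patient_ids``), the driver
    gene forced to 1 in that patient.
    """

    matrix: MutationMatrix
    driver_set: GeneSet
    driver_assignment: tuple[str, ...]

    def __post_init__(self) -> None:
        drivers = set(self.driver_set)
        if len(drivers) != len(self.driver_set):
            raise ValueError("driver_set contains duplicates")
        if len(self.driver_assignment) != self.matrix.m:
            raise ValueError("driver_assignment length must equal patient count")
        for p, g in zip(self.matrix.patient_ids, self.driver_assignment):
            if g not in drivers:
                raise ValueError(f"assigned driver {g!r} not in driver_set")
            if self.matrix.entry(p, g) != 1:
                raise ValueError(f"assigned driver {g!r} not mutated in patient {p!r}")


def exclusive_rate_r(params: DePModelParams) -> float:
    """Within-pathway mutation rate r = (qk−1)/(k−1) of the D=P model.

    This is the unique rate at which the non-assigned driver entries must be
    flipped so that the marginal identity 1/k + (1−1/k)·r = q holds, i.e. so
    that driver genes are mutated exactly as often as passengers.
    """
    k, q = params.k, params.q
    if q < 1.0 / k:
        raise ValueError(f"r is a probability only for q >= 1/k (q={q}, k={k})")
    # q == 1/k can leave q·k − 1 a few ulp below zero; clamp to exact 0
    return max(0.0, (q * k - 1.0) / (k - 1.0))


def _labels(m: int, n: int) -> tuple[list[str], list[str]]:
    return [f"p{i + 1}" for i in range(m)], [f"g{j + 1}" for j in range(n)]


def _finish(
    data: np.ndarray,
    assignment_idx: np.ndarray,
    params,
    rng: np.random.Generator,
    shuffle_genes: bool,
) -> SimulatedDataset:
    m, n, k = params.m, params.n, params.k
    patient_ids, gene_ids = _labels(m, n)
    driver_set = tuple(gene_ids[:k])
    assignment = tuple(gene_ids[j] for j in assignment_idx)
    if shuffle_genes:
        perm = rng.permutation(n)
        data = data[:, perm]
        gene_ids = [gene_ids[j] for j in perm]
    matrix = MutationMatrix(data, patient_ids, gene_ids)
    return SimulatedDataset(matrix=matrix, driver_set=driver_set, driver_assignment=assignment)


def simulate_dgp(params: DpModelParams, *, shuffle_genes: bool = False) -> SimulatedDataset:
    """Draw one mutation matrix from the D>P model.

    Per patient, one of the first k genes (the planted pathway, by the
    package's labelling convention) is chosen uniformly to carry the driver
    mutation; every other entry of the row is independently Bernoulli(q).
    With ``shuffle_genes`` the columns are randomly permuted afterwards —
    labels travel with their columns, so the recorded ``driver_set`` remains
    valid while the drivers no longer sit in the leading columns.
    """
    rng = np.random.default_rng(params.seed)
    m, n, k, q = params.m, params.n, params.k, params.q
    assignment = rng.integers(k, size=m)
    data = (rng.random((m, n)) < q).astype(np.uint8)
    data[np.arange(m), assignment] = 1
    return _finish(data, assignment, params, rng, shuffle_genes)


def simulate_dep(params: DePModelParams, *, shuffle_genes: bool = False) -> SimulatedDataset:
    """Draw one mutation matrix from the D=P model.

    Per patient: one driver gene is forced to 1; the other k−1 driver entries
    are Bernoulli(r) with r = (qk−1)/(k−1); the n−k passenger entries are
    Bernoulli(q).  Every gene's marginal mutation probability is exactly q.
    """
    rng = np.random.default_rng(params.seed)
    m, n, k, q = params.m, params.n, params.k, params.q
    r = exclusive_rate_r(params)
    assignment = rng.integers(k, size=m)
    driver_block = (rng.random((m, k)) < r).astype(np.uint8)
    driver_block[np.arange(m), assignment] = 1
    passenger_block = (rng.random((m, n - k)) < q).astype(np.uint8)
    data = np.concatenate([driver_block, passenger_block], axis=1)
    return _finish(data, assignment, params, rng, shuffle_genes)


def simulate_dgp_counts(
    params: DpModelParams, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sample only the per-gene mutation *counts* of a D>P dataset.

    A recurrence test reads nothing but column sums, and under the D>P model
    these have a simple exact law: a passenger gene's count is
    Binomial(m, q); a driver gene's count is N_d + Binomial(m − N_d, q)
    where (N_1, …, N_k) ~ Multinomial(m, 1/k each) are the per-gene driver
    assignment totals.  Sampling counts directly is O(n) per dataset instead
    of O(mn), which makes cohort-level experiments at n = 10000 cheap.

    Returns ``(driver_counts, passenger_counts)`` of lengths k and n − k.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    m, n, k, q = params.m, params.n, params.k, params.q
    assigned = rng.multinomial(m, np.full(k, 1.0 / k))
    driver_counts = assigned + rng.binomial(m - assigned, q)
    passenger_counts = rng.binomial(m, q, size=n - k)
    return driver_counts.astype(np.int64), passenger_counts.astype(np.int64)


def expected_weight_dgp(m: int, k: int, q: float, l: int) -> float:
    """Exact expected weight E[W(M_{k,ℓ})] of a size-k set containing ℓ
    planted driver genes, under the D>P model.

    Per-patient contribution: with probability ℓ/k the patient's assigned
    driver lies in the set (contribution 2 − (1 + q(k−1))); otherwise all k
    member entries are independent Bernoulli(q) (contribution
    2(1 − (1−q)^k) − qk).  Summing over m patients:

        E[W] = m·[(1 − q(k−1))·ℓ/k + (2(1 − (1−q)^k) − qk)·(1 − ℓ/k)].

    At ℓ = k this reduces to m(1 − q(k−1)); at q = 0, ℓ = k it equals m
    (a perfect mutually exclusive cover).
    """
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ValueError(f"k must be a positive integer, got {k!r}")
    if not (isinstance(l, (int, np.integer)) and 0 <= l <= k):
        raise ValueError(f"l must lie in [0, k], got {l!r}")
    if not (0.0 <= q < 1.0):
        raise ValueError(f"q must lie in [0, 1), got {q!r}")
    if m < 0:
        raise ValueError(f"m must be non-negative, got {m!r}")
    in_set = 2.0 - (1.0 + q * (k - 1))
    out_set = 2.0 * (1.0 - (1.0 - q) ** k) - q * k
    frac = l / k
    return m * (in_set * frac + out_set * (1.0 - frac))
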