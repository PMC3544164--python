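"""Single-gene recurrence testing with multiple-testing correction.

The classical route to driver genes: a gene not under selection is mutated
in a number of patients distributed Binomial(m, q), where q is the per-gene
passenger mutation probability (the background mutation rate aggregated
over the gene's length).  A gene mutated in c patients therefore gets the
exact upper-tail p-value p = Pr[B(m, q) ≥ c], and genes surviving a
family-wise correction across the n tested genes are reported as
recurrently mutated.

The whole approach hinges on the supplied estimate of q: an underestimate
manufactures false positives, an overestimate costs patients.  The
sample-size calculator quantifies the cohort needed when q is known
exactly; under the D=P model (see :mod:`driverpath.models`) the test is
provably powerless at any cohort size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import GeneSet, MutationMatrix

__all__ = [
    "TestOutcome",
    "binomial_tail",
    "rmg_test",
    "rmg_test_counts",
    "min_patients_single_gene",
    "family_wise_alpha",
]

BONFERRONI = "bonferroni"
BH = "bh"


@dataclass(frozen=True)
class TestOutcome:
    """Result of the recurrence test over all genes of a matrix."""

    gene_ids: tuple[str, ...]
    counts: np.ndarray          # per-gene mutation counts |Γ(g)|
    p_values: np.ndarray        # exact binomial upper tails
    alpha: float
    correction: str
    reported_mask: np.ndarray   # True where the gene is called recurrent

    @property
    def reported(self) -> GeneSet:
        """The reported gene set O, in matrix column order."""
        return tuple(g for g, r in zip(self.gene_ids, self.reported_mask) if r)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "count": self.counts,
                "p_value": self.p_values,
                "reported": self.reported_mask,
            }
        )


def binomial_tail(count: int, m: int, q: float) -> float:
    """Exact upper tail Pr[B(m, q) ≥ count].

    Evaluated through the regularized incomplete beta function (scipy's
    binomial survival function), which stays accurate down to ~1e-300 —
    needed because Bonferroni thresholds α/n reach 1e-7 and the observed
    tails can be far smaller.
    """
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise ValueError(f"m must be a positive integer, got {m!r}")
    if not (isinstance(count, (int, np.integer)) and 0 <= count <= m):
        raise ValueError(f"count must lie in [0, m], got {count!r}")
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"q must lie in [0, 1], got {q!r}")
    if count == 0:
        return 1.0
    return float(stats.binom.sf(count - 1, m, q))


def _tail_vector(counts: np.ndarray, m: int, q: float) -> np.ndarray:
    p = stats.binom.sf(counts - 1, m, q)
    return np.where(counts == 0, 1.0, p)


def _report_mask(p_values: np.ndarray, alpha: float, correction: str) -> np.ndarray:
    n = len(p_values)
    if correction == BONFERRONI:
        # inclusive comparison, matching the test's reporting rule
        return p_values <= alpha / n
    if correction == BH:
        reject, _, _, _ = multipletests(p_values, alpha=alpha, method="fdr_bh")
        return reject
    raise ValueError(f"unknown correction: {correction!r}")


def rmg_test_counts(
    counts: Sequence[int] | np.ndarray,
    m: int,
    q_est: float,
    alpha: float,
    correction: str = BONFERRONI,
    gene_ids: Sequence[str] | None = None,
) -> TestOutcome:
    """Recurrence test on per-gene mutation counts.

    This is the count-level core of :func:`rmg_test`; it exists separately
    because large simulation studies can sample column counts directly
    (see :func:`driverpath.models.simulate_dgp_counts`) without ever
    materializing an m × n matrix.
    """
    if not (0.0 < q_est < 1.0):
        raise ValueError(f"q_est must lie in (0, 1), got {q_est!r}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise ValueError(f"m must be a positive integer, got {m!r}")
    counts = np.asarray(counts, dtype=np.int64)
    if counts.ndim != 1 or len(counts) == 0:
        raise ValueError("counts must be a non-empty 1-D sequence")
    if counts.min() < 0 or counts.max() > m:
        raise ValueError("counts must lie in [0, m]")
    if gene_ids is None:
        gene_ids = tuple(f"g{j + 1}" for j in range(len(counts)))
    else:
        gene_ids = tuple(gene_ids)
        if len(gene_ids) != len(counts):
            raise ValueError("gene_ids length must match counts")
    p = _tail_vector(counts, m, q_est)
    mask = _report_mask(p, alpha, correction)
    return TestOutcome(
        gene_ids=gene_ids,
        counts=counts,
        p_values=p,
        alpha=float(alpha),
        correction=correction,
        reported_mask=np.asarray(mask, dtype=bool),
    )


def rmg_test(
    matrix: MutationMatrix,
    q_est: float,
    alpha: float,
    correction: str = BONFERRONI,
) -> TestOutcome:
    """Test every gene of a matrix for recurrent mutation.

    Computes p_g = Pr[B(m, q_est) ≥ |Γ(g)|] for each gene and reports the
    set O of genes passing the chosen correction: Bonferroni reports g iff
    p_g ≤ α/n (guaranteeing that the probability of reporting any
    non-driver gene is at most α), BH runs the standard step-up at level α.
    Deterministic given the matrix and parameters.
    """
    return rmg_test_counts(
        matrix.column_sums,
        matrix.m,
        q_est,
        alpha,
        correction,
        gene_ids=matrix.gene_ids,
    )


def family_wise_alpha(n: int, eps: float) -> float:
    """The significance level α = 1/(2n^ε) paired with the sample-size bound.

    At this α the recurrence test recovers exactly the driver pathway with
    failure probability at most 1/n^ε once the cohort reaches
    :func:`min_patients_single_gene`.
    """
    if not (isinstance(n, (int, np.integer)) and n >= 2):
        raise ValueError(f"n must be an integer >= 2, got {n!r}")
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps!r}")
    return 1.0 / (2.0 * n**eps)


def min_patients_single_gene(k: int, n: int, eps: float, q: float) -> int:
    """Smallest cohort size m guaranteeing the recurrence test succeeds
    with high probability under the D>P model.

    Implements the reading m ≥ 2k²(1+ε)·ln(2n)/(1−q)², under which, with
    α = 1/(2n^ε) (see :func:`family_wise_alpha`) and a perfect estimate of
    q, the reported set equals the planted driver pathway with probability
    at least 1 − 1/n^ε.  The algebraic form is isolated here on purpose:
    the published rendering of the bound is typographically ambiguous, and
    this function is the single place encoding the adopted reading.  Treat
    the output as an order-of-magnitude planning figure, not a sharp
    threshold — the empirical cohort sizes are far smaller.
    """
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ValueError(f"k must be a positive integer, got {k!r}")
    if not (isinstance(n, (int, np.integer)) and n >= 2):
        raise ValueError(f"n must be an integer >= 2, got {n!r}")
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps!r}")
    if not (0.0 <= q < 1.0):
        raise ValueError(f"q must lie in [0, 1), got {q!r}")
    bound = 2.0 * k**2 * (1.0 + eps) * math.log(2 * n) / (1.0 - q) ** 2
    return int(math.ceil(bound))
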