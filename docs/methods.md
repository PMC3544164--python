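# Methods

## Data model

A cohort is an m × n binary incidence matrix A over labelled patients and
genes; A[i, g] = 1 iff gene g carries a somatic mutation in patient i.
Internally all indexing is 0-based positional and labels live only at the
I/O boundary, so file identity is decoupled from array layout. Per-gene
supports Γ(g) and column sums are cached immutably on the matrix, because
the search algorithms evaluate many overlapping sets: a weight evaluation
costs O(Σ|Γ(g)|), and the Metropolis sampler uses an incremental ΔW
(per-patient multiplicity counter) costing O(|Γ(v)| + |Γ(w)|) per step,
verified in the tests against full recomputation.

Patients with all-zero rows are legal input (real cohorts contain them);
the simulators never produce them, but no scoring code assumes full
coverage. In the sparse pair-list format, duplicate (patient, gene) events
collapse idempotently to a single 1 with a logged warning, and an explicit
gene universe can be supplied so never-mutated genes survive a round trip.

## Generative models

Both simulators plant a driver pathway D of size k: per patient, one gene
of D chosen uniformly i.i.d. carries the driver mutation (uniform is taken
literally — no balancing across patients). Passenger mutations are
independent Bernoulli(q) per gene per patient. q aggregates the
per-nucleotide background mutation rate over a gene's length, hence the
realistic range q ≈ 10⁻² – 10⁻¹; a single q is shared by all genes
(per-gene background modelling is out of scope by design).

- D>P: all non-forced entries, driver columns included, are Bernoulli(q).
  Driver marginal frequency: 1/k + (1 − 1/k)q > q.
- D=P: the non-forced driver entries are Bernoulli(r) with
  r = (qk − 1)/(k − 1), requiring q ≥ 1/k; then every gene's marginal is
  exactly q (the identity 1/k + (1 − 1/k)r = q holds to machine precision;
  q·k a few ulp under 1 is clamped so r is never a negative zero-width
  artifact).

Randomness is consumed in a documented order — per-patient driver
assignments first, then the Bernoulli field row-major — from one
numpy Generator per dataset, so (params, seed) reproduces a dataset
bit-for-bit. Driver genes occupy the first k labels by convention; a
shuffle flag permutes columns (labels travel with columns) so discovery
code can be tested without positional leakage, and the planted truth is
always recorded separately from the matrix.

A count-level sampler mirrors the D>P column-sum law exactly
(passenger counts Binomial(m, q); driver counts N_d + Binomial(m − N_d, q)
with multinomial assignment totals N). Experiments that only read column
sums — everything involving the recurrence test — use it to run cohorts of
n = 10000 genes in O(n) per dataset.

The theory's low-passenger regime q ≤ 1/(4k) (the constant 1/4 standing in
for "a set of k passenger genes misses most patients") is an advisory
flag plus warning, not an error: simulating outside the regime is
legitimate, the guarantees just need not hold there.

## Recurrence test

p_g = Pr[B(m, q_est) ≥ |Γ(g)|], evaluated by scipy's binomial survival
function (regularized incomplete beta), accurate in the far tail where
Bonferroni thresholds α/n ~ 10⁻⁷ live; a normal approximation would not
be. Bonferroni reports g iff p_g ≤ α/n with n the number of genes actually
tested, comparison inclusive; Benjamini–Hochberg (statsmodels step-up) is
offered as an alternative, with Bonferroni the default. The companion
significance level α = 1/(2n^ε) and the cohort-size bound
m ≥ 2k²(1+ε)·ln(2n)/(1 − q)² are provided as calculators. The published
typesetting of that bound is ambiguous; the adopted algebraic reading is
isolated in a single function (`min_patients_single_gene`) so it can be
swapped, and its output is treated as an order-of-magnitude planning
figure, never asserted against a printed value.

## Weight maximization

W(M) = 2|Γ(M)| − Σ|Γ(g)| is maximized by:

- **Greedy local search.** From a random (or supplied) size-k start,
  repeated passes over the members; for each member the best outside
  replacement is computed vectorized (one m-vector/matrix product per
  member) and applied on strict improvement, lowest column index winning
  ties. The original single pass over the initial members is generalized
  to passes-until-fixed-point, which strictly dominates it; a k·n pass cap
  guarantees termination (unreachable in practice since W is integer,
  bounded by m, and strictly increases per accepted swap). Candidates are
  drawn from G ∖ M only, and an equal-weight candidate is *not* swapped.
- **Pair-swap initialization** for the equal-frequency regime: remove the
  start's first two members, scan all outside pairs for the best double
  swap, apply on strict improvement. Rationale: under D=P a start with
  zero driver genes is a local trap for single swaps (each driver alone
  adds coverage r-correlated with the others), but the best *pair* of
  entering genes is, with high probability, a driver pair; one such
  injection suffices. With n < k + 2 there is no outside pair and a random
  start is returned with a warning.
- **Unknown k**: run the fixed-k greedy for 2 ≤ k ≤ k_max and keep the
  best weight found, ties to the smaller k — justified because at
  sufficient cohort size the planted pathway outweighs every set of every
  size.
- **Exhaustive oracle**: full enumeration below a configurable C(n, k) cap
  (default 2·10⁶), returning *all* argmax sets (the maximum need not be
  unique, e.g. under duplicated columns).

Cohort-size bound calculators: m ≥ 8k³(k+ε)·ln n (D>P), and for D=P
m ≥ k³(k+ε)·ln n / (2·((1−q)^k + (1/k)·((k−1)/k)^k)²), the latter derived
from that model's per-driver expected-weight increment because its
published typesetting is also ambiguous; both are isolated, documented as
worst-case figures, and empirically the greedy succeeds at cohort sizes
orders of magnitude smaller.

The closed-form expectation under D>P for a size-k set with ℓ planted
drivers,

    E[W(M_{k,ℓ})] = m[(1 − q(k−1))·ℓ/k + (2(1 − (1−q)^k) − qk)·(1 − ℓ/k)],

is exact (not a bound) and is checked against Monte-Carlo means; in the
regime q ≤ 1/(4k) each additional driver raises it by at least m/(2k),
which is what makes the greedy landscape benign.

## Metropolis sampler

States are size-k sets; a step proposes replacing a uniformly chosen
member v with a gene w uniform over *all* n genes, accepting with
min[1, e^{c·ΔW}]. A proposal with w already in the set would shrink it, so
the chain self-loops that iteration — preserving the size-k state space
and the stationary law Π(M) ∝ e^{cW(M)} (the proposal kernel is symmetric,
1/(nk) per ordered swap, so the chain is reversible; verified exactly by
transition-matrix enumeration on small instances). Defaults: c = 1.0
(convergence to the planted pathway holds for any c > 0 under the models;
c < 1/k additionally gives provable rapid mixing for arbitrary matrices —
the practical choice of c is genuinely open and left configurable) and an
iteration budget ⌈2kn·ln(2kn)⌉ + burn-in from the coupon-collector count
of driver-acquiring swaps.

## Experimental protocols and problem sizes

The empirical minimum cohort m_{R,x}(s(q)) / m_{G,x} is the *first* grid
point m_i = i·step whose exact-recovery fraction over the replicates
exceeds x; success means the output set equals the planted D exactly, and
later dips of the curve (binomial noise) do not move the estimate, though
the full curve with binomial standard errors is always reported. One
greedy run per dataset is the default, matching a single-run discovery
protocol; multi-restart is a flag.

Problem sizes used by the shipped checks were chosen to make each claim
sharp at desk scale: the false-positive and family-wise-error experiments
run at the full cohort scale (n = 10000, k = 20, m = 1000) via count-level
sampling; the equal-frequency minimum-cohort protocol ships in a
scaled-down form (n = 30, k = 4, q = 0.25, grid step 250 × 12 points, 40
replicates) with the pair-swap initializer — at this small n a random
start misses the pathway entirely about half the time, so the initializer
is the scientifically appropriate protocol, and the full-scale
(n = 120, k = 20, grid to 10⁵) run remains available through the same API
and CLI. The MCMC stationarity check uses an enumerable instance
(n = 6, k = 2, m = 8; 15 states) with 2·10⁵ retained samples, where the
total-variation gap to the exact law lands well inside the 0.05 criterion
and shrinks as the sample count grows.

Iterative discovery of multiple disjoint pathways removes each found
set's columns and searches again, stopping on a round cap, a weight
floor, or gene exhaustion.

## What the simulations do and do not show

The generators embody idealized assumptions: exactly one driver mutation
per patient within a single planted pathway, a constant q across genes,
independent passengers, fully assayed gene panels. Real cohorts violate
all four (per-gene background rates vary with length, replication timing
and expression; pathways overlap; co-occurring drivers exist; panels are
incomplete), so passing the simulation checks demonstrates correctness of
the algorithms under the stated models — not that the weight function
will dominate on any particular real dataset. The multi-restart machinery
needed for real-data runs (report the best set and its frequency across
restarts) is included, but no real matrices are bundled and no claim about
them is tested here.

## Numerical choices

Binomial tails via the regularized incomplete beta, never a normal
approximation; Bonferroni comparison inclusive (≤); greedy and argmax ties
broken to the lowest column index for determinism; strict improvement
required for every accepted move (greedy and pair swap); stationary-law
enumeration shifts weights by their maximum before exponentiating to avoid
overflow; all experiment-level randomness derives from one seed through a
spawned SeedSequence tree, so every reported number is a pure function of
(config, seed).
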