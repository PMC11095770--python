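# Methods

## The objects

A partite 3-uniform hypergraph `H = (A, B, C, E)` has three disjoint
vertex classes and hyperedges that take exactly one vertex from each
class; we encode an edge as an index triple `(i, j, k)` and require
simplicity (no parallel edges), so `H` is a 0-1 tensor of shape
`n1 x n2 x n3`.  The degree of a vertex is the number of incident
hyperedges; a degree sequence `D = (D_A, D_B, D_C)` is *graphic* when some
simple hypergraph realizes it.  These objects model (agent, event type,
time point) records: each agent's activity, each event type's frequency
and each time point's load are exactly the three degree lists.

Deciding graphicality is NP-complete in general (the package carries the
reduction from numerical 3-dimensional matching that proves it, as a
generator of hard/diagnostic instances).  Two tractable islands are
implemented exactly:

* **Third almost-regular sequences** — every degree in class A equal to
  `k` or `k-1`.  Graphicality is then decidable, and a realization
  constructible, in polynomial time (`realize_third_almost_regular`).
* **Desk-scale instances** — exhaustively enumerable by backtracking
  (`oracle` module), used as ground truth throughout the test suite.

## The polynomial constructor

The pipeline is: (1) realize `(D_A, D_B)` as a bipartite multigraph by
north-west-corner filling; (2) *B-balance* the multiplicity matrix —
make every column hold only two values differing by one — by
margin-preserving exchanges, processing columns in ascending order and
rows lowest-index first (any order terminates; fixing one makes runs
reproducible); each exchange lowers the current column's L1 deviation
from its forced balanced values by 2, so the run ends within half the
initial deviation; (3) treat the balanced entries as degrees of the
`n1*n2` pair-vertices `(a_i, b_j)` and realize the bipartite *simple*
graph towards class C (the shadow) by the greedy maximal-degree-first
construction, which succeeds exactly when the Gale–Ryser inequalities
hold; (4) lift each shadow edge `((a_i, b_j), c_k)` to the hyperedge
`(a_i, b_j, c_k)`.  The sequence is graphic iff step 3 succeeds;
failures return a typed `Infeasible` certificate naming the violated
condition (class sums, capacity, or the Gale–Ryser index).

`flatten_class_by_hinge_flips` is the constructive half of the
irreducibility argument behind the sampler: any realization reaches an
almost-regular first class by hinge flips, each flip moving one hyperedge
from the largest-index over-target vertex to the smallest-index
under-target one (a free `(b, c)` slot exists by counting), so the flip
count is exactly half the initial L1 distance.  The canonical flat target
(`flat_target`) puts the ceiling values at the low indices, following the
sorted convention of the underlying argument.

## The sampler

Switches alone are not irreducible on the realizations of a fixed degree
sequence — `(2,4,7)^3` has exactly two realizations, six hyperedges
apart, and a switch moves only four — so the chain walks on *all* simple
hypergraphs over the fixed classes, with the energy

    Delta_G(H) = sum_v |d(v) - d_H(v)|

(the L1 deviation from the target) and stationary law
`pi_T(H) ∝ exp(-Delta_G(H)/T)`.  Realizations are exactly the zero-energy
states.  One step draws, with probability 1/3 each:

* a **switch** — two edges drawn independently uniformly (with
  replacement) and a uniform class whose vertices are exchanged; energy
  never changes, so valid switches are always accepted;
* a **hinge flip** — a uniform edge, class, and replacement vertex drawn
  from the class excluding the current one; changes two degrees by one,
  so the energy moves by -2, 0 or +2;
* a **toggle** — a uniform cell, deleted if occupied, inserted otherwise;
  moves three degrees, energy change in {-3, -1, +1, +3}.

A proposal that would duplicate an edge, repeats the same switch edge, or
cannot be formed (empty edge set, singleton class) is an *invalid*
proposal: the step counts and the state stays, which keeps the proposal
kernel symmetric (checked exhaustively in the tests) and makes the plain
Metropolis ratio `exp(-(ΔG' - ΔG)/T)` the correct acceptance rule.
Acceptance probabilities for the (small integer) uphill energy gaps are
cached per chain; at very cold temperatures the exponential underflows to
zero, which is the correct limit, so no log-space machinery is needed.

**Parallel Tempering** couples chains at `T_1 < ... < T_k`: each
composite move either advances one uniformly chosen chain or proposes to
swap a uniformly chosen adjacent pair of states, accepted with
probability `min(1, exp((G_i - G_{i+1})(1/T_i - 1/T_{i+1})))`.  Every
marginal keeps its own Boltzmann law (verified against full enumeration
on a 16-state space), while swaps let the cold chain tunnel between
energy minima.  All randomness of a run flows through a single seeded
generator, so runs are bit-reproducible.

### Ladder design

Temperatures follow a quartile-matching rule.  Independent probe chains
estimate the energy's lower/upper quartiles on a log-spaced temperature
grid (default 100 points from 0.1 to the infinite-temperature energy
estimate `sum_v |d(v) - max_deg(v)/2|`); probes run coldest-first, each
warm-starting from the previous probe's final state, and discard the
first 20% as burn-in.  The quartile curves are made monotone in log-T by
isotonic regression (pool-adjacent-violators — the canonical monotone
smoother).  The coldest temperature is the smallest probed T whose
zero-energy occupancy exceeds 90% (so realizations dominate there); the
warmest is the smallest probed T whose median energy is within 5% of the
infinite-temperature estimate (so the hot chain is essentially mixing on
the uniform law).  The ladder then walks a staircase: the next
temperature is where the lower-quartile curve reaches the current upper
quartile, inverted on the log-linear interpolant.  Because the energy is
integer-valued the smoothed curves can be locally flat and the inverse
can stall; progress is then clamped to the next probe grid point, and
entirely flat curves (no quartile information at all) fall back to the
two endpoints with a warning.  Matched quartiles make the colder state
the more energetic one with probability at least `(1/4)^2`, in which case
the swap is auto-accepted — hence the 6.25% lower bound on long-run swap
acceptance that the acceptance tests measure.

### Harvesting

Realizations are collected from the coldest chain whenever its energy is
zero and at least `spacing` coldest-chain proposals have passed since the
last harvest.  The default spacing is the target edge count `|E|`, i.e.
roughly one proposed modification per hyperedge between harvests; the
count includes all proposal kinds, not only switches (the narrower
switch-only reading would triple the spacing without changing the
estimand).  The sampler starts from empty hypergraphs and so doubles as a
stochastic search for a first realization; since even existence is
NP-hard, a step budget bounds the run and overruns raise a typed
`SamplerTimeout` carrying the best energy seen.  Harvest diagnostics
include per-pair swap acceptance, per-kind proposal statistics per
temperature, the zero-energy occupancy of the coldest chain, and a PCA of
the harvested 0-1 indicator vectors with autocorrelation of the two
leading principal coordinates.

## The aggregation tests

For a table `t` with margins `R_i, C_j` and total `N`, the aggregation
index is Pearson's statistic `chi2_H = sum (t_ij - e_ij)^2 / e_ij` with
`e_ij = R_i C_j / N`; for a hypergraph the table is its (B, C)-projection,
whose total is `|E|` (cells in an all-zero row or column are excluded —
they carry no information and would divide by zero).  Three null
distributions give three tests, all one-sided upper-tail (aggregation
means a large statistic):

* **theoretical** — `chi2` with `(n_b - 1)(n_c - 1)` degrees of freedom;
* **exact** — the generalized hypergeometric law
  `prod R_i! prod C_j! / (N! prod a_ij!)` over the fiber of tables with
  the observed margins, sampled by a Metropolis chain whose move adds a
  `+-1` checkerboard on a uniform 2x2 subrectangle (the minimal connected
  move basis for fixed-margin non-negative tables; moves that would go
  negative self-loop);
* **hypergraph-based exact** — the uniform law over hypergraphs with the
  observed degree sequence, sampled by Parallel Tempering, so agent
  activity is held fixed under the null.

For the sampled nulls the p-value is the upper tail of a normal fitted to
the null sample (sample mean and unbiased n-1 standard deviation), which
resolves p-values below the reciprocal sample size; the raw empirical
exceedance fraction is reported alongside, and a zero-variance null
(unique realization) is flagged degenerate.  When every agent has degree
one the two exact tests coincide exactly: each fiber table `T` is the
projection of `multinomial(N; t_11, ..., t_bc)` realizations (verified by
enumeration in the tests).  With fewer, more active agents the hypergraph
null shifts to smaller statistics — an agent cannot place two identical
records, so its entries spread — which is why the hypergraph test is the
more sensitive one on small samples.

## Synthetic data

The generators stand in for triplet-table data of the social-media kind:

* `random_er_hypergraph(n1, n2, n3, p)` — each cell independently with
  probability p; `p = 1/2` is the uniform law over all hypergraphs and
  the infinite-temperature reference.
* `regular_degree_sequence` — exact regular targets (the null-shift
  experiments use `n2 = n3 = 4`, 24 edges, agent degree `d` in {1, 2, 4}
  on `24/d` agents — a deliberately desk-scale rendition of the same
  design at larger sizes).
* `planted_aggregation_table(n_agents, n_events, n_times, activity,
  theta)` — agents with a prescribed activity profile (explicit counts,
  a constant, or the deterministic `zipf_activity` heavy-tail helper)
  place records with a uniform event type and a time point drawn with
  weight `1 + theta` on the event's preferred time (`event mod n_times`)
  and 1 elsewhere.  `theta = 0` is exact independence; large `theta`
  concentrates each event on one time point.  Duplicate records are kept
  in the table and collapse only on conversion to a hypergraph, which
  reproduces the deduplication a real pipeline performs.

What the generators do *not* emulate: temporal burstiness and trend
structure, correlated agents, label noise, and margin heterogeneity
beyond the activity profile.  Tests passing on these synthetics certify
the algorithms (correct stationary laws, correct constructions, the
predicted orderings of the nulls), not domain conclusions about any
particular real data set.

## Numerical and design choices

* Degrees and energies are integers end to end; incremental energy
  bookkeeping is exact and checked against full recomputation in tests.
* Edge draws use an indexed list with swap-with-last deletion, so every
  chain step is O(1) at any density.
* The chains use Python's Mersenne-Twister `random.Random` (one seeded
  instance per run, shared by all coupled chains); array-scale generation
  (ER tensors) uses `numpy`'s generator.  Seeds always come from the
  caller.
* Problem sizes in the tests are chosen so exhaustive oracles stay exact:
  Boltzmann checks enumerate all `2^4` hypergraphs of a (1,2,2) space at
  10^6 steps (total-variation bounds 0.02-0.03), constructor/oracle
  agreement runs 200+ random targets with classes up to 4, fiber
  normalization enumerates margins with N up to 8, and harvest-uniformity
  runs 800 samples of the two-realization counterexample with
  batch-means standard errors (harvests are a dependent sequence; the
  naive binomial error would be anticonservative).
* Oracle guards (slice grid up to 30 cells, 9 vertices non-partite, 3DM
  up to k = 5) are conservative defaults; callers can raise them
  explicitly, and exceeding one is an error, never a silent truncation.

## Known limitations

* Finding any realization of a general (not third almost-regular) target
  is NP-hard; on adversarial inputs the sampler's budget will expire with
  a `SamplerTimeout`, which is the designed behavior, not a failure mode.
* Uniformity over realizations is asymptotic in chain length; the
  diagnostics (swap acceptance, zero-energy occupancy, autocorrelation)
  are necessary-condition checks, not proofs of mixing.
* The normal fit for small p-values is an approximation to the null's
  tail; for very skewed nulls the reported empirical exceedance is the
  more honest, if coarser, summary.
* The mixture weights of the three move kinds are uniform by default;
  non-uniform mixtures are exposed as a knob but not auto-tuned.
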