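# Methods

This note records the models implemented in `spreadrank`, the conventions
and numerical choices behind them, and what the test suite's synthetic
experiments do and do not demonstrate.

## Scope and data model

All methods operate on undirected, unweighted simple graphs held as
`networkx.Graph` objects with string node labels.  Edge lists are the only
input format: two labels per line, `#` comments, comma or whitespace
delimited; self-loops and duplicate lines are dropped (and counted in the
log) rather than rejected, since published network datasets routinely
contain both.

Distance-based quantities (closeness, average distance, every gravity sum)
are undefined across components, so analyses run on the largest connected
component by default; the CLI exposes `--no-lcc` for callers who know
their graph is connected.  Gravity sums themselves simply skip unreachable
pairs (d = ∞ contributes nothing), so they tolerate disconnection even
when the LCC policy is overridden.  For graphs with equally sized largest
components the tie breaks toward the component containing the smallest
label, making the choice deterministic.

## Topology statistics

One summary row per graph: N, M, ⟨k⟩, ⟨k²⟩, ⟨d⟩, C, r, H, β_c.

- ⟨d⟩ averages hop distance over unordered distinct pairs (the symmetric
  convention; for a path of n nodes it equals (n+1)/3, which the tests use
  as a closed-form check).
- C is the *mean of local* clustering coefficients, with nodes of degree
  < 2 contributing 0 — not transitivity.  The two definitions differ on
  heterogeneous graphs and the mean-of-local convention is the one the
  reference values follow.
- r is the degree Pearson correlation over edge endpoints; it is NaN on
  regular graphs (zero degree variance), reported quietly.
- H = ⟨k²⟩/⟨k⟩² ≥ 1 (Cauchy–Schwarz), and the epidemic threshold
  β_c = ⟨k⟩/(⟨k²⟩−⟨k⟩) = 1/(H⟨k⟩−1).  The second identity holds to
  1e−12 by construction and is asserted on every test graph; it also lets
  β_c be recomputed from a published (⟨k⟩, H) pair alone.

## Classic centralities

Degree, H-index and the k-shell are computed by hand (the k-shell by the
iterative pruning that defines it; `networkx.core_number` serves as an
independent oracle in the tests, never as the implementation).  Isolated
nodes take shell 0: they are removed before the 1-shell forms.

Eigenvector centrality is deterministic power iteration from the uniform
positive vector, normalized to **unit L1 sum** each step, with tolerance
1e−12 on the fixed-point residual ‖x − Ax/λ‖∞ and a 10⁵-iteration cap.
The unit-sum convention matters: it is what makes the published toy
values (which sum to 0.9999 at 4 printed decimals) reproducible, and the
maxima x_max feeding the MCGM mass inherit it.  The common L2 convention
would rescale x_max and x identically, leaving MCGM unchanged, but the
printed per-node EC values would not match.

Betweenness (unnormalized, unordered pairs, Brandes accumulation) and
closeness ((N−1)/Σd) go through networkx; tests verify betweenness against
a path-enumeration oracle on small graphs.

## Gravity family

All variants share one kernel, `gravity_sum`: truncated BFS to radius R
from each node, summing m(i)m(j)/d² with integer hop distances and no
smoothing.  Scores are non-negative and non-decreasing in R.

Fixed conventions:

- GC/IGC use radius 3 *by definition*; the CLI `--radius` flag does not
  touch them.
- GC+/IGC+ sum the base score strictly over 1-hop neighbors, excluding
  the focal node's own score, exactly as the defining formula reads.
- The estimated optimal radius R\* ≈ ⟨d⟩/2 is rounded half-up and floored
  at 1 (⟨d⟩ = 2.2350 → 1, ⟨d⟩ = 3.6925 → 2, matching the published R\*
  values for those networks).
- MCGM defaults to R = 2, where the optimal radius of most real networks
  concentrates; `radius="auto"` applies the R\* estimate instead.
- The exhaustive radius search scans R = 1..diameter and breaks τ ties
  toward the smallest R (the cheapest model among equals).

MCGM normalizations: `none` (raw k + k_s + x masses), `plain` (each term
divided by its maximum), `alpha` (default; the k-shell term further
multiplied by α).  Setting α = 1 reproduces the plain form exactly, which
the tests assert.  α's medians use the standard convention (mean of the
two middle order statistics for even N).  The eigenvector values feeding
the mass are full machine precision, not the 4-decimal printed roundings;
the toy reference scores carry that rounding, which is why the anchor
tolerance there is ±0.01 rather than machine precision.

The unified model UGM(a, b) exists to tie the family together: a = b = 1
is LGM, a = b = 0 at R = 3 is GC, a = 0, b = 1 at R = 3 is IGC.  These
degenerations hold to 1e−12 and are asserted on 20 random graphs.

## SIR ground truth

Synchronous discrete-time dynamics.  Per step: (1) every infected node
attempts to infect each susceptible neighbor with probability β — a
susceptible node with m infected neighbors is infected with probability
1 − (1−β)^m, the exact distribution of m independent Bernoulli trials,
drawn as one variate per exposed node for speed and determinism; (2) the
nodes that began the step infected recover with probability λ (default 1,
so each infection is infectious for exactly one step).  Newly infected
nodes activate on the *next* step.  Infections resolve before recoveries,
so at λ = 1 every infected node gets one full infectious step.  Absorption
is guaranteed for λ = 1 and almost surely for λ > 0.

F(i) is the mean of N_r/N over independent realizations seeded at i, with
its Monte-Carlo standard error.  Each (seed node, replicate) pair uses its
own RNG substream, `SeedSequence(master_seed, spawn_key=(node, rep))`, so
the table is bit-for-bit reproducible and independent of execution order.
β defaults to the heterogeneous-mean-field threshold β_c, the regime where
ranking quality is hardest and most informative; sweeps use multiples
{0.5, 0.75, 1, 1.25, 1.5}·β_c.

Analytic anchors in the tests: β = 0 gives F ≡ 1/N exactly; β = 1 on a
connected graph gives F ≡ 1; a star seeded at the hub with λ = 1 has
E[N_r] = 1 + n_leaves·β (one infection round), checked within three
Monte-Carlo standard errors.

## Rank comparison

Kendall's τ is the plain 2(n₊−n₋)/(N(N−1)) form: a pair tied in either
sequence counts in neither n₊ nor n₋ but stays in the denominator.  This
is intentionally not tau-b; the two coincide only on tie-free data (the
tests check that coincidence against `scipy.stats.kendalltau` and check
the tied case against an independent pair-enumeration oracle).  One
consequence worth knowing: τ of a ranking against itself is 1 − 2t/(N(N−1))
when the ranking contains t tied pairs, not 1.  The implementation is an
O(N²) pair count, vectorized in 512-row blocks to bound memory; at the
scale of the largest published networks (~16k nodes) that is ~1.2×10⁸
sign comparisons, well within reach.

Monotonicity M(L) = [1 − Σ_r U_r(U_r−1)/(U(U−1))]² after rounding scores
to 9 decimals — enough that float noise cannot split genuine ties
(structurally symmetric nodes must tie in every method) while true score
differences at realistic magnitudes survive.  M is invariant under any
strictly increasing transform of the scores.

## Synthetic experiments: what they show

The full published comparison runs ten real networks with 1000-realization
SIR ground truths; those require external downloads, so the repository's
experiments are scaled down and fully self-contained:

- the 9-node toy fixture anchors every stage against exact published
  per-node values (the strongest check — it validates the arithmetic, not
  just trends);
- property tests run on 25-node Barabási–Albert / Erdős–Rényi /
  Watts–Strogatz graphs, where brute-force oracles are affordable;
- the end-to-end evaluation runs on the LCC of BA(n = 200, m = 2), at
  β = β_c with 300 realizations per seed node — large enough for a
  scale-free degree distribution and a stable ranking signal, small
  enough to rerun routinely.

On that testbed the gravity methods separate cleanly from the integer
baselines (MCGM reaches τ ≈ 0.8 where degree sits near 0.4, and BA's
uniform core number makes the k-shell ranking uninformative), and MCGM's
real-valued scores out-resolve integer degrees on essentially every
generator seed.  What these experiments do *not* show: behavior at real
network scale, under community structure, high clustering, or
assortativity regimes absent from BA graphs — for that, point the CLI at
downloaded edge lists.

## Known limitations

- Directed, weighted, temporal and multilayer graphs are out of scope, as
  are asymmetric or weighted gravity kernels.
- β_c is a mean-field estimate; on networks with strong degree
  correlations the true threshold can differ, and `--beta` accepts an
  explicit value for that case.
- The SIR simulator is synchronous discrete-time; continuous-time
  (Gillespie) dynamics would shift F(i) values slightly, though rankings
  at λ = 1 are insensitive in practice.
- Whether a newly infected node may transmit within its infection step is
  a modelling choice; we forbid it (next-step activation).
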