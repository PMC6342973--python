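# Methods

## Model

The package models information propagation on a finite connected metric
graph 𝒩(V, E, l) without terminal nodes (every node has degree ≥ 2).  Each
undirected edge is split into two oriented edges of equal length; q denotes
the oriented-edge count.  A generalized Markov system z_k = L(h) z_{k+1} is
placed on oriented edges with L_ef(h) = a_ef e^{−h l(f)}, where the 0/1
structure matrix a_ef marks *non-backtracking* continuations: a_ef = 1 iff
t(e) = i(f) and f ≠ ē.  The backtracking exclusion is essential — without
it every edge pair (e, ē) forms a 2-cycle that inflates path counts and the
resulting entropy.  The convention is that f *continues* e (successor
form); the stationary equation reads z_e = Σ_f a_ef e^{−h l(f)} z_f.

The volume entropy h_vol is the unique h ≥ 0 with spectral radius
ρ(L(h)) = 1.  Uniqueness follows from strict monotonicity: every entry of
L(h) is strictly decreasing in h, so by Perron–Frobenius theory
g(h) = log ρ(L(h)) is strictly decreasing.  At h = 0, L(0) is the
non-backtracking edge-adjacency matrix; if ρ(L(0)) ≤ 1 (cycles are the
canonical case: path counts grow linearly) the graph is *non-expansive*
and h_vol = 0 is reported with a flag rather than an error.

### Volume convention

"Volume 2" counts **oriented** edges: Σ_e l(e) = 2 over both orientations,
i.e. the undirected length sum is 1.  This is the single convention used
throughout (no switch is exposed; a silent mixture of conventions rescales
every entropy by a factor 2).  For an unnormalized network,
h̃_vol = (2 / vol(𝒩̃)) h_vol, where vol is the oriented volume; the
stationary distribution z is invariant under this rescaling, which the
tests assert directly.

## Numerics

* **Root finding.**  g(h) = log ρ(L(h)) is bracketed (doubling from [0, 1],
  cap 2^60, or a two-sided bracket around a caller-supplied hint) and
  solved with Brent's method at xtol = 1e-13.  Because |g′(h)| is of the
  order of the mean edge length, this leaves the residual |ρ(L(h_vol)) − 1|
  far below the default tolerance 1e-10; the residual is checked and a
  failure raises rather than returning a degraded result.
* **Spectral radius.**  Dense `eigvals` for q ≤ 300 (with an in-place
  fast path that avoids rebuilding sparse matrices inside the root finder),
  ARPACK (`scipy.sparse.linalg.eigs`, warm-started between evaluations)
  above, with a dense fallback on non-convergence.
* **Stationary vector.**  The transition structure is first checked for
  strong connectivity (reducibility — e.g. a pure cycle, whose two travel
  directions never mix — is reported as an error for
  `stationary_distribution`, and as a uniform-vector fallback inside the
  solver's non-expansive branch).  The Perron vector is then taken in
  absolute value and polished with up to 60 power iterations at eigenvalue
  1, which washes out eigensolver sign noise on entries many orders of
  magnitude below the dominant ones without leaving the positive cone.
  Extremely heterogeneous geometries (length ratios of ~10³ and solved
  h·l_max ≫ 1) produce genuinely tiny stationary entries; these underflow
  gracefully instead of triggering false "reducible" reports.
* **Degenerate inputs.**  Self-loops, parallel edges, non-positive lengths
  and lengths below 1e-12 of the mean are rejected at construction; the
  solver refuses disconnected graphs and graphs with terminal nodes.

## Covering-tree oracle

The defining quantity — the growth rate of metric balls B(v₀, r) in the
universal covering tree — is computed independently of the eigenvalue
machinery.  Path counts N_r(v₀) satisfy a linear recursion over the
non-backtracking structure and are propagated with exact Python integers
(they exceed 64-bit range near r ≈ 60 on 3-regular graphs).  Two readings
of the ball are provided: the combinatorial one (radius counts edges) and
the metric one (radius is a length; final edges truncated at the boundary,
edges counted with multiplicity, one copy per path prefix).  For
equal-length graphs the metric ball is evaluated exactly via the step
recursion, and the shell-ratio estimate log[l(B_n)/l(B_{n−1})]/l converges
geometrically to h_vol; for unequal lengths the exact prefix enumeration is
used, which is exponential in depth and restricted to small radii.  The
oracle-vs-solver agreement is asserted at 5% relative tolerance on random
graphs with q ≤ 60 at metric radius 40, where the shell-ratio estimate has
long since converged to many digits; cycles must give exactly 0 on both
routes.

## Kernel network construction

Pearson correlations are computed once per measurement matrix (rows
centred, two-pass).  Kernel widths take the *literal* k-th smallest value
of {1 − corr(x_i, x_t), t ≠ i} with k = 10 by default (configurable), used
directly — not squared — in w_it = exp(−(1 − corr)/(σ_i σ_t)), matching
the form of the kernel; ties at perfect correlation fall back to the
smallest positive distance, and fully duplicated rows are an error.  Since
√(1 − corr) is conditionally negative semi-definite, the kernel is positive
definite for all positive widths; the kernel-trick distance
d_it = √(2 − 2w_it) is the exact feature-space Euclidean distance (asserted
against an explicit Gram-matrix embedding in the tests).  Networks built
this way are complete graphs; a zero off-diagonal distance (metrically
identical nodes) is rejected.

## Synthetic networks

`generate_topology` produces five unit-length topologies at **exactly**
⌊sparsity·p(p−1)/2⌋ edges each, so cross-topology comparisons are made at
identical volume — the volume entropy is strongly monotone in edge count at
fixed volume, and letting the edge count drift with generator rounding
would swamp the topology signal.  RE is a ring lattice (full chord rings
plus a greedily degree-balanced partial ring; degree spread ≤ 1), SW
rewires each lattice edge with probability 0.1, RA is G(n, M), SF is
Barabási–Albert trimmed down to the exact count, and HY places nodes on a
hyperbolic disk of radius 2·log p with radial density ∝ exp(0.75·r)
(power-law degree exponent ≈ 2.5) and connects the M closest pairs in
hyperbolic distance.  Draws failing validation (disconnected or with a
terminal node) are regenerated up to 500 times; at sparsity 0.09 the G(n, M)
model sits near its connectivity floor and uses many retries.

`apply_geometry` assigns lengths from the **sum** of endpoint degrees
(U uniform, L proportional, S inverse-proportional) and normalizes.  The
sum rather than the product is used; both produce the same qualitative
orderings at the benchmark scale, and the sum keeps length ratios milder.

**Benchmark scale.**  The default is p = 16, sparsity 0.27, 20 replicates.
At this scale the five topologies order cleanly by median entropy
(RE < SW < RA < SF < HY) and the hyperbolic geometries order L < U < S —
short hub edges (S) accelerate path growth, long hub edges (L) retard it.
This geometry contrast is a genuine *small/sparse-network* phenomenon: at
fixed volume the uniform metric is close to the entropy-minimizing metric
of a large dense graph, whose optimal lengths vary only logarithmically
with degree, so linear-in-degree lengths overshoot the optimum and L
*raises* the entropy above U for p ≳ 30 at this sparsity (verified across
radial exponents, sum/product schemes and sparsities up to 0.81).  The
benchmark therefore runs where the degree-geometry effect is actually
expressed; conclusions about large dense networks should not be drawn from
the L/U/S ordering.

`synthetic_timeseries` emulates community-structured ROI signals:
multivariate Gaussian draws with a block correlation target (within 0.5,
between 0.1, five modules, 90 × 112 by default — the shape of a
parcellated resting-state recording).  It reproduces block-structured
correlations and nothing else: no autocorrelation, no hemodynamics, no
scanner drift, no subject heterogeneity.  Passing tests demonstrate the
machinery's statistical calibration and sensitivity on this idealized
structure, not performance on real recordings.

## Statistics

* **Permutation test.**  Group networks are rebuilt from pooled per-subject
  measurement columns under every permuted labelling (the design in which
  one network summarizes each group); p-values use the add-one estimator
  (1 + #{null ≤ obs}) / (1 + n_perm), reported for both tails of both
  groups plus a two-sided difference p.  Below 100 permutations a coarse-
  resolution warning flag is set.  Entropy solves inside the loop reuse the
  previous solution as a bracket hint and skip the stationary vector.
* **Capacity comparisons.**  Wilcoxon rank-sum per feature (midranks, so
  all-tied features give p = 1 exactly) with Benjamini–Hochberg correction;
  BH (not BY) is the interpretation of "FDR-corrected" adopted here.
* **Age models.**  OLS with intercept on age (linear) or age and age²
  (quadratic); the quadratic reports the vertex −b/(2a).  At least 10
  subjects and a non-constant age vector are required.

Calibration is verified by simulation: type-I error of the two-sided
difference p at 500 permutations over 80 exchangeable-null replicates, and
the all-null FDR of the capacity test on per-subject node capacities
produced by the full pipeline (120 identically generated subjects resampled
into 19-vs-19 splits), both bounded by nominal + 2 Monte-Carlo SEs.

## Problem sizes

Defaults keep every computation on a laptop scale: the benchmark at
p = 16 (q ≈ 64) solves in milliseconds; the 90-node kernel network
(q = 8010) solves in a few seconds via ARPACK; calibration studies use
7–10-node kernel networks so that hundreds of thousands of eigensolves stay
cheap.  The covering-tree oracle is limited by exact big-integer counting
to a few thousand propagation steps, ample for its testing role.

## Known limitations

* The L/U/S geometry ordering is scale-dependent (see above).
* The metric-ball oracle for unequal lengths enumerates path prefixes
  explicitly and is exponential in depth — it is a verification tool, not a
  production solver.
* Permutation tests rebuild one network per group per permutation; designs
  with per-subject networks must aggregate capacities first (the
  capacity_group_test route).
* BH control is exact under independence and PRDS; node capacities are
  weakly coupled (they sum to zero), which the all-null simulation shows is
  harmless in practice but is not a theorem.
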