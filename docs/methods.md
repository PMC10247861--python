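# Methods

## Model and quantities

We consider the death–Birth (dB) Moran process on a simple connected
undirected graph G with N vertices: a uniformly random individual dies and one
of its neighbors, chosen with probability proportional to fitness (1 for
residents, r for mutants), copies its type into the vacancy. Mutants start at
a uniformly random vertex (uniform initialization).

The weak-selection amplifier test works on coalescing random walks. At each
time step one of two walkers moves (each with probability ½) to a uniform
neighbor; the expected pair meeting times τ_ij solve

    τ_ij = 1 + ½ Σ_k (p_ik τ_jk + p_jk τ_ik),   τ_ii = 0,   p_ij = e_ij / k_i.

Remeeting times τ_i = 1 + Σ_j p_ij τ_ij, relative degrees π_i = k_i / Σ_j k_j
and the effective population size N_eff = Σ_i π_i τ_i follow. The identity
Σ_i π_i² τ_i = 1 holds for every connected graph and serves as a built-in
correctness check. N_eff > N certifies a weak-selection (tangential)
amplifier; for k-regular graphs N_eff = N exactly (isothermal theorem), so
amplifiers must be non-regular. Genuine transient amplification is the
statement about fixation-probability curves, ϱ_G(r) > ϱ_N(r) exactly on a
bounded window (1, r_max); the N_eff test is the cheap necessary-side
surrogate, and the fixation module measures the curves directly.

## Numerical choices

**Coalescence system.** Assembled over unordered pairs (C(N,2) unknowns) and
solved densely up to 1600 unknowns (N ≈ 57), sparsely (SuperLU) above. At the
sizes treated here (N ≤ ~130) the direct solves are exact to ~1e-12; the
identity above is satisfied to 1e-15..1e-9 in all tests.

**Amplifier threshold.** `N_eff − N > 1e-9` by default. Real amplifier margins
observed in this package's outputs are ≥ 7e-4, so the threshold is orders of
magnitude below any genuine margin and orders above solver noise. One
consequence worth knowing: the smallest amplifying dumbbell found by the scan
is D(3,11) with N = 16 and margin 7.1e-4 — confirmed by exact
rational-arithmetic elimination of the coalescence system, so it is not solver
noise. Published scans that used a coarser threshold (~1e-3) place the minimum
at D(3,12), N = 17 instead; this package reports what the equations give at
tol = 1e-9.

**Spectra.** Symmetric eigensolvers (`numpy.linalg.eigvalsh`); normalized
Laplacian eigenvalues are clipped to [0, 2] when within 1e-9 of the bounds.
Spectral densities use a Gaussian kernel with σ = 1/(3N) on a 2001-point
uniform grid over [0, 2] (normalized spectra) or [0, 2Δ(G)] (standard
spectra, reusing the same σ convention; σ is recorded in the output). The
kernel carries the standard minus sign in the exponent. Distances use the
trapezoidal rule on the shared grid; the quadrature error is far below the
distances of interest at this resolution.

**Search (guided edge removal).** Per removal step, each pool member selects
the vertex with the largest moving difference Δʲτ_i = τ_i(j) − τ_i(j−1)
(τ_i(0) itself before the first removal) — a plain argmax over all vertices;
ties go to the lowest vertex index, with a 1e-9 tie tolerance so
vertex-transitive inputs deterministically pick vertex 0. The full forward
difference Σ_p (−1)^{j−p} C(j,p) τ_i(p) is available as an alternative rule
(`guidance_rule="forward"`). One child per edge at the selected vertex;
disconnected children are discarded; the pooled children of a step are
deduplicated by their normalized-Laplacian spectrum rounded to 9 decimals
(eigensolver noise is ~1e-12 at these sizes, and 9 decimals separates
genuinely distinct spectra in practice). On a dedup collision the surviving
child keeps the lineage and τ-history of the first-encountered duplicate under
the deterministic processing order. In greedy mode the filter keeps the
`filter_size` (default 500) candidates with smallest λ₂; boundary ties are
broken by the rounded spectrum tuple, which is unique after dedup, so the
retained set is total and deterministic and an exact-isomorphism key is never
needed during the search. N_eff is evaluated for retained children only —
this matches the procedure (every candidate admitted to the next iteration is
tested) and keeps the per-step cost at one small linear solve per retained
member. Amplifier children continue to be expanded (consecutive amplifiers
occur); a flag stops lineages at the first hit for speed. The removal budget
defaults to 1 + (k−2)N/2. A μ₂ (standard-Laplacian) filter mode exists for
comparison; it is expected to find no amplifiers at practical filter sizes.
An optional interlacing assertion hook verifies both interlacing theorems for
every executed edge removal; it is exercised by the test suite on small
campaigns and off by default in production runs (it doubles the eigensolver
work).

Counting conventions: a run's amplifier total deduplicates records by
cospectral key within that run; the pooled non-isomorphic count across a
campaign uses an exact canonical labeling (BLISS canonical permutations).
Campaign-level amplifying-input counts proved mildly sensitive to
pool-ordering conventions in our experiments (e.g., the 8-regular N = 11
campaign yields amplifiers from all 6 inputs at filter size 500 but from 5 at
filter size 100) — counts of this kind are reproducible only together with the
tie-breaking rules documented above.

**Fixation chain.** Mutant sets are encoded as bitmasks; the absorbing linear
system over the 2^N − 2 transient configurations is assembled vectorized per
vertex and solved with SuperLU using the symmetric-pattern minimum-degree
ordering (≈3× less fill than COLAMD on this hypercube-like sparsity; ~1 s at
N = 12). The exact solver is limited to N ≤ 13 by memory/time of the 2^N state
space; beyond that the vectorized Monte-Carlo estimator applies. The default
fitness grid is 41 geometric points on [0.25, 4] plus fixed probes at
1 ± {0.005, 0.01, 0.02}: weak transient amplifiers have windows (1, r_max)
with r_max within a few percent of 1 (the window exists because
dϱ/dr|₁ exceeds the complete graph's when N_eff > N), and a purely geometric
grid steps over them. Detected sign changes of ϱ_G − ϱ_N above r = 1 are
tightened by 12 bisection steps when the exact solver is available. The
classification *reports* the transient window; it never asserts one.

## Graph plumbing

Graphs are `networkx.Graph` objects with 0-based integer labels; the search
operates internally on dense numpy adjacency matrices to avoid object
overhead. Connectivity is decided by traversal, not spectrally. The
(N−3)-regular input families are built as complements of disjoint-cycle
unions, one per partition of N into parts ≥ 3 — pairwise non-isomorphic by
construction and emitted in lexicographic partition order, matching the known
counts (6 at N = 11, 9 at N = 12, 13 at N = 14). A small backtracking
enumerator provides all connected k-regular graphs for N ≤ 10 (used for the
cubic test inputs); exhaustive regular-graph generation at larger orders is
out of scope. Exact isomorphism uses igraph's BLISS canonical labeling;
graph6 files are read and written in the headerless nauty dialect with
per-line error reporting.

Bell-like constructors place the two blocks on vertices 0..a−1 and a..2a−1
with bridgeheads at block vertex 0 (block types are vertex-transitive, so the
choice is immaterial); b = 1 means a direct edge. Two-bridge variants attach
vertex-disjoint bridges at adjacent block vertices 0 and 1 on each side
(offset configurable), giving N = 2a + 2(b−1); deleting the
bridgehead–bridgehead edge is available as a flag. For even a = 4 the Möbius
ladder and antiprism blocks both degenerate to K₄, intentionally allowed so
that M(4,b) ≡ A(4,b) ≡ B(4,b).

## Scope and limitations

- Unweighted, undirected graphs and dB updating with uniform initialization
  only; no Birth–death variant, no temperature initialization.
- The perturbation expansions behind the vertex-selection rule are used as
  rationale only; their coefficient structure is not computed.
- Default problem sizes are desk-scale: the bundled campaigns use the N = 11
  8-regular inputs and cubic inputs with N ≤ 8. Campaigns over hundreds of
  inputs (e.g., all quartic/sextic graphs on 11 vertices, or N = 20/26 with
  k = N−3) are supported by the same `run_campaign` API but take hours and
  additionally need an external regular-graph enumerator for degrees other
  than N−3 at N > 10.
- The N_eff test certifies weak-selection amplification; whether each such
  graph is a transient amplifier in the exact-ϱ sense is measured (fixation
  module) but not guaranteed.
- The test suite's randomized graphs are G(n,p) rejection samples — small,
  dense-ish and connected. They exercise the identities and invariants; they
  say nothing about performance or behavior on large sparse networks.
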