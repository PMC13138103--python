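# Methods

## The model

`pathpersist` asks whether the *directed wiring* of a biological pathway is
used differently by two groups of samples (e.g. disease vs control).  It
combines two ingredients:

1. **A directed pathway graph** G = (V, E): one node per gene, one directed
   edge per annotated interaction (activation, inhibition, or other), taken
   from KGML or a plain edge-list/adjacency table.  Self-loops are removed;
   a mutual interaction is two directed edges; KEGG group nodes are expanded
   so each member gene inherits all of the group's interactions.

2. **A condition-specific co-expression distance** on the edges.  Within one
   condition each gene's profile is its vector of (log-scale) expression
   values over that condition's samples, and each edge (u, v) is weighted by

       d(u, v) = 1 − |ρ(u, v)|,

   ρ being the Pearson correlation of the two profiles.  The absolute value
   treats strong negative co-expression (an inhibitor tracking its target)
   as "close": d ranges from 0 (perfectly co-expressed) to 1 (uncorrelated).

### Regular path homology

The topological summary is regular path homology of the digraph, in
dimensions 0 and 1.  Chain spaces are built from *allowed paths*: a p-path
(v0, …, vp) is allowed when every consecutive pair is an edge.  Ω₀ is
spanned by the vertices and Ω₁ by the edges; Ω₂ is the subspace of allowed
2-path combinations whose boundary ∂(a,b,c) = (b,c) − (a,c) + (a,b) lands
only on actual edges (a degenerate middle term (a,a) is dropped — the
"regular" convention).  Then

    β₀ = dim Ω₀ − rank ∂₁,      β₁ = dim ker ∂₁ − rank(∂₂|Ω₂).

β₀ counts weakly connected components.  β₁ counts directed cycles that no
allowed 2-path combination fills: a transitive triangle a→b→c with shortcut
a→c is filled (β₁ = 0), while a consistently oriented square, a long cycle,
or a bi-fan (a→c, a→d, b→c, b→d) is not (β₁ = 1).  This is what the
directionality buys over undirected cycle counting.

All ranks use exact field arithmetic.  The default backend runs Gaussian
elimination over the rationals (`fractions.Fraction`; the boundary matrices
of pathway-sized graphs are small with ±1 entries, so this is fast and
removes any numerical-rank ambiguity).  A GF(2³¹−1) backend is available
for larger problems; over a random 31-bit prime the modular rank of a
small-integer matrix coincides with the rational rank away from a vanishing
set of inputs, and the rational backend remains the reference.

### Persistence

Thresholding the edge weights gives a filtration: at level f the subgraph
G_f contains every node and the edges with d ≤ f.  f is swept over the grid
0, 0.01, …, 1 (τ = 101 steps; the step balances feature resolution against
compute, and weights live on [0, 1] so the grid needs no calibration).
Because all vertices are present from f = 0 and edge sets are nested,
Ω_p(G_i) ⊆ Ω_p(G_j) for i ≤ j and the persistent Betti numbers

    β₁(i, j) = dim Z₁(G_i) − dim(Z₁(G_i) ∩ B₁(G_j))

form a valid one-parameter rank invariant.  Bar multiplicities follow by
inclusion–exclusion, μ(i, j) = β(i, j−1) − β(i, j) − β(i−1, j−1) + β(i−1, j),
which is the canonical pairing for one-parameter persistence over a field.
(A Betti curve alone does not determine a pairing; a "curve" mode
reproducing the naive convention — each decrement kills the youngest living
bar — is provided for comparison, and the two agree on bar counts alive at
every threshold.)  Dimension-0 classes are all born at f = 0; classes still
alive at f = 1 are capped at death 1.0 by default so landscapes stay
finite — the full network is always reached at f = 1 because d ≤ 1.
Dropping essential bars instead is a configuration option.  Betti numbers
are only recomputed where the edge set actually changes; the ≤ comparison
carries a 10⁻¹² tolerance so weights lying exactly on a grid value enter
deterministically.

### Landscapes and the global test

A barcode becomes a persistence landscape λ_k(t) = k-th largest of
max(0, min(t − b, d − t)) over bars (b, d), evaluated on the same 101-point
grid.  Births and deaths are grid-snapped, so tent kinks sit at most half a
step off-grid and the 1-Lipschitz property bounds the discretisation error
by half a step; the finer-grid oracle in the test suite quantifies it.
Landscape size is measured by the sup-norm, the 1-norm (levelwise
trapezoidal integral of |λ_k|, summed) and the 2-norm (square root of the
summed integral of λ_k²); the trapezoidal rule is exact for the
piecewise-linear integrand up to kink placement.  All nonzero levels are
retained; truncating to the top levels is a plotting concern only.

The global test averages the per-pathway landscapes per condition, takes
the disease-minus-control difference, and compares each norm of it to a
permutation null: pathway landscapes from both conditions are pooled and
reassigned into two groups of the original sizes (1000 permutations by
default), and p = the proportion of permuted statistics ≥ observed.  The
three norms within one homological dimension form one Benjamini–Hochberg
family (the test runs separately per dimension); a joint six-value family
is a configuration option.

### Per-pathway tests

For each pathway and dimension, the two conditions' Betti series (101
values each) are compared by

* the two-sample KS statistic K = sup |F_C − F_D| between the empirical
  distributions of the two value sets (computed with SciPy's `ks_2samp`,
  read as: the series are two samples of τ = 101 Betti values each), and
* Cohen's d = (mean_C − mean_D)/s with the pooled n−1 standard deviation,
  so d > 0 means the control series runs higher (e.g. more disconnected
  components in control).

p-values come from 5000 permutations that pool the 2τ values and reassign
them to two groups of size τ, recomputing K or |d| (two-sided; ties count
as ≥).  Each of the four test families (KS/d × dim 0/1) is BH-corrected
across pathways, and a pathway is called significant only when all four
q-values are below α = 0.05.  The permutation treats grid points as
exchangeable, which makes the test sensitive to any systematic difference
between the curves; the four-way intersection is the conservative guard.

## Numerical and degenerate-case choices

* Zero-variance profile: ρ is undefined; the edge gets d = 1 (enters last)
  with a warning, so an uninformative gene cannot create early connectivity.
* Pathway genes without measurements are dropped (with their edges) and
  recorded, not imputed; a pathway left with < 2 measured genes is skipped.
  An edge-less weighted graph is valid — its curves are constant.
* Weights are clamped to [0, 1] with tolerance 10⁻¹²; both orientations of
  a mutual edge pair share one weight (d is symmetric).
* Cohen's d with pooled s = 0: d = 0 if the means agree, otherwise a signed
  infinity sentinel (reported, never silently dropped).
* A zero permutation count gives p = 0 exactly (printed as "< 1/N"); the
  conservative (count+1)/(N+1) estimator is a configuration switch.
* `log_tpm` uses log2(TPM + 1); the pseudocount keeps zero counts finite.
* KGML relation subtypes other than activation/inhibition collapse to
  "other"; the label never affects topology.  All gene–gene relations are
  kept, including indirect effects.

## The simulator

`simulate_expression` draws unit-variance multivariate normal profiles
whose correlation matrix carries the prescribed pairwise |ρ| targets
(positive sign convention; unspecified pairs 0), so realised correlations
converge to their targets as the per-condition sample count grows.  With
`noise_sd` > 0 an independent noise term is added and the signal
correlations are inflated by 1 + noise_sd² beforehand, keeping the
realised values on target (an infeasible combination raises).  A non-PSD
target matrix raises rather than being silently repaired.

The 10-gene toy network's canonical edge distances come from a one-factor
model per component (distance 1 − l_u·l_v from per-gene loadings).  The
loadings were chosen once so that the filtration reproduces the reference
milestones — only g9→g7 (d = 0.184) present at f = 0.2 (β₀ = 9), the
bi-fan complete by f = 0.4 (β₀ = 7, β₁ = 1), the last edge at d = 0.946 so
the full network (β₀ = 3, β₁ = 2) is visible from f = 0.95 — and the same
factor structure drives the toy expression simulation, which guarantees a
positive semi-definite target matrix.

`two_condition_study` builds a planted-signal benchmark: every synthetic
pathway is a copy of the toy topology on its own genes; "rewired" pathways
get strong within-component co-expression (|ρ| = 0.9) in the disease
condition and weak (0.15) in control, null pathways 0.5 in both, with 17
samples per condition (the study design the defaults emulate).  What the
simulator does **not** emulate: count noise and library-size effects (it
draws Gaussian profiles directly on the log scale), heavy-tailed or
non-linear dependence, hub genes shared between pathways, and condition
effects on mean expression rather than co-expression.  Passing tests
therefore certify the topology and inference machinery, not robustness to
RNA-seq artefacts; real count data should be normalised (e.g. via
`log_tpm`) upstream.

## Problem sizes and defaults

| parameter | default | note |
| --- | --- | --- |
| filtration step | 0.01 (τ = 101) | grid on [0, 1]; must divide 1 |
| global permutations | 1000 | landscape pool reassignment |
| per-pathway permutations | 5000 | pooled Betti values |
| α (FDR) | 0.05 | per family, four-way intersection |
| samples per condition (simulator) | 17 | matches the emulated study design |
| linear algebra | exact ℚ | GF(2³¹−1) optional |

The test suite and the acceptance script run the benchmark at reduced
sizes chosen as the smallest that leave the conclusions stable: 20
pathways with 5 planted, 200 global / 500 per-pathway permutations, and
random-digraph property checks on ≤ 6 nodes (where the exhaustive oracle
is exact and cheap).

## Known limitations

* Homology is computed for dimensions 0 and 1 only; most pathway networks
  carry no meaningful higher-dimensional structure.
* Exact rational elimination scales to pathway-sized graphs (tens to a few
  hundred edges), not to dense graphs with thousands of 2-paths; switch to
  the GF backend there.
* The per-pathway permutation test treats the 101 grid values as
  exchangeable samples although neighbouring thresholds are strongly
  dependent; its p-values are best read comparatively (which pathways
  stand out) rather than as calibrated error rates for a single pathway —
  hence the four-test intersection and the FDR control across pathways.
* Each homological dimension is permuted independently; any pairing
  between a pathway's dimension-0 and dimension-1 series is ignored.
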