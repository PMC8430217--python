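# Methods

## Model

A PPI network is a simple undirected graph over n proteins with symmetric
non-negative adjacency `A` (zero diagonal; unweighted edges have weight 1).
Tri-factorization approximates `A ≈ F G Fᵀ` with `F ∈ R₊^{n×k}` the
node-to-module membership and `G ∈ R₊^{k×k}` the module-relationship matrix;
unlike the two-factor symmetric NMF, the middle factor lets the product carry
negative eigenvalues and keeps both axes of the approximation indexed by the
same proteins.

Prior knowledge enters as must-link pairs: `m_ij = α` when proteins i and j
are known to share a complex, 0 otherwise. With degree matrix
`d_ii = Σ_j m_ij`, the Laplacian `L = D − M` is positive semi-definite and

    xᵀ L x = ½ Σ_ij m_ij (x_i − x_j)²,

so `Tr(FᵀLF)` penalizes constrained pairs with dissimilar membership rows,
and `Tr((FG)ᵀL(FG))` penalizes them with dissimilar *reconstructed*
propensities `R = FG` — the term that shapes `G` toward diagonal dominance
(a "clear" module structure in which within-module relationships outweigh
between-module ones). The objective is the sum of the squared Frobenius
reconstruction error and the two penalties.

## Optimization

Alternating multiplicative updates, derived from the KKT conditions of the
Lagrangian with the non-negativity multipliers eliminated:

    F ← F ⊗ [2AFG + MF(GG+I)] ⊘ [2FGFᵀFG + DF(GG+I)]
    G ← G ⊗ [FᵀAF + GFᵀMF]   ⊘ [FᵀFGFᵀF + GFᵀDF]

Notes on fidelity and numerics:

* Differentiating the penalty terms directly gives `2LFGG` and `2LF`; the
  update rules implemented here use the form without that factor of 2, which
  is how the algorithm is conventionally stated. The fixed points coincide,
  and the KKT diagnostics use the matching gradient so that
  residual-at-fixed-point is exactly zero.
* The raw G update does not structurally preserve symmetry although G is
  meant to be symmetric (and the F update assumes it). By default G is
  re-symmetrized to `(G+Gᵀ)/2` after each update; `symmetrize_g=False`
  restores the literal rule.
* `GG + I` is read as the matrix square of G plus the identity; under the
  default re-symmetrization this is identical to `GGᵀ + I`.
* Update denominators are floored at `denom_floor` (default 1e-12) before
  division; entries with zero numerator *and* zero denominator keep their
  value. Non-negativity is preserved exactly (Hadamard products of
  non-negative terms).
* Convergence: stop when `|J_t − J_{t−1}| / J_{t−1} < rel_tol` or after
  `max_iter` (default 1000) iterations. Default `rel_tol = 1e-9`; the
  `paper_strict` flag sets 1e-15, which float64 cannot resolve on a changing
  objective, so the iteration cap then effectively governs.
* Cost per iteration is `O(nnz(A)·k + n·k²)`: A, M, D, L are held sparse and
  the objective is evaluated through its trace expansion
  (`||A−FGFᵀ||² = ||A||² − 2Tr(FᵀAFG) + Tr(GᵀFᵀFGFᵀF)`), never forming the
  n×n residual. Tiny negative objective values from cancellation at
  near-exact fits are clipped to zero.
* Multiplicative updates converge sublinearly; KKT residuals
  `min(W, |∂J/∂W|)` reach 1e-6 only on well-separated small instances run
  for ~1e5 iterations. This is a property of the update family, not a bug;
  detection quality saturates far earlier.

## Initialization

The fit is sensitive to its starting point, so both factors get structured
starts (a `random` mode exists for ablation):

* **F (seeded):** k seed nodes are picked greedily — highest degree first,
  then repeatedly the highest-degree node not adjacent to any chosen seed
  (fallback: highest-degree remaining). Every node is softly assigned to all
  seeds, `f_ic ∝ 1 + cos(a_i, a_{seed_c}) + 1[a_{i,seed_c} > 0]`,
  row-normalized and floored at 1e-6 (multiplicative updates cannot revive
  exact zeros). This replaces a published seeding algorithm with the same
  intent — central, well-separated seeds — that is not reproduced here.
* **G:** every row sums to exactly 1 with entries near 1/k: uniform(0, 0.1/k)
  jitter is added to 1/k before exact row renormalization. The jitter must
  be numerically visible to break the symmetry between modules, so a
  vanishingly small perturbation is deliberately not used.

The module budget k is an upper bound: for real networks it defaults to
1000; for synthetic benchmarks 1.5× the planted module count is used.
Columns that win no node (non-overlapping) or an empty prefix (overlapping)
produce no complex, so the effective number of modules adapts downward.

## Complex extraction

* **Non-overlapping:** node i joins `argmax_c f_ic`; ties break to the
  lowest column index; all-zero rows go to module 0 with a warning.
* **Overlapping:** for each column c, entries sorted descending (ties by
  ascending node index) are accumulated until the running sum first reaches
  `s_c = (FᵀF)_cc`. For a binary membership matrix this diagonal equals the
  module size and the rule returns exactly the column supports; for real
  values it is a parameter-free size estimate. If the whole column sums to
  less than `s_c`, all its nodes are taken.
* Both modes drop complexes with fewer than 3 members by default; the
  overlapping mode also removes exact duplicates (distinct columns can
  select the same member set).

## Must-link sampling

From a reference catalog, candidate pairs are formed within each complex
**only among proteins that belong to exactly one complex** in the catalog
(shared proteins give ambiguous priors); a complex with `N_c` such members
contributes `N_c(N_c−1)/2` pairs. A fraction of the *pooled* candidate list
(global, not per-complex — the stratification is not specified in the
source experiments and global sampling matches "randomly chose 10%") is
drawn uniformly without replacement, round-half-up. α defaults to 10, the
value at which detection quality peaks in the original sensitivity analysis.
Constrained labels absent from the network are dropped with a warning in the
pipeline path (strict validation is available).

## Synthetic benchmark

The generator emulates the LFR family: degrees from a truncated power law
(exponent 2; the continuous lower cutoff is solved by bisection so the
floored sample has the target mean), module sizes from a truncated power law
(exponent 1) summing to `N + on·(om−1)` memberships; `on` randomly chosen
nodes get `om` memberships each. Exponents follow standard LFR practice as
the experimental design does not state them. Nodes are assigned to modules
high-degree-first into modules that can host their internal degree. Each
node aims `round((1−μ)·d)` stubs inside its module(s) (split evenly across
memberships, capped at module size − 1) and the rest outside. Intra-module
stubs are paired by configuration-model matching; external stubs are paired
globally with pairs forbidden from landing inside a shared module. Up to 100
rewiring sweeps repair self-loops, multi-edges and forbidden pairs; residual
irreparable stubs are dropped with a logged count. At μ = 0 external pairing
is skipped entirely, so every edge is intra-module by construction.

What it reproduces: power-law degree and size heterogeneity, a tunable and
empirically accurate mixing fraction (±0.05 of μ), exact overlap counts, and
full determinism per seed. What it does not: bit-compatibility with the
original C++ generator, weighted/directed variants, degree-mixing
correlations, or the noisy, incomplete edge structure of real PPI data — so
synthetic recovery rates bound what to expect on curated benchmarks, not on
real interactomes.

`planted_partition` (Erdős–Rényi blocks) is a separate light fixture for
unit tests where full LFR generation is overkill.

## Evaluation metrics

Neighborhood affinity `NA(p,g) = |p∩g|²/(|p||g|)`; matches are declared at
NA ≥ 0.25 (`count_matched`), while the precision/recall/F1 family uses the
looser 0.2 threshold, realizing the overlap score as NA (the only set
overlap score defined in this suite). Sn/PPV/Acc follow the cluster-wise
intersection-table definitions with Acc the geometric mean; PPV is 0 when
the table is all zero, F1 is 0 when both rates are 0. MMR defaults to the
best-match average over *reference* complexes (the denominator reading that
matches "mapping to gold standard"); a `strict_matching` mode solves the
true one-to-one maximum-weight assignment and is never larger. Partition
NMI is `2I/(H_A+H_B)` from the contingency table; the overlapping-cover NMI
follows Lancichinetti–Fortunato–Kertész over binary membership variables
with the usual admissibility condition. The hypergeometric enrichment
p-value is the exact upper tail; no multiple-testing correction is applied —
the correction method is left to the user, as none is prescribed in the
source experiments.

## Problem sizes used in tests

The test suite exercises full-scale benchmark recovery (N=1000, 10
replicates) once; all property tests run on planted-partition instances of
18–30 nodes or benchmark networks of N=300, and the must-link-benefit curve
uses 10 replicates at N=300 — sizes chosen so the whole suite stays fast
while every statistical claim is still tested at its design point.

## Known limitations

* The objective is non-convex; different seeds reach different local minima.
  The seeded initialization makes runs reproducible, not globally optimal.
* k far above the true module count fragments modules when constraints are
  sparse; the empty-module pruning mitigates but does not remove this.
* The overlapping extractor's size estimate `(FᵀF)_cc` is scale-sensitive:
  badly scaled F columns (e.g. from an unconverged fit) shift prefix sizes.
* Real-data reproductions (published PPI networks, CORUM/PCDq, GO/KEGG
  enrichment) require the corresponding files from their providers; the
  loaders and metrics support them, but no data are bundled.
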