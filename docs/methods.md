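# Methods

## Model and assumptions

The package treats disease-miRNA prioritization as network proximity.
Its central object is the *mutual heterogeneous miRNA network*: the
bipartite graph whose nodes are miRNAs and genes and whose unit-weight
edges are miRNA-target interactions, taken as reciprocal. The modelling
assumption is twofold: (1) targets reciprocally control the level and
function of their miRNAs, so information may flow gene→miRNA as well as
miRNA→gene; and (2) the disease-module principle — miRNAs (and genes)
associated with similar phenotypes lie close together in this graph
because disease miRNAs regulate common disease genes.

A random walk with restart propagates seed information:

p_{t+1} = (1 − γ) W′ p_t + γ p_0.

W′ is obtained by dividing each node's outgoing edge weights by their
sum. Because the update multiplies a column vector of node
probabilities, the operator actually applied is the **transpose of the
row-normalized adjacency** (column-stochastic over nodes with outgoing
edges). On regular graphs the row- and column-normalized operators
coincide; in general they do not, and the transpose convention is the
one that conserves probability mass, so it is fixed throughout.

Seeding policies:

* miRNA-only (homogeneous networks): uniform mass 1/|S_m| on the known
  disease miRNAs;
* miRNA+target (mutual heterogeneous networks): mass α split uniformly
  over S_m and 1 − α over S_g, the union of the *current* seeds'
  targets. S_g is recomputed from the seed miRNAs of each
  cross-validation round, never from the held-out miRNA, so held-out
  information cannot leak through the gene side.

On directed bipartite networks gene nodes have no outgoing edges; the
walker's mass drains into them, non-seed miRNAs receive exactly zero,
and the result is tagged `mass_deficient`. This is why the miRNA+target
ranker refuses directed networks.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| γ | restart probability; locality of the walk | 0.7 | optimum of the LOOCV parameter sweep on both real mutual networks |
| α | seed-mass share of miRNAs vs. their targets | 0.9 | same sweep; most disease information is carried by the miRNAs themselves |
| tol | L1 convergence threshold on successive p_t | 1e-6 | the published stopping rule ‖p_{t+1} − p_t‖ < 10⁻⁶, read as L1 (scale-matched to probability vectors, standard in this literature) |
| max_iter | iteration cap | 1000 | non-convergence is an error carrying the last residual, never a silent return |
| η_M, η_D | RLSMDA ridge trade-offs | 1.0 | the comparator's published setting |
| w | RLSMDA miRNA/disease space blend | 0.9 | the comparator's published setting |

## Numerical and procedural choices

* **Homogeneous similarity** between miRNAs i, j is
  |T_i ∩ T_j| / min(|T_i|, |T_j|); miRNAs sharing no target with any
  other miRNA are dropped. Computed sparsely as B Bᵀ on the bipartite
  incidence B, so the TargetScan-scale network (≈1500 miRNAs, ≈500k
  interactions) builds in seconds.
* **Identifier normalization**: miRNA ids are stripped and lowercased,
  gene symbols stripped and uppercased, identically for interaction and
  association files; duplicate interaction rows collapse silently with a
  logged count. Seeds absent from a network are dropped and the
  remaining seed mass renormalized (a hard error would make
  cross-validation on real association lists impossible); an error is
  raised only when *no* seed is present.
* **Ranking ties** break by descending score then ascending
  lexicographic id (deterministic across platforms). AUC uses midranks,
  so tied scores contribute ½ — the per-disease AUC equals both the
  trapezoidal ROC area over achieved rank thresholds and the
  Mann-Whitney pair-winning fraction, which the tests verify by brute
  force.
* **Cross-validation**: a LOOCV round ranks the held-out miRNA against
  the held-out plus every universe miRNA not known-associated with the
  disease; diseases with fewer than two known miRNAs in the universe are
  skipped with a logged reason. k-fold uses a per-disease seeded
  shuffle; with k equal to the association count it reproduces LOOCV
  exactly (tested). Per-disease AUCs are averaged unweighted.
* **RLSMDA** is solved as linear systems (LU), never an explicit
  inverse; since the factorized similarity systems are independent of
  the association matrix, cross-validation rounds reuse them and only
  recompute two matrix-vector products. The published formulas print
  the classifier without an inverse, S(S + ηI)Aᵀ, which is dimensionally
  valid but is not the minimizer of the regularized least-squares cost;
  the inverse form is implemented (and checked against a brute-force
  cost minimizer), with the inverse-free product available behind
  `inverse=False` for comparison.
* **Hypergeometric enrichment** uses the convention: universe N = network
  miRNAs minus the disease's seeds; K = reference miRNAs for that
  disease inside the universe; n = the top-k actually drawn. The
  upper-tail probability comes from `scipy.stats.hypergeom` and is
  checked against exhaustive enumeration for small N; with
  (k, K, n, N) = (2, 3, 100, 1547) this convention gives p = 0.012, the
  published top-100 value for the one row where the population can be
  reconstructed.

## Synthetic fixtures: what they emulate and what they do not

`FixtureSpec` defaults — 60 miRNAs × 240 genes at background density
0.02, four diseases, module size 10 with a 12-gene core at cohesion
0.8 — are a roughly tenfold scale-down of the experimentally validated
miRNA-target network (miRNA:gene ratio ≈ 1:4, a handful of targets per
miRNA), chosen once as the package's study conditions. Each disease's
module miRNAs are additionally wired to a shared gene core with
probability `module_cohesion` per pair; half the module is labelled
known, half hidden. Generators draw from per-operation sub-streams of
one seed, so outputs are byte-reproducible and adding a call never
perturbs earlier draws.

The fixtures reproduce the *mechanism* the methods exploit (co-targeting
modules) but not real data's heavy-tailed degree distributions,
many-to-many disease overlaps, or identifier noise. Passing
planted-module tests therefore shows the pipeline recovers modular
signal and beats permutation nulls under controlled conditions; it does
not certify the absolute AUC levels reachable on real interaction
databases, which the published-data tests cover when the supplementary
tables are supplied.

## Known limitations

* The shared-target similarity matrix with unit diagonal (the prescribed
  S_M for RLSMDA) is not positive semi-definite; on small dense fixtures
  its minimum eigenvalue can fall just below −1, making the η = 1 system
  (S_M + I) nearly singular and RLSMDA's fixture AUC unstable (it can
  drop below chance while both walkers exceed 0.9). The closed form is
  implemented exactly as specified; conditioning is a property of the
  inputs, not of the solver.
* Mutual bipartite networks make the underlying walk 2-periodic, so
  convergence slows as γ → 0; the default γ = 0.7 converges in tens of
  iterations.
* The phenotype similarity matrix is consumed as given (or synthesized);
  deriving one from OMIM text is out of scope, as are GO- or
  expression-based miRNA similarities and bilayer disease-miRNA
  networks.
* Reference identifiers are matched by exact normalized string;
  mature-arm naming drift ("-5p"/"-3p") between databases is the user's
  responsibility to harmonize.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` uses the default fixture (60 × 240, four
diseases, 20 holdout rounds), 20 random ≤10-node networks for the
fixed-point oracle, a 2 × 2 (α, γ) sweep grid, k = 3 folds, and exact
enumeration up to N = 11 for the hypergeometric check — all chosen so
the whole script recomputes every number in about a second.
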