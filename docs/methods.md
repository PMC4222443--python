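# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmark does and does not show. Symbols: Ω is the panel of
cell lines, `x_i = (x_i^G, x_i^D)` its paired expression / drug-activity
profiles, K the number of clusters.

## Distance

All clustering operates on `d(x_i, x_j) = 1 − corr(x_i, x_j)` (Pearson),
clamped into [0, 2] against floating-point drift. The choice is deliberate:
microarray log-ratios and GI50 profiles differ in scale and baseline between
cell lines, and correlation is invariant to positive affine rescaling of a
profile where Euclidean distance is not. `1 − corr` violates the triangle
inequality; nothing here assumes a metric. Profiles with zero variance are
rejected rather than patched, since their correlation is undefined.

## Exact p-Median

The assignment formulation (binary z_ij, one-cluster-per-cell, exactly K
self-assigned medians, linking z_ij ≤ z_jj) is solved with HiGHS
branch-and-cut through `scipy.optimize.milp` at MIP gap 0, so solutions are
proven optima and runs are deterministic. Two performance-relevant facts:

- For the *unconstrained* problem only the K median indicators need
  integrality: once the z_jj are binary, the remaining assignment polytope
  is integral, so the relaxation is exact. This roughly halves solve time at
  |Ω| = 60 (~2 s per solve on one CPU). The result is still verified for
  integrality and falls back to the fully integer model if ever needed.
- The ε-constrained consensus problem can fractionate that relaxation, so
  there the integrality check + fallback path is load-bearing.

After solving, each cell is re-assigned to its nearest selected median
(ties to the lowest median index) — a no-op at the optimum except among
exact ties, where it canonicalises the assignment. This re-assignment is
*not* applied to consensus solutions: deviating from the d1-nearest median
to respect the d2 budget is precisely what the ε-constraint buys, and
re-assignment could violate it.

Reproducibility of alternate optima rests on the deterministic backend plus
cluster relabelling by sorted median index; we did not add a second
lexicographic-tie-break solve, which would double MILP cost for a property
no downstream computation depends on.

## Consensus p-Median and the μ-sweep

Step 1 solves the plain model under d^(2); step 2 minimises the d^(1) cost
subject to `Σ z_ij d^(2) ≤ μ · (step-1 optimum)`. μ < 1 is infeasible by
construction and rejected. The sweep raises μ on a fixed grid (default
1.0 : 0.1 : 3.0) and stops at the first μ where the budget is *redundant* —
tested exactly by solving the unconstrained d^(1) problem once and checking
whether its d^(2) cost fits the budget. This makes `F_r(μ*) =` unconstrained
optimum hold by construction and is stricter than stopping when consecutive
assignments repeat with slack, which can trigger while a better
unconstrained solution still lies outside the budget. The step-2 solve is
not warm-started with the step-1 incumbent (the backend exposes no incumbent
API); feasibility at μ ≥ 1 is guaranteed regardless. Budget feasibility uses
a 1e−6 relative slack for summed-distance roundoff.

Naming: method `consensus-gd` clusters the gene space in step 1 and
optimises the drug-space cost in step 2; `consensus-dg` is the reverse. Both
orientations are exposed because the two-step protocol is meaningful either
way round.

## Probabilistic D-clustering

Membership is `p_k(x_i) ∝ Π_{j≠k} d(x_i, c_j)` (equivalently ∝ 1/d_k), with
a limit rule giving a coinciding point full membership in its center's
cluster; centers update as convex combinations weighted by `p_k(x_i)² /
d(x_i, c_k)`, with zero-distance points excluded from the sums. Iteration
stops when the summed center movement drops below ε = 1e−6 (max 500
iterations). Initialisation is a seeded farthest-point heuristic (random
first pick, then greedy max-min), which is deterministic given the seed and
spreads centers across well-separated structure. The weight exponent reads
the printed update as p², the only dimensionally coherent reading of the
squared-membership working principle. With the correlation distance the
objective is not guaranteed monotone (the Weiszfeld convergence argument
assumes norm-induced distances); the distance is therefore configurable
(`correlation` default, `euclidean` available) and convergence is reported,
not asserted. Hardening takes the row-wise argmax (ties to the lowest
cluster index) and reports as medians the data points nearest each center,
self-assigned for consistency.

## Discretization

**Genes.** Values are log2 ratios; a ratio-scale cut-off β ∈ (0, 1) maps to
thresholds (log2 β, −log2 β) with the closed interval coding normo, so
boundary values are conservative. β = 0.86 (thresholds ±0.2175) is the
canonical operating point and the pipeline default. β can instead be derived
from the data: per-gene two-sided one-sample t-tests against zero, a
multiple-testing filter, and β = 2^(−min |mean log2 FC|) over the
significant genes. Because that minimum is destroyed by even a single false
positive near zero fold change, the filter controls the false-discovery
*proportion* with high confidence (Lehmann–Romano step-down,
P(FDP > 0.05) ≤ 0.01) rather than the mean FDR; mean-FDR control tolerates
exactly the borderline calls that collapse the cut-off. The derivation is
well-posed only when truly differential genes are strongly significant; on
weak-signal data it errors and asks for an explicit β rather than returning
a degenerate one — which is why the default config pins 0.86 instead of
re-deriving per fold.

**Drugs.** Per compound, mean μ_d and sample SD σ_d (ddof = 1) across cell
lines; values ≥ μ_d + 0.8σ_d are resistant, ≤ μ_d − 0.8σ_d sensitive,
boundaries included in the extreme class ("at least" semantics), zero-SD
drugs entirely intermediate. Higher log10(GI50) = more drug needed = more
resistant. The (μ_d, σ_d) pair can be supplied externally so held-out cells
are coded with training-fold statistics. Note a structural property of this
rule: on a pure-noise Gaussian column ~42% of entries code extreme, so
"intermediate" is a 58% majority, which is what makes the trivial baseline
non-trivial to beat.

## Gene selection

Information Gain uses plug-in frequencies, log base 2, 0·log 0 = 0; ties
keep original gene order. CFS scores a subset S of g features by Hall's
merit `g r_bf / sqrt(g + g(g−1) r_ff)` with symmetric uncertainty as the
discrete correlation (the printed denominator variant is dimensionally wrong
at g = 1, where merit must reduce to r_bf). Search is best-first forward
expansion stopping after 5 consecutive non-improving expansions; on small
instances the incumbent matches exhaustive powerset search. Pairwise
symmetric uncertainty over all gene pairs is computed from indicator-matrix
products (nine 3×3-level matmuls) — per-pair contingency scans would
dominate the leave-one-out budget.

When the model needs exactly `n_top` genes: an oversized CFS subset is
truncated by greedy forward selection under the CFS merit itself, so the
kept genes stay mutually non-redundant; truncating by IG rank instead
demonstrably reintroduces near-duplicate genes from the largest clusters
(measured on the synthetic panel: 9-group coverage collapsed to 6). An
undersized subset is padded by IG rank. The default policy is CFS for
exactly this reason: a 10-gene evidence panel for K = 9 clusters only
identifies all clusters if the genes are complementary, and univariate IG
ranking has no mechanism to enforce that. Cross-fold aggregation is by
voting (one vote per appearance in a fold's top list; ties by mean
within-fold rank, then first appearance). The vote aggregates across folds
by construction and is reported as a descriptive summary, flagged in the
report; per-fold predictions use per-fold genes only, and `strict_loo`
suppresses the vote entirely.

## Bayesian network

Structure is fixed: selected genes — cluster — drugs, each drug a child of
the cluster alone. CPTs are relative frequencies with additive pseudo-count
α (default 1, Laplace; α = 0 supported for noise-free constructions).
Inference is exact by a single sum over the K cluster states; no inference
engine is involved.

Two orientations of the gene–cluster edges are provided because the drawn
structure is data-starved at screen scale: with genes→cluster the cluster
CPT is indexed by 3^10 ≈ 59 000 gene configurations against ~59 training
rows, so almost every test configuration is unseen and falls back to the
α-smoothed uniform posterior. The cluster→genes (naive-Bayes) orientation
pools evidence across genes multiplicatively and is the default
(`direction="cluster_to_genes"`). Predicted labels are posterior argmax with
exact ties resolved to intermediate — the least-committal class. The trivial
baseline predicts each drug's training-majority class (ties intermediate).
Accuracy is micro-averaged over fold × drug cells, on the 0–100 scale.

## Leave-one-out protocol

For each held-out cell: cluster the 59 training cells, derive all
discretization statistics from them alone, select genes, fit the network,
then code the held-out cell's genes with the training thresholds and score
its n predicted drug responses against its training-statistic drug codes.
Nothing from the held-out cell reaches any fitted quantity (a perturbation
audit in the test suite verifies this). Homogeneity indices R^G and R^D are
computed per fold on the 59 clustered cells — they describe the clustering
actually used — with singleton clusters contributing weight × 1 (a point
correlates perfectly with itself; the raw formula is 0/0 there). Confidence
intervals are normal-approximation mean ± z·sd/√L (z = 1.959964 at 95%).
Pareto flags mark (R^G, R^D) pairs not weakly dominated.

## Synthetic panel

The generator emulates a 60-cell, 9-group two-space screen: disjoint
per-group gene blocks of ⌊m/2K⌋ genes shifted ±2 log2 units (comfortably
beyond the ±0.2175 coding thresholds), disjoint drug blocks of ⌊n/2K⌋
drugs shifted ±8 noise-SDs, i.i.d. Gaussian noise (σ = 0.1), optional
missingness that never leaves a feature with fewer than two observations,
and a cross-space agreement rate (1.0 by default; lower values re-draw
drug-space memberships for a Bernoulli-selected subset of cells). The drug
shift comes from the discretization-recoverability condition — the member
shift must clear the 0.8·σ_column threshold, and the threshold must clear
the non-member mean, each by about two noise SDs — which is the drug-space
analogue of requiring gene_effect > −log2 β, and matches the orders-of-
magnitude GI50 contrasts real responder/non-responder lines show. Blocks
are disjoint across groups so selection has an unambiguous ground truth.

What the benchmark does *not* emulate: correlated noise and batch structure,
heavy-tailed expression, dose–response curve artefacts, genes informative
about several clusters at once, and cluster–drug associations weaker than
block-structured. Passing the end-to-end benchmark therefore shows the
pipeline is implemented correctly and extracts planted cross-space structure
under calibrated noise; it does not certify effect sizes on real screens,
where roughly half the compounds may carry no cluster signal at all and the
margin over the majority-class baseline is correspondingly small.

## Problem sizes and determinism

Defaults keep every stage desk-scale: 60 cells × 200 genes × 100 drugs for
the end-to-end run (a full 60-fold leave-one-out with per-fold consensus
clustering and CFS selection completes in a few minutes on one CPU), n ≤ 10
instances for enumeration cross-checks, ≤ 4-gene networks for full-joint
inference checks. All stochastic components (generator, D-clustering
initialisation) take explicit seeds; given a config and seed, reports are
bit-for-bit reproducible.

## Known limitations

- The μ grid is a grid: μ* is located to mu_step resolution, not exactly.
- CFS best-first search is a heuristic; optimality versus powerset search is
  verified only at small m.
- The auto-β derivation requires strongly significant differential genes;
  bimodal weak-t signals make it error by design.
- With α = 0, unseen gene configurations in the genes→cluster orientation
  have an undefined posterior; the implementation returns uniform and
  documents it.
- `1 − corr` on profiles dominated by a few extreme features can make
  distinct cell lines near-identical; no robust-correlation variant is
  provided.
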