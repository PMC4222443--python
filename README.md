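# pmedianrx

Integrative clustering and multi-drug response prediction for tumour
cell-line panels.

Screens such as the NCI60 characterise each cell line twice: a gene (or
miRNA) expression profile `x_i^G ∈ R^m` and a drug-activity profile
`x_i^D ∈ R^n` of log10(GI50) values over hundreds of compounds. The question
this package addresses is whether groups of cell lines that are homogeneous
in *both* spaces are characterised by a small gene signature that predicts
the response to every drug at once — so that a new sample's discretized
expression profile is enough to call, in silico, its sensitivity to the
whole compound panel. It is written for computational biologists and
cheminformaticians working with paired expression / drug-sensitivity
matrices.

## The method

1. **Exact p-Median clustering.** With the correlation dissimilarity
   `d(x_i, x_j) = 1 − corr(x_i, x_j)`, select K cell lines as geometric
   medians and assign every cell line to one:

   ```
   min Σ_ij z_ij d(x_i, x_j)
   s.t. Σ_j z_ij = 1,  Σ_j z_jj = K,  z_ij ≤ z_jj,  z_ij ∈ {0,1}
   ```

   solved to proven global optimality by branch-and-cut (HiGHS), so the
   clustering carries no stochastic variance.

2. **Consensus p-Median.** To make the clusters homogeneous in both spaces,
   a second solve minimises the cost under `d^(1)` (say, the gene space)
   subject to an ε-constraint budgeting the cost under `d^(2)` (the drug
   space) at `μ ≥ 1` times the step-1 optimum. Sweeping μ from 1 upward
   traces the trade-off front between the two spaces until the constraint
   becomes redundant (μ*). A soft alternative, probabilistic D-clustering
   (membership inversely proportional to center distance, generalized
   Weiszfeld updates), is included.

3. **Discretization.** Expression log2 ratios become {down, normo, up} via a
   ratio-scale cut-off β (β = 0.86 ⇒ thresholds ±0.2175, derivable from the
   data by an FDP-exceedance-controlled differential test); log10(GI50)
   becomes {sensitive, intermediate, resistant} per drug by the 0.8-SD rule.

4. **Gene selection.** Information Gain `IG(C, A) = H(C) − H(C|A)` ranks
   genes against the cluster label; CFS picks a subset maximising Hall's
   merit `g·r_bf / sqrt(g + g(g−1) r_ff)` (predictive yet mutually
   non-redundant) by best-first search.

5. **Bayesian network.** A fixed-structure discrete network — 10 selected
   gene nodes, one K-state cluster node, n drug nodes hanging off the
   cluster — is fit by Laplace-smoothed counts. Exact inference is a sum
   over the cluster states: `P(drug | genes) = Σ_k P(drug | k) P(k | genes)`,
   predicting all n drug responses simultaneously.

Everything is evaluated by leave-one-out cross-validation in which
clustering, thresholds, selection and network training see only the 59
training cells, against a trivial per-drug majority-class baseline, with
per-space cluster-homogeneity indices R^G and R^D (cardinality-weighted mean
within-cluster Pearson correlation) and Pareto-point identification over
(R^G, R^D).

## Worked example

Simulate a small panel with 3 planted groups and evaluate the full pipeline:

```sh
pmedianrx simulate --out sim --n-cells 24 --k 3 --m 60 --n 30 --seed 11
pmedianrx evaluate --genes sim/genes.tsv --drugs sim/drugs.tsv \
                   --method consensus-dg --k 3 --out eval
```

which prints

```
wrote synthetic panel (24 cells, 60 genes, 30 drugs) to sim
LOO accuracy 63.61% (baseline 49.86%), R_G=0.9855, R_D=0.9135
```

Reading: across 24 leave-one-out folds × 30 drugs, the network called 63.6%
of the held-out ternary drug responses correctly versus 49.9% for the
per-drug majority class, and the consensus clusters are highly homogeneous
in both spaces (mean within-cluster correlation 0.99 for genes, 0.91 for
drugs). `eval/report.json` carries per-fold records, 95% confidence
half-widths, and the cross-fold gene vote.

The same stages are available as library functions
(`pmedianrx.solve_pmedian`, `consensus_sweep`, `solve_pdclustering`,
`derive_beta`, `information_gain`, `cfs_select`, `fit_cpds`,
`predict_drugs`, `loo_evaluate`, ...) and as the other CLI subcommands
(`cluster`, `discretize`, `select`, `train`, `predict`).

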