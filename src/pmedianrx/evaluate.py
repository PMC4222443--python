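"""Leave-one-out evaluation of the full pipeline and cluster-quality indices.

For each cell line in turn: cluster the remaining cells, derive the
discretization thresholds from those cells only, select the
cluster-characterising genes, fit the Bayesian network, and predict the
held-out cell's full drug-response profile (its genes coded with the
training thresholds). Nothing about the held-out cell enters any training
stage. The report aggregates prediction accuracy, the per-space cluster
homogeneity index

    R = sum_k (n_k / |Omega|) * [ 2 / (n_k (n_k - 1)) * sum_{i<j in k} corr(x_i, x_j) ]

(singleton clusters contribute their weight times 1), normal-approximation
confidence intervals, the cross-fold gene vote, and a trivial majority-class
baseline measured on the same folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import bayesnet, discretize, features
from .config import RunConfig
from .distance import distance_matrix
from .panel import CellLinePanel
from .pmedian import ClusteringSolution, consensus_sweep, solve_pmedian
from .soft import harden, solve_pdclustering


def cluster_correlation_index(labels: np.ndarray, matrix: np.ndarray) -> float:
    """Cardinality-weighted mean within-cluster Pearson correlation."""
    labels = np.asarray(labels)
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels must cover every row of the matrix")
    corr = np.clip(np.corrcoef(X), -1.0, 1.0)
    R = 0.0
    for k in np.unique(labels):
        members = np.flatnonzero(labels == k)
        nk = members.size
        if nk == 1:
            R += 1.0 / n  # a point correlates perfectly with itself
            continue
        sub = corr[np.ix_(members, members)]
        pair_sum = (sub.sum() - np.trace(sub)) / 2.0
        R += (nk / n) * (2.0 / (nk * (nk - 1))) * pair_sum
    return float(R)


def confidence_interval(values: list[float] | np.ndarray, level: float = 0.95):
    """Normal-approximation mean +/- z * sd / sqrt(L) interval; returns (mean, half_width)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    if level <= 0:
        return float(v.mean()), 0.0
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    return float(v.mean()), float(z * v.std(ddof=1) / np.sqrt(v.size))


def pareto_points(points: list[tuple[float, float]]) -> list[bool]:
    """True for points not dominated (>= in both coordinates, > in one) by any other."""
    if not points:
        raise ValueError("need at least one point")
    flags = []
    for i, (a1, a2) in enumerate(points):
        dominated = any(
            (b1 >= a1 and b2 >= a2) and (b1 > a1 or b2 > a2)
            for j, (b1, b2) in enumerate(points)
            if j != i
        )
        flags.append(not dominated)
    return flags


@dataclass
class FoldRecord:
    """Everything one leave-one-out fold produced."""

    fold: int
    held_out: str
    labels: np.ndarray
    selected_genes: list[str]
    accuracy: float
    baseline_accuracy: float
    R_G: float
    R_D: float


@dataclass
class EvaluationReport:
    """Aggregated leave-one-out results plus the per-fold records."""

    folds: list[FoldRecord]
    accuracy_mean: float
    accuracy_half_width: float
    baseline_mean: float
    baseline_half_width: float
    micro_accuracy: float
    micro_baseline_accuracy: float
    R_G_mean: float
    R_G_half_width: float
    R_D_mean: float
    R_D_half_width: float
    voted_genes: list[str]
    config: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        doc = {
            "config": self.config,
            "accuracy": {"mean": self.accuracy_mean, "half_width": self.accuracy_half_width},
            "baseline": {"mean": self.baseline_mean, "half_width": self.baseline_half_width},
            "micro_accuracy": self.micro_accuracy,
            "micro_baseline_accuracy": self.micro_baseline_accuracy,
            "R_G": {"mean": self.R_G_mean, "half_width": self.R_G_half_width},
            "R_D": {"mean": self.R_D_mean, "half_width": self.R_D_half_width},
            "voted_genes": self.voted_genes,
            "notes": self.notes,
            "folds": [
                {
                    "fold": f.fold,
                    "held_out": f.held_out,
                    "selected_genes": f.selected_genes,
                    "accuracy": f.accuracy,
                    "baseline_accuracy": f.baseline_accuracy,
                    "R_G": f.R_G,
                    "R_D": f.R_D,
                }
                for f in self.folds
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def _cluster_training_fold(
    panel: CellLinePanel, config: RunConfig
) -> ClusteringSolution:
    """Run the configured clustering method on a (training) panel."""
    if config.method == "pmedian":
        D = distance_matrix(panel.joint_matrix, "joint", panel.cell_ids)
        return solve_pmedian(D, config.K)
    if config.method in ("consensus-gd", "consensus-dg"):
        Dg = distance_matrix(panel.gene_matrix, "gene", panel.cell_ids)
        Dd = distance_matrix(panel.drug_matrix, "drug", panel.cell_ids)
        # (g-d): step 1 in the gene space (d2), step-2 objective in the drug space (d1)
        D2, D1 = (Dg, Dd) if config.method == "consensus-gd" else (Dd, Dg)
        trace = consensus_sweep(
            D1, D2, config.K, config.mu_start, config.mu_step, config.max_mu
        )
        return trace.entries[-1][1]
    if config.method == "pdclust":
        soft = solve_pdclustering(panel.joint_matrix, config.K, seed=config.seed)
        return harden(soft, panel.joint_matrix)
    raise ValueError(f"unknown clustering method {config.method!r}")


def loo_evaluate(panel: CellLinePanel, config: RunConfig) -> EvaluationReport:
    """Leave-one-out run of clustering, discretization, selection and BN prediction."""
    config.validate()
    if np.isnan(panel.gene_matrix).any() or np.isnan(panel.drug_matrix).any():
        raise ValueError("panel contains missing values; impute before evaluation")
    n = panel.n_cells
    if config.K > n - 1:
        raise ValueError("K exceeds the training-fold size")

    folds: list[FoldRecord] = []
    fold_gene_lists: list[list[str]] = []
    correct = 0
    correct_baseline = 0
    total = 0
    for i in range(n):
        train_idx = np.array([j for j in range(n) if j != i])
        train = panel.subset_cells(train_idx)

        solution = _cluster_training_fold(train, config)
        labels = solution.labels + 1  # 1..K for the BN

        if config.beta == "auto":
            beta = discretize.derive_beta(train.gene_matrix, config.fdr_level)
        else:
            beta = float(config.beta)
        gene_codes = discretize.discretize_genes(train.gene_matrix, beta)
        drug_stats = discretize.drug_thresholds(train.drug_matrix, config.sd_factor)
        drug_codes = discretize.discretize_drugs(
            train.drug_matrix, config.sd_factor, stats_=drug_stats
        )

        selected = features.select_genes_for_model(
            gene_codes, labels, train.gene_ids, config.selection, config.n_top
        )
        fold_gene_lists.append(selected)
        sel_idx = [train.gene_ids.index(g) for g in selected]

        n_clusters = int(labels.max())
        model = bayesnet.build_structure(selected, n_clusters, train.drug_ids, config.direction)
        bayesnet.fit_cpds(model, gene_codes[:, sel_idx], labels, drug_codes, config.alpha)

        test_gene_codes = discretize.discretize_genes(
            panel.gene_matrix[i : i + 1], beta
        )[0, sel_idx]
        truth = discretize.discretize_drugs(
            panel.drug_matrix[i : i + 1], config.sd_factor, stats_=drug_stats
        )[0]
        pred = bayesnet.predict_drugs(model, test_gene_codes)
        base = bayesnet.trivial_baseline(drug_codes, 1)[0]

        acc = bayesnet.accuracy(pred.predicted_labels, truth)
        base_acc = bayesnet.accuracy(base, truth)
        correct += int((pred.predicted_labels == truth).sum())
        correct_baseline += int((base == truth).sum())
        total += truth.size

        folds.append(
            FoldRecord(
                fold=i,
                held_out=panel.cell_ids[i],
                labels=labels,
                selected_genes=selected,
                accuracy=acc,
                baseline_accuracy=base_acc,
                R_G=cluster_correlation_index(labels, train.gene_matrix),
                R_D=cluster_correlation_index(labels, train.drug_matrix),
            )
        )

    acc_mean, acc_hw = confidence_interval([f.accuracy for f in folds])
    base_mean, base_hw = confidence_interval([f.baseline_accuracy for f in folds])
    rg_mean, rg_hw = confidence_interval([f.R_G for f in folds])
    rd_mean, rd_hw = confidence_interval([f.R_D for f in folds])
    notes = []
    if not config.strict_loo:
        notes.append(
            "voted_genes aggregates per-fold top lists across folds (mild leakage "
            "by construction of the voting protocol); per-fold predictions use "
            "per-fold genes only"
        )
    return EvaluationReport(
        folds=folds,
        accuracy_mean=acc_mean,
        accuracy_half_width=acc_hw,
        baseline_mean=base_mean,
        baseline_half_width=base_hw,
        micro_accuracy=100.0 * correct / total,
        micro_baseline_accuracy=100.0 * correct_baseline / total,
        R_G_mean=rg_mean,
        R_G_half_width=rg_hw,
        R_D_mean=rd_mean,
        R_D_half_width=rd_hw,
        voted_genes=[] if config.strict_loo else features.vote_across_folds(
            fold_gene_lists, config.n_top
        ),
        config={**config.to_dict(), "config_hash": config.hash()},
        notes=notes,
    )
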