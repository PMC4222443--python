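"""Synthetic cell-line panels with planted cluster structure in both spaces.

The generator emulates the structure of an NCI60-style screen: ``n_cells``
cell lines fall into K groups; each group owns a disjoint block of genes
shifted by +/-``gene_effect`` log2 units for its members and a disjoint
block of drugs shifted by +/-``drug_effect`` noise SDs; i.i.d. Gaussian
noise and optional missing entries are layered on top. Drug-space group
membership agrees with the gene-space grouping for an expected fraction
``cross_space_agreement`` of cells and is re-drawn for the rest, so the
tension the consensus clustering trades off can be dialled in. Blocks are
disjoint across groups, which gives feature selection an unambiguous ground
truth.

Defaults mirror the screen the pipeline targets: 60 cell lines in 9 groups,
a couple of hundred genes, about a hundred drugs, a 2 log2-unit expression
effect over 0.1-SD noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import CellLinePanel


@dataclass(frozen=True)
class SyntheticSpec:
    """Design parameters of a planted-structure panel."""

    n_cells: int = 60
    K: int = 9
    m: int = 200
    n: int = 100
    gene_effect: float = 2.0  # log2 units added to a group's gene block
    # Drug-block shift in units of noise_sd. Chosen so the planted
    # sensitive/resistant classes survive the 0.8-SD coding (the drug-space
    # analogue of gene_effect > -log2(beta)): with member fraction p = 1/K the
    # column SD is noise_sd*sqrt(1 + s^2 p(1-p)), and s = 8 puts members ~4.5
    # noise SDs beyond the threshold and the threshold ~1.6 noise SDs above
    # the non-member mean. Real log10(GI50) contrasts between responsive and
    # resistant lines span orders of magnitude against ~0.1-0.3 assay noise.
    drug_effect: float = 8.0
    noise_sd: float = 0.1
    cross_space_agreement: float = 1.0
    missing_rate: float = 0.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.K > self.n_cells or self.K < 1:
            raise ValueError("require 1 <= K <= n_cells")
        if self.gene_effect < 0 or self.drug_effect < 0 or self.noise_sd < 0:
            raise ValueError("effects and noise must be non-negative")
        if not 0 <= self.cross_space_agreement <= 1:
            raise ValueError("cross_space_agreement must lie in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.m < self.K or self.n < self.K:
            raise ValueError("need at least one feature per group in each space")


def _block_means(
    labels: np.ndarray,
    n_features: int,
    K: int,
    effect: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean matrix with one disjoint signed feature block per group."""
    block = max(1, n_features // (2 * K))
    order = rng.permutation(n_features)
    means = np.zeros((labels.size, n_features))
    for k in range(K):
        cols = order[k * block : (k + 1) * block]
        signs = rng.choice([-1.0, 1.0], size=cols.size)
        means[np.ix_(labels == k, cols)] = signs * effect
    return means


def _inject_missing(
    matrix: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    if rate == 0:
        return matrix
    out = matrix.copy()
    mask = rng.random(out.shape) < rate
    # keep at least two observed values per feature so imputation and
    # variance-based steps stay defined
    for j in range(out.shape[1]):
        col = np.flatnonzero(mask[:, j])
        excess = col.size - (out.shape[0] - 2)
        if excess > 0:
            keep_observed = rng.choice(col, size=excess, replace=False)
            mask[keep_observed, j] = False
    out[mask] = np.nan
    return out


def generate(spec: SyntheticSpec) -> tuple[CellLinePanel, np.ndarray, np.ndarray]:
    """A panel plus the planted gene-space and drug-space group labels."""
    rng = np.random.default_rng(spec.seed)
    labels_gene = rng.permutation(np.arange(spec.n_cells) % spec.K)

    labels_drug = labels_gene.copy()
    disagree = rng.random(spec.n_cells) >= spec.cross_space_agreement
    if spec.K > 1:
        for i in np.flatnonzero(disagree):
            others = [k for k in range(spec.K) if k != labels_gene[i]]
            labels_drug[i] = rng.choice(others)

    gene_means = _block_means(labels_gene, spec.m, spec.K, spec.gene_effect, rng)
    drug_means = _block_means(
        labels_drug, spec.n, spec.K, spec.drug_effect * spec.noise_sd, rng
    )
    genes = gene_means + rng.normal(0.0, spec.noise_sd, size=gene_means.shape)
    drugs = drug_means + rng.normal(0.0, spec.noise_sd, size=drug_means.shape)
    genes = _inject_missing(genes, spec.missing_rate, rng)
    drugs = _inject_missing(drugs, spec.missing_rate, rng)

    panel = CellLinePanel(
        cell_ids=[f"CELL{i:03d}" for i in range(spec.n_cells)],
        gene_matrix=genes,
        drug_matrix=drugs,
        gene_ids=[f"G{j:04d}" for j in range(spec.m)],
        drug_ids=[f"D{j:04d}" for j in range(spec.n)],
    )
    return panel, labels_gene, labels_drug


def write_panel(
    panel: CellLinePanel,
    gene_path: str,
    drug_path: str,
    truth_path: str | None = None,
    labels_gene: np.ndarray | None = None,
    labels_drug: np.ndarray | None = None,
) -> None:
    """Write a panel in the delimited layout the loader reads (features in columns)."""
    sep_for = lambda p: "," if str(p).lower().endswith(".csv") else "\t"
    pd.DataFrame(panel.gene_matrix, index=panel.cell_ids, columns=panel.gene_ids).to_csv(
        gene_path, sep=sep_for(gene_path)
    )
    pd.DataFrame(panel.drug_matrix, index=panel.cell_ids, columns=panel.drug_ids).to_csv(
        drug_path, sep=sep_for(drug_path)
    )
    if truth_path is not None:
        truth = pd.DataFrame({"cell_id": panel.cell_ids})
        if labels_gene is not None:
            truth["group_gene_space"] = labels_gene
        if labels_drug is not None:
            truth["group_drug_space"] = labels_drug
        truth.to_csv(truth_path, sep=sep_for(truth_path), index=False)
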