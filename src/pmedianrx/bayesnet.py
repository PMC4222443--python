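"""Fixed-structure discrete Bayesian network for simultaneous drug-response prediction.

The graph links the selected genes and the drugs only through one latent
cluster variable: gene nodes (3 states: down/normo/up) on top, the cluster
node (K states) in the middle, drug nodes (3 states: sensitive/intermediate/
resistant) at the bottom, each drug a child of the cluster alone. Because
the genes are always fully observed at query time and every drug hangs off
the single cluster node, exact inference is a plain sum over the K cluster
states — no general-purpose engine is needed.

Two orientations of the gene-cluster edges are supported. With
``genes_to_cluster`` (the drawn structure) the cluster's CPT is indexed by
the 3^g gene configurations; with 10 genes that is far more configurations
than a 60-cell panel can populate, so unseen configurations fall back to the
alpha-smoothed uniform posterior. ``cluster_to_genes`` is the naive-Bayes
reading: the cluster is the root and each gene an independent child, which
pools evidence across genes and is far less data-starved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .discretize import INTERMEDIATE, LEVELS

_LEVEL_INDEX = {v: i for i, v in enumerate(LEVELS)}  # -1 -> 0, 0 -> 1, 1 -> 2


@dataclass
class BNModel:
    """Genes-cluster-drugs network with CPTs estimated by alpha-smoothed counts."""

    gene_ids: list[str]
    K: int
    drug_ids: list[str]
    direction: str = "genes_to_cluster"
    alpha: float = 1.0
    fitted: bool = False
    # genes_to_cluster: P(cluster | gene config) for observed configs, else smoothed uniform
    cluster_given_genes: dict[tuple[int, ...], np.ndarray] = field(default_factory=dict)
    # cluster_to_genes: P(gene level | cluster), one 3 x K table per gene
    gene_given_cluster: np.ndarray | None = None
    cluster_prior: np.ndarray | None = None
    # P(drug level | cluster): n_drugs x 3 x K
    drug_given_cluster: np.ndarray | None = None
    gene_marginals: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("duplicate drug ids")
        if not self.gene_ids:
            raise ValueError("need at least one gene node")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.direction not in ("genes_to_cluster", "cluster_to_genes"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.gene_ids) + 1 + len(self.drug_ids)

    @property
    def n_edges(self) -> int:
        return len(self.gene_ids) + len(self.drug_ids)

    def to_json(self, path: str) -> None:
        doc = {
            "gene_ids": self.gene_ids,
            "K": self.K,
            "drug_ids": self.drug_ids,
            "direction": self.direction,
            "alpha": self.alpha,
            "fitted": self.fitted,
            "cluster_prior": None if self.cluster_prior is None else self.cluster_prior.tolist(),
            "cluster_given_genes": {
                ",".join(map(str, k)): v.tolist() for k, v in self.cluster_given_genes.items()
            },
            "gene_given_cluster": None
            if self.gene_given_cluster is None
            else self.gene_given_cluster.tolist(),
            "drug_given_cluster": None
            if self.drug_given_cluster is None
            else self.drug_given_cluster.tolist(),
            "gene_marginals": None
            if self.gene_marginals is None
            else self.gene_marginals.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path: str) -> "BNModel":
        with open(path) as fh:
            doc = json.load(fh)
        model = cls(
            gene_ids=doc["gene_ids"],
            K=doc["K"],
            drug_ids=doc["drug_ids"],
            direction=doc["direction"],
            alpha=doc["alpha"],
            fitted=doc["fitted"],
        )
        if doc["cluster_prior"] is not None:
            model.cluster_prior = np.array(doc["cluster_prior"])
        model.cluster_given_genes = {
            tuple(int(t) for t in k.split(",")): np.array(v)
            for k, v in doc["cluster_given_genes"].items()
        }
        if doc["gene_given_cluster"] is not None:
            model.gene_given_cluster = np.array(doc["gene_given_cluster"])
        if doc["drug_given_cluster"] is not None:
            model.drug_given_cluster = np.array(doc["drug_given_cluster"])
        if doc["gene_marginals"] is not None:
            model.gene_marginals = np.array(doc["gene_marginals"])
        return model


@dataclass
class PredictionResult:
    """Per-drug posteriors and argmax labels plus the cluster posterior."""

    drug_posteriors: np.ndarray  # n_drugs x 3, columns ordered (-1, 0, 1)
    predicted_labels: np.ndarray  # int8 codes in {-1, 0, 1}
    cluster_posterior: np.ndarray


def build_structure(
    gene_ids: list[str],
    K: int,
    drug_ids: list[str],
    direction: str = "genes_to_cluster",
) -> BNModel:
    """An unfitted network with the fixed genes-cluster-drugs topology."""
    return BNModel(gene_ids=list(gene_ids), K=K, drug_ids=list(drug_ids), direction=direction)


def _smooth(counts: np.ndarray, alpha: float) -> np.ndarray:
    """Additive smoothing along the first axis; all-zero unsmoothed columns go uniform."""
    counts = counts.astype(float) + alpha
    totals = counts.sum(axis=0, keepdims=True)
    out = np.where(totals > 0, counts / np.where(totals > 0, totals, 1.0), 1.0 / counts.shape[0])
    return out


def fit_cpds(
    model: BNModel,
    gene_codes: np.ndarray,
    cluster_labels: np.ndarray,
    drug_codes: np.ndarray,
    alpha: float = 1.0,
) -> BNModel:
    """Estimate every CPT by relative frequency with pseudo-count ``alpha``.

    ``cluster_labels`` take values 1..K; gene and drug codes are ternary
    {-1, 0, 1} matrices row-aligned with the labels.
    """
    genes = np.asarray(gene_codes)
    drugs = np.asarray(drug_codes)
    labels = np.asarray(cluster_labels, dtype=int)
    if genes.shape[0] == 0:
        raise ValueError("empty training set")
    if not (genes.shape[0] == drugs.shape[0] == labels.shape[0]):
        raise ValueError("inputs must be row-aligned")
    if genes.shape[1] != len(model.gene_ids) or drugs.shape[1] != len(model.drug_ids):
        raise ValueError("code matrices inconsistent with the model's node lists")
    if labels.min() < 1 or labels.max() > model.K:
        raise ValueError("cluster labels must lie in 1..K")
    K = model.K
    n_cells = genes.shape[0]
    k_idx = labels - 1

    # drug CPTs: 3 x K counts per drug
    drug_counts = np.zeros((drugs.shape[1], 3, K))
    for v, vi in _LEVEL_INDEX.items():
        mask = drugs == v
        for k in range(K):
            drug_counts[:, vi, k] += mask[k_idx == k].sum(axis=0)
    model.drug_given_cluster = np.stack(
        [_smooth(drug_counts[d], alpha) for d in range(drugs.shape[1])]
    )

    prior_counts = np.bincount(k_idx, minlength=K).astype(float)
    model.cluster_prior = _smooth(prior_counts[:, None], alpha).ravel()

    if model.direction == "genes_to_cluster":
        configs: dict[tuple[int, ...], np.ndarray] = {}
        for i in range(n_cells):
            cfg = tuple(int(v) for v in genes[i])
            configs.setdefault(cfg, np.zeros(K))[k_idx[i]] += 1.0
        model.cluster_given_genes = {
            cfg: _smooth(c[:, None], alpha).ravel() for cfg, c in configs.items()
        }
        marg = np.zeros((genes.shape[1], 3))
        for v, vi in _LEVEL_INDEX.items():
            marg[:, vi] = (genes == v).sum(axis=0)
        model.gene_marginals = np.stack([_smooth(row[:, None], alpha).ravel() for row in marg])
    else:
        gene_counts = np.zeros((genes.shape[1], 3, K))
        for v, vi in _LEVEL_INDEX.items():
            mask = genes == v
            for k in range(K):
                gene_counts[:, vi, k] += mask[k_idx == k].sum(axis=0)
        model.gene_given_cluster = np.stack(
            [_smooth(gene_counts[g], alpha) for g in range(genes.shape[1])]
        )
    model.alpha = alpha
    model.fitted = True
    return model


def _cluster_posterior(model: BNModel, evidence: np.ndarray) -> np.ndarray:
    K = model.K
    if model.direction == "genes_to_cluster":
        cfg = tuple(int(v) for v in evidence)
        post = model.cluster_given_genes.get(cfg)
        if post is None:
            # configuration unseen in training: the smoothed CPT column is uniform
            # (and undefined at alpha = 0, where uniform is the least-informative choice)
            post = np.full(K, 1.0 / K)
        return post.copy()
    log_post = np.log(np.maximum(model.cluster_prior, 1e-300)).copy()
    for g, v in enumerate(evidence):
        vi = _LEVEL_INDEX[int(v)]
        log_post += np.log(np.maximum(model.gene_given_cluster[g][vi], 1e-300))
    log_post -= log_post.max()
    post = np.exp(log_post)
    total = post.sum()
    return post / total if total > 0 else np.full(K, 1.0 / K)


def predict_drugs(model: BNModel, gene_evidence: np.ndarray) -> PredictionResult:
    """Exact posteriors for every drug given a complete ternary gene profile.

    The cluster posterior is computed from the joint factorisation; each
    drug's posterior is sum_k P(drug | k) P(k | evidence). Predicted labels
    are the argmax level, with exact posterior ties resolved to intermediate.
    """
    if not model.fitted:
        raise ValueError("model is not fitted")
    evidence = np.asarray(gene_evidence).ravel()
    if evidence.shape[0] != len(model.gene_ids):
        raise ValueError("evidence must cover every gene node")
    post_c = _cluster_posterior(model, evidence)
    drug_post = model.drug_given_cluster @ post_c  # n_drugs x 3
    totals = drug_post.sum(axis=1, keepdims=True)
    drug_post = np.where(totals > 0, drug_post / np.where(totals > 0, totals, 1.0), 1.0 / 3.0)
    labels = np.empty(drug_post.shape[0], dtype=np.int8)
    level_arr = np.array(LEVELS, dtype=np.int8)
    for d in range(drug_post.shape[0]):
        row = drug_post[d]
        best = row.max()
        tied = np.flatnonzero(np.isclose(row, best, rtol=0, atol=1e-12))
        if tied.size > 1:
            labels[d] = INTERMEDIATE
        else:
            labels[d] = level_arr[tied[0]]
    return PredictionResult(
        drug_posteriors=drug_post, predicted_labels=labels, cluster_posterior=post_c
    )


def accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Percentage of drug-response labels predicted correctly (micro-average)."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("prediction/truth shape mismatch")
    return 100.0 * float((predicted == truth).mean())


def trivial_baseline(drug_codes_train: np.ndarray, n_test_rows: int) -> np.ndarray:
    """Majority-class prediction per drug, replicated over the test rows.

    Modal ties resolve to intermediate.
    """
    train = np.asarray(drug_codes_train)
    if train.shape[0] == 0:
        raise ValueError("empty training set")
    modes = np.empty(train.shape[1], dtype=np.int8)
    for d in range(train.shape[1]):
        counts = np.array([(train[:, d] == v).sum() for v in LEVELS])
        best = counts.max()
        tied = np.flatnonzero(counts == best)
        modes[d] = INTERMEDIATE if tied.size > 1 else LEVELS[tied[0]]
    return np.tile(modes, (n_test_rows, 1))
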