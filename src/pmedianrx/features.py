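"""Cluster-characterising gene selection on ternary-coded expression.

Two policies: Information Gain ranks every gene by the entropy reduction of
the cluster label given that gene's code, and CFS (correlation-based feature
subset selection) searches for a subset whose members are individually
predictive of the cluster while mutually non-redundant, scored by Hall's
merit

    Merit(S) = g * r_bf / sqrt(g + g(g-1) * r_ff)

with r_bf the mean feature-cluster and r_ff the mean pairwise feature-feature
symmetric uncertainty. Per-fold top-10 lists from a leave-one-out run are
combined by voting.
"""

from __future__ import annotations

import heapq
import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np


@dataclass
class FeatureRanking:
    """Information-gain scores per gene and the descending-score order."""

    scores: dict[str, float]
    ordered_ids: list[str]


@dataclass
class CFSSubset:
    """A CFS-selected gene subset, its merit and the search effort spent."""

    gene_ids: list[str]
    merit: float
    search_log: int


def _entropy(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _information_gain_column(codes: np.ndarray, labels: np.ndarray) -> float:
    """IG(C, A) = H(C) - H(C|A) from the label x code contingency table."""
    label_vals, label_idx = np.unique(labels, return_inverse=True)
    code_vals, code_idx = np.unique(codes, return_inverse=True)
    table = np.zeros((label_vals.size, code_vals.size))
    np.add.at(table, (label_idx, code_idx), 1.0)
    n = table.sum()
    h_c = _entropy(table.sum(axis=1))
    h_c_given_a = sum(
        (table[:, t].sum() / n) * _entropy(table[:, t]) for t in range(code_vals.size)
    )
    return max(0.0, h_c - h_c_given_a)


def information_gain(
    gene_codes: np.ndarray, labels: np.ndarray, gene_ids: list[str] | None = None
) -> FeatureRanking:
    """Rank genes by IG against the cluster labels (ties keep original gene order)."""
    codes = np.asarray(gene_codes)
    labels = np.asarray(labels)
    if codes.shape[0] != labels.shape[0]:
        raise ValueError("gene_codes rows and labels must align")
    ids = gene_ids if gene_ids is not None else [str(j) for j in range(codes.shape[1])]
    scores = {ids[j]: _information_gain_column(codes[:, j], labels) for j in range(codes.shape[1])}
    order = sorted(range(len(ids)), key=lambda j: (-scores[ids[j]], j))
    return FeatureRanking(scores=scores, ordered_ids=[ids[j] for j in order])


def top_k(ranking: FeatureRanking, k: int = 10) -> list[str]:
    """The k best-ranked gene ids."""
    if k > len(ranking.ordered_ids):
        raise ValueError(f"k={k} exceeds the {len(ranking.ordered_ids)} ranked genes")
    return ranking.ordered_ids[:k]


def symmetric_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """2 IG(X,Y) / (H(X) + H(Y)); 0 when both variables are constant."""
    hx = _entropy(np.unique(x, return_counts=True)[1])
    hy = _entropy(np.unique(y, return_counts=True)[1])
    if hx + hy == 0.0:
        return 0.0
    ig = _information_gain_column(np.asarray(x), np.asarray(y))
    return float(2.0 * ig / (hx + hy))


def _pairwise_su(codes: np.ndarray) -> np.ndarray:
    """All-pairs symmetric uncertainty between ternary columns via joint counts.

    Joint level counts for every column pair come from indicator-matrix
    products, so the m x m table costs nine small matmuls instead of m^2
    contingency scans.
    """
    codes = np.asarray(codes)
    n, m = codes.shape
    indicators = [(codes == v).astype(float) for v in (-1, 0, 1)]
    marg = np.stack([ind.sum(axis=0) for ind in indicators])  # 3 x m
    with np.errstate(divide="ignore", invalid="ignore"):
        p = marg / n
        H = -np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0).sum(axis=0)
    joint_entropy = np.zeros((m, m))
    for a in indicators:
        for b in indicators:
            J = a.T @ b  # joint counts for (level_a, level_b) per column pair
            pj = J / n
            joint_entropy -= np.where(pj > 0, pj * np.log2(np.where(pj > 0, pj, 1.0)), 0.0)
    mi = H[:, None] + H[None, :] - joint_entropy
    denom = H[:, None] + H[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        su = np.where(denom > 0, 2.0 * mi / np.where(denom > 0, denom, 1.0), 0.0)
    su = np.clip((su + su.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(su, 1.0)
    return su


def cfs_merit(subset: tuple[int, ...], su_class: np.ndarray, su_pair: np.ndarray) -> float:
    """Hall's merit of a feature subset from precomputed symmetric uncertainties."""
    g = len(subset)
    if g == 0:
        return 0.0
    r_bf = float(su_class[list(subset)].mean())
    if g == 1:
        return r_bf
    pairs = list(itertools.combinations(subset, 2))
    r_ff = float(np.mean([su_pair[a, b] for a, b in pairs]))
    denom = np.sqrt(g + g * (g - 1) * r_ff)
    return g * r_bf / denom if denom > 0 else 0.0


def cfs_select(
    gene_codes: np.ndarray,
    labels: np.ndarray,
    gene_ids: list[str] | None = None,
    max_stale: int = 5,
) -> CFSSubset:
    """Best-first forward search for the highest-merit subset.

    Subsets are expanded by single-feature additions in decreasing merit
    order; the search stops after ``max_stale`` consecutive expansions fail
    to improve the incumbent.
    """
    codes = np.asarray(gene_codes)
    labels = np.asarray(labels)
    m = codes.shape[1]
    ids = gene_ids if gene_ids is not None else [str(j) for j in range(m)]
    su_class = np.array([symmetric_uncertainty(codes[:, j], labels) for j in range(m)])
    su_pair = _pairwise_su(codes)

    best_subset: tuple[int, ...] = ()
    best_merit = 0.0
    # heap entries: (-merit, subset) with subsets as sorted tuples; ties pop smaller subsets
    frontier: list[tuple[float, tuple[int, ...]]] = [(0.0, ())]
    visited: set[tuple[int, ...]] = {()}
    stale = 0
    evaluated = 0
    while frontier and stale < max_stale:
        _, subset = heapq.heappop(frontier)
        improved = False
        for j in range(m):
            if j in subset:
                continue
            child = tuple(sorted(subset + (j,)))
            if child in visited:
                continue
            visited.add(child)
            merit = cfs_merit(child, su_class, su_pair)
            evaluated += 1
            heapq.heappush(frontier, (-merit, child))
            if merit > best_merit + 1e-12:
                best_merit = merit
                best_subset = child
                improved = True
        stale = 0 if improved else stale + 1
    return CFSSubset(
        gene_ids=[ids[j] for j in best_subset],
        merit=best_merit,
        search_log=evaluated,
    )


def vote_across_folds(per_fold_lists: list[list[str]], k: int = 10) -> list[str]:
    """Genes by descending vote count over the folds' top lists.

    Ties break first by mean within-fold rank (lower is better), then by
    first-appearance order across the fold lists.
    """
    if not per_fold_lists:
        raise ValueError("need at least one fold list")
    votes: Counter[str] = Counter()
    ranks: dict[str, list[int]] = {}
    first_seen: dict[str, int] = {}
    counter = 0
    for fold in per_fold_lists:
        for rank, gene in enumerate(fold):
            votes[gene] += 1
            ranks.setdefault(gene, []).append(rank)
            if gene not in first_seen:
                first_seen[gene] = counter
                counter += 1
    ordered = sorted(
        votes,
        key=lambda g: (-votes[g], float(np.mean(ranks[g])), first_seen[g]),
    )
    return ordered[:k]


def select_genes_for_model(
    gene_codes: np.ndarray,
    labels: np.ndarray,
    gene_ids: list[str],
    method: str = "ig",
    n_top: int = 10,
    max_stale: int = 5,
) -> list[str]:
    """The gene list a predictive model is trained on, under either policy.

    IG takes the top ``n_top`` ranked genes. CFS takes its selected subset;
    when that subset is larger than ``n_top`` it is truncated by greedy
    forward selection under the CFS merit itself (so the kept genes stay
    mutually non-redundant — an IG-rank truncation would reintroduce exactly
    the redundancy the policy removed), and when smaller it is padded by IG
    rank. The model therefore always sees ``n_top`` genes when enough exist.
    """
    ranking = information_gain(gene_codes, labels, gene_ids)
    if method == "ig":
        return top_k(ranking, min(n_top, len(gene_ids)))
    if method != "cfs":
        raise ValueError(f"unknown selection method {method!r}")
    codes = np.asarray(gene_codes)
    ids = list(gene_ids)
    subset = cfs_select(codes, labels, ids, max_stale=max_stale)
    chosen = list(subset.gene_ids)
    by_ig = {g: r for r, g in enumerate(ranking.ordered_ids)}
    if len(chosen) > n_top:
        su_class = np.array(
            [symmetric_uncertainty(codes[:, j], np.asarray(labels)) for j in range(len(ids))]
        )
        su_pair = _pairwise_su(codes)
        pool = sorted((ids.index(g) for g in chosen), key=lambda j: (by_ig[ids[j]], j))
        kept: tuple[int, ...] = ()
        while len(kept) < n_top:
            best_j, best_merit = None, -np.inf
            for j in pool:
                if j in kept:
                    continue
                merit = cfs_merit(tuple(sorted(kept + (j,))), su_class, su_pair)
                if merit > best_merit + 1e-12:
                    best_j, best_merit = j, merit
            kept = tuple(sorted(kept + (best_j,)))
        chosen = [ids[j] for j in sorted(kept, key=lambda j: (by_ig[ids[j]], j))]
    elif len(chosen) < n_top:
        pad = [g for g in ranking.ordered_ids if g not in chosen]
        chosen = chosen + pad[: n_top - len(chosen)]
    return chosen
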