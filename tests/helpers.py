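"""Independent brute-force oracles the test suite checks the implementation against."""

from __future__ import annotations

import itertools
import math

import numpy as np


def enum_pmedian(D: np.ndarray, K: int) -> float:
    """Optimal p-median objective by exhaustive enumeration of median subsets."""
    n = D.shape[0]
    best = math.inf
    for subset in itertools.combinations(range(n), K):
        cost = D[:, list(subset)].min(axis=1).sum()
        best = min(best, cost)
    return best


def enum_pmedian_optima(D: np.ndarray, K: int, tol: float = 1e-9):
    """All optimal (median subset, nearest assignment) pairs."""
    n = D.shape[0]
    best = enum_pmedian(D, K)
    optima = []
    for subset in itertools.combinations(range(n), K):
        sub = D[:, list(subset)]
        cost = sub.min(axis=1).sum()
        if cost <= best + tol:
            assign = np.array(subset)[np.argmin(sub, axis=1)]
            optima.append((subset, assign))
    return best, optima


def enum_consensus(D1: np.ndarray, D2: np.ndarray, K: int, cap: float):
    """Optimal constrained objective by enumerating medians AND assignments.

    Feasible assignments must keep the D2 cost within ``cap``. Only viable
    for tiny instances (K^n assignment vectors per median subset).
    """
    n = D1.shape[0]
    best = math.inf
    best_assign = None
    for subset in itertools.combinations(range(n), K):
        for choice in itertools.product(range(K), repeat=n):
            assign = np.array([subset[c] for c in choice])
            if any(assign[m] != m for m in subset):
                continue
            d2cost = D2[np.arange(n), assign].sum()
            if d2cost > cap + 1e-9:
                continue
            d1cost = D1[np.arange(n), assign].sum()
            if d1cost < best - 1e-12:
                best = d1cost
                best_assign = assign
    return best, best_assign


def contingency_information_gain(codes: np.ndarray, labels: np.ndarray) -> float:
    """IG from explicit joint/marginal frequencies over the contingency table."""
    n = len(labels)
    ig = 0.0
    for c in set(labels.tolist()):
        pc = (labels == c).sum() / n
        if pc > 0:
            ig -= pc * math.log2(pc)
    for a in set(codes.tolist()):
        pa = (codes == a).sum() / n
        h = 0.0
        for c in set(labels.tolist()):
            pca = ((codes == a) & (labels == c)).sum() / n
            if pca > 0:
                h -= (pca / pa) * math.log2(pca / pa)
        ig -= pa * h
    return ig


def entropy_of(values: np.ndarray) -> float:
    n = len(values)
    h = 0.0
    for v in set(values.tolist()):
        p = (values == v).sum() / n
        if p > 0:
            h -= p * math.log2(p)
    return h


def su_oracle(x: np.ndarray, y: np.ndarray) -> float:
    hx, hy = entropy_of(x), entropy_of(y)
    if hx + hy == 0:
        return 0.0
    return 2.0 * contingency_information_gain(x, y) / (hx + hy)


def cfs_merit_oracle(codes: np.ndarray, labels: np.ndarray, subset: tuple[int, ...]) -> float:
    g = len(subset)
    if g == 0:
        return 0.0
    r_bf = np.mean([su_oracle(codes[:, j], labels) for j in subset])
    if g == 1:
        return float(r_bf)
    r_ff = np.mean(
        [su_oracle(codes[:, a], codes[:, b]) for a, b in itertools.combinations(subset, 2)]
    )
    return float(g * r_bf / math.sqrt(g + g * (g - 1) * r_ff))


def best_subset_by_powerset(codes: np.ndarray, labels: np.ndarray) -> tuple[tuple, float]:
    m = codes.shape[1]
    best, best_s = -1.0, ()
    for r in range(1, m + 1):
        for subset in itertools.combinations(range(m), r):
            merit = cfs_merit_oracle(codes, labels, subset)
            if merit > best + 1e-12:
                best, best_s = merit, subset
    return best_s, best


def bn_full_joint_posteriors(model, evidence):
    """Drug posteriors by brute-force summation over the full joint distribution.

    Enumerates every (cluster, drug-state vector) configuration consistent
    with the observed gene evidence and marginalises per drug.
    """
    levels = (-1, 0, 1)
    K = model.K
    n_drugs = len(model.drug_ids)
    idx = {v: i for i, v in enumerate(levels)}

    def p_cluster_and_evidence(k):
        if model.direction == "genes_to_cluster":
            cfg = tuple(int(v) for v in evidence)
            post = model.cluster_given_genes.get(cfg)
            if post is None:
                post = np.full(K, 1.0 / K)
            p = post[k]
            for g, v in enumerate(evidence):
                p *= model.gene_marginals[g][idx[int(v)]]
            return p
        p = model.cluster_prior[k]
        for g, v in enumerate(evidence):
            p *= model.gene_given_cluster[g][idx[int(v)], k]
        return p

    drug_post = np.zeros((n_drugs, 3))
    total = 0.0
    for k in range(K):
        base = p_cluster_and_evidence(k)
        for states in itertools.product(levels, repeat=n_drugs):
            p = base
            for d, s in enumerate(states):
                p *= model.drug_given_cluster[d][idx[s], k]
            total += p
            for d, s in enumerate(states):
                drug_post[d, idx[s]] += p
    return drug_post / total


def pareto_oracle(points):
    """Dominance flags computed with an independently written scan."""
    flags = []
    for i in range(len(points)):
        ok = True
        for j in range(len(points)):
            if i == j:
                continue
            ge = points[j][0] >= points[i][0] and points[j][1] >= points[i][1]
            gt = points[j][0] > points[i][0] or points[j][1] > points[i][1]
            if ge and gt:
                ok = False
                break
        flags.append(ok)
    return flags
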