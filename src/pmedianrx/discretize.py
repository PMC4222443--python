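"""Ternary coding of expression and drug-activity values.

Genes become {down, normo, up} through a double filter: a one-sample t-test
on the per-gene log2 ratios with Benjamini-Hochberg FDR control identifies
differentially expressed genes, and the smallest absolute mean log2 fold
change among them fixes the ratio-scale cut-off beta (e.g. beta = 0.86 gives
log2 thresholds of +/-0.2175). Drugs become {sensitive, intermediate,
resistant} per compound: log10(GI50) at least ``sd_factor`` (default 0.8)
standard deviations above the mean is resistant, at least that far below is
sensitive, everything within the band is intermediate.

Codes are stored as int8 with the convention -1 = down/sensitive,
0 = normo/intermediate, +1 = up/resistant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DOWN, NORMO, UP = -1, 0, 1
SENSITIVE, INTERMEDIATE, RESISTANT = -1, 0, 1
LEVELS = (-1, 0, 1)


@dataclass
class DiscretePanel:
    """Ternary-coded gene and drug matrices plus the thresholds that made them."""

    gene_codes: np.ndarray
    drug_codes: np.ndarray
    beta: float
    sd_factor: float

    def __post_init__(self) -> None:
        if not 0 < self.beta:
            raise ValueError("beta must be positive")
        if self.sd_factor <= 0:
            raise ValueError("sd_factor must be positive")
        for codes in (self.gene_codes, self.drug_codes):
            if not np.isin(codes, LEVELS).all():
                raise ValueError("codes must be in {-1, 0, 1}")


def fdp_exceedance_reject(
    pvals: np.ndarray, gamma: float = 0.05, confidence: float = 0.99
) -> np.ndarray:
    """Lehmann-Romano step-down control of the false-discovery proportion.

    Rejects a set of hypotheses such that P(FDP > ``gamma``) <= 1 - ``confidence``,
    i.e. the rate of false significant calls stays below ``gamma`` with the
    stated confidence — a stronger guarantee than mean-FDR control, which
    tolerates borderline false positives in any single analysis. Critical
    values are c_i = (floor(gamma i) + 1) alpha / (m + floor(gamma i) + 1 - i)
    for the i-th smallest p-value; rejection stops at the first exceedance.
    Returns a boolean mask. ``gamma`` >= 1 degenerates to rejecting everything
    (any proportion of false calls is tolerated).
    """
    pvals = np.asarray(pvals, dtype=float)
    m = pvals.size
    if gamma >= 1.0:
        return np.ones(m, dtype=bool)
    alpha = 1.0 - confidence
    order = np.argsort(pvals, kind="stable")
    i = np.arange(1, m + 1)
    crit = (np.floor(gamma * i) + 1) * alpha / (m + np.floor(gamma * i) + 1 - i)
    passed = pvals[order] <= crit
    n_reject = int(np.argmin(passed)) if not passed.all() else m
    mask = np.zeros(m, dtype=bool)
    mask[order[:n_reject]] = True
    return mask


def derive_beta(
    gene_matrix: np.ndarray, fdr_level: float = 0.05, confidence: float = 0.99
) -> float:
    """Ratio-scale cut-off beta from the double filter on per-gene mean log2 fold changes.

    Each gene's log2 ratios are tested against zero (two-sided one-sample
    t-test); the multiple-testing step keeps the proportion of false
    significant genes below ``fdr_level`` with probability ``confidence``
    (Lehmann-Romano step-down). beta is 2 to the minus smallest absolute mean
    log2 fold change among the significant genes, so that every significant
    gene lies beyond the resulting +/-(-log2 beta) thresholds. Exceedance
    rather than mean-FDR control matters here: the cut-off is a minimum over
    the significant set, so even a handful of false positives near zero fold
    change would collapse it.
    """
    M = np.asarray(gene_matrix, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("need a cells x genes matrix with at least 2 genes")
    if np.isnan(M).any():
        raise ValueError("matrix contains missing values; impute first")
    means = M.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.ttest_1samp(M, popmean=0.0, axis=0)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    reject = fdp_exceedance_reject(pvals, fdr_level, confidence)
    if not reject.any():
        raise ValueError(
            "no significant genes at the requested FDR level; pass an explicit beta"
        )
    cut = float(np.abs(means[reject]).min())
    beta = float(2.0 ** (-cut))
    return min(beta, 1.0 - 1e-12)


def log2_thresholds(beta: float) -> tuple[float, float]:
    """(lower, upper) log2 fold-change thresholds for a ratio-scale cut-off beta.

    Values above the upper threshold are up-regulated, below the lower are
    down-regulated; the closed interval between them is normo-regulated.
    """
    if not 0 < beta < 1:
        raise ValueError(f"beta must lie in (0, 1), got {beta}")
    upper = -float(np.log2(beta))
    return -upper, upper


def discretize_genes(gene_matrix: np.ndarray, beta: float) -> np.ndarray:
    """Elementwise ternary coding of log2 ratios by the beta thresholds.

    Boundary values exactly at a threshold code as normo (closed interval).
    """
    lower, upper = log2_thresholds(beta)
    M = np.asarray(gene_matrix, dtype=float)
    codes = np.zeros(M.shape, dtype=np.int8)
    codes[M > upper] = UP
    codes[M < lower] = DOWN
    return codes


def drug_thresholds(
    drug_matrix: np.ndarray, sd_factor: float = 0.8
) -> tuple[np.ndarray, np.ndarray]:
    """Per-drug mean and sample standard deviation (the 0.8-SD rule's parameters)."""
    M = np.asarray(drug_matrix, dtype=float)
    if np.isnan(M).any():
        raise ValueError("matrix contains missing values; impute first")
    if sd_factor <= 0:
        raise ValueError("sd_factor must be positive")
    return M.mean(axis=0), M.std(axis=0, ddof=1)


def discretize_drugs(
    drug_matrix: np.ndarray,
    sd_factor: float = 0.8,
    stats_: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Ternary sensitivity coding of log10(GI50) values per drug.

    A value at least ``sd_factor`` SDs above the drug's mean is resistant
    (boundary included: "at least"), at least that far below is sensitive,
    otherwise intermediate. A zero-SD drug codes entirely intermediate.
    ``stats_`` supplies externally fitted (mean, sd) — e.g. the training
    fold's — so held-out cells can be coded without leakage.
    """
    M = np.asarray(drug_matrix, dtype=float)
    mean, sd = stats_ if stats_ is not None else drug_thresholds(M, sd_factor)
    codes = np.zeros(M.shape, dtype=np.int8)
    # a numerically-zero SD (constant drug up to roundoff) codes all intermediate
    pos = sd > 1e-12 * (np.abs(mean) + 1.0)
    hi = mean + sd_factor * sd
    lo = mean - sd_factor * sd
    codes[(M >= hi) & pos[None, :]] = RESISTANT
    codes[(M <= lo) & pos[None, :]] = SENSITIVE
    return codes
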