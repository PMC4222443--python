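"""Exact p-Median and Consensus p-Median clustering via integer programming.

The p-Median model picks K data points (geometric medians) and assigns every
point to one of them so that the total assigned dissimilarity is minimal:

    min  sum_ij z_ij d(x_i, x_j)
    s.t. sum_j z_ij = 1          (each point in exactly one cluster)
         sum_j z_jj = K          (exactly K medians)
         z_ij <= z_jj            (assign only to medians)
         z_ij binary

The Consensus variant runs in two feature spaces: step 1 solves the plain
model under d2, step 2 re-optimises the total cost under d1 subject to an
epsilon-constraint budgeting the d2 cost at mu times the step-1 optimum
(mu >= 1; mu = 1 reproduces the step-1 assignment when it is unique). The
mu-sweep raises mu on a fixed grid until the budget constraint goes slack
and the assignment stabilises, yielding a trade-off curve between the two
spaces.

Both models are solved to proven optimality with HiGHS branch-and-cut
(absolute MIP gap 0, deterministic). For the unconstrained model only the
median indicator variables z_jj need to be integer: with the medians fixed,
the assignment polytope is integral, which roughly halves solve times at
|Omega| = 60. The budget constraint breaks that property, so the consensus
solve verifies integrality of the relaxed solution and falls back to a fully
integer model when needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .distance import DistanceMatrix

logger = logging.getLogger(__name__)

#: relative slack when checking the d2 budget constraint for feasibility
FEASIBILITY_RTOL = 1e-6


class SolverError(RuntimeError):
    """The MILP backend failed to return a proven optimum."""


@dataclass
class ClusteringSolution:
    """A hard clustering: K medians and an assignment of every cell to one.

    ``assignment[i]`` is the index of the median cell line *i* is assigned to
    (every median is assigned to itself). ``objective_primary`` is the sum of
    assigned distances under the distance matrix the model optimised;
    ``objective_secondary`` carries the same sum under the other space's
    distances for consensus solutions.
    """

    medians: list[int]
    assignment: np.ndarray
    objective_primary: float
    K: int
    objective_secondary: float | None = None
    mu: float | None = None

    def __post_init__(self) -> None:
        self.medians = sorted(int(m) for m in self.medians)
        self.assignment = np.asarray(self.assignment, dtype=int)
        if len(set(self.medians)) != self.K:
            raise ValueError("need exactly K distinct medians")
        if not set(self.assignment).issubset(set(self.medians)):
            raise ValueError("assignment targets must be medians")
        for m in self.medians:
            if self.assignment[m] != m:
                raise ValueError("each median must be assigned to itself")

    @property
    def labels(self) -> np.ndarray:
        """Cluster index per cell, 0..K-1 in sorted-median order."""
        lookup = {m: k for k, m in enumerate(self.medians)}
        return np.array([lookup[a] for a in self.assignment], dtype=int)

    def cost_under(self, D: DistanceMatrix) -> float:
        """Total assigned distance of this clustering under another distance matrix."""
        return float(D.values[np.arange(len(self.assignment)), self.assignment].sum())


@dataclass
class ConsensusTrace:
    """The mu-sweep record: one consensus solution per visited mu."""

    step1: ClusteringSolution
    entries: list[tuple[float, ClusteringSolution]] = field(default_factory=list)
    mu_star: float | None = None

    @property
    def mus(self) -> list[float]:
        return [mu for mu, _ in self.entries]

    @property
    def solutions(self) -> list[ClusteringSolution]:
        return [sol for _, sol in self.entries]


def _pmedian_constraints(n: int):
    """Assignment, cardinality and linking constraints over flattened z (row-major)."""
    N = n * n
    A_assign = sparse.kron(sparse.eye(n), np.ones((1, n)), format="csr")
    diag = np.arange(n) * n + np.arange(n)
    A_card = sparse.csr_matrix((np.ones(n), (np.zeros(n), diag)), shape=(1, N))
    i_idx, j_idx = np.nonzero(~np.eye(n, dtype=bool))
    k = i_idx.size
    rows = np.repeat(np.arange(k), 2)
    cols = np.empty(2 * k, dtype=int)
    cols[0::2] = i_idx * n + j_idx
    cols[1::2] = j_idx * n + j_idx
    vals = np.tile([1.0, -1.0], k)
    A_link = sparse.csr_matrix((vals, (rows, cols)), shape=(k, N))
    return diag, A_assign, A_card, A_link


def _solve_milp(D1v: np.ndarray, K: int, budget: tuple[np.ndarray, float] | None,
                full_integrality: bool) -> np.ndarray:
    n = D1v.shape[0]
    diag, A_assign, A_card, A_link = _pmedian_constraints(n)
    constraints = [
        LinearConstraint(A_assign, 1, 1),
        LinearConstraint(A_card, K, K),
        LinearConstraint(A_link, -np.inf, 0),
    ]
    if budget is not None:
        D2v, cap = budget
        constraints.append(
            LinearConstraint(sparse.csr_matrix(D2v.ravel()[None, :]), -np.inf, cap)
        )
    integrality = np.ones(n * n) if full_integrality else np.zeros(n * n)
    if not full_integrality:
        integrality[diag] = 1
    res = milp(
        D1v.ravel(),
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(0, 1),
        options={"mip_rel_gap": 0.0},
    )
    if res.status != 0:
        raise SolverError(f"MILP solve failed: status={res.status} ({res.message})")
    return res.x.reshape(n, n)


def _is_integral(Z: np.ndarray, tol: float = 1e-6) -> bool:
    return bool(np.abs(Z - np.round(Z)).max() <= tol)


def _extract(Z: np.ndarray, K: int) -> tuple[list[int], np.ndarray]:
    medians = sorted(np.flatnonzero(np.round(np.diag(Z)) == 1).tolist())
    if len(medians) != K:
        raise SolverError(f"solver returned {len(medians)} medians, expected {K}")
    assignment = np.argmax(np.round(Z), axis=1)
    return medians, np.asarray(assignment, dtype=int)


def _nearest_assignment(D: np.ndarray, medians: list[int]) -> np.ndarray:
    """Assign every point to its nearest median; distance ties go to the lowest index."""
    med = np.array(medians)  # sorted, so argmin picks the lowest index on ties
    sub = D[:, med]
    assignment = med[np.argmin(sub, axis=1)]
    assignment[med] = med  # self-distance 0 is always minimal; keep medians self-assigned
    return assignment


def solve_pmedian(D: DistanceMatrix, K: int) -> ClusteringSolution:
    """Globally optimal p-Median clustering of the panel under ``D``.

    Raises a ``ValueError`` for infeasible K and :class:`SolverError` if the
    backend does not prove optimality.
    """
    n = D.n
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, {n}], got {K}")
    Z = _solve_milp(D.values, K, budget=None, full_integrality=False)
    if not _is_integral(Z):  # pragma: no cover - integral by LP structure
        Z = _solve_milp(D.values, K, budget=None, full_integrality=True)
    medians, _ = _extract(Z, K)
    assignment = _nearest_assignment(D.values, medians)
    objective = float(D.values[np.arange(n), assignment].sum())
    return ClusteringSolution(
        medians=medians, assignment=assignment, objective_primary=objective, K=K
    )


def solve_consensus(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    K: int,
    mu: float,
    z_star: ClusteringSolution,
) -> ClusteringSolution:
    """Minimise the d1 cost subject to the d2 cost staying within mu x step-1 optimum.

    ``z_star`` must be an optimal plain p-Median solution under ``D2``; its
    d2 cost defines the budget base. ``mu`` < 1 is rejected: the step-1 cost
    is already the d2 optimum, so no feasible solution exists below it.
    """
    n = D1.n
    if D2.n != n:
        raise ValueError("distance matrices must cover the same panel")
    if mu < 1.0:
        raise ValueError(f"mu must be >= 1.0 (no feasible solution exists below); got {mu}")
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, {n}], got {K}")
    base = z_star.cost_under(D2)
    cap = mu * base * (1.0 + FEASIBILITY_RTOL) + 1e-12
    Z = _solve_milp(D1.values, K, budget=(D2.values, cap), full_integrality=False)
    if not _is_integral(Z):
        Z = _solve_milp(D1.values, K, budget=(D2.values, cap), full_integrality=True)
    medians, assignment = _extract(Z, K)
    idx = np.arange(n)
    return ClusteringSolution(
        medians=medians,
        assignment=assignment,
        objective_primary=float(D1.values[idx, assignment].sum()),
        objective_secondary=float(D2.values[idx, assignment].sum()),
        K=K,
        mu=mu,
    )


def consensus_sweep(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    K: int,
    mu_start: float = 1.0,
    mu_step: float = 0.1,
    max_mu: float = 3.0,
) -> ConsensusTrace:
    """Solve the consensus problem over an increasing mu grid until it stabilises.

    Step 1 solves the plain p-Median under ``D2`` once. The sweep then visits
    mu = mu_start, mu_start + mu_step, ... and stops at mu* — the first mu at
    which the budget constraint is redundant, i.e. the unconstrained d1
    optimum already fits the d2 budget, so larger mu cannot change the
    solution. If ``max_mu`` is reached first the trace is returned with
    ``mu_star`` unset and a warning is logged.
    """
    if mu_step <= 0:
        raise ValueError("mu_step must be positive")
    if mu_start < 1.0:
        raise ValueError("mu_start must be >= 1.0")
    step1 = solve_pmedian(D2, K)
    base = step1.cost_under(D2)
    unconstrained = solve_pmedian(D1, K)
    unconstrained_d2 = unconstrained.cost_under(D2)
    trace = ConsensusTrace(step1=step1)
    mu = mu_start
    while mu <= max_mu + 1e-12:
        if unconstrained_d2 <= mu * base * (1.0 + FEASIBILITY_RTOL):
            # budget redundant: the unconstrained optimum is the consensus optimum
            sol = ClusteringSolution(
                medians=unconstrained.medians,
                assignment=unconstrained.assignment,
                objective_primary=unconstrained.objective_primary,
                objective_secondary=unconstrained_d2,
                K=K,
                mu=mu,
            )
            trace.entries.append((mu, sol))
            trace.mu_star = mu
            return trace
        sol = solve_consensus(D1, D2, K, mu, step1)
        trace.entries.append((mu, sol))
        mu = round(mu + mu_step, 12)
    logger.warning("mu sweep reached max_mu=%.3g without convergence", max_mu)
    return trace
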