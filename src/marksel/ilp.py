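"""Exact marker-set optimization by mixed-integer linear programming.

Two models are exposed: minimize the marker count subject to every father
pair reaching power h (a weighted set-multicover), and minimize the adjacency
objective g(x) = x^T Q x under the same constraints, linearized with binary
products y_kl = x_k x_l and the standard linking rows

    x_k + x_l - y_kl <= 1,   x_k - y_kl >= 0,   x_l - y_kl >= 0.

Both run on the HiGHS branch-and-bound solver behind ``scipy.optimize.milp``.
The backend contract is: binary variables, linear constraints, and either a
proof of optimality or an explicit status/gap — any solver meeting it could
be slotted in here.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .discrimination import (
    FEAS_TOL,
    AdjacencyMatrix,
    MarkerSolution,
    PairPowerTensor,
    make_solution,
    objective_g,
)

logger = logging.getLogger(__name__)

BACKEND = "scipy-highs"

__all__ = [
    "SolveReport",
    "solve_min_count",
    "solve_min_adjacency",
    "drop_infeasible_pairs",
]


@dataclass
class SolveReport:
    status: str  # optimal | feasible-not-proven | infeasible | timeout
    objective: float | None
    solution: MarkerSolution | None
    wall_time: float
    backend: str = BACKEND
    gap: float | None = None
    infeasible_pairs: list[tuple[str, str, float]] | None = None

    def __post_init__(self) -> None:
        if self.status == "optimal" and self.gap is None:
            self.gap = 0.0


def drop_infeasible_pairs(
    P: PairPowerTensor, h: float
) -> tuple[PairPowerTensor, list[tuple[str, str, float]]]:
    """Remove father pairs whose total available power is below h.

    Such pairs (clones, duplicated accessions) make every model infeasible;
    they are returned for reporting, and downstream solutions are feasible
    only with respect to the reduced tensor.
    """
    totals = P.total_power()
    mask = totals >= h - FEAS_TOL
    dropped = [
        (
            P.individual_ids[P.pairs[p, 0]],
            P.individual_ids[P.pairs[p, 1]],
            float(totals[p]),
        )
        for p in np.flatnonzero(~mask)
    ]
    if not dropped:
        return P, []
    logger.info("dropping %d pair(s) with insufficient total power", len(dropped))
    return P.keep_pairs(mask), dropped


def _pair_constraint_matrix(P: PairPowerTensor, h: float) -> tuple[sp.csr_matrix, float]:
    """Pair-power rows, rescaled to integers when h is integral.

    With integer h the stored powers are exactly {1, h, 1/h}; multiplying the
    rows by h gives integer coefficients {h, h^2, 1} and right-hand side h^2,
    sidestepping solver float tolerances on the 1/h entries.
    """
    A = P.matrix.tocsr().astype(float)
    if float(h).is_integer() and h >= 1:
        data = A.data.copy()
        hi = data == float(h)
        one = data == 1.0
        data[hi] = h * h
        data[one] = h
        data[~(hi | one)] = 1.0  # the 1/h entries
        A = sp.csr_matrix((data, A.indices, A.indptr), shape=A.shape)
        return A, float(h * h)
    return A, float(h)


def _weakest_pairs(P: PairPowerTensor, k: int = 5) -> list[tuple[str, str, float]]:
    totals = P.total_power()
    order = np.argsort(totals)[:k]
    return [
        (
            P.individual_ids[P.pairs[p, 0]],
            P.individual_ids[P.pairs[p, 1]],
            float(totals[p]),
        )
        for p in order
    ]


def _report_from_milp(
    res,
    P: PairPowerTensor,
    Q: AdjacencyMatrix | None,
    h: float,
    n_markers: int,
    t0: float,
) -> SolveReport:
    wall = time.perf_counter() - t0
    if res.status == 2:
        return SolveReport(
            status="infeasible",
            objective=None,
            solution=None,
            wall_time=wall,
            infeasible_pairs=_weakest_pairs(P),
        )
    if res.x is None:
        return SolveReport(status="timeout", objective=None, solution=None, wall_time=wall)
    x = np.round(res.x[:n_markers]).astype(int)
    selected = [P.marker_ids[k] for k in np.flatnonzero(x)]
    solution = make_solution(selected, P, Q, h)
    status = "optimal" if res.status == 0 else "feasible-not-proven"
    gap = float(getattr(res, "mip_gap", 0.0) or 0.0) if status != "optimal" else 0.0
    return SolveReport(
        status=status,
        objective=float(res.fun),
        solution=solution,
        wall_time=wall,
        gap=gap,
    )


def solve_min_count(
    P: PairPowerTensor, h: float, time_limit: float = 3600.0
) -> SolveReport:
    """Minimum-cardinality marker subset giving every pair at least h power."""
    t0 = time.perf_counter()
    totals = P.total_power()
    if np.any(totals < h - FEAS_TOL):
        return SolveReport(
            status="infeasible",
            objective=None,
            solution=None,
            wall_time=time.perf_counter() - t0,
            infeasible_pairs=_weakest_pairs(P),
        )
    m = len(P.marker_ids)
    A, rhs = _pair_constraint_matrix(P, h)
    res = milp(
        c=np.ones(m),
        constraints=[LinearConstraint(A, lb=rhs, ub=np.inf)],
        integrality=np.ones(m),
        bounds=Bounds(0, 1),
        options={"time_limit": time_limit},
    )
    report = _report_from_milp(res, P, None, h, m, t0)
    if report.solution is not None and not report.solution.feasible:
        raise RuntimeError("solver returned an infeasible selection")  # pragma: no cover
    return report


def solve_min_adjacency(
    P: PairPowerTensor,
    Q: AdjacencyMatrix,
    h: float,
    time_limit: float = 3600.0,
    lexico_min_count: bool = False,
) -> SolveReport:
    """Feasible marker subset minimizing the adjacency objective x^T Q x.

    The quadratic objective is linearized with one binary y_kl per marker
    pair (k > l, q_kl > 0). Because q >= 0 and the objective is minimized,
    the linking rows force y_kl = x_k x_l at optimality; this is re-checked
    on the returned assignment, and the reported g is recomputed from Q.

    When ``lexico_min_count`` is set, a second solve fixes g at its optimum
    and minimizes the marker count among g-optimal subsets.
    """
    t0 = time.perf_counter()
    totals = P.total_power()
    if np.any(totals < h - FEAS_TOL):
        return SolveReport(
            status="infeasible",
            objective=None,
            solution=None,
            wall_time=time.perf_counter() - t0,
            infeasible_pairs=_weakest_pairs(P),
        )
    m = len(P.marker_ids)
    if Q.marker_ids != P.marker_ids:
        raise ValueError("adjacency matrix and power tensor index different markers")

    # y variables only where q_kl > 0 (k > l)
    ks, ls, qs = [], [], []
    for k in range(m):
        if k:
            w = Q.weights_between(k, np.arange(k))
            nz = np.flatnonzero(w > 0)
            ks.extend([k] * nz.size)
            ls.extend(nz.tolist())
            qs.extend(w[nz].tolist())
    n_y = len(qs)
    n_var = m + n_y

    A_pair, rhs = _pair_constraint_matrix(P, h)
    A_pair = sp.hstack([A_pair, sp.csr_matrix((A_pair.shape[0], n_y))], format="csr")

    rows, cols, vals, lb, ub = [], [], [], [], []
    r = 0
    for idx, (k, l) in enumerate(zip(ks, ls)):
        y = m + idx
        # x_k + x_l - y <= 1
        rows += [r, r, r]
        cols += [k, l, y]
        vals += [1.0, 1.0, -1.0]
        lb.append(-np.inf)
        ub.append(1.0)
        r += 1
        # x_k - y >= 0
        rows += [r, r]
        cols += [k, y]
        vals += [1.0, -1.0]
        lb.append(0.0)
        ub.append(np.inf)
        r += 1
        # x_l - y >= 0
        rows += [r, r]
        cols += [l, y]
        vals += [1.0, -1.0]
        lb.append(0.0)
        ub.append(np.inf)
        r += 1
    A_link = sp.csr_matrix((vals, (rows, cols)), shape=(r, n_var))

    c = np.concatenate([np.zeros(m), np.asarray(qs)])
    constraints = [
        LinearConstraint(A_pair, lb=rhs, ub=np.inf),
        LinearConstraint(A_link, lb=np.array(lb), ub=np.array(ub)),
    ]
    res = milp(
        c=c,
        constraints=constraints,
        integrality=np.ones(n_var),
        bounds=Bounds(0, 1),
        options={"time_limit": time_limit},
    )
    report = _report_from_milp(res, P, Q, h, m, t0)
    if report.solution is None:
        return report

    # linearization soundness: y_kl must equal x_k * x_l in the assignment
    x = np.round(res.x[:m]).astype(int)
    y = np.round(res.x[m:]).astype(int)
    expect = x[np.asarray(ks, dtype=int)] * x[np.asarray(ls, dtype=int)]
    if n_y and not np.array_equal(y, expect):
        raise RuntimeError("linearization violated: y_kl != x_k * x_l")
    g_check = objective_g(report.solution.selected, Q)
    if abs(g_check - float(res.fun)) > 1e-6 * max(1.0, abs(g_check)):
        raise RuntimeError(
            f"backend objective {res.fun} disagrees with recomputed g {g_check}"
        )

    if lexico_min_count and report.status == "optimal":
        g_star = float(res.fun)
        cap = LinearConstraint(
            sp.csr_matrix((np.asarray(qs), (np.zeros(n_y, int), np.arange(m, n_var))),
                          shape=(1, n_var)) if n_y else sp.csr_matrix((1, n_var)),
            lb=-np.inf,
            ub=g_star + 1e-9,
        )
        c2 = np.concatenate([np.ones(m), np.zeros(n_y)])
        res2 = milp(
            c=c2,
            constraints=constraints + [cap],
            integrality=np.ones(n_var),
            bounds=Bounds(0, 1),
            options={"time_limit": time_limit},
        )
        if res2.status == 0 and res2.x is not None:
            report = _report_from_milp(res2, P, Q, h, m, t0)
            report.objective = g_star
    return report
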