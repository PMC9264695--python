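"""Greedy marker selection and 1/2-flip neighborhood search.

The greedy constructor maintains a residual matrix r_ij (initialised at h)
holding the power each father pair still needs. At every iteration the
marker maximising

    e_k(r) = z_k(r) / denom(k),   z_k(r) = sum_ij min(p_ijk, r_ij)

is added, where denom(k) = 1 + the summed adjacency weights q > 1 between k
and already-selected markers — so candidates clustered near the current
selection on a chromosome are discounted, and the first pick is purely
power-driven. Residuals are then decremented and the loop stops at r = 0.

The neighborhood search polishes a feasible start: a 1-flip pass drops any
marker whose removal keeps all pairs at h, and a 2-flip pass swaps a selected
marker s for a non-selected t, accepting a swap when it stays feasible and
strictly lowers g — or ties g while raising the depth (median pair power), a
tie-break that staves off early convergence. Swap candidates for each s are
the top v-fraction of non-selected markers ranked by |genotypic correlation|
with s, since only markers carrying similar information can cover for s.
All tie-breaks are by lowest marker index, so the whole pipeline is
deterministic.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .discrimination import (
    FEAS_TOL,
    AdjacencyMatrix,
    MarkerSolution,
    PairPowerTensor,
    build_adjacency,
    build_pair_power,
    check_feasible,
    make_solution,
)
from .ilp import SolveReport, drop_infeasible_pairs, solve_min_adjacency, solve_min_count
from .panel import GenotypePanel, MarkerMap

logger = logging.getLogger(__name__)

METHODS = ("ilp-count", "ilp-quad", "greedy", "greedy+ns")

__all__ = [
    "greedy_select",
    "genotype_correlation",
    "neighborhood_search",
    "optimize",
    "METHODS",
]


def _adjacency_discount(Q: AdjacencyMatrix | None, k: int, selected: list[int]) -> float:
    """1 + summed same-chromosome weights (q > 1) between k and the selection."""
    if Q is None or not selected:
        return 1.0
    w = Q.weights_between(k, np.array(selected, dtype=int))
    return 1.0 + float(w[w > 1.0].sum())


def greedy_select(
    P: PairPowerTensor, Q: AdjacencyMatrix | None, h: float
) -> MarkerSolution:
    """Construct a feasible marker set by iterative best-gain selection.

    Requires infeasible pairs to have been dropped; raises if some residual
    cannot be covered by any remaining marker.
    """
    m = len(P.marker_ids)
    n_pairs = P.n_pairs
    r = np.full(n_pairs, float(h))
    if n_pairs == 0:
        r = np.zeros(0)

    Pc = P.matrix.tocsc()
    col_of_entry = np.repeat(np.arange(m), np.diff(Pc.indptr))

    selected: list[int] = []
    denom = np.ones(m)
    selectable = np.ones(m, dtype=bool)

    while r.size and r.max() > FEAS_TOL:
        gains = np.minimum(Pc.data, r[Pc.indices])
        z = np.bincount(col_of_entry, weights=gains, minlength=m)
        z[~selectable] = 0.0
        if z.max() <= FEAS_TOL:
            stuck = np.flatnonzero(r > FEAS_TOL)
            names = [
                (P.individual_ids[P.pairs[p, 0]], P.individual_ids[P.pairs[p, 1]])
                for p in stuck[:10]
            ]
            raise RuntimeError(
                f"uncoverable residual for {stuck.size} pair(s), e.g. {names}; "
                "drop infeasible pairs before running greedy"
            )
        e = np.where(z > FEAS_TOL, z / denom, 0.0)
        k = int(np.argmax(e))  # argmax takes the lowest index on ties
        col = Pc.getcol(k)
        rows = col.indices
        r[rows] -= np.minimum(col.data, r[rows])
        np.clip(r, 0.0, None, out=r)
        if Q is not None:
            w = Q.weights_between(k, np.arange(m))
            denom += np.where(w > 1.0, w, 0.0)
        selected.append(k)
        selectable[k] = False
        logger.debug("greedy: picked %s, max residual %.4g", P.marker_ids[k], r.max() if r.size else 0)

    ids = [P.marker_ids[k] for k in sorted(selected)]
    return make_solution(ids, P, Q, h)


def genotype_correlation(panel: GenotypePanel) -> np.ndarray:
    """|Pearson correlation| between marker dosage vectors.

    Pairwise-complete over non-missing individuals; correlations undefined
    for zero-variance columns are set to 0.
    """
    if panel.n_markers < 2:
        raise ValueError("need at least two markers")
    corr = pd.DataFrame(panel.dosages).corr(min_periods=1).to_numpy()
    corr = np.abs(np.nan_to_num(corr, nan=0.0))
    return corr


def _flip_candidates(
    s: int, non_selected: np.ndarray, corr: np.ndarray, v: float
) -> np.ndarray:
    """Top ceil(v * #non-selected) replacement markers for s, by |correlation|.

    At least one candidate is always examined; ranking ties break toward the
    lowest marker index.
    """
    if non_selected.size == 0:
        return non_selected
    n_cand = max(1, math.ceil(v * non_selected.size))
    order = np.lexsort((non_selected, -corr[s, non_selected]))
    return non_selected[order[:n_cand]]


def neighborhood_search(
    start: MarkerSolution,
    P: PairPowerTensor,
    Q: AdjacencyMatrix | None,
    h: float,
    v: float = 0.2,
    max_rounds: int = 50,
    corr: np.ndarray | None = None,
) -> MarkerSolution:
    """Improve a feasible solution with alternating 1-flip and 2-flip passes.

    ``corr`` is the marker-by-marker |genotypic correlation| matrix from
    ``genotype_correlation``; without it the 2-flip pass ranks candidates by
    index order only (v still limits how many are tried).
    """
    if not start.feasible:
        raise ValueError("neighborhood search requires a feasible starting solution")
    if not 0.0 <= v <= 1.0:
        raise ValueError("flip fraction v must be in [0, 1]")
    m = len(P.marker_ids)
    Pd = P.matrix.toarray()
    if corr is None:
        corr = np.zeros((m, m))

    sel = sorted(P.marker_indices(start.selected).tolist())
    S = Pd[:, sel].sum(axis=1) if sel else np.zeros(P.n_pairs)
    g_cur = Q.selection_g(np.array(sel)) if Q is not None else None
    depth_cur = float(np.median(S)) if P.n_pairs else 0.0

    for round_no in range(max_rounds):
        changed = False

        # 1-flip: drop redundant markers (f strictly decreases; g cannot grow)
        for s in list(sel):
            S_wo = S - Pd[:, s]
            if S_wo.size == 0 or S_wo.min() >= h - FEAS_TOL:
                sel.remove(s)
                S = S_wo
                if Q is not None:
                    g_cur = Q.selection_g(np.array(sel))
                depth_cur = float(np.median(S)) if S.size else 0.0
                changed = True

        # 2-flip: swap s -> t, first improvement per s
        non_sel = np.array([k for k in range(m) if k not in set(sel)], dtype=int)
        for s in list(sel):
            cands = _flip_candidates(s, non_sel, corr, v)
            if cands.size == 0:
                continue
            S_wo = S - Pd[:, s]
            trial = S_wo[:, None] + Pd[:, cands]
            feas = (
                trial.min(axis=0) >= h - FEAS_TOL
                if trial.size
                else np.ones(cands.size, dtype=bool)
            )
            rest = np.array([k for k in sel if k != s], dtype=int)
            for ci in np.flatnonzero(feas):
                t = int(cands[ci])
                if Q is not None:
                    g_new = g_cur - Q.weights_between(s, rest).sum() + Q.weights_between(t, rest).sum()
                else:
                    g_new = None
                d_new = float(np.median(trial[:, ci])) if trial.size else 0.0
                better_g = Q is not None and g_new < g_cur - 1e-12
                tie_g = Q is None or abs(g_new - g_cur) <= 1e-9 * max(1.0, g_cur)
                if better_g or (tie_g and d_new > depth_cur + 1e-12):
                    sel = sorted(rest.tolist() + [t])
                    S = S_wo + Pd[:, t]
                    if Q is not None:
                        g_cur = Q.selection_g(np.array(sel))
                    depth_cur = d_new
                    non_sel = np.array(
                        [k for k in range(m) if k not in set(sel)], dtype=int
                    )
                    changed = True
                    break

        logger.debug("ns round %d: f=%d g=%s depth=%.3f", round_no + 1, len(sel), g_cur, depth_cur)
        if not changed:
            break

    ids = [P.marker_ids[k] for k in sel]
    result = make_solution(ids, P, Q, h)
    assert result.feasible, "neighborhood search must preserve feasibility"
    return result


def optimize(
    panel: GenotypePanel,
    mmap: MarkerMap | None,
    h: float,
    method: str = "greedy+ns",
    v: float = 0.2,
    time_limit: float = 3600.0,
    max_rounds: int = 50,
    lexico_min_count: bool = False,
) -> tuple[MarkerSolution, SolveReport]:
    """Dispatch to the chosen optimizer and report metrics uniformly.

    Infeasible father pairs (total power < h over all markers) are dropped
    first and surfaced on the report.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if mmap is None and method == "ilp-quad":
        raise ValueError(f"method {method!r} requires a marker map")

    P = build_pair_power(panel, h)
    P, dropped = drop_infeasible_pairs(P, h)
    Q = build_adjacency(mmap, panel.marker_ids) if mmap is not None else None

    import time as _time

    if method == "ilp-count":
        report = solve_min_count(P, h, time_limit=time_limit)
    elif method == "ilp-quad":
        assert Q is not None
        report = solve_min_adjacency(
            P, Q, h, time_limit=time_limit, lexico_min_count=lexico_min_count
        )
    else:
        t0 = _time.perf_counter()
        solution = greedy_select(P, Q, h)
        if method == "greedy+ns":
            corr = genotype_correlation(panel) if panel.n_markers >= 2 else None
            solution = neighborhood_search(
                solution, P, Q, h, v=v, max_rounds=max_rounds, corr=corr
            )
        report = SolveReport(
            status="feasible-not-proven",
            objective=float(solution.g) if solution.g is not None else float(solution.f),
            solution=solution,
            wall_time=_time.perf_counter() - t0,
            backend=method,
            gap=None,
        )

    if report.solution is not None:
        ok, violations = check_feasible(report.solution.selected, P, h)
        if not ok:  # pragma: no cover - guarded by construction
            raise RuntimeError(f"optimizer returned infeasible set: {violations[:5]}")
    report.infeasible_pairs = (report.infeasible_pairs or []) + dropped
    return report.solution, report
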