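"""Pairwise discriminatory power, physical-adjacency weights, and solution metrics.

The discriminatory power p_ijk scores how well marker k separates the gametes
of candidate fathers i and j: opposing homozygotes (|a_ik - a_jk| = 2) give
deterministic exclusion and score the heterozygosity weight h; a homozygote/
heterozygote pair scores 1; a shared heterozygote scores h^-1 (weak,
probabilistic information); anything else, including a missing call on either
side, scores 0. A marker subset x is feasible when every unordered father
pair accumulates at least h of summed power over the selected markers.

The adjacency weight q_kl penalises physically close same-chromosome marker
pairs as a proxy for linkage disequilibrium: q = 1 across chromosomes, and
(|B_k - B_l| / D)^-1 within a chromosome of length D, populated strictly for
k > l.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .panel import GenotypePanel, MarkerMap

logger = logging.getLogger(__name__)

#: slack for comparing accumulated power sums against h (float accumulation
#: of h^-1 terms; h itself may not be a power of two)
FEAS_TOL = 1e-9

__all__ = [
    "PairPowerTensor",
    "AdjacencyMatrix",
    "MarkerSolution",
    "discriminatory_power",
    "build_pair_power",
    "build_adjacency",
    "objective_g",
    "depth",
    "check_feasible",
    "FEAS_TOL",
]


def discriminatory_power(a_i, a_j, h: float) -> float:
    """Power of one marker to separate the gametes of two candidate fathers.

    Returns 1 for a homozygote/heterozygote pair, ``h`` for opposing
    homozygotes, ``1/h`` for a shared heterozygote, and 0 otherwise
    (including when either dosage is missing). Missing may be passed as
    ``None`` or nan.
    """
    if h <= 0:
        raise ValueError("heterozygosity weight h must be positive")
    if a_i is None or a_j is None:
        return 0.0
    a_i, a_j = float(a_i), float(a_j)
    if math.isnan(a_i) or math.isnan(a_j):
        return 0.0
    d = abs(a_i - a_j)
    if d == 1.0:
        return 1.0
    if d == 2.0:
        return float(h)
    if a_i == 1.0 and a_j == 1.0:
        return 1.0 / h
    return 0.0


@dataclass
class PairPowerTensor:
    """Sparse discriminatory-power values for every unordered father pair.

    ``matrix`` has one row per pair (in lexicographic (i, j) order, i < j)
    and one column per marker; stored values are exactly 1, h, or 1/h and
    zeros are implicit.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    pairs: np.ndarray  # (n_pairs, 2) int indices into individual_ids, i < j
    matrix: sp.csr_matrix  # (n_pairs, n_markers)
    h: float
    infeasible_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]

    def pair_labels(self) -> list[tuple[str, str]]:
        return [
            (self.individual_ids[i], self.individual_ids[j]) for i, j in self.pairs
        ]

    def total_power(self) -> np.ndarray:
        """Sum of p_ijk over all markers, per pair."""
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def selected_sums(self, marker_indices: np.ndarray) -> np.ndarray:
        """Per-pair power accumulated over the given marker columns."""
        marker_indices = np.asarray(marker_indices, dtype=int)
        if marker_indices.size == 0:
            return np.zeros(self.n_pairs)
        return np.asarray(self.matrix[:, marker_indices].sum(axis=1)).ravel()

    def marker_indices(self, marker_ids: list[str]) -> np.ndarray:
        lookup = {mk: k for k, mk in enumerate(self.marker_ids)}
        return np.array([lookup[mk] for mk in marker_ids], dtype=int)

    def keep_pairs(self, mask: np.ndarray) -> "PairPowerTensor":
        return PairPowerTensor(
            individual_ids=self.individual_ids,
            marker_ids=self.marker_ids,
            pairs=self.pairs[mask],
            matrix=self.matrix[mask],
            h=self.h,
            infeasible_pairs=list(self.infeasible_pairs),
        )


def build_pair_power(panel: GenotypePanel, h: float) -> PairPowerTensor:
    """Evaluate the discriminatory power for all n(n-1)/2 candidate pairs.

    Pairs whose total power over *all* markers falls below h can never be
    separated by any subset; they are flagged on the tensor (and logged) but
    not removed here — see ``drop_infeasible_pairs``.
    """
    if h <= 0:
        raise ValueError("heterozygosity weight h must be positive")
    n = panel.n_individuals
    if n < 2:
        raise ValueError("need at least two candidate fathers")
    iu, ju = np.triu_indices(n, k=1)
    A = panel.dosages
    Ai, Aj = A[iu], A[ju]
    diff = np.abs(Ai - Aj)
    P = np.zeros_like(diff)
    P[diff == 1.0] = 1.0
    P[diff == 2.0] = h
    P[(Ai == 1.0) & (Aj == 1.0)] = 1.0 / h  # nan comparisons are False
    tensor = PairPowerTensor(
        individual_ids=list(panel.individual_ids),
        marker_ids=list(panel.marker_ids),
        pairs=np.column_stack([iu, ju]),
        matrix=sp.csr_matrix(P),
        h=float(h),
    )
    totals = tensor.total_power()
    weak = np.flatnonzero(totals < h - FEAS_TOL)
    tensor.infeasible_pairs = [
        (panel.individual_ids[iu[p]], panel.individual_ids[ju[p]], float(totals[p]))
        for p in weak
    ]
    if tensor.infeasible_pairs:
        logger.warning(
            "%d candidate pair(s) cannot reach h=%g with any marker subset: %s",
            len(tensor.infeasible_pairs),
            h,
            [(a, b) for a, b, _ in tensor.infeasible_pairs[:10]],
        )
    return tensor


class AdjacencyMatrix:
    """Strictly lower-triangular physical-distance weights q_kl over markers.

    q_kl = 1 when markers k and l sit on different chromosomes, the inverse
    of their distance expressed as a fraction of chromosome length when they
    share one, and 0 for k <= l. Entries are evaluated lazily from per-marker
    chromosome codes, positions, and chromosome lengths, which keeps large
    panels cheap; ``toarray`` materialises the full matrix for small ones.

    Markers absent from the map are put on private pseudo-chromosomes (weight
    1 against everything): without a position no distance penalty can be
    claimed.
    """

    def __init__(self, marker_ids: list[str], mmap: MarkerMap):
        self.marker_ids = list(marker_ids)
        self._index = {mk: k for k, mk in enumerate(self.marker_ids)}
        chrom_codes: dict[str, int] = {}
        codes = np.empty(len(marker_ids), dtype=int)
        pos = np.zeros(len(marker_ids))
        length = np.ones(len(marker_ids))
        pseudo = 0
        unmapped = []
        for k, mk in enumerate(marker_ids):
            if mk in mmap:
                chrom = mmap.chromosome[mk]
                if chrom not in mmap.chromosome_length:
                    raise ValueError(f"no length for chromosome {chrom!r}")
                codes[k] = chrom_codes.setdefault(chrom, len(chrom_codes))
                pos[k] = mmap.position[mk]
                length[k] = mmap.chromosome_length[chrom]
            else:
                unmapped.append(mk)
                pseudo += 1
                codes[k] = -pseudo  # unique negative code: q=1 vs everything
                pos[k] = 0.0
        if unmapped:
            logger.warning(
                "%d marker(s) not in map; treated as unlinked (q=1): %s",
                len(unmapped), unmapped[:10],
            )
        self.chrom_code = codes
        self.position = pos
        self.chrom_length = length
        # coincident same-chromosome positions make q undefined
        for c in np.unique(codes[codes >= 0]):
            p = pos[codes == c]
            if len(p) != len(np.unique(p)):
                dup = [
                    mk for mk in marker_ids
                    if self.chrom_code[self._index[mk]] == c
                ]
                raise ValueError(
                    f"coincident same-chromosome positions among markers {dup}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def index_of(self, marker_ids: list[str]) -> np.ndarray:
        return np.array([self._index[mk] for mk in marker_ids], dtype=int)

    def weight(self, k: int, l: int) -> float:
        """q_kl for marker indices; 0 when k <= l."""
        if k <= l:
            return 0.0
        if self.chrom_code[k] != self.chrom_code[l]:
            return 1.0
        return float(self.chrom_length[k] / abs(self.position[k] - self.position[l]))

    def weights_between(self, k: int, others: np.ndarray) -> np.ndarray:
        """Unordered weights q between marker k and each of ``others``.

        Orientation-free (uses max/min index implicitly: the same-chromosome
        branch is symmetric and the cross-chromosome branch is constant).
        """
        others = np.asarray(others, dtype=int)
        same = self.chrom_code[others] == self.chrom_code[k]
        w = np.ones(others.size)
        if same.any():
            d = np.abs(self.position[others[same]] - self.position[k])
            with np.errstate(divide="ignore"):  # k itself; zeroed below
                w[same] = self.chrom_length[k] / d
        w[others == k] = 0.0
        return w

    def selection_g(self, indices: np.ndarray) -> float:
        """x^T Q x over the selected marker indices (sum of q over k > l pairs)."""
        indices = np.asarray(indices, dtype=int)
        total = 0.0
        for a in range(1, indices.size):
            total += self.weights_between(indices[a], indices[:a]).sum()
        return float(total)

    def toarray(self) -> np.ndarray:
        m = self.n_markers
        Q = np.zeros((m, m))
        for k in range(m):
            for l in range(k):
                Q[k, l] = self.weight(k, l)
        return Q


def build_adjacency(mmap: MarkerMap, marker_ids: list[str]) -> AdjacencyMatrix:
    """Construct the triangular adjacency weight matrix for the given markers."""
    return AdjacencyMatrix(marker_ids, mmap)


@dataclass
class MarkerSolution:
    """A selected marker subset with its evaluation metrics.

    ``f`` is the marker count, ``g`` the adjacency objective x^T Q x (None
    when no map was available), ``depth`` the median per-pair power sum — a
    buffer over the minimum requirement h that confers tolerance to missing
    genotypes.
    """

    selected: list[str]
    f: int
    g: float | None
    depth: float
    feasible: bool
    h_used: float

    def __post_init__(self) -> None:
        if self.f != len(self.selected):
            raise ValueError("f must equal the number of selected markers")
        if self.g is not None and self.g < 0:
            raise ValueError("g must be non-negative")


def objective_g(marker_ids: list[str], Q: AdjacencyMatrix) -> float:
    """Adjacency objective: sum of q_kl over selected ordered pairs k > l."""
    return Q.selection_g(Q.index_of(marker_ids))


def depth(marker_ids: list[str], P: PairPowerTensor) -> float:
    """Median over father pairs of the power accumulated by the selection.

    Even pair counts use the midpoint of the two central values; an empty
    selection has depth 0.
    """
    if P.n_pairs == 0:
        return 0.0
    sums = P.selected_sums(P.marker_indices(marker_ids))
    return float(np.median(sums))


def check_feasible(
    marker_ids: list[str], P: PairPowerTensor, h: float
) -> tuple[bool, list[tuple[str, str, float]]]:
    """Does every father pair accumulate at least h over the selection?

    Returns the verdict and the violating pairs with their sums.
    """
    sums = P.selected_sums(P.marker_indices(marker_ids))
    bad = np.flatnonzero(sums < h - FEAS_TOL)
    violations = [
        (P.individual_ids[P.pairs[p, 0]], P.individual_ids[P.pairs[p, 1]], float(sums[p]))
        for p in bad
    ]
    return len(violations) == 0, violations


def make_solution(
    marker_ids: list[str],
    P: PairPowerTensor,
    Q: AdjacencyMatrix | None,
    h: float,
) -> MarkerSolution:
    """Assemble a MarkerSolution with freshly computed metrics."""
    feasible, _ = check_feasible(marker_ids, P, h)
    return MarkerSolution(
        selected=list(marker_ids),
        f=len(marker_ids),
        g=objective_g(marker_ids, Q) if Q is not None else None,
        depth=depth(marker_ids, P),
        feasible=feasible,
        h_used=float(h),
    )
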