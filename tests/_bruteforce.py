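"""Exhaustive-enumeration oracle for small marker-selection instances.

Independent of the solver path: evaluates feasibility and both objectives
for every one of the 2^m subsets directly from the dense power matrix and
the dense adjacency matrix.
"""

import numpy as np

from marksel.discrimination import FEAS_TOL


def enumerate_optima(P, Q, h):
    """(min feasible f, min feasible g) by brute force; g is None without Q.

    Returns (None, None) when no subset is feasible.
    """
    m = len(P.marker_ids)
    assert m <= 20, "enumeration oracle is for tiny instances"
    Pd = P.matrix.toarray()
    bits = ((np.arange(2**m)[:, None] >> np.arange(m)) & 1).astype(float)
    sums = bits @ Pd.T  # (2^m, n_pairs)
    feasible = (
        (sums >= h - FEAS_TOL).all(axis=1)
        if Pd.shape[0]
        else np.ones(2**m, dtype=bool)
    )
    if not feasible.any():
        return None, None
    f = bits.sum(axis=1)
    f_min = int(f[feasible].min())
    g_min = None
    if Q is not None:
        Qarr = Q.toarray()
        sym = Qarr + Qarr.T
        g_all = 0.5 * np.einsum("ij,jk,ik->i", bits, sym, bits)
        g_min = float(g_all[feasible].min())
    return f_min, g_min
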