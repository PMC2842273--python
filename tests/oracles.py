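"""Independent brute-force oracles for profile alignment scores.

These enumerate every gapped alignment combinatorially (matched
position/residue chains with affine gap costs between consecutive
pairs) and never share code with the dynamic-programming implementation
they check. Feasible only for tiny instances.
"""

from itertools import combinations

import numpy as np


def _chain_gap_cost(rows, cols, gap_open, gap_extend):
    cost = 0.0
    for t in range(len(rows) - 1):
        gi = rows[t + 1] - rows[t] - 1
        gj = cols[t + 1] - cols[t] - 1
        if gi:
            cost += gap_open + gap_extend * (gi - 1)
        if gj:
            cost += gap_open + gap_extend * (gj - 1)
    return cost


def brute_force_local(S: np.ndarray, gap_open: float, gap_extend: float) -> float:
    """Best local alignment score, floored at 0, by full enumeration."""
    L, m = S.shape
    best = 0.0
    for k in range(1, min(L, m) + 1):
        for rows in combinations(range(L), k):
            for cols in combinations(range(m), k):
                sc = sum(S[i, j] for i, j in zip(rows, cols))
                sc -= _chain_gap_cost(rows, cols, gap_open, gap_extend)
                best = max(best, sc)
    return best


def brute_force_semiglobal(S: np.ndarray, gap_open: float, gap_extend: float) -> float:
    """Best full-profile alignment score with free query overhangs."""
    L, m = S.shape

    def profile_overhang(n_rows: int) -> float:
        return gap_open + gap_extend * (n_rows - 1) if n_rows else 0.0

    # whole profile aligned to gaps
    best = -profile_overhang(L)
    for k in range(1, min(L, m) + 1):
        for rows in combinations(range(L), k):
            for cols in combinations(range(m), k):
                sc = sum(S[i, j] for i, j in zip(rows, cols))
                sc -= _chain_gap_cost(rows, cols, gap_open, gap_extend)
                sc -= profile_overhang(rows[0])
                sc -= profile_overhang(L - 1 - rows[-1])
                best = max(best, sc)
    return best
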