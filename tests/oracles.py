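"""Independent brute-force oracles shared by the test modules.

These deliberately re-derive results by exhaustive enumeration so the
dynamic programs they check can never be their own referee.
"""

import itertools

import numpy as np

from octdark.bands import _tie_penalty
from octdark.core_io import BANDS


def brute_force_min_path(cost, max_step=2):
    """Enumerate every admissible path; return (best path, best cost), ties
    broken toward the lexicographically smallest depth sequence."""
    n_a, n_z = cost.shape
    best = (np.inf, None)
    for z0 in range(n_z):
        stack = [((cost[0][z0],), (z0,))]
        while stack:
            costs, path = stack.pop()
            a = len(path)
            if a == n_a:
                cand = (sum(costs), path)
                if cand[0] < best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                    best = cand
                continue
            for dz in range(-max_step, max_step + 1):
                z = path[-1] + dz
                if 0 <= z < n_z:
                    stack.append((costs + (cost[a][z],), path + (z,)))
    return np.array(best[1]), best[0]


def brute_force_assign(depths, proms, windows, tie_scale=0.0):
    """Enumerate every ordered band→candidate assignment; maximize the same
    score as the DP (prominence minus the positional tie penalty)."""
    n = len(depths)
    best_score, best = -1.0, {b: -1 for b in BANDS}
    options = [list(range(n)) + [None]] * len(BANDS)
    for combo in itertools.product(*options):
        chosen = [c for c in combo if c is not None]
        if len(set(chosen)) != len(chosen):
            continue
        if any(
            a is not None and b is not None and depths[a] >= depths[b]
            for a, b in zip(combo, combo[1:])
        ):
            continue
        ok = all(
            c is None or windows[band][0] <= depths[c] <= windows[band][1]
            for band, c in zip(BANDS, combo)
        )
        if not ok:
            continue
        score = sum(
            proms[c] - _tie_penalty(depths[c], windows[band], tie_scale)
            for band, c in zip(BANDS, combo)
            if c is not None
        )
        if score > best_score:
            best_score, best = score, dict(
                zip(BANDS, (c if c is not None else -1 for c in combo))
            )
    return best
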