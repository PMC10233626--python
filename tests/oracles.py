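"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the local-alignment
oracles are a hand-rolled Gotoh dynamic program and (for tiny inputs) a
full recursive enumeration of alignment paths; the superposition oracle is
a rotation-grid search.
"""

from __future__ import annotations

import itertools

import numpy as np


def gotoh_local_score(
    a: str, b: str, sub, gap_open: float, gap_extend: float
) -> float:
    """Smith–Waterman score with affine gaps; a gap of length L costs
    gap_open + (L-1)·gap_extend (EMBOSS water convention).

    Plain-Python row-rolling Gotoh recursion, independent of any alignment
    library. ``sub`` is any mapping supporting ``sub[x, y]``.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    Hprev = [0.0] * (m + 1)
    Fprev = [neg] * (m + 1)
    best = 0.0
    for i in range(1, n + 1):
        ca = a[i - 1]
        Hcur = [0.0] * (m + 1)
        Fcur = [neg] * (m + 1)
        e = neg  # E for the current row, column j
        for j in range(1, m + 1):
            e = max(Hcur[j - 1] - gap_open, e - gap_extend)
            f = max(Hprev[j] - gap_open, Fprev[j] - gap_extend)
            h = max(0.0, Hprev[j - 1] + sub[ca, b[j - 1]], e, f)
            Hcur[j] = h
            Fcur[j] = f
            if h > best:
                best = h
        Hprev, Fprev = Hcur, Fcur
    return best


def enumerate_local_score(
    a: str, b: str, sub, gap_open: float, gap_extend: float
) -> float:
    """Exhaustive local alignment: try every substring pair and every
    monotone alignment path between them. Exponential; lengths ≤ 4 only."""
    best = 0.0

    def paths(x: str, y: str):
        # all global alignments of x vs y as lists of column kinds
        if not x and not y:
            yield []
            return
        if x:
            for rest in paths(x[1:], y):
                yield [("D", x[0], None)] + rest
        if y:
            for rest in paths(x, y[1:]):
                yield [("I", None, y[0])] + rest
        if x and y:
            for rest in paths(x[1:], y[1:]):
                yield [("M", x[0], y[0])] + rest

    def score(cols) -> float:
        total = 0.0
        prev = None
        for kind, ca, cb in cols:
            if kind == "M":
                total += sub[ca, cb]
            else:
                total -= gap_extend if kind == prev else gap_open
            prev = kind
        return total

    for i1, i2 in itertools.combinations(range(len(a) + 1), 2):
        for j1, j2 in itertools.combinations(range(len(b) + 1), 2):
            x, y = a[i1:i2], b[j1:j2]
            for cols in paths(x, y):
                # local alignments never start or end with a gap column
                if cols and cols[0][0] == "M" and cols[-1][0] == "M":
                    best = max(best, score(cols))
    return best


def grid_search_rmsd(
    coords_a: np.ndarray, coords_b: np.ndarray, n_steps: int = 24
) -> float:
    """Brute-force minimum rmsd over a grid of Euler-angle rotations,
    followed by local polish with Nelder–Mead on the best grid cell."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    a = coords_a - coords_a.mean(axis=0)
    b = coords_b - coords_b.mean(axis=0)

    def rmsd_of(euler: np.ndarray) -> float:
        R = Rotation.from_euler("zyx", euler).as_matrix()
        return float(np.sqrt(np.mean(np.sum((b @ R.T - a) ** 2, axis=1))))

    angles = np.linspace(-np.pi, np.pi, n_steps, endpoint=False)
    half = np.linspace(-np.pi / 2, np.pi / 2, n_steps // 2)
    best_euler, best = None, np.inf
    for ez in angles:
        for ey in half:
            for ex in angles:
                val = rmsd_of(np.array([ez, ey, ex]))
                if val < best:
                    best, best_euler = val, np.array([ez, ey, ex])
    res = minimize(rmsd_of, best_euler, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    return float(min(best, res.fun))
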