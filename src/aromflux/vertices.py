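"""Exhaustive vertex enumeration for small flux polytopes.

The feasible set of FBA, P = {v : S·v = 0, lb <= v <= ub}, is a bounded
polytope when all bounds are finite.  Its vertices are the basic feasible
solutions: pick n - rank(S) variables, pin each to one of its bounds, and
solve the equality system for the rest.  A linear objective attains its
optimum at a vertex, and the optimal face's vertices are vertices of P, so
both the FBA optimum and the flux-variability ranges can be read off the
vertex list.  Cost is exponential in the number of reactions — this is a
ground-truth oracle for small networks, not an engine.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


def enumerate_vertices(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    feas_tol: float = 1e-8,
) -> np.ndarray:
    """All vertices of {v : S v = 0, lb <= v <= ub} as rows of an array.

    Bounds must be finite.  Raises if the polytope has no vertices within
    tolerance (infeasible problem).
    """
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("vertex enumeration requires finite bounds")
    m, n = S.shape
    r = int(np.linalg.matrix_rank(S)) if S.size else 0
    f = n - r
    verts: list[np.ndarray] = []
    bound_pairs = np.stack([lb, ub], axis=1)  # (n, 2)
    for nonbasic in combinations(range(n), f):
        basic = [j for j in range(n) if j not in nonbasic]
        SB = S[:, basic]
        if basic and np.linalg.matrix_rank(SB) < r:
            continue
        SN = S[:, list(nonbasic)]
        # Solve SB @ X = -SN once; each bound pattern is a linear combination.
        if basic:
            X, *_ = np.linalg.lstsq(SB, -SN, rcond=None)
            resid_base = SB @ X + SN  # should be ~0 columnwise if consistent
            if np.max(np.abs(resid_base)) > feas_tol:
                continue
        for pattern in product((0, 1), repeat=f):
            vN = np.array([bound_pairs[j, p] for j, p in zip(nonbasic, pattern)])
            v = np.empty(n)
            for idx, j in enumerate(nonbasic):
                v[j] = vN[idx]
            if basic:
                vB = X @ vN if f else np.zeros(len(basic))
                v[basic] = vB
                if np.max(np.abs(S @ v)) > feas_tol:
                    continue
            if np.all(v >= lb - feas_tol) and np.all(v <= ub + feas_tol):
                verts.append(np.clip(v, lb, ub))
    if not verts:
        raise ValueError("no vertices found; polytope empty within tolerance")
    return np.array(verts)


def lp_optimum(vertices: np.ndarray, c: np.ndarray) -> float:
    """Maximum of c·v over the enumerated vertices (= the LP optimum)."""
    return float(np.max(vertices @ np.asarray(c, dtype=float)))


def optimal_face_ranges(
    vertices: np.ndarray,
    c: np.ndarray,
    face_tol: float = 1e-7,
) -> np.ndarray:
    """Per-coordinate [min, max] over vertices attaining the LP optimum.

    Equivalent to flux variability at objective_fraction = 1.
    Returns an (n, 2) array.
    """
    c = np.asarray(c, dtype=float)
    vals = vertices @ c
    best = np.max(vals)
    face = vertices[vals >= best - face_tol]
    return np.stack([face.min(axis=0), face.max(axis=0)], axis=1)
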