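"""Independent oracles used by the test suite.

These deliberately avoid the package's LP wrapper: vertices are enumerated
combinatorially and checked by direct substitution, so agreement with the
simplex-based solver is a genuine cross-check.
"""

from itertools import combinations

import numpy as np

FEAS_TOL = 1e-9


def enumerate_vertices(A_eq, b_eq, G, h, n):
    """All vertices of {A_eq x = b_eq, G x <= h} in R^n by basis enumeration.

    Every choice of (n - rank(A_eq)) inequality rows is made active; the
    square system is solved and the candidate kept if it satisfies all
    constraints.  Exponential - fine for toy polytopes.
    """
    A_eq = np.atleast_2d(A_eq) if A_eq is not None else np.zeros((0, n))
    b_eq = np.atleast_1d(b_eq) if b_eq is not None else np.zeros(0)
    m_eq = A_eq.shape[0]
    need = n - np.linalg.matrix_rank(A_eq) if m_eq else n
    vertices = []
    for rows in combinations(range(len(G)), need):
        M = np.vstack([A_eq, G[list(rows)]])
        rhs = np.concatenate([b_eq, h[list(rows)]])
        if np.linalg.matrix_rank(M) < n:
            continue
        x, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        if np.max(np.abs(M @ x - rhs)) > 1e-7:
            continue
        if np.all(G @ x <= h + 1e-7) and (
                m_eq == 0 or np.max(np.abs(A_eq @ x - b_eq)) < 1e-7):
            vertices.append(x)
    if not vertices:
        return np.zeros((0, n))
    V = np.array(vertices)
    # deduplicate
    keep = []
    for v in V:
        if not any(np.allclose(v, V[k], atol=1e-7) for k in keep):
            keep.append(len(keep))
            V[len(keep) - 1] = v
    return V[:len(keep)]


def problem_polytope(problem):
    """Stack a HybridProblem's constraints into (A_eq, b_eq, G, h)."""
    c, A_eq, b_eq, A_ub, b_ub, bounds, _ = problem.arrays()
    n = problem.n_vars
    rows, rhs = [], []
    if A_ub is not None:
        rows.append(A_ub)
        rhs.append(b_ub)
    eye = np.eye(n)
    lo = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
    hi = np.array([b[1] if b[1] is not None else np.inf for b in bounds])
    fin_hi = np.isfinite(hi)
    fin_lo = np.isfinite(lo)
    rows.append(eye[fin_hi])
    rhs.append(hi[fin_hi])
    rows.append(-eye[fin_lo])
    rhs.append(-lo[fin_lo])
    return c, A_eq, b_eq, np.vstack(rows), np.concatenate(rhs)


def vertex_optimum(problem, objective_vector=None, sense="max"):
    """Optimum of a hybrid LP by exhaustive vertex enumeration."""
    c, A_eq, b_eq, G, h = problem_polytope(problem)
    if objective_vector is not None:
        c = objective_vector
    V = enumerate_vertices(A_eq, b_eq, G, h, problem.n_vars)
    if len(V) == 0:
        raise RuntimeError("no vertices found (empty or unbounded polytope)")
    vals = V @ c
    return (vals.max(), V[np.argmax(vals)]) if sense == "max" else \
        (vals.min(), V[np.argmin(vals)])


def vertex_flux_ranges(problem):
    """Per-variable min/max over the vertex set (bounded polytopes only)."""
    c, A_eq, b_eq, G, h = problem_polytope(problem)
    V = enumerate_vertices(A_eq, b_eq, G, h, problem.n_vars)
    return V.min(axis=0), V.max(axis=0)
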