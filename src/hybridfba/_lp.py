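"""Thin wrapper around scipy's HiGHS linear-programming interface.

All LPs in this package (FBA, HybridFBA, FVA, blocked-reaction detection) go
through :func:`solve_lp` so that solver options and tolerances are set in one
place.  The dual-simplex algorithm is used throughout.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

#: primal/dual feasibility tolerance passed to HiGHS
FEAS_TOL = 1e-9

_OPTIONS = {
    "primal_feasibility_tolerance": FEAS_TOL,
    "dual_feasibility_tolerance": FEAS_TOL,
    "presolve": True,
}


class LPError(RuntimeError):
    """Raised when an LP terminates with an unexpected solver status."""


def solve_lp(c, A_eq=None, b_eq=None, A_ub=None, b_ub=None, bounds=None,
             sense="min"):
    """Solve ``min/max c^T x`` subject to equality, inequality and box bounds.

    Maximization is performed by negating the objective; the returned
    ``fun`` and all multipliers are re-signed so they refer to the problem
    in its *stated* sense.

    Returns the scipy ``OptimizeResult`` augmented with ``fun`` in the stated
    sense.  ``res.status``: 0 optimal, 2 infeasible, 3 unbounded.
    """
    c = np.asarray(c, dtype=float)
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(sign * c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs-ds", options=_OPTIONS)
    if res.status == 0:
        res.fun = sign * res.fun
        # marginals of the sign-flipped problem; re-sign so they are
        # derivatives of the stated-sense objective.
        for block in ("eqlin", "ineqlin", "lower", "upper"):
            blk = getattr(res, block, None)
            if blk is not None and getattr(blk, "marginals", None) is not None:
                blk.marginals = sign * blk.marginals
    return res
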