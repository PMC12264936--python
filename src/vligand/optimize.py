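"""Shared conjugate-gradient minimizer.

Both the nearest-point projection (minimizing the squared descriptor
distance) and the parameter optimization against a chemical objective use the
same gradient-driven scheme: Polak–Ribiere conjugate gradients with a
backtracking Armijo line search and restart to steepest descent whenever the
conjugate direction is not a descent direction.  Every accepted iterate is
recorded, because the trajectory itself is an input to the weighted
surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = ["CGResult", "minimize_cg"]


@dataclass
class CGResult:
    x: np.ndarray
    fun: float
    grad: np.ndarray
    iterates: list = field(default_factory=list)  # (x, f, g) accepted steps
    n_iter: int = 0
    converged: bool = False
    message: str = ""


def minimize_cg(
    fun_grad: Callable[[np.ndarray], tuple],
    x0,
    tol: float = 1e-8,
    max_iter: int = 500,
    armijo_c: float = 1e-4,
    shrink: float = 0.5,
    initial_step: float = 1.0,
    max_backtracks: int = 60,
    accept: Optional[Callable[[np.ndarray], bool]] = None,
) -> CGResult:
    """Minimize ``f`` given a ``fun_grad(x) -> (f, g)`` callable.

    Parameters
    ----------
    accept : callable, optional
        Feasibility predicate; trial points failing it are rejected and the
        step is shrunk (used to keep VL parameters strictly positive).
    """
    x = np.asarray(x0, dtype=float).copy()
    f, g = fun_grad(x)
    iterates = [(x.copy(), f, g.copy())]
    d = -g
    t_prev = initial_step

    for it in range(1, max_iter + 1):
        gnorm = np.linalg.norm(g)
        if gnorm <= tol:
            return CGResult(x, f, g, iterates, it - 1, True, "gradient tolerance")
        slope = float(d @ g)
        if slope >= 0:  # restart on non-descent
            d = -g
            slope = -float(gnorm**2)
        # backtracking Armijo line search
        t = t_prev
        accepted = False
        for _ in range(max_backtracks):
            x_new = x + t * d
            if accept is not None and not accept(x_new):
                t *= shrink
                continue
            f_new, g_new = fun_grad(x_new)
            if np.isfinite(f_new) and f_new <= f + armijo_c * t * slope:
                accepted = True
                break
            t *= shrink
        if not accepted:
            # no descent step is representable at this floating-point scale:
            # the iterate is a local minimizer to machine precision
            return CGResult(
                x, f, g, iterates, it, True,
                "stalled at floating-point precision",
            )
        # Polak-Ribiere (nonnegative) conjugacy
        beta = max(0.0, float(g_new @ (g_new - g)) / float(g @ g))
        d = -g_new + beta * d
        no_progress = (
            np.max(np.abs(x_new - x)) <= 1e-12 * (1.0 + np.max(np.abs(x)))
            and f - f_new <= 1e-15 * (1.0 + abs(f))
        )
        x, f, g = x_new, f_new, g_new
        iterates.append((x.copy(), f, g.copy()))
        if no_progress:
            return CGResult(
                x, f, g, iterates, it, True,
                "converged to floating-point resolution",
            )
        # grow the trial step back so progress is not permanently throttled
        t_prev = min(t / shrink, 1.0) if t < 1.0 else 1.0

    converged = bool(np.linalg.norm(g) <= tol)
    return CGResult(
        x, f, g, iterates, max_iter, converged,
        "gradient tolerance" if converged else "maximum iterations",
    )
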