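"""Nearest-point projection H of a descriptor onto the G_virt(P) surface.

The virtual-ligand parameter space traces an n-dimensional surface
``G_virt(P)`` inside the m-dimensional descriptor space.  The projection
``H(x)`` returns the parameters of the surface point nearest to ``x`` in the
Euclidean metric; the residual distance ``l_min`` measures how well a real
ligand can be represented by any virtual ligand and is used downstream as a
reliability index.

Following the database-construction procedure, the squared distance
``l(x, p)**2`` is minimized (avoiding the non-differentiable point at
``l = 0``) by conjugate gradients from the standard initial guess
``p = (1.6, 3.0, 2.0)`` Angstrom.  On warped (non-affine) surfaces a small
number of seeded restarts guards against secondary local minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .optimize import minimize_cg

__all__ = [
    "DEFAULT_P_INIT",
    "ProjectionResult",
    "descriptor_distance",
    "project",
    "project_all",
]

#: Standard initial parameter guess (r0, a1, b1) in Angstrom.
DEFAULT_P_INIT = np.array([1.6, 3.0, 2.0])


@dataclass
class ProjectionResult:
    p: np.ndarray
    l_min: float
    iterations: int
    converged: bool
    trace: list = field(default_factory=list)  # (p, l^2) accepted iterates

    def __post_init__(self):
        if self.l_min < 0:
            raise ValueError("l_min must be nonnegative")


def descriptor_distance(x, p, backend, with_gradient: bool = False):
    """Euclidean distance ``||x - G_virt(p)||`` (optionally with d(l^2)/dp)."""
    x = np.asarray(x, dtype=float)
    gx, jac = backend.eval_descriptors(np.asarray(p, dtype=float))
    if gx.shape != x.shape:
        raise ValueError(
            f"descriptor dimension mismatch: x has {x.shape}, G_virt {gx.shape}"
        )
    r = x - gx
    dist = float(np.linalg.norm(r))
    if not with_gradient:
        return dist
    grad_sq = -2.0 * (jac.T @ r)  # gradient of l^2, smooth everywhere
    return dist, grad_sq


def _project_single(x, backend, p0, tol, max_iter):
    def fun_grad(p):
        gx, jac = backend.eval_descriptors(p)
        r = x - gx
        return float(r @ r), -2.0 * (jac.T @ r)

    res = minimize_cg(
        fun_grad,
        p0,
        tol=tol,
        max_iter=max_iter,
        accept=lambda p: bool(np.all(p > 0)),  # parameters stay positive
    )
    trace = [(xi.copy(), fi) for xi, fi, _ in res.iterates]
    return ProjectionResult(
        p=res.x,
        l_min=float(np.sqrt(max(res.fun, 0.0))),
        iterations=res.n_iter,
        converged=res.converged,
        trace=trace,
    )


def project(
    x,
    backend,
    p_init=None,
    tol: float = 1e-8,
    max_iter: int = 500,
    restarts: int = 5,
    restart_scale: float = 0.25,
    seed: int = 0,
) -> ProjectionResult:
    """Project descriptor ``x`` onto the surface; return parameters and l_min.

    ``restarts`` additional seeded starting points (relative perturbations of
    ``p_init``) are tried and the best local minimum kept.  Ties on the
    residual are broken by smaller ``||p - p_init||``, then lexicographically.
    """
    x = np.asarray(x, dtype=float)
    p0 = DEFAULT_P_INIT.copy() if p_init is None else np.asarray(p_init, float)
    if not np.all(np.isfinite(p0)):
        raise ValueError("p_init must be finite")

    candidates = [_project_single(x, backend, p0, tol, max_iter)]
    rng = np.random.default_rng(seed)
    starts = [
        np.abs(p0 * (1.0 + restart_scale * rng.standard_normal(p0.size)))
        for _ in range(restarts)
    ]
    for start in starts:
        candidates.append(_project_single(x, backend, start, tol, max_iter))

    def key(res):
        return (
            round(res.l_min, 10),
            round(float(np.linalg.norm(res.p - p0)), 10),
            tuple(np.round(res.p, 10)),
        )

    return min(candidates, key=key)


def project_all(xs, backend, ids=None, **options) -> list:
    """Order-preserving batch projection; failures are collected with ids."""
    xs = list(xs)
    if not xs:
        raise ValueError("empty descriptor list")
    if ids is None:
        ids = list(range(len(xs)))
    results, errors = [], []
    for ident, x in zip(ids, xs):
        try:
            results.append(project(x, backend, **options))
        except Exception as exc:  # collected, reported together
            errors.append((ident, exc))
    if errors:
        detail = "; ".join(f"{i}: {e}" for i, e in errors)
        raise RuntimeError(f"projection failed for {len(errors)} item(s): {detail}")
    return results
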