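"""Virtual-ligand-assisted optimization (VLAO).

The VL parameters are optimized by conjugate gradients against a chemical
objective ``y`` (reaction energy, activation energy, ...) corrected by a
smooth barrier ``B(p)`` that confines the parameters to a realistic range —
the range spanned by real ligands — so that the optimum stays in a region
where database ligands exist.  Every accepted iterate (parameters, objective,
gradient) is recorded: the trajectory is the raw material for the weighted
surrogate, and the final point anchors the Taylor surrogate.

The surrogate derivatives are those of the *uncorrected* objective: the
gradient comes from the backend and the Hessian from central differences of
that gradient.  At a barrier-constrained optimum the uncorrected gradient
need not vanish and the Hessian may have negative eigenvalues — both are
handled downstream (clipping).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .optimize import minimize_cg
from .vl_model import ParamBounds

__all__ = [
    "ObjectiveSpec",
    "BarrierSpec",
    "VLAOTrajectory",
    "barrier",
    "optimize",
    "numerical_hessian",
    "save_trajectory",
    "load_trajectory",
]


@dataclass
class ObjectiveSpec:
    """An objective ``y`` supplied by a backend, with optimization sense."""

    backend: object                     # must expose eval_objective(p)
    sense: str = "minimize"             # or "maximize"
    label: str = "dE"

    def __post_init__(self):
        if self.sense not in ("minimize", "maximize"):
            raise ValueError("sense must be 'minimize' or 'maximize'")

    @property
    def sign(self) -> float:
        return 1.0 if self.sense == "minimize" else -1.0


@dataclass
class BarrierSpec:
    """Smooth wall confining ``p`` to its bounds.

    ``B(p)`` is zero on the central ``plateau_fraction`` of each range and
    grows quartically in the normalized excess beyond it, so it is twice
    differentiable everywhere, strictly positive on the bounds themselves
    and steep outside them.
    """

    bounds: ParamBounds
    stiffness: float = 50.0        # kcal/mol per unit^4 normalized excess
    plateau_fraction: float = 0.90

    def __post_init__(self):
        if not 0.0 < self.plateau_fraction < 1.0:
            raise ValueError("plateau_fraction must be in (0, 1)")


def barrier(p, spec: BarrierSpec):
    """Barrier energy and gradient at ``p``."""
    p = np.asarray(p, dtype=float)
    w = spec.bounds.width
    s = (p - spec.bounds.lower) / w           # normalized position in [0,1]
    half_gap = 0.5 * (1.0 - spec.plateau_fraction)
    lo_excess = np.maximum(half_gap - s, 0.0)
    hi_excess = np.maximum(s - (1.0 - half_gap), 0.0)
    energy = spec.stiffness * float(np.sum(lo_excess**4 + hi_excess**4))
    grad = spec.stiffness * 4.0 * (hi_excess**3 - lo_excess**3) / w
    return energy, grad


@dataclass
class VLAOTrajectory:
    """Accepted iterates of a VLAO run (objective values are uncorrected)."""

    params: list                      # list of (n,) arrays p_i
    values: list                      # y_i, uncorrected objective
    gradients: list                   # (n,) arrays, uncorrected gradient
    totals: list                      # (sign * y + B)_i, the minimized quantity
    p_star: np.ndarray
    f_star: float                     # uncorrected objective at p_star
    n_iter: int
    converged: bool
    sense: str = "minimize"
    label: str = "dE"
    hessian: Optional[np.ndarray] = None  # of the uncorrected objective
    truncated: bool = False

    def __len__(self):
        return len(self.params)


def optimize(
    obj: ObjectiveSpec,
    bar: BarrierSpec,
    p_init=None,
    tol: float = 1e-6,
    max_iter: int = 500,
    hessian_step: float = 1e-4,
    with_hessian: bool = True,
) -> VLAOTrajectory:
    """Minimize ``y + B`` (or ``-y + B`` when maximizing) from ``p_init``."""
    from .projection import DEFAULT_P_INIT

    p0 = DEFAULT_P_INIT.copy() if p_init is None else np.asarray(p_init, float)
    if not bar.bounds.contains(p0):
        raise ValueError("p_init must lie inside the barrier bounds")

    sign = obj.sign
    record = {}

    def fun_grad(p):
        res = obj.backend.eval_objective(p)
        b, gb = barrier(p, bar)
        record[p.tobytes()] = (res.value, res.gradient)
        return sign * res.value + b, sign * res.gradient + gb

    truncated = False
    try:
        cg = minimize_cg(
            fun_grad, p0, tol=tol, max_iter=max_iter,
            accept=lambda p: bool(np.all(p > 0)),
        )
    except Exception:
        raise

    params, values, gradients, totals = [], [], [], []
    for p_i, f_i, _ in cg.iterates:
        y_i, g_i = record[p_i.tobytes()]
        params.append(p_i)
        values.append(float(y_i))
        gradients.append(np.asarray(g_i, dtype=float))
        totals.append(float(f_i))

    hess = None
    if with_hessian:
        hess = numerical_hessian(obj, cg.x, step=hessian_step)

    return VLAOTrajectory(
        params=params,
        values=values,
        gradients=gradients,
        totals=totals,
        p_star=cg.x,
        f_star=values[-1],
        n_iter=cg.n_iter,
        converged=cg.converged,
        sense=obj.sense,
        label=obj.label,
        hessian=hess,
        truncated=truncated,
    )


def numerical_hessian(obj: ObjectiveSpec, p, step: float = 1e-4) -> np.ndarray:
    """Symmetrized central differences of the backend gradient at ``p``."""
    if step <= 0:
        raise ValueError("finite-difference step must be positive")
    p = np.asarray(p, dtype=float)
    n = p.size
    H = np.empty((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = step
        gp = obj.backend.eval_objective(p + e).gradient
        gm = obj.backend.eval_objective(p - e).gradient
        H[i] = (gp - gm) / (2.0 * step)
    return 0.5 * (H + H.T)


# -- trajectory file contract (input to the surrogate module) ---------------

def save_trajectory(traj: VLAOTrajectory, path) -> None:
    payload = {
        "sense": traj.sense,
        "label": traj.label,
        "params": [list(p) for p in traj.params],
        "values": list(traj.values),
        "gradients": [list(g) for g in traj.gradients],
        "totals": list(traj.totals),
        "p_star": list(traj.p_star),
        "f_star": traj.f_star,
        "n_iter": traj.n_iter,
        "converged": traj.converged,
        "truncated": traj.truncated,
        "hessian": None if traj.hessian is None else [
            list(row) for row in traj.hessian
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_trajectory(path) -> VLAOTrajectory:
    raw = json.loads(Path(path).read_text())
    return VLAOTrajectory(
        params=[np.array(p, dtype=float) for p in raw["params"]],
        values=[float(v) for v in raw["values"]],
        gradients=[np.array(g, dtype=float) for g in raw["gradients"]],
        totals=[float(t) for t in raw["totals"]],
        p_star=np.array(raw["p_star"], dtype=float),
        f_star=float(raw["f_star"]),
        n_iter=int(raw["n_iter"]),
        converged=bool(raw["converged"]),
        sense=raw.get("sense", "minimize"),
        label=raw.get("label", "dE"),
        hessian=None if raw.get("hessian") is None else np.array(
            raw["hessian"], dtype=float
        ),
        truncated=bool(raw.get("truncated", False)),
    )
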