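"""Surrogate predictors of the objective over the VL parameter space.

Three prediction modes, in increasing fidelity and cost:

* :class:`TaylorSurrogate` — the second-order Taylor expansion of the
  objective around the optimized reference point ``p*``, with negative
  Hessian eigenvalues clipped to zero.  At a barrier-constrained optimum the
  Hessian of the uncorrected objective may have negative eigenvalues; left
  unclipped these would drive the prediction to absurdly favorable values
  far from ``p*``.
* :class:`TrajectorySurrogate` — the inverse-square-distance weighted
  average of Taylor expansions built at every accepted iterate of the VLAO
  run, accurate wherever the query point is close to the trajectory.
* :func:`predict_direct` — the backend objective itself (no surrogate
  error; one backend evaluation per candidate).

Distances inside the weighted surrogate use the range-normalized metric
``||dp'||`` shared with the ranking module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .ranking import delta_p_norm
from .vl_model import ParamBounds
from .vlao import VLAOTrajectory, numerical_hessian, ObjectiveSpec

__all__ = [
    "clip_psd",
    "TaylorSurrogate",
    "TrajectorySurrogate",
    "predict_direct",
]


def clip_psd(H) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone sharing its eigenvectors.

    Negative eigenvalues are set to exactly zero; this is the nearest PSD
    matrix in the Frobenius norm.  The input is symmetrized first.
    """
    H = np.asarray(H, dtype=float)
    if not np.all(np.isfinite(H)):
        raise ValueError("Hessian has non-finite entries")
    H = 0.5 * (H + H.T)
    vals, vecs = np.linalg.eigh(H)
    return (vecs * np.maximum(vals, 0.0)) @ vecs.T


@dataclass
class TaylorSurrogate:
    """Quadratic model ``f0 + g.dp + dp.Hc.dp/2`` around ``p_star``."""

    p_star: np.ndarray
    f0: float
    g: np.ndarray
    Hc: np.ndarray  # clipped (PSD) Hessian

    def __post_init__(self):
        self.p_star = np.asarray(self.p_star, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.Hc = np.asarray(self.Hc, dtype=float)

    @classmethod
    def build(cls, p_star, f0, gradient, hessian, clip: bool = True):
        H = np.asarray(hessian, dtype=float)
        return cls(p_star, float(f0), gradient, clip_psd(H) if clip else
                   0.5 * (H + H.T))

    @classmethod
    def from_trajectory(cls, traj: VLAOTrajectory, clip: bool = True):
        """Anchor at the final VLAO point (requires a stored Hessian)."""
        if traj.hessian is None:
            raise ValueError("trajectory carries no Hessian")
        return cls.build(traj.p_star, traj.f_star, traj.gradients[-1],
                         traj.hessian, clip=clip)

    def __call__(self, p) -> float:
        dp = np.asarray(p, dtype=float) - self.p_star
        return float(self.f0 + self.g @ dp + 0.5 * dp @ self.Hc @ dp)


@dataclass
class TrajectorySurrogate:
    """Inverse-square-distance weighted average of per-iterate Taylor models.

    The weight of member ``i`` at query ``p`` is ``1 / ||dp_i'||**2`` with
    ``||dp_i'||`` the range-normalized deviation between ``p`` and the
    member's anchor.  Queries within ``epsilon`` (normalized units) of an
    anchor return that member's value alone (the singular-weight limit).
    """

    members: list                    # of TaylorSurrogate
    bounds: ParamBounds
    epsilon: float = 1e-8

    def __post_init__(self):
        if not self.members:
            raise ValueError("trajectory surrogate needs at least one member")

    @classmethod
    def from_trajectory(
        cls,
        traj: VLAOTrajectory,
        obj: ObjectiveSpec,
        bounds: ParamBounds,
        clip: bool = True,
        subsample: Optional[int] = None,
        hessian_step: float = 1e-4,
        epsilon: float = 1e-8,
    ):
        """Build one Taylor member per accepted VLAO iterate.

        ``subsample`` keeps at most that many evenly spaced iterates (always
        including the final point) for long trajectories.
        """
        idx = np.arange(len(traj))
        if subsample is not None and subsample < len(traj):
            idx = np.unique(
                np.round(np.linspace(0, len(traj) - 1, subsample)).astype(int)
            )
        members = []
        for i in idx:
            H = numerical_hessian(obj, traj.params[i], step=hessian_step)
            members.append(
                TaylorSurrogate.build(
                    traj.params[i], traj.values[i], traj.gradients[i], H,
                    clip=clip,
                )
            )
        return cls(members, bounds, epsilon)

    def __call__(self, p) -> float:
        p = np.asarray(p, dtype=float)
        dists = np.array(
            [delta_p_norm(p, mem.p_star, self.bounds) for mem in self.members]
        )
        nearest = int(np.argmin(dists))
        if dists[nearest] <= self.epsilon:
            return self.members[nearest](p)
        weights = 1.0 / dists**2
        values = np.array([mem(p) for mem in self.members])
        return float(weights @ values / weights.sum())


def predict_direct(backend, p) -> float:
    """The backend objective itself — the zero-surrogate-error mode."""
    return float(backend.eval_objective(np.asarray(p, dtype=float)).value)
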