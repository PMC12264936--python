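"""Energy backends: the contract that supplies objective values and descriptors.

In production the objective ``F_virt(p)`` (a reaction or activation energy of
the virtual-ligand complex) and the descriptor map ``G_virt(p)`` (dissociation
energies of the VL against a fixed fragment set) come from quantum-chemical
calculations.  Both are smooth in the VL parameters, which is all the rest of
the pipeline relies on.  This module provides

* :class:`SyntheticSurfaceSpec` — a seeded analytic stand-in with the same
  smoothness structure: a positive-definite quadratic objective plus a small
  smooth bump (so a quadratic surrogate degrades with distance), and an
  affine descriptor map with an optional mild quadratic warp;
* :class:`FileBackend` — an interface-only adapter for externally computed
  single-point results.

All derivatives are analytic.  Identical seeds give bit-identical surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "BackendResult",
    "SyntheticSurfaceSpec",
    "SyntheticLigandSpec",
    "SyntheticLigand",
    "make_synthetic_ligand",
    "FileBackend",
]


@dataclass
class BackendResult:
    """Scalar objective value (kcal/mol) and its gradient w.r.t. ``p``."""

    value: float
    gradient: np.ndarray

    def __post_init__(self):
        self.gradient = np.asarray(self.gradient, dtype=float)
        if not (np.isfinite(self.value) and np.all(np.isfinite(self.gradient))):
            raise ValueError("backend returned non-finite result")


class SyntheticSurfaceSpec:
    """Seeded analytic ``F_virt``/``G_virt`` surfaces.

    Parameters
    ----------
    n, m : int
        Parameter and descriptor dimensions, ``m > n``.
    center : array-like, shape (n,), optional
        Location of the quadratic minimum of the objective.  Defaults to a
        seeded point near the middle of typical parameter ranges.
    quad_scale : float
        Typical curvature of the objective (kcal/mol per unit^2).
    bump_amplitude : float
        Amplitude of the smooth sinusoidal perturbation of the objective.
        ``0`` gives the exact-quadratic oracle mode.
    warp : float
        Amplitude of the quadratic warp of the descriptor map.  ``0`` gives
        the exact-affine oracle mode.
    offset : float
        Constant shift of the objective (kcal/mol), e.g. a reference energy.
    seed : int
        Seeds every random coefficient; surfaces are reproducible bit-for-bit.
    """

    def __init__(
        self,
        n: int = 3,
        m: int = 16,
        center=None,
        quad_scale: float = 10.0,
        bump_amplitude: float = 0.0,
        warp: float = 0.0,
        offset: float = 0.0,
        seed: int = 0,
    ):
        if m <= n:
            raise ValueError("descriptor dimension m must exceed n")
        self.n, self.m = int(n), int(m)
        self.bump_amplitude = float(bump_amplitude)
        self.warp = float(warp)
        self.offset = float(offset)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)

        if center is None:
            center = np.array([1.6, 2.75, 2.25])[:n] if n <= 3 else rng.uniform(
                1.0, 3.0, n
            )
        self.center = np.asarray(center, dtype=float)

        # positive-definite quadratic form A for the objective
        q = rng.standard_normal((n, n))
        self.A = quad_scale * (q @ q.T / n + np.eye(n))
        # smooth bump: amplitude * sin(w.p + phase)
        self.bump_w = rng.uniform(1.0, 2.0, n)
        self.bump_phase = float(rng.uniform(0, 2 * np.pi))
        # affine descriptor map x = M p + b (+ warp)
        self.M = rng.standard_normal((self.m, n)) * 3.0
        self.b = rng.standard_normal(self.m) * 2.0
        # per-output quadratic warp coefficients
        w = rng.standard_normal((self.m, n, n))
        self.W = 0.5 * (w + np.transpose(w, (0, 2, 1)))

    # -- objective -------------------------------------------------------
    def eval_objective(self, p) -> BackendResult:
        """Value and analytic gradient of the synthetic ``F_virt`` at ``p``."""
        p = np.asarray(p, dtype=float)
        dp = p - self.center
        value = self.offset + 0.5 * dp @ self.A @ dp
        grad = self.A @ dp
        if self.bump_amplitude:
            s = self.bump_w @ dp + self.bump_phase
            value += self.bump_amplitude * np.sin(s)
            grad = grad + self.bump_amplitude * np.cos(s) * self.bump_w
        return BackendResult(float(value), grad)

    def eval_descriptors(self, p):
        """Synthetic ``G_virt(p)`` (m-vector) and its exact Jacobian (m, n)."""
        p = np.asarray(p, dtype=float)
        dp = p - self.center
        x = self.M @ p + self.b
        jac = self.M.copy()
        if self.warp:
            x = x + self.warp * np.einsum("kij,i,j->k", self.W, dp, dp)
            jac = jac + 2.0 * self.warp * np.einsum("kij,j->ki", self.W, dp)
        return x, jac

    # convenience callables used throughout the pipeline
    def objective(self, p) -> float:
        return self.eval_objective(p).value

    def __repr__(self):
        return (
            f"SyntheticSurfaceSpec(n={self.n}, m={self.m}, "
            f"bump={self.bump_amplitude}, warp={self.warp}, seed={self.seed})"
        )


@dataclass
class SyntheticLigandSpec:
    """Recipe for a synthetic 'real ligand' descriptor vector.

    The descriptor is placed at ``G_virt(p_true)`` plus an offset of magnitude
    ``delta`` orthogonal to the tangent space of the surface at ``p_true`` —
    the component of a real ligand that no virtual ligand can reproduce.
    """

    p_true: np.ndarray
    delta: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.p_true = np.asarray(self.p_true, dtype=float)
        if self.delta < 0:
            raise ValueError("orthogonal offset delta must be >= 0")


@dataclass
class SyntheticLigand:
    """A generated descriptor vector with its ground truth attached."""

    x: np.ndarray
    p_true: np.ndarray
    delta: float


def make_synthetic_ligand(
    spec: SyntheticSurfaceSpec, lig: SyntheticLigandSpec
) -> SyntheticLigand:
    """Place a descriptor at ``G_virt(p_true) + delta * u``, ``u`` orthonormal
    to the local tangent space of the surface."""
    x0, jac = spec.eval_descriptors(lig.p_true)
    # orthonormal basis of the orthogonal complement of range(jac)
    q, _ = np.linalg.qr(jac, mode="complete")
    null_basis = q[:, np.linalg.matrix_rank(jac):]
    rng = np.random.default_rng(lig.seed)
    coeff = rng.standard_normal(null_basis.shape[1])
    u = null_basis @ (coeff / np.linalg.norm(coeff))
    return SyntheticLigand(x0 + lig.delta * u, lig.p_true.copy(), lig.delta)


class FileBackend:
    """Adapter for precomputed single-point results (interface only).

    Maps a parameter vector to results read from files produced by an
    external electronic-structure code.  Only the contract is defined here;
    instantiating it requires user-supplied tables.
    """

    def __init__(self, objective_table=None, descriptor_table=None):
        self.objective_table = objective_table
        self.descriptor_table = descriptor_table

    def eval_objective(self, p) -> BackendResult:  # pragma: no cover
        raise NotImplementedError(
            "FileBackend requires externally computed tables"
        )

    def eval_descriptors(self, p):  # pragma: no cover
        raise NotImplementedError(
            "FileBackend requires externally computed tables"
        )
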