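"""The virtual ligand: parameters, fixed settings and penalty-function energies.

A virtual ligand replaces the three substituents of a phosphine PR3 by Cl
pseudo-atoms (``Cl*``) whose electronic and steric character is imposed by
three penalty terms added to the energy of the resulting PCl*3 fragment:

* a *keep potential* — harmonic restraint on each P–Cl* distance toward an
  equilibrium value ``r0`` (electronic tuning knob),
* a *keep-angle potential* — harmonic restraint on each Cl*–P–Cl* angle
  toward ``phi0`` (held fixed here),
* an *ovoid Lennard-Jones potential* — a steric wall built from an
  ovoid surface aligned with each P–Cl* axis, whose transverse half-axes
  ``a1`` (width) and ``b1`` (thickness) are the steric tuning knobs.

Only ``p = (r0, a1, b1)`` is variable; all other geometric settings are held
at fixed defaults.  Units are kcal/mol, Angstrom and degrees throughout.

The concrete ovoid functional form is isolated behind
:func:`ovoid_lj_energy` so it can be swapped without touching callers: the
ovoid is a piecewise ellipsoidal closed surface with transverse half-axes
``(a1, a2)`` and ``(b1, b2)``, axial half-lengths ``(c1, c2)``, centered a
distance ``d`` from P along each P–Cl* axis.  Each environment atom at scaled
radius ``rho`` (``rho = 1`` on the surface) contributes a 12-6 potential
``eps * (rho**-12 - 2 * rho**-6)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._jet import Jet, seed_jets

__all__ = [
    "VLParams",
    "FixedVLSettings",
    "ParamBounds",
    "EnergyResult",
    "keep_energy",
    "keep_angle_energy",
    "ovoid_lj_energy",
    "vl_penalty_energy",
    "DegenerateGeometryError",
]


class DegenerateGeometryError(ValueError):
    """Raised for geometries where an energy term is not differentiable."""


@dataclass(frozen=True)
class VLParams:
    """The variable virtual-ligand parameter vector ``p = (r0, a1, b1)``.

    r0 : equilibrium P–Cl* distance (Angstrom), electronic knob.
    a1 : ovoid width half-axis (Angstrom), steric knob.
    b1 : ovoid thickness half-axis (Angstrom), steric knob.
    """

    r0: float
    a1: float
    b1: float

    def __post_init__(self):
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("VL parameters must be finite")
        if np.any(arr <= 0):
            raise ValueError("VL parameters must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.r0, self.a1, self.b1], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "VLParams":
        r0, a1, b1 = np.asarray(arr, dtype=float)
        return cls(float(r0), float(a1), float(b1))

    names = ("r0", "a1", "b1")


@dataclass(frozen=True)
class FixedVLSettings:
    """Settings held constant during optimization.

    ``a2``/``b2`` default to ``None``, meaning the symmetric-substituent mode
    is active and they follow ``a1``/``b1`` (including in derivatives).
    """

    phi0: float = 65.0          # equilibrium Cl*-P-Cl* angle (deg)
    a2: Optional[float] = None  # mirror width half-axis (A); None -> = a1
    b2: Optional[float] = None  # mirror thickness half-axis (A); None -> = b1
    c1: float = 3.0             # ovoid forward half-length (A)
    c2: float = 3.0             # ovoid backward half-length (A)
    d: float = 3.0              # ovoid-center offset from P (A)
    k_keep: float = 100.0       # kcal/mol/A^2
    k_angle: float = 0.1        # kcal/mol/deg^2
    lj_epsilon: float = 0.1     # kcal/mol

    @property
    def symmetric(self) -> bool:
        return self.a2 is None and self.b2 is None


@dataclass(frozen=True)
class ParamBounds:
    """Componentwise accessible range ``[lower, upper]`` of the VL parameters."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape:
            raise ValueError("bound shapes differ")
        if not np.all(self.upper - self.lower > 0):
            raise ValueError("bounds must satisfy lower < upper componentwise")

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    def contains(self, p, margin: float = 0.0) -> bool:
        p = np.asarray(p, dtype=float)
        return bool(
            np.all(p >= self.lower - margin) and np.all(p <= self.upper + margin)
        )


#: Parameter ranges used for the barrier function and the normalized
#: deviation metric in the phosphine screening study.
DEFAULT_BOUNDS = ParamBounds(np.array([1.3, 2.0, 1.5]), np.array([1.9, 3.5, 3.0]))

#: Expanded ranges enclosing every database ligand.
EXPANDED_BOUNDS = ParamBounds(np.array([1.0, 1.5, 0.5]), np.array([2.2, 5.5, 2.5]))


@dataclass
class EnergyResult:
    """Energy with gradients w.r.t. Cartesian coordinates and (a1, b1)."""

    energy: float
    grad_coords: np.ndarray                 # (n_atoms, 3)
    grad_params: np.ndarray = field(
        default_factory=lambda: np.zeros(2)
    )                                        # d/d(a1, b1)

    def __add__(self, other: "EnergyResult") -> "EnergyResult":
        return EnergyResult(
            self.energy + other.energy,
            self.grad_coords + other.grad_coords,
            self.grad_params + other.grad_params,
        )


def _pcl_pairs(geom):
    if len(geom.cl_indices) != 3:
        raise DegenerateGeometryError("three Cl* indices are required")
    return [(geom.p_index, i) for i in geom.cl_indices]


def keep_energy(geom, r0: float, k_keep: float = 100.0) -> EnergyResult:
    """Harmonic restraint ``sum_b k_keep (r_b - r0)^2`` on the P–Cl* bonds."""
    grad = np.zeros_like(geom.coords)
    energy = 0.0
    for ip, icl in _pcl_pairs(geom):
        v = geom.coords[icl] - geom.coords[ip]
        r = float(np.linalg.norm(v))
        if r == 0.0:
            raise DegenerateGeometryError("coincident P and Cl* atoms")
        energy += k_keep * (r - r0) ** 2
        dEdr = 2.0 * k_keep * (r - r0)
        u = v / r
        grad[icl] += dEdr * u
        grad[ip] -= dEdr * u
    return EnergyResult(energy, grad)


def keep_angle_energy(geom, phi0: float = 65.0, k_angle: float = 0.1) -> EnergyResult:
    """Harmonic restraint ``sum_a k_angle (phi_a - phi0)^2`` on Cl*–P–Cl* angles.

    Angles are in degrees.  Collinear Cl*–P–Cl* configurations have an
    undefined angle derivative and raise :class:`DegenerateGeometryError`.
    """
    grad = np.zeros_like(geom.coords)
    energy = 0.0
    ip = geom.p_index
    cls_ = geom.cl_indices
    deg = 180.0 / np.pi
    for k in range(3):
        ia, ib = cls_[k], cls_[(k + 1) % 3]
        u = geom.coords[ia] - geom.coords[ip]
        v = geom.coords[ib] - geom.coords[ip]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        uh, vh = u / nu, v / nv
        c = float(np.clip(uh @ vh, -1.0, 1.0))
        s = np.sqrt(max(1.0 - c * c, 0.0))
        if s < 1e-8:
            raise DegenerateGeometryError("collinear Cl*-P-Cl* configuration")
        phi = deg * np.arccos(c)
        energy += k_angle * (phi - phi0) ** 2
        dEdphi = 2.0 * k_angle * (phi - phi0) * deg  # chain rule deg->rad
        dphi_da = -(vh - c * uh) / (nu * s)
        dphi_db = -(uh - c * vh) / (nv * s)
        grad[ia] += dEdphi * dphi_da
        grad[ib] += dEdphi * dphi_db
        grad[ip] -= dEdphi * (dphi_da + dphi_db)
    return EnergyResult(energy, grad)


def _unit(j: Jet) -> Jet:
    return j / j.norm()


def ovoid_lj_energy(
    geom, params: VLParams, settings: FixedVLSettings = FixedVLSettings()
) -> EnergyResult:
    """Ovoid-based steric potential summed over environment atoms.

    One ovoid is attached to each P–Cl* axis.  The local frame is derived
    from the geometry itself (axis = P→Cl*, width direction = in-plane
    component of the other two P–Cl* directions), so the energy is invariant
    under rigid motions.  Derivatives w.r.t. all coordinates and w.r.t.
    ``(a1, b1)`` are exact (forward-mode differentiation).
    """
    n = geom.n_atoms
    nvars = 3 * n + 2
    vars_ = np.concatenate([geom.coords.ravel(), [params.a1, params.b1]])
    jets = seed_jets(vars_)

    def atom(i) -> Jet:
        return Jet.stack([jets[3 * i], jets[3 * i + 1], jets[3 * i + 2]])

    a1 = jets[3 * n]
    b1 = jets[3 * n + 1]
    if settings.symmetric:
        a2, b2 = a1, b1
    else:
        a2 = Jet.constant(settings.a2, nvars)
        b2 = Jet.constant(settings.b2, nvars)
    eps = settings.lj_epsilon

    if not geom.env_indices:
        return EnergyResult(0.0, np.zeros_like(geom.coords), np.zeros(2))

    p_atom = atom(geom.p_index)
    cl_atoms = [atom(i) for i in geom.cl_indices]
    energy = Jet.constant(0.0, nvars)

    for k in range(3):
        u = _unit(cl_atoms[k] - p_atom)
        w = Jet.constant(np.zeros(3), nvars)
        for j in range(3):
            if j != k:
                w = w + _unit(cl_atoms[j] - p_atom)
        w_perp = w - u * w.dot(u)
        if w_perp.norm().val < 1e-10:
            raise DegenerateGeometryError(
                "Cl* atoms collinear: ovoid frame undefined"
            )
        e1 = _unit(w_perp)
        e2 = u.cross(e1)
        center = p_atom + u * settings.d

        for ie in geom.env_indices:
            q = atom(ie) - center
            if q.norm().val < 1e-8:
                raise DegenerateGeometryError(
                    f"environment atom {ie} coincides with ovoid center"
                )
            x, y, z = q.dot(e1), q.dot(e2), q.dot(u)
            ax = a1 if x.val >= 0 else a2
            by = b1 if y.val >= 0 else b2
            cz = settings.c1 if z.val >= 0 else settings.c2
            rho2 = (x / ax) ** 2 + (y / by) ** 2 + (z / cz) ** 2
            inv6 = rho2 ** -3
            energy = energy + (inv6 * inv6 - inv6 * 2.0) * eps

    grad = energy.jac
    return EnergyResult(
        float(energy.val),
        grad[: 3 * n].reshape(n, 3),
        grad[3 * n:].copy(),
    )


def vl_penalty_energy(
    geom, params: VLParams, settings: FixedVLSettings = FixedVLSettings()
) -> EnergyResult:
    """Total penalty energy: keep + keep-angle + ovoid LJ (gradients additive)."""
    total = keep_energy(geom, params.r0, settings.k_keep)
    total = total + keep_angle_energy(geom, settings.phi0, settings.k_angle)
    total = total + ovoid_lj_energy(geom, params, settings)
    return total
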