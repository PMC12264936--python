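"""Penalty-function energies of the virtual ligand: values and exact gradients."""

import numpy as np
import pytest

from conftest import make_pcl3_geometry
from vligand.geometry import MolecularGeometry
from vligand.vl_model import (
    DegenerateGeometryError,
    FixedVLSettings,
    ParamBounds,
    VLParams,
    keep_angle_energy,
    keep_energy,
    ovoid_lj_energy,
    vl_penalty_energy,
)


def fd_coord_gradient(energy_of_coords, coords, h=1e-5):
    g = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for j in range(3):
            cp, cm = coords.copy(), coords.copy()
            cp[i, j] += h
            cm[i, j] -= h
            g[i, j] = (energy_of_coords(cp) - energy_of_coords(cm)) / (2 * h)
    return g


def equilateral_pcl3(r=1.6, phi_deg=65.0):
    """PCl*3 with all bonds at r and all Cl-P-Cl angles equal to phi."""
    # place Cl atoms symmetrically on a cone about z with half-angle theta:
    # angle between any two Cl directions is phi  =>
    # cos(phi) = cos^2(theta) + sin^2(theta) * cos(120 deg)
    phi = np.radians(phi_deg)
    cos_theta_sq = (np.cos(phi) + 0.5) / 1.5
    theta = np.arccos(np.sqrt(cos_theta_sq))
    cl = []
    for k in range(3):
        az = 2 * np.pi * k / 3
        cl.append(
            r * np.array([
                np.sin(theta) * np.cos(az),
                np.sin(theta) * np.sin(az),
                np.cos(theta),
            ])
        )
    coords = np.vstack([np.zeros(3), cl])
    return MolecularGeometry(["P", "Cl", "Cl", "Cl"], coords, 0, (1, 2, 3))


class TestKeepPotential:
    def test_zero_at_equilibrium(self):
        geom = equilateral_pcl3(r=1.7)
        res = keep_energy(geom, r0=1.7, k_keep=100.0)
        assert res.energy == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(res.grad_coords, 0.0, atol=1e-12)

    def test_single_bond_displacement(self):
        geom = equilateral_pcl3(r=1.6)
        coords = geom.coords.copy()
        delta = 0.13
        u = coords[1] / np.linalg.norm(coords[1])
        coords[1] = coords[1] + delta * u
        geom2 = MolecularGeometry(geom.symbols, coords, 0, (1, 2, 3))
        res = keep_energy(geom2, r0=1.6, k_keep=100.0)
        assert res.energy == pytest.approx(100.0 * delta**2, rel=1e-12)

    def test_gradient_matches_finite_difference(self, pcl3_geometry):
        res = keep_energy(pcl3_geometry, r0=1.5, k_keep=100.0)
        fd = fd_coord_gradient(
            lambda c: keep_energy(
                MolecularGeometry(pcl3_geometry.symbols, c, 0, (1, 2, 3)),
                r0=1.5, k_keep=100.0,
            ).energy,
            pcl3_geometry.coords,
        )
        scale = np.abs(fd).max()
        assert np.abs(res.grad_coords - fd).max() / scale < 1e-6


class TestKeepAnglePotential:
    def test_zero_at_equilibrium_angle(self):
        geom = equilateral_pcl3(phi_deg=65.0)
        res = keep_angle_energy(geom, phi0=65.0, k_angle=0.1)
        assert res.energy == pytest.approx(0.0, abs=1e-18)

    def test_single_angle_displacement(self):
        # rotating one Cl about the axis normal to the plane of (Cl1, P, Cl2)
        # changes exactly the angles involving that Cl; use a planar probe
        coords = np.array([
            [0.0, 0.0, 0.0],      # P
            [1.6, 0.0, 0.0],      # Cl1
            [1.6 * np.cos(np.radians(70.0)), 1.6 * np.sin(np.radians(70.0)), 0.0],
            [0.3, -0.5, 1.5],     # Cl3 out of plane
        ])
        geom = MolecularGeometry(["P", "Cl", "Cl", "Cl"], coords, 0, (1, 2, 3))
        res65 = keep_angle_energy(geom, phi0=65.0, k_angle=0.1)
        # recompute the two out-of-plane angles directly for reference
        def angle(i, j):
            u = coords[i] / np.linalg.norm(coords[i])
            v = coords[j] / np.linalg.norm(coords[j])
            return np.degrees(np.arccos(u @ v))
        expected = 0.1 * (
            (70.0 - 65.0) ** 2
            + (angle(2, 3) - 65.0) ** 2
            + (angle(3, 1) - 65.0) ** 2
        )
        assert res65.energy == pytest.approx(expected, rel=1e-10)

    def test_gradient_matches_finite_difference(self, pcl3_geometry):
        res = keep_angle_energy(pcl3_geometry, phi0=65.0, k_angle=0.1)
        fd = fd_coord_gradient(
            lambda c: keep_angle_energy(
                MolecularGeometry(pcl3_geometry.symbols, c, 0, (1, 2, 3)),
                phi0=65.0, k_angle=0.1,
            ).energy,
            pcl3_geometry.coords,
        )
        scale = np.abs(fd).max()
        assert np.abs(res.grad_coords - fd).max() / scale < 1e-6

    def test_collinear_configuration_is_degenerate(self):
        coords = np.array([
            [0.0, 0.0, 0.0],
            [1.6, 0.0, 0.0],
            [-1.6, 0.0, 0.0],   # collinear with Cl1 through P
            [0.0, 1.6, 0.0],
        ])
        geom = MolecularGeometry(["P", "Cl", "Cl", "Cl"], coords, 0, (1, 2, 3))
        with pytest.raises(DegenerateGeometryError):
            keep_angle_energy(geom)


class TestOvoidLJ:
    params = VLParams(1.6, 2.5, 1.2)

    def test_no_environment_atoms_gives_zero(self):
        geom = equilateral_pcl3()
        res = ovoid_lj_energy(geom, self.params)
        assert res.energy == 0.0
        assert np.all(res.grad_coords == 0.0)
        assert np.all(res.grad_params == 0.0)

    def test_mirror_symmetric_atoms_contribute_equally(self):
        # P at origin, Cl1 along +z; Cl2/Cl3 a mirror pair across the xz=0
        # plane -> the whole core is symmetric under x -> -x, so two
        # environment atoms mirrored in that plane must have equal energies.
        core = np.array([
            [0.0, 0.0, 0.0],
            [0.0, 0.0, 1.6],
            [1.5, 0.3, -0.5],
            [-1.5, 0.3, -0.5],
        ])
        symbols = ["P", "Cl", "Cl", "Cl", "C"]
        e = []
        for sx in (+1.0, -1.0):
            coords = np.vstack([core, [[sx * 1.2, 0.8, 2.5]]])
            geom = MolecularGeometry(symbols, coords, 0, (1, 2, 3))
            e.append(ovoid_lj_energy(geom, self.params).energy)
        assert e[0] == pytest.approx(e[1], rel=1e-12)

    def test_gradients_match_finite_difference(self, pcl3_geometry):
        res = ovoid_lj_energy(pcl3_geometry, self.params)
        fd = fd_coord_gradient(
            lambda c: ovoid_lj_energy(
                MolecularGeometry(pcl3_geometry.symbols, c, 0, (1, 2, 3)),
                self.params,
            ).energy,
            pcl3_geometry.coords,
        )
        scale = max(np.abs(fd).max(), 1e-12)
        assert np.abs(res.grad_coords - fd).max() / scale < 1e-5

        h = 1e-5
        for k, (da, db) in enumerate([(h, 0.0), (0.0, h)]):
            ep = ovoid_lj_energy(
                pcl3_geometry, VLParams(1.6, 2.5 + da, 1.2 + db)
            ).energy
            em = ovoid_lj_energy(
                pcl3_geometry, VLParams(1.6, 2.5 - da, 1.2 - db)
            ).energy
            fd_k = (ep - em) / (2 * h)
            assert res.grad_params[k] == pytest.approx(fd_k, rel=1e-5)

    def test_atom_at_ovoid_center_is_singular(self):
        core = equilateral_pcl3()
        u = core.coords[1] / np.linalg.norm(core.coords[1])
        center = 3.0 * u  # settings.d along the first axis
        coords = np.vstack([core.coords, [center]])
        geom = MolecularGeometry(core.symbols + ["C"], coords, 0, (1, 2, 3))
        with pytest.raises(DegenerateGeometryError):
            ovoid_lj_energy(geom, self.params)


class TestTotalPenalty:
    def test_zero_at_equilibrium_without_environment(self):
        geom = equilateral_pcl3(r=1.6, phi_deg=65.0)
        res = vl_penalty_energy(geom, VLParams(1.6, 2.5, 1.2))
        assert res.energy == pytest.approx(0.0, abs=1e-18)

    def test_additivity_of_terms(self, pcl3_geometry):
        params = VLParams(1.5, 2.2, 1.4)
        settings = FixedVLSettings()
        total = vl_penalty_energy(pcl3_geometry, params, settings)
        parts = (
            keep_energy(pcl3_geometry, params.r0, settings.k_keep).energy
            + keep_angle_energy(pcl3_geometry, settings.phi0, settings.k_angle).energy
            + ovoid_lj_energy(pcl3_geometry, params, settings).energy
        )
        assert total.energy == pytest.approx(parts, abs=1e-14)

    def test_keep_stiffness_scales_only_keep_term(self, pcl3_geometry):
        params = VLParams(1.5, 2.2, 1.4)
        s1 = FixedVLSettings(k_keep=100.0)
        s2 = FixedVLSettings(k_keep=200.0)
        e1 = vl_penalty_energy(pcl3_geometry, params, s1).energy
        e2 = vl_penalty_energy(pcl3_geometry, params, s2).energy
        keep = keep_energy(pcl3_geometry, params.r0, 100.0).energy
        assert e2 - e1 == pytest.approx(keep, rel=1e-10)

    def test_rigid_motion_invariance(self, pcl3_geometry):
        params = VLParams(1.5, 2.2, 1.4)
        e0 = vl_penalty_energy(pcl3_geometry, params).energy
        # rotation about an arbitrary axis + translation
        axis = np.array([0.3, -1.2, 0.7])
        theta = np.linalg.norm(axis)
        k = axis / theta
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
        moved = pcl3_geometry.transformed(R, [1.0, -2.0, 0.5])
        e1 = vl_penalty_energy(moved, params).energy
        assert abs(e1 - e0) < 1e-9


class TestDomainTypes:
    def test_vlparams_reject_nonpositive_and_nonfinite(self):
        with pytest.raises(ValueError):
            VLParams(-1.0, 2.0, 1.0)
        with pytest.raises(ValueError):
            VLParams(np.nan, 2.0, 1.0)

    def test_bounds_require_positive_width(self):
        with pytest.raises(ValueError):
            ParamBounds(np.array([1.0, 2.0]), np.array([1.0, 3.0]))

    def test_geometry_requires_three_distinct_cl(self):
        coords = np.zeros((4, 3))
        coords[1:] = np.eye(3)
        with pytest.raises(ValueError):
            MolecularGeometry(["P", "Cl", "Cl", "Cl"], coords, 0, (1, 2))
        with pytest.raises(ValueError):
            MolecularGeometry(["P", "Cl", "Cl", "Cl"], coords, 0, (0, 1, 2))
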