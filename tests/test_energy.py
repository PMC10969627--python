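"""Energy terms: closed forms, analytic gradients, invariances."""

import numpy as np
import pytest

from fullersim.bonds import assign_variant, formal_charges
from fullersim.cage import CageGraph
from fullersim.forcefield import (
    ForceFieldParams,
    MolecularSystem,
    bond_energy,
    nonbonded_energy,
    planarity_energy,
    total_energy,
)
from fullersim.synthetic import jittered_cage


@pytest.fixture(scope="module")
def params():
    return ForceFieldParams()


def _fd_gradient(fun, x, h=1e-6):
    g = np.zeros_like(x)
    for i in range(x.shape[0]):
        for k in range(3):
            xp = x.copy()
            xp[i, k] += h
            xm = x.copy()
            xm[i, k] -= h
            g[i, k] = (fun(xp) - fun(xm)) / (2 * h)
    return g


class TestBondEnergy:
    def test_equilibrium_is_zero(self, params):
        x = np.array([[0.0, 0, 0], [params.r0_of(1), 0, 0]])
        e, g = bond_energy(x, [(0, 1)], [1], params)
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(g, 0.0, atol=1e-12)

    def test_closed_form_displacement(self):
        # 0.1 A stretch at k = 500 gives 1/2 * 500 * 0.01 = 2.5 kJ/mol
        p = ForceFieldParams(k1=500.0, k2=500.0)
        x = np.array([[0.0, 0, 0], [p.r0_of(1) + 0.1, 0, 0]])
        e, _ = bond_energy(x, [(0, 1)], [1], p)
        assert e == pytest.approx(2.5, rel=1e-12)

    def test_gradient_matches_finite_differences(self, params):
        rng = np.random.default_rng(5)
        x = np.cumsum(rng.normal(1.0, 0.1, size=(10, 3)), axis=0)
        edges = [(i, i + 1) for i in range(9)]
        orders = [1 + (i % 2) for i in range(9)]
        e, g = bond_energy(x, edges, orders, params)
        fd = _fd_gradient(lambda y: bond_energy(y, edges, orders, params)[0], x)
        assert np.linalg.norm(g - fd) / np.linalg.norm(fd) < 1e-6

    def test_zero_length_bond_raises(self, params):
        x = np.zeros((2, 3))
        with pytest.raises(ValueError):
            bond_energy(x, [(0, 1)], [1], params)

    def test_convex_around_r0(self, params):
        r0 = params.r0_of(1)
        energies = [
            bond_energy(
                np.array([[0.0, 0, 0], [r0 + d, 0, 0]]), [(0, 1)], [1], params
            )[0]
            for d in (-0.05, 0.0, 0.05)
        ]
        assert energies[1] < energies[0] and energies[1] < energies[2]


class TestPlanarityEnergy:
    @staticmethod
    def _star():
        # central atom 0 bonded to 1, 2, 3; spectators keep 3-regularity
        edges = [(0, 1), (0, 2), (0, 3), (1, 2), (2, 3), (1, 3)]
        return CageGraph(n_atoms=4, edges=edges)

    def test_in_plane_atom_contributes_zero(self, params):
        g = self._star()
        x = np.array([[0.0, 0, 0], [1, 0, 0], [-0.5, 0.9, 0], [-0.5, -0.9, 0]])
        e, _ = planarity_energy(x, g, params)
        assert e == pytest.approx(0.0, abs=1e-18)

    def test_perpendicular_displacement_closed_form(self):
        # 0.2 A out of plane at l_p = 100 gives 1/2 * 100 * 0.04 = 2 kJ/mol
        p = ForceFieldParams(lp=100.0)
        g = self._star()
        x = np.array([[0.0, 0, 0.2], [1, 0, 0], [-0.5, 0.9, 0], [-0.5, -0.9, 0]])
        e, _ = planarity_energy(x, g, p)
        # every atom's neighbor plane contributes; isolate atom 0 by
        # comparing against the flat configuration
        x_flat = x.copy()
        x_flat[0, 2] = 0.0
        e_flat, _ = planarity_energy(x_flat, g, p)
        assert e >= 2.0 - 1e-9  # atom 0 alone contributes 2 kJ/mol

    def test_gradient_on_jittered_cage(self, c60, params):
        geometry, graph = c60
        x = jittered_cage(geometry, 0.03, 7)
        e, g = planarity_energy(x, graph, params)
        fd = _fd_gradient(lambda y: planarity_energy(y, graph, params)[0], x)
        assert np.linalg.norm(g - fd) / np.linalg.norm(fd) < 1e-6

    def test_collinear_neighbors_raise(self, params):
        g = self._star()
        x = np.array([[0.0, 0, 1.0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError):
            planarity_energy(x, g, params)


class TestNonbondedEnergy:
    def test_zero_charges_zero_coulomb(self, c60, params):
        geometry, graph = c60
        (ev, ec), _ = nonbonded_energy(
            geometry.positions, graph, np.zeros(60), params
        )
        assert ec == 0.0

    def test_vdw_crossing_point(self, params):
        # the Born-Mayer curve crosses zero where A e^(-Br) = C r^-6
        from scipy.optimize import brentq

        f = lambda r: params.bm_A * np.exp(-params.bm_B * r) - params.bm_C / r**6
        r_cross = brentq(f, 2.0, 6.0)
        g = CageGraph(n_atoms=2, edges=[])
        x = np.array([[0.0, 0, 0], [r_cross, 0, 0]])
        (ev, ec), _ = nonbonded_energy(x, g, np.zeros(2), params)
        assert ev == pytest.approx(0.0, abs=1e-9)

    def test_gradient_with_charges(self, c60, params):
        geometry, graph = c60
        from fullersim.bonds import assign_variant

        a = assign_variant(graph, "FB3")
        q = formal_charges(a, graph, "increment").charges
        x = jittered_cage(geometry, 0.03, 9)
        (ev, ec), g = nonbonded_energy(x, graph, q, params)
        fd = _fd_gradient(
            lambda y: sum(nonbonded_energy(y, graph, q, params)[0]), x, h=1e-5
        )
        assert np.linalg.norm(g - fd) / np.linalg.norm(fd) < 1e-6

    def test_exclusions_skip_bonded_pairs(self, c60, params):
        # with 1-3 policy no pair closer than ~2.8 A contributes
        geometry, graph = c60
        system = MolecularSystem(graph, assign_variant(graph, "C60"), None,
                                 params, geometry.masses)
        d = np.linalg.norm(
            geometry.positions[system.pi] - geometry.positions[system.pj], axis=1
        )
        assert d.min() > 2.5


class TestTotalEnergy:
    def test_breakdown_sums(self, c60, params):
        geometry, graph = c60
        a = assign_variant(graph, "FB2")
        q = formal_charges(a, graph, "increment").charges
        x = jittered_cage(geometry, 0.05, 1)
        e, _ = total_energy(x, graph, a, q, params)
        assert e.total == pytest.approx(
            e.bond + e.planarity + e.vdw + e.coulomb, rel=1e-12
        )

    def test_ideal_cage_matched_r0_near_zero_bond_terms(self, c60):
        # r0(4/3) set to the built edge length: bond and planarity-free
        geometry, graph = c60
        p = ForceFieldParams(r0_1=1.44 + 0.064 / 3, r0_2=1.44 + 0.064 / 3 - 0.064)
        assert p.r0_of(4 / 3) == pytest.approx(1.44, abs=1e-12)
        a = assign_variant(graph, "C60")
        e, _ = total_energy(geometry.positions, graph, a, None, p)
        assert e.bond < 1e-9

    def test_rigid_motion_invariance(self, c60, params):
        from scipy.spatial.transform import Rotation

        geometry, graph = c60
        a = assign_variant(graph, "FB1")
        x = jittered_cage(geometry, 0.05, 2)
        e0, g0 = total_energy(x, graph, a, None, params)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        x2 = x @ rot.T + np.array([5.0, -3.0, 1.0])
        e1, _ = total_energy(x2, graph, a, None, params)
        assert e1.total == pytest.approx(e0.total, abs=1e-9)

    def test_net_force_vanishes(self, c60, params):
        geometry, graph = c60
        a = assign_variant(graph, "FB4")
        q = formal_charges(a, graph, "increment").charges
        x = jittered_cage(geometry, 0.05, 4)
        _, g = total_energy(x, graph, a, q, params)
        assert np.abs(g.sum(axis=0)).max() < 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_system_gradient_matches_fd_many_configs(self, c60, params, seed):
        # spot-check the fast compiled path on jittered configurations
        geometry, graph = c60
        a = assign_variant(graph, "FB3")
        q = formal_charges(a, graph, "increment").charges
        system = MolecularSystem(graph, a, q, params, geometry.masses)
        x = jittered_cage(geometry, 0.05, 100 + seed)
        e, g = system.energy_grad(x)
        rng = np.random.default_rng(seed)
        # random directional derivative instead of full 180-dim FD
        d = rng.normal(size=x.shape)
        d /= np.linalg.norm(d)
        h = 1e-6
        fd = (system.energy_grad(x + h * d)[0].total
              - system.energy_grad(x - h * d)[0].total) / (2 * h)
        assert fd == pytest.approx(float((g * d).sum()), rel=1e-5)


class TestForceFieldParams:
    def test_interpolation_anchors(self, params):
        assert params.r0_of(1) == 1.455
        assert params.r0_of(2) == 1.391
        assert params.r0_of(4 / 3) == pytest.approx(1.4337, abs=1e-4)
        assert params.r0_of(1.5) == pytest.approx(1.423, abs=1e-12)
        assert params.k_of(1.5) == pytest.approx(2400.0)

    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            ForceFieldParams(k1=3200, k2=1600)
        with pytest.raises(ValueError):
            ForceFieldParams(r0_1=1.39, r0_2=1.46)

    def test_config_round_trip(self, tmp_path, params):
        path = tmp_path / "ff.yaml"
        custom = params.replace(lp=250.0, bm_B=4.0)
        custom.to_file(path)
        assert ForceFieldParams.from_file(path) == custom

    def test_unknown_section_rejected(self):
        with pytest.raises(ValueError):
            ForceFieldParams.from_sections({"torsions": {"k": 1.0}})
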