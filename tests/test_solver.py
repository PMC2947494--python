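"""Operator assembly, slab profile, boundary conditions, solve, energies."""

import math

import numpy as np
import pytest

import memslab as m
from memslab.grids import GridSpec, ScalarGrid
from memslab.solver import (
    LevelMaps,
    SlabProfileParams,
    assemble_operator,
    boundary_values,
    energy,
    focus_ladder,
    slab_profile,
    solve,
)
from memslab.structure import Atom, Structure

C = m.CONSTANTS_298


def ion_at(pos=(0.0, 0.0, 0.0), q=1.0, r=2.0):
    return Structure([Atom(1, "K", "ION", 1, np.array(pos, float), q, r)])


def uniform_maps(g, eps=80.0, acc=0.0):
    return ScalarGrid.full(g, eps), ScalarGrid.full(g, acc)


class TestOperator:
    def test_linear_function_in_kernel(self):
        # uniform eps, no screening: a field linear in z solves the discrete
        # equation exactly, so solving with linear boundary data returns it
        g = GridSpec.from_center_length((0, 0, 0), 10.0, 9)
        diel, kappa = uniform_maps(g)
        op = assemble_operator(diel, kappa, 0.0)
        z = g.meshgrid()[2]
        lin = 0.3 * z + 1.0
        bv = lin.copy()
        phi, _ = solve(op, ScalarGrid.full(g, 0.0), bv, tol=1e-10)
        assert np.allclose(phi.values, lin, atol=1e-8)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        g = GridSpec.from_center_length((0, 0, 0), 6.0, 7)
        diel = ScalarGrid(g, rng.uniform(2, 80, g.shape))
        kappa = ScalarGrid(g, (rng.uniform(0, 1, g.shape) > 0.5).astype(float))
        A = assemble_operator(diel, kappa, 0.5).matrix
        u = rng.standard_normal(A.shape[0])
        v = rng.standard_normal(A.shape[0])
        assert np.dot(A @ u, v) == pytest.approx(np.dot(u, A @ v), rel=1e-12)

    def test_matches_dense_flux_balance_assembly(self):
        # independent dense assembly from the flux-balance formula on 5^3
        rng = np.random.default_rng(11)
        g = GridSpec((5, 5, 5), np.zeros(3), np.array([1.0, 1.2, 0.8]))
        eps = rng.uniform(1, 80, g.shape)
        acc = (rng.uniform(0, 1, g.shape) > 0.4).astype(float)
        kbar2 = 0.7
        op = assemble_operator(ScalarGrid(g, eps), ScalarGrid(g, acc), kbar2)
        hx, hy, hz = g.spacing
        vol = g.voxel_volume

        def hmean(a, b):
            return 2 * a * b / (a + b)

        interior = [(i, j, k) for i in range(1, 4) for j in range(1, 4) for k in range(1, 4)]
        index = {ijk: n for n, ijk in enumerate(interior)}
        dense = np.zeros((27, 27))
        for (i, j, k), row in index.items():
            for axis, (di, dj, dk), area_over_d in (
                (0, (1, 0, 0), hy * hz / hx),
                (1, (0, 1, 0), hx * hz / hy),
                (2, (0, 0, 1), hx * hy / hz),
            ):
                for sgn in (+1, -1):
                    nb = (i + sgn * di, j + sgn * dj, k + sgn * dk)
                    cond = hmean(eps[i, j, k], eps[nb]) * area_over_d
                    dense[row, row] += cond
                    if nb in index:
                        dense[row, index[nb]] -= cond
            dense[row, row] += kbar2 * acc[i, j, k] * vol
        assert np.allclose(op.matrix.toarray(), dense, rtol=1e-12)

    def test_incongruent_grids_rejected(self):
        g1 = GridSpec.from_center_length((0, 0, 0), 10.0, 9)
        g2 = GridSpec.from_center_length((0, 0, 0), 12.0, 9)
        with pytest.raises(ValueError):
            assemble_operator(ScalarGrid.full(g1, 80.0), ScalarGrid.full(g2, 1.0), 0.0)


class TestSlabProfile:
    def setup_method(self):
        self.kap = math.sqrt(m.debye_kappa2(m.default_counterions(0.1), 80.0))
        self.p = SlabProfileParams(-50.0, -14.0, 14.0, 2.0, 80.0, self.kap)

    def test_asymptotics(self):
        vbar = -50.0 * C.phi_per_mV
        assert slab_profile(1000.0, self.p) == pytest.approx(0.0, abs=1e-12)
        assert slab_profile(-1000.0, self.p) == pytest.approx(vbar, abs=1e-12)

    def test_symmetric_center_is_half_voltage(self):
        vbar = -50.0 * C.phi_per_mV
        assert slab_profile(0.0, self.p) == pytest.approx(vbar / 2, rel=1e-12)

    def test_continuity_at_faces(self):
        for zf in (-14.0, 14.0):
            lo = slab_profile(zf - 1e-9, self.p)
            hi = slab_profile(zf + 1e-9, self.p)
            assert lo == pytest.approx(hi, abs=1e-10)

    def test_against_1d_finite_difference_oracle(self):
        # independent two-point-boundary solve of the 1-D equation
        # d/dz(eps phi') - kbar^2(z) (phi - theta vbar) = 0
        vbar = -50.0 * C.phi_per_mV
        kbar2 = m.modified_kappa2(m.default_counterions(0.1))
        h = 0.05
        zmin = -150.025
        n = int(round(300.05 / h)) + 1
        z = zmin + h * np.arange(n)
        eps = np.where((z >= -14) & (z <= 14), 2.0, 80.0)
        inner = z < -14.0
        outer = z > 14.0
        k2 = np.where(inner | outer, kbar2, 0.0)
        face = 2 * eps[:-1] * eps[1:] / (eps[:-1] + eps[1:]) / h
        nin = n - 2
        main = face[:-1] + face[1:] + k2[1:-1] * h
        rhs = k2[1:-1] * h * np.where(inner[1:-1], vbar, 0.0)
        rhs[0] += face[0] * vbar  # phi(zmin) = vbar
        import scipy.sparse as sp
        import scipy.sparse.linalg as spla

        A = sp.diags([-face[1:-1], main, -face[1:-1]], [-1, 0, 1], format="csc")
        phi = spla.spsolve(A, rhs)
        zs = np.linspace(-40, 40, 20)
        ana = slab_profile(zs, self.p)
        num = np.interp(zs, z[1:-1], phi)
        assert np.all(np.abs(num - ana) <= 1e-3 * abs(vbar))


class TestBoundaryValues:
    def test_focus_exact_at_parent_nodes(self):
        parent_spec = GridSpec.from_center_length((0, 0, 0), 20.0, 11)
        rng = np.random.default_rng(3)
        parent = m.PotentialField(ScalarGrid(parent_spec, rng.standard_normal(parent_spec.shape)))
        child = GridSpec.from_center_length((0, 0, 0), 8.0, 5)  # nodes on parent nodes
        bv = boundary_values(child, "focus", parent=parent)
        # corner (−4,−4,−4) coincides with parent node (3,3,3)
        assert bv[0, 0, 0] == pytest.approx(parent.values[3, 3, 3], rel=1e-12)

    def test_focus_child_must_be_inside_parent(self):
        parent_spec = GridSpec.from_center_length((0, 0, 0), 20.0, 11)
        parent = m.PotentialField(ScalarGrid.full(parent_spec, 0.0))
        child = GridSpec.from_center_length((0, 0, 0), 40.0, 5)
        with pytest.raises(ValueError):
            boundary_values(child, "focus", parent=parent)

    def test_multiple_dh_reduces_to_single_for_one_atom(self):
        g = GridSpec.from_center_length((0, 0, 0), 40.0, 9)
        s = ion_at(q=1.0, r=2.0)
        kw = dict(structure=s, eps_solvent=80.0, kappa_bulk=0.1)
        b1 = boundary_values(g, "single_debye_huckel", **kw)
        b2 = boundary_values(g, "multiple_debye_huckel", **kw)
        assert np.allclose(b1, b2, atol=1e-14)

    def test_membrane_potential_faces_follow_slab_profile(self):
        kap = 0.103
        p = SlabProfileParams(-50.0, -14.0, 14.0, 2.0, 80.0, kap)
        g = GridSpec.from_center_length((0, 0, 0), 120.0, 9)
        bv = boundary_values(g, "membrane_potential", slab=p)
        vbar = -50.0 * C.phi_per_mV
        assert bv[4, 4, -1] == pytest.approx(slab_profile(60.0, p), rel=1e-12)
        assert bv[4, 4, 0] == pytest.approx(slab_profile(-60.0, p), rel=1e-12)
        # far faces sit near the asymptotic bath values
        assert abs(bv[4, 4, -1]) < 0.02 * abs(vbar)
        assert abs(bv[4, 4, 0] - vbar) < 0.02 * abs(vbar)


class TestSolve:
    def test_zero_everything_gives_zero(self):
        g = GridSpec.from_center_length((0, 0, 0), 10.0, 9)
        diel, kappa = uniform_maps(g)
        op = assemble_operator(diel, kappa, 0.0)
        phi, rec = solve(op, ScalarGrid.full(g, 0.0), np.zeros(g.shape))
        assert np.all(phi.values == 0.0)

    def test_superposition(self):
        g = GridSpec.from_center_length((0, 0, 0), 24.0, 25)
        diel, kappa = uniform_maps(g)
        op = assemble_operator(diel, kappa, 0.0)
        bv = np.zeros(g.shape)
        qa = m.spread_charges(ion_at((3, 0, 0)), g)
        qb = m.spread_charges(ion_at((-3, 1, 0)), g)
        qab = ScalarGrid(g, qa.values + qb.values)
        fa, _ = solve(op, qa, bv, tol=1e-10)
        fb, _ = solve(op, qb, bv, tol=1e-10)
        fab, _ = solve(op, qab, bv, tol=1e-10)
        assert np.allclose(fab.values, fa.values + fb.values, atol=1e-6)

    def test_discrete_maximum_principle(self):
        rng = np.random.default_rng(5)
        g = GridSpec.from_center_length((0, 0, 0), 10.0, 11)
        diel = ScalarGrid(g, rng.uniform(2, 80, g.shape))
        op = assemble_operator(diel, ScalarGrid.full(g, 0.0), 0.0)
        bv = np.zeros(g.shape)
        mask = np.zeros(g.shape, bool)
        for face in (np.s_[0, :, :], np.s_[-1, :, :], np.s_[:, 0, :], np.s_[:, -1, :],
                     np.s_[:, :, 0], np.s_[:, :, -1]):
            bv[face] = rng.uniform(-1.0, 2.0, bv[face].shape)
        phi, _ = solve(op, ScalarGrid.full(g, 0.0), bv, tol=1e-10)
        assert phi.values.min() >= -1.0 - 1e-8
        assert phi.values.max() <= 2.0 + 1e-8

    def test_nonconvergence_raises(self):
        g = GridSpec.from_center_length((0, 0, 0), 24.0, 25)
        diel, kappa = uniform_maps(g)
        op = assemble_operator(diel, kappa, 0.0)
        rho = m.spread_charges(ion_at(), g)
        with pytest.raises(m.ConvergenceError):
            solve(op, rho, np.zeros(g.shape), tol=1e-12, max_iterations=2)


class TestEnergy:
    def test_zero_field_zero_energy(self):
        g = GridSpec.from_center_length((0, 0, 0), 16.0, 9)
        phi = m.PotentialField(ScalarGrid.full(g, 0.0))
        rep = energy(phi, ion_at(), C)
        assert rep.kT == 0.0 and rep.kcal_per_mol == 0.0 and rep.kJ_per_mol == 0.0

    def test_unit_triple_consistency(self):
        rep = m.EnergyReport(kT=10.0)
        assert rep.kJ_per_mol == pytest.approx(4.184 * rep.kcal_per_mol, rel=1e-12)

    def test_total_scales_quadratically_interaction_linearly(self):
        g = GridSpec.from_center_length((0, 0, 0), 24.0, 25)
        diel, kappa = uniform_maps(g)
        op = assemble_operator(diel, kappa, 0.0)
        bv = np.zeros(g.shape)
        e = {}
        for a in (1.0, 2.0):
            rho = m.spread_charges(ion_at(q=a), g)
            phi, _ = solve(op, rho, bv, tol=1e-10)
            e[a] = energy(phi, rho, C, total=True).kT
        assert e[2.0] == pytest.approx(4.0 * e[1.0], rel=1e-6)

    def test_atom_outside_grid_rejected(self):
        g = GridSpec.from_center_length((0, 0, 0), 16.0, 9)
        phi = m.PotentialField(ScalarGrid.full(g, 1.0))
        with pytest.raises(ValueError):
            energy(phi, ion_at(pos=(30, 0, 0)), C)


class TestFocusLadder:
    def _levels(self, lengths, n, eps=80.0):
        s = ion_at()
        levels = []
        for L in lengths:
            g = GridSpec.from_center_length((0, 0, 0), L, n)
            diel = ScalarGrid.full(g, eps)
            kappa = ScalarGrid.full(g, 0.0)
            levels.append(LevelMaps(diel, kappa, m.spread_charges(s, g)))
        return s, levels

    def test_single_level_equals_direct_solve(self):
        s, levels = self._levels([40.0], 33)
        phi, recs = focus_ladder(levels, "single_debye_huckel", kbar2=0.0,
                                 structure=s, eps_solvent=80.0)
        bv = boundary_values(levels[0].spec, "single_debye_huckel",
                             structure=s, eps_solvent=80.0, kappa_bulk=0.0)
        op = assemble_operator(levels[0].diel, levels[0].kappa, 0.0)
        direct, _ = solve(op, levels[0].charge, bv)
        assert np.allclose(phi.values, direct.values, atol=1e-9)
        assert len(recs) == 1

    def test_two_level_energy_close_to_direct_fine_solve(self):
        s, levels = self._levels([80.0, 40.0], 41)
        phi2, _ = focus_ladder(levels, "single_debye_huckel", kbar2=0.0,
                               structure=s, eps_solvent=80.0)
        e2 = energy(phi2, levels[-1].charge, C).kT
        _, fine_only = self._levels([40.0], 41)
        phi1, _ = focus_ladder(fine_only, "single_debye_huckel", kbar2=0.0,
                               structure=s, eps_solvent=80.0)
        e1 = energy(phi1, fine_only[-1].charge, C).kT
        assert e2 == pytest.approx(e1, rel=0.01)

    def test_child_outside_parent_rejected(self):
        s, levels = self._levels([40.0, 60.0], 17)
        with pytest.raises(ValueError):
            focus_ladder(levels, "zero", kbar2=0.0, structure=s)

    def test_case1_style_ladder_runs_without_boundary_errors(self, helix):
        # 200 -> 100 -> 50 Å ladder holds the helix charges clear of every
        # fine-grid boundary
        levels = []
        for L in (200.0, 100.0, 50.0):
            g = GridSpec.from_center_length((0, 0, 0), L, 33)
            levels.append(LevelMaps(
                ScalarGrid.full(g, 80.0), ScalarGrid.full(g, 0.0),
                m.spread_charges(helix, g)))
        phi, recs = focus_ladder(levels, "multiple_debye_huckel", kbar2=0.0,
                                 structure=helix, eps_solvent=80.0)
        assert len(recs) == 3
        assert all(r.relative_residual <= 1e-6 for r in recs)
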