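"""Membrane slab insertion, exclusion cylinders, inner-space source."""

import numpy as np
import pytest

import memslab as m
from memslab.grids import GridSpec, ScalarGrid
from memslab.membrane import membrane_source_density
from memslab.structure import Atom, Structure


@pytest.fixture
def slab_geom():
    return m.MembraneGeometry(z_bottom=-14.0, thickness=28.0, eps_membrane=2.0)


@pytest.fixture
def water_maps():
    g = GridSpec.from_center_length((0, 0, 0), 80.0, 41)
    return ScalarGrid.full(g, 80.0), ScalarGrid.full(g, 1.0)


def node_at(g: GridSpec, xyz):
    return tuple(int(round(v)) for v in (np.array(xyz) - g.origin) / g.spacing)


class TestAddMembrane:
    def test_midplane_node_becomes_membrane(self, water_maps, slab_geom):
        diel, kappa = water_maps
        d2, k2 = m.add_membrane(diel, kappa, slab_geom, eps_protein=5.0)
        i = node_at(diel.spec, (20, 0, 0))
        assert d2.values[i] == 2.0
        assert k2.values[i] == 0.0

    def test_protein_nodes_untouched(self, water_maps, slab_geom):
        diel, kappa = water_maps
        diel.values[20, 20, 20] = 5.0  # a protein node at the origin (mid-slab)
        d2, _ = m.add_membrane(diel, kappa, slab_geom, eps_protein=5.0)
        assert d2.values[20, 20, 20] == 5.0

    def test_exclusion_cylinder_keeps_lumen_water(self, water_maps):
        diel, kappa = water_maps
        geom = m.MembraneGeometry(
            z_bottom=-12.0, thickness=24.0,
            upper_exclusion_radius=24.0, lower_exclusion_radius=16.0,
        )
        d2, k2 = m.add_membrane(diel, kappa, geom, eps_protein=5.0)
        on_axis = node_at(diel.spec, (0, 0, 0))
        assert d2.values[on_axis] == 80.0
        assert k2.values[on_axis] == 1.0
        far = node_at(diel.spec, (30, 0, 0))
        assert d2.values[far] == 2.0

    def test_headgroup_layers(self, water_maps):
        diel, kappa = water_maps
        geom = m.MembraneGeometry(
            z_bottom=-21.0, thickness=42.0, eps_membrane=2.0,
            eps_headgroup=80.0, headgroup_thickness=8.0,
        )
        d2, k2 = m.add_membrane(diel, kappa, geom, eps_protein=5.0)
        hg = node_at(diel.spec, (10, 0, 17))  # 4 Å below the top face
        assert d2.values[hg] == 80.0
        assert k2.values[hg] == 0.0  # ions excluded from head groups too
        core = node_at(diel.spec, (10, 0, 0))
        assert d2.values[core] == 2.0

    def test_idempotent(self, water_maps, slab_geom):
        diel, kappa = water_maps
        once = m.add_membrane(diel, kappa, slab_geom, eps_protein=5.0)
        twice = m.add_membrane(once[0], once[1], slab_geom, eps_protein=5.0)
        assert np.array_equal(once[0].values, twice[0].values)
        assert np.array_equal(once[1].values, twice[1].values)

    def test_protein_region_preserved_even_when_eps_coincide(self, helix):
        # the degenerate parameterization eps_protein == eps_membrane == 2
        g = GridSpec.from_center_length((0, 0, 0), 60.0, 33)
        region = m.protein_region_mask(helix, g, m.SurfaceSpec())
        diel = m.build_dielectric_map(helix, g, 2.0, 80.0, region=region)
        kappa = m.build_kappa_map(helix, g, m.default_counterions(), protein_region=region)
        geom = m.MembraneGeometry(z_bottom=-12.0, thickness=24.0, eps_membrane=2.0)
        d2, k2 = m.add_membrane(diel, kappa, geom, 2.0, protein_region=region)
        # protein nodes keep their dielectric and the non-protein midplane is membrane
        assert np.all(d2.values[region] == 2.0)
        d3, k3 = m.add_membrane(d2, k2, geom, 2.0, protein_region=region)
        assert np.array_equal(d2.values, d3.values)

    def test_slab_outside_grid_warns(self, water_maps):
        diel, kappa = water_maps
        geom = m.MembraneGeometry(z_bottom=200.0, thickness=20.0)
        with pytest.warns(UserWarning, match="outside the grid"):
            m.add_membrane(diel, kappa, geom, eps_protein=5.0)

    def test_oversized_exclusion_radius_warns(self, water_maps, slab_geom):
        diel, kappa = water_maps
        geom = m.MembraneGeometry(
            z_bottom=-14.0, thickness=28.0,
            upper_exclusion_radius=100.0, lower_exclusion_radius=100.0,
        )
        with pytest.warns(UserWarning, match="exclusion radius"):
            m.add_membrane(diel, kappa, geom, eps_protein=5.0)


class TestExclusionRadius:
    def test_endpoints_and_midpoint(self):
        geom = m.MembraneGeometry(
            z_bottom=-12.0, thickness=24.0,
            upper_exclusion_radius=24.0, lower_exclusion_radius=16.0,
        )
        assert m.interpolate_exclusion_radius(-12.0, geom) == 16.0
        assert m.interpolate_exclusion_radius(12.0, geom) == 24.0
        assert m.interpolate_exclusion_radius(0.0, geom) == 20.0

    def test_outside_slab_rejected(self):
        geom = m.MembraneGeometry(z_bottom=-12.0, thickness=24.0)
        with pytest.raises(ValueError):
            m.interpolate_exclusion_radius(13.0, geom)


class TestInnerSpace:
    def _masks(self, slab_geom):
        g = GridSpec.from_center_length((0, 0, 0), 80.0, 41)
        diel = ScalarGrid.full(g, 80.0)
        kappa = ScalarGrid.full(g, 1.0)
        # carve a protein blob below the slab and a water lumen through it
        geom = m.MembraneGeometry(
            z_bottom=-14.0, thickness=28.0,
            upper_exclusion_radius=6.0, lower_exclusion_radius=6.0,
        )
        protein = np.zeros(g.shape, bool)
        i = node_at(g, (0, 0, -20))
        protein[i] = True
        diel.values[protein] = 5.0
        kappa.values[protein] = 0.0
        d2, k2 = m.add_membrane(diel, kappa, geom, eps_protein=5.0, protein_region=protein)
        return g, geom, k2, protein

    def test_bulk_below_slab_is_inner(self, slab_geom):
        g, geom, k2, protein = self._masks(slab_geom)
        mask = m.build_inner_space_mask(k2, geom)
        assert mask[node_at(g, (20, 0, -30))]

    def test_lumen_water_is_outer(self, slab_geom):
        g, geom, k2, protein = self._masks(slab_geom)
        mask = m.build_inner_space_mask(k2, geom)
        assert not mask[node_at(g, (0, 0, 0))]  # water on-axis at mid-slab

    def test_protein_below_slab_is_not_inner(self, slab_geom):
        g, geom, k2, protein = self._masks(slab_geom)
        mask = m.build_inner_space_mask(k2, geom)
        assert not mask[node_at(g, (0, 0, -20))]

    def test_mask_kappa_consistency(self, slab_geom):
        g, geom, k2, _ = self._masks(slab_geom)
        mask = m.build_inner_space_mask(k2, geom)
        z = g.meshgrid()[2]
        assert np.all(k2.values[mask] != 0.0)
        assert np.all(z[mask] < geom.z_bottom)


class TestMembraneSource:
    def test_zero_voltage_is_identity(self, water_maps, slab_geom):
        diel, kappa = water_maps
        charge = ScalarGrid.full(diel.spec, 0.0)
        mask = np.ones(diel.spec.shape, bool)
        out = m.apply_membrane_source(charge, mask, 0.0, m.default_counterions(0.1))
        assert np.array_equal(out.values, charge.values)

    def test_sign_flips_with_voltage(self, water_maps):
        diel, _ = water_maps
        charge = ScalarGrid.full(diel.spec, 0.0)
        mask = np.zeros(diel.spec.shape, bool)
        mask[::3] = True
        ions = m.default_counterions(0.1)
        plus = m.apply_membrane_source(charge, mask, 50.0, ions)
        minus = m.apply_membrane_source(charge, mask, -50.0, ions)
        assert np.allclose(plus.values, -minus.values)

    def test_closed_form_density(self):
        # rho_eff = 2 c N_A phi_in / 1e27 for a 1:1 electrolyte
        consts = m.CONSTANTS_298
        c, V = 0.1, -50.0
        phi_in = V * consts.phi_per_mV
        expected = 2.0 * c * consts.avogadro * phi_in / 1e27
        got = membrane_source_density(V, m.default_counterions(c), consts)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_voltage_without_ions_rejected(self):
        with pytest.raises(ValueError, match="ionic strength|mobile ions"):
            membrane_source_density(50.0, [m.IonSpecies(1.0, 0.0), m.IonSpecies(-1.0, 0.0)])

    def test_neutrality_preserved_at_zero_voltage(self, helix, slab_geom):
        g = GridSpec.from_center_length((0, 0, 0), 60.0, 33)
        rho = m.spread_charges(helix, g)
        total_before = rho.values.sum()
        mask = np.zeros(g.shape, bool)
        out = m.apply_membrane_source(rho, mask, 0.0, m.default_counterions(0.1))
        assert out.values.sum() == total_before
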