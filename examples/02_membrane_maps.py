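"""Build solution-phase maps for the helix fixture and insert a membrane.

Produces the dielectric, ion-accessibility, and charge maps that the solver
consumes, rewrites them with a 42 Å slab carrying 8 Å high-dielectric
head-group layers, and writes the membrane dielectric map as OpenDX.
"""

import numpy as np

import memslab as m
from memslab.grids import GridSpec

helix = m.build_helix()
print(f"helix: {len(helix)} atoms, net charge {helix.net_charge:+.2f} e")

g = GridSpec.from_center_length((0, 0, 0), 80.0, 65)
surf = m.SurfaceSpec(solvent_probe_radius=1.4, surface_sphere_density=10.0)
region = m.protein_region_mask(helix, g, surf)
diel = m.build_dielectric_map(helix, g, 5.0, 80.0, surf, region=region)
kappa = m.build_kappa_map(helix, g, m.default_counterions(0.1), protein_region=region)
rho = m.spread_charges(helix, g)
print(f"protein region: {region.sum()} nodes "
      f"({region.sum() * g.voxel_volume:.0f} Å^3 molecular volume)")
print(f"spread charge conserves net charge: "
      f"{rho.values.sum() * g.voxel_volume:+.6f} e")

geom = m.MembraneGeometry(
    z_bottom=-21.0, thickness=42.0, eps_membrane=2.0,
    eps_headgroup=80.0, headgroup_thickness=8.0,
)
diel_m, kappa_m = m.add_membrane(diel, kappa, geom, eps_protein=5.0, protein_region=region)
changed = (diel_m.values != diel.values).sum()
print(f"membrane insertion rewrote {changed} nodes; "
      f"ion-accessible nodes {int(kappa.values.sum())} -> {int(kappa_m.values.sum())}")

m.write_dx(diel_m, "helix_membrane_diel.dx")
print("wrote helix_membrane_diel.dx (eps=2 core, eps=80 head groups, eps=5 protein)")
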