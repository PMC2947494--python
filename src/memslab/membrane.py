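"""Membrane slab insertion into solution-phase coefficient maps.

The membrane is a low-dielectric slab between two z-planes, optionally
capped by high-dielectric head-group layers on both faces, with one or two
exclusion cylinders around the z-axis that keep aqueous channel lumens free
of membrane.  Map rewriting visits every node in a fixed order:

1. nodes inside the protein region are never touched;
2. non-protein nodes inside the slab and outside the (z-interpolated)
   exclusion cylinder become membrane: dielectric set to the core or
   head-group value, ion accessibility zeroed;
3. for transmembrane-potential runs, ion-accessible nodes below the slab
   (the inner bath) receive a uniform effective source density that pins the
   far-field potential at the inner-bath voltage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import PhysicalConstants, CONSTANTS_298
from .field_maps import IonSpecies, modified_kappa2
from .grids import ScalarGrid

__all__ = [
    "MembraneGeometry",
    "add_membrane",
    "interpolate_exclusion_radius",
    "build_inner_space_mask",
    "apply_membrane_source",
    "membrane_source_density",
]


@dataclass(frozen=True)
class MembraneGeometry:
    """Slab extent and dielectric assignment.

    z_bottom/thickness are the full slab including head groups;
    headgroup_thickness is per leaflet (the core is thickness minus twice
    that).  Exclusion radii define a frustum around the z-axis, linearly
    interpolated from the lower radius at the slab bottom to the upper
    radius at the slab top.
    """

    z_bottom: float  # Å
    thickness: float  # Å, head groups included
    eps_membrane: float = 2.0
    eps_headgroup: float = 80.0
    headgroup_thickness: float = 0.0  # Å per leaflet
    upper_exclusion_radius: float = 0.0  # Å, at slab top
    lower_exclusion_radius: float = 0.0  # Å, at slab bottom

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("membrane thickness must be positive")
        if self.headgroup_thickness < 0 or 2 * self.headgroup_thickness >= self.thickness:
            raise ValueError("head-group layers must fit inside the slab")
        if self.upper_exclusion_radius < 0 or self.lower_exclusion_radius < 0:
            raise ValueError("exclusion radii must be >= 0")

    @property
    def z_top(self) -> float:
        return self.z_bottom + self.thickness


def interpolate_exclusion_radius(z: float, geom: MembraneGeometry) -> float:
    """Exclusion-cylinder radius at height z inside the slab.

    Linear ramp between the lower radius at the slab bottom and the upper
    radius at the slab top; z outside the slab is an error.
    """
    if z < geom.z_bottom - 1e-9 or z > geom.z_top + 1e-9:
        raise ValueError(f"z={z} lies outside the membrane slab")
    t = (z - geom.z_bottom) / geom.thickness
    t = min(max(t, 0.0), 1.0)
    return (1.0 - t) * geom.lower_exclusion_radius + t * geom.upper_exclusion_radius


def add_membrane(
    diel: ScalarGrid,
    kappa: ScalarGrid,
    geom: MembraneGeometry,
    eps_protein: float,
    protein_region: np.ndarray | None = None,
) -> tuple[ScalarGrid, ScalarGrid]:
    """Rewrite dielectric and ion-accessibility maps to embed the slab.

    Protein nodes are detected by exact equality of the dielectric with
    ``eps_protein`` unless ``protein_region`` is given; passing the retained
    mask is required when the protein and membrane dielectrics coincide
    (equality testing cannot tell them apart then).  Returns new grids; the
    inputs are untouched.  The operation is idempotent.
    """
    if not diel.congruent(kappa):
        raise ValueError("dielectric and kappa grids are not congruent")
    if protein_region is None:
        protein_region = diel.values == float(eps_protein)
    spec = diel.spec
    x, y, z = spec.meshgrid()

    zb, zt = geom.z_bottom, geom.z_top
    if zt < spec.origin[2] or zb > spec.upper_corner[2]:
        warnings.warn("membrane slab lies entirely outside the grid z-range")
    half_width = float(min(spec.lengths[:2]) / 2.0)
    if max(geom.upper_exclusion_radius, geom.lower_exclusion_radius) > half_width:
        warnings.warn(
            "exclusion radius exceeds the lateral grid half-width; "
            "the membrane may be written nowhere"
        )

    in_slab = (z >= zb) & (z <= zt)
    t = np.clip((z - zb) / geom.thickness, 0.0, 1.0)
    excl_r = (1.0 - t) * geom.lower_exclusion_radius + t * geom.upper_exclusion_radius
    radial = np.hypot(x, y)
    membrane = in_slab & ~protein_region & (radial >= excl_r)

    headgroup = membrane & (
        (z < zb + geom.headgroup_thickness) | (z > zt - geom.headgroup_thickness)
    )
    core = membrane & ~headgroup

    new_diel = diel.values.copy()
    new_diel[core] = float(geom.eps_membrane)
    new_diel[headgroup] = float(geom.eps_headgroup)
    new_kappa = kappa.values.copy()
    new_kappa[membrane] = 0.0  # ions excluded from core and head groups alike
    return ScalarGrid(spec, new_diel), ScalarGrid(spec, new_kappa)


def build_inner_space_mask(kappa_mem: ScalarGrid, geom: MembraneGeometry) -> np.ndarray:
    """Indicator of the inner solution space (the bath held at voltage V).

    A node is inner space exactly when it lies below the membrane bottom and
    is ion-accessible in the membrane-modified kappa map.  Channel-lumen
    water inside the slab belongs to the outer space, as does anything
    inside the protein.
    """
    _, _, z = kappa_mem.spec.meshgrid()
    return (z < geom.z_bottom) & (kappa_mem.values != 0.0)


def membrane_source_density(
    V_mV: float,
    ions: Sequence[IonSpecies],
    consts: PhysicalConstants = CONSTANTS_298,
) -> float:
    """Effective inner-bath source density in e/Å^3.

    For a symmetric 1:1 electrolyte this equals 2 c N_A phi_in / 10^27 with
    c the molar salt concentration and phi_in the reduced inner potential;
    in general it is kappa-bar^2 * phi_in / (e^2/(eps0 kT)).  The linearized
    operator applied to a constant phi_in in bulk then returns exactly this
    source, so far below the membrane the potential settles at V.
    """
    kbar2 = modified_kappa2(ions, consts)
    if V_mV != 0.0 and kbar2 == 0.0:
        raise ValueError(
            "a membrane potential requires mobile ions: the effective source "
            "density vanishes at zero ionic strength"
        )
    phi_in = V_mV * consts.phi_per_mV
    return kbar2 * phi_in / consts.coulomb_factor


def apply_membrane_source(
    charge: ScalarGrid,
    mask: np.ndarray,
    V_mV: float,
    ions: Sequence[IonSpecies],
    consts: PhysicalConstants = CONSTANTS_298,
) -> ScalarGrid:
    """Add the uniform effective source density at inner-space nodes.

    Used only for the membrane-potential subproblem (protein charges are
    zeroed there); outer-space and membrane nodes are untouched.  Flipping
    the sign of V flips the sign of every added density.
    """
    rho_eff = membrane_source_density(V_mV, ions, consts)
    values = charge.values.copy()
    values[mask] += rho_eff
    return ScalarGrid(charge.spec, values)
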