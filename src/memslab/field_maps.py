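"""Solution-phase coefficient maps: dielectric, ion accessibility, charge.

These are the three grids the finite-difference solver consumes, built from
an atomic structure as if it were in bulk solvent (the membrane is inserted
afterwards by :mod:`memslab.membrane`).

* The dielectric map uses a two-pass probe-carved molecular surface: pass 1
  marks every node within (r_atom + probe) of an atom as candidate protein;
  pass 2 rolls a solvent probe over the structure and re-marks as solvent
  any candidate node covered by an accessible probe sphere.  For a single
  atom this recovers the van-der-Waals sphere exactly.
* The kappa map stores a binary ion accessibility (0 inside the ion-inflated
  protein, 1 in bulk); the bulk screening coefficient kappa-bar^2 is applied
  at solve time so ionic strength stays a solver parameter.
* Charges are spread with a cubic B-spline kernel (two-node half-support per
  axis), which conserves total charge exactly and reproduces the atom
  position as the centroid of the spread density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import PhysicalConstants, CONSTANTS_298
from .grids import GridSpec, ScalarGrid
from .structure import Structure

__all__ = [
    "SurfaceSpec",
    "IonSpecies",
    "default_counterions",
    "debye_kappa2",
    "modified_kappa2",
    "debye_length",
    "build_dielectric_map",
    "protein_region_mask",
    "build_kappa_map",
    "spread_charges",
    "interpolate_at",
    "bspline3_weights",
]


@dataclass(frozen=True)
class SurfaceSpec:
    """Molecular-surface construction parameters.

    solvent_probe_radius (srad): radius of the rolling solvent sphere, Å.
    surface_sphere_density (sdens): probe-placement sampling density on the
    inflated atom spheres, points per Å^2.
    ion_exclusion_radius: Stern-layer inflation used for the kappa map, Å.
    """

    solvent_probe_radius: float = 1.4
    surface_sphere_density: float = 10.0
    ion_exclusion_radius: float = 2.0
    two_pass: bool = True  # False = inflated-vdW surface (fast preview)

    def __post_init__(self) -> None:
        if self.solvent_probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        if self.surface_sphere_density <= 0:
            raise ValueError("surface sphere density must be > 0")


@dataclass(frozen=True)
class IonSpecies:
    """A mobile ion species: valence (e), concentration (mol/L), radius (Å)."""

    valence: float
    concentration: float
    radius: float = 2.0

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("ion concentration must be >= 0")


def default_counterions(concentration: float = 0.1, radius: float = 2.0) -> list[IonSpecies]:
    """Symmetric 1:1 counter-ion pair at the given molarity."""
    return [
        IonSpecies(+1.0, concentration, radius),
        IonSpecies(-1.0, concentration, radius),
    ]


def modified_kappa2(
    ions: Sequence[IonSpecies], consts: PhysicalConstants = CONSTANTS_298
) -> float:
    """Modified screening coefficient kappa-bar^2 = eps_w * kappa^2, in Å^-2.

    kappa-bar^2 = (e^2/(eps0 kT)) * sum_i z_i^2 n_i with n_i in Å^-3; the
    solvent dielectric cancels, so this is what multiplies phi in the
    linearized PB operator at ion-accessible nodes.  It is twice the
    single-species Debye constant because both the cationic and anionic
    species are mobile.
    """
    s = sum(ion.valence**2 * consts.number_density(ion.concentration) for ion in ions)
    return consts.coulomb_factor * s


def debye_kappa2(
    ions: Sequence[IonSpecies],
    eps_solvent: float,
    consts: PhysicalConstants = CONSTANTS_298,
) -> float:
    """Solvent-referenced Debye screening parameter kappa^2 in Å^-2."""
    return modified_kappa2(ions, consts) / eps_solvent


def debye_length(
    ions: Sequence[IonSpecies],
    eps_solvent: float,
    consts: PhysicalConstants = CONSTANTS_298,
) -> float:
    """Bulk Debye length 1/kappa in Å (inf for pure water)."""
    k2 = debye_kappa2(ions, eps_solvent, consts)
    return math.inf if k2 == 0 else 1.0 / math.sqrt(k2)


# ---------------------------------------------------------------------------
# dielectric map
# ---------------------------------------------------------------------------


def _mark_spheres(
    mask: np.ndarray,
    spec: GridSpec,
    centers: np.ndarray,
    radii: np.ndarray,
    value: bool,
    where: np.ndarray | None = None,
) -> None:
    """Set ``mask`` to ``value`` at nodes within radii[i] of centers[i].

    Operates on local index boxes per sphere, so cost scales with occupied
    volume rather than grid size.  ``where`` optionally restricts writes to
    nodes currently True in that array.
    """
    nx, ny, nz = spec.shape
    h = spec.spacing
    o = spec.origin
    for c, r in zip(centers, radii):
        if r <= 0:
            continue
        lo = np.maximum(np.ceil((c - r - o) / h).astype(int), 0)
        hi = np.minimum(np.floor((c + r - o) / h).astype(int), [nx - 1, ny - 1, nz - 1])
        if np.any(lo > hi):
            continue
        ax = o[0] + h[0] * np.arange(lo[0], hi[0] + 1)
        ay = o[1] + h[1] * np.arange(lo[1], hi[1] + 1)
        az = o[2] + h[2] * np.arange(lo[2], hi[2] + 1)
        d2 = (
            (ax[:, None, None] - c[0]) ** 2
            + (ay[None, :, None] - c[1]) ** 2
            + (az[None, None, :] - c[2]) ** 2
        )
        inside = d2 <= r * r
        sl = (slice(lo[0], hi[0] + 1), slice(lo[1], hi[1] + 1), slice(lo[2], hi[2] + 1))
        if where is not None:
            inside &= where[sl]
        region = mask[sl]
        region[inside] = value
        mask[sl] = region


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    cos_t = 1.0 - 2.0 * i / n
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def _accessible_probe_centers(s: Structure, surf: SurfaceSpec) -> np.ndarray:
    """Probe-sphere centers rolled over the structure (solvent-accessible).

    Candidate centers are sampled on each atom's probe-inflated sphere at
    ``surface_sphere_density`` points/Å^2 and rejected if buried inside any
    other atom's inflated sphere.
    """
    pos = s.positions
    probe = surf.solvent_probe_radius
    inflated = s.radii + probe
    centers: list[np.ndarray] = []
    for p, r in zip(pos, inflated):
        n_pts = max(8, int(round(surf.surface_sphere_density * 4.0 * math.pi * r * r)))
        pts = p + r * _fibonacci_sphere(n_pts)
        # buried test against every inflated atom sphere, chunk-vectorized
        keep = np.ones(len(pts), dtype=bool)
        for start in range(0, len(pts), 4096):
            chunk = pts[start : start + 4096]
            d = np.linalg.norm(chunk[:, None, :] - pos[None, :, :], axis=2)
            keep[start : start + 4096] = np.all(d >= inflated[None, :] - 1e-6, axis=1)
        if keep.any():
            centers.append(pts[keep])
    if not centers:
        return np.zeros((0, 3))
    return np.vstack(centers)


def protein_region_mask(
    s: Structure, spec: GridSpec, surf: SurfaceSpec
) -> np.ndarray:
    """Boolean mask of nodes inside the probe-carved molecular region.

    Pass 1 inflates every atom by the probe radius; pass 2 carves back the
    solvent-accessible shell with probe spheres, leaving the molecular
    (solvent-excluded) region.  With ``surf.two_pass`` False only pass 1 runs
    and atoms are *not* inflated, giving the plain van-der-Waals region.
    """
    if len(s) == 0:
        raise ValueError("cannot build a surface for an empty structure")
    mask = np.zeros(spec.shape, dtype=bool)
    pos = s.positions
    radii = s.radii
    probe = surf.solvent_probe_radius
    if not surf.two_pass:
        _mark_spheres(mask, spec, pos, radii, True)
        return mask
    _mark_spheres(mask, spec, pos, radii + probe, True)
    if probe > 0 and mask.any():
        centers = _accessible_probe_centers(s, surf)
        if len(centers):
            from scipy.spatial import cKDTree

            # only candidate nodes outside every vdW sphere can be carved back
            vdw = np.zeros(spec.shape, dtype=bool)
            _mark_spheres(vdw, spec, pos, radii, True)
            carvable = mask & ~vdw
            idx = np.argwhere(carvable)
            if len(idx):
                coords = spec.origin + idx * spec.spacing
                d, _ = cKDTree(centers).query(coords, k=1)
                covered = d <= probe + 1e-9
                mask[tuple(idx[covered].T)] = False
    return mask


def build_dielectric_map(
    s: Structure,
    spec: GridSpec,
    eps_protein: float,
    eps_solvent: float,
    surf: SurfaceSpec = SurfaceSpec(),
    region: np.ndarray | None = None,
) -> ScalarGrid:
    """Per-node relative permittivity: eps_protein inside the molecular
    region, eps_solvent outside.

    ``region`` lets callers reuse a precomputed :func:`protein_region_mask`
    (the membrane builder needs the mask separately when the protein and
    membrane dielectric values coincide).
    """
    if eps_protein < 1 or eps_solvent < 1:
        raise ValueError("dielectric values must be >= 1")
    if region is None:
        region = protein_region_mask(s, spec, surf)
    values = np.where(region, float(eps_protein), float(eps_solvent))
    if not region.any():
        import warnings

        warnings.warn("no grid node falls inside the structure; grid too coarse/small")
    return ScalarGrid(spec, values)


def build_kappa_map(
    s: Structure,
    spec: GridSpec,
    ions: Sequence[IonSpecies],
    consts: PhysicalConstants = CONSTANTS_298,
    protein_region: np.ndarray | None = None,
) -> ScalarGrid:
    """Binary ion-accessibility map: 0 within (r_atom + r_ion) of any atom
    (and anywhere inside a supplied protein region), 1 in bulk electrolyte.

    The bulk screening coefficient consistent with ``ions`` is obtained from
    :func:`modified_kappa2` and applied at solve time.
    """
    for ion in ions:
        if ion.concentration < 0:
            raise ValueError("negative ion concentration")
    ion_r = max((ion.radius for ion in ions), default=0.0)
    excluded = np.zeros(spec.shape, dtype=bool)
    if len(s):
        _mark_spheres(excluded, spec, s.positions, s.radii + ion_r, True)
    if protein_region is not None:
        excluded |= protein_region
    return ScalarGrid(spec, np.where(excluded, 0.0, 1.0))


# ---------------------------------------------------------------------------
# charge spreading (cubic B-spline, "spl2")
# ---------------------------------------------------------------------------


def _bspline3(u: np.ndarray) -> np.ndarray:
    """Cubic B-spline basis, support |u| < 2, partition of unity."""
    a = np.abs(u)
    out = np.zeros_like(a)
    inner = a < 1.0
    outer = (a >= 1.0) & (a < 2.0)
    out[inner] = 2.0 / 3.0 - a[inner] ** 2 + 0.5 * a[inner] ** 3
    out[outer] = (2.0 - a[outer]) ** 3 / 6.0
    return out


def bspline3_weights(frac: float) -> tuple[int, np.ndarray]:
    """Stencil base offset and 4 weights for a fractional grid coordinate."""
    base = int(math.floor(frac)) - 1
    offsets = base + np.arange(4)
    return base, _bspline3(offsets - frac)


def _atom_stencils(s: Structure, spec: GridSpec):
    """Yield (atom index, index slices, 4x4x4 weight block) per atom."""
    for idx, atom in enumerate(s.atoms):
        frac = (atom.position - spec.origin) / spec.spacing
        bases = []
        weights = []
        for d in range(3):
            b, w = bspline3_weights(frac[d])
            if b < 0 or b + 3 >= spec.shape[d]:
                raise ValueError(
                    f"atom {atom.serial} ({atom.name} {atom.residue_name}"
                    f"{atom.residue_number}) lies within the charge-kernel "
                    f"support of the grid boundary along axis {d}"
                )
            bases.append(b)
            weights.append(w)
        block = (
            weights[0][:, None, None]
            * weights[1][None, :, None]
            * weights[2][None, None, :]
        )
        sl = tuple(slice(b, b + 4) for b in bases)
        yield idx, sl, block


def spread_charges(s: Structure, spec: GridSpec) -> ScalarGrid:
    """Spread atomic point charges onto the grid as a density in e/Å^3.

    The cubic B-spline kernel guarantees sum(density) * voxel_volume equals
    the structure's net charge to round-off, and places the density centroid
    exactly at the atom position.  Atoms closer than two nodes to the grid
    boundary raise an error naming the atom.
    """
    rho = np.zeros(spec.shape)
    inv_vol = 1.0 / spec.voxel_volume
    for idx, sl, block in _atom_stencils(s, spec):
        q = s.atoms[idx].charge
        if q != 0.0:
            rho[sl] += q * inv_vol * block
    return ScalarGrid(spec, rho)


def interpolate_at(field: ScalarGrid, s: Structure) -> np.ndarray:
    """Evaluate a grid field at atom positions with the same cubic B-spline
    used for charge spreading (the adjoint pairing that makes grid
    self-energies cancel exactly in same-grid differences)."""
    out = np.zeros(len(s))
    for idx, sl, block in _atom_stencils(s, field.spec):
        out[idx] = float(np.sum(field.values[sl] * block))
    return out
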