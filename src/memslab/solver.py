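"""Finite-difference linearized Poisson-Boltzmann solver.

The linearized PB equation in reduced units (phi = e*psi/kT, lengths in Å,
charge density rho in e/Å^3),

    -div(eps grad phi) + kbar^2(r) phi = C rho,   C = e^2/(eps0 kT)  [Å],

is discretized on a regular node-centered grid with the standard 7-point
flux-balance stencil: face dielectric values are harmonic means of the two
adjacent node values, and the screening term kbar^2 (the modified
Debye-Hückel coefficient, solvent dielectric folded in) acts only at
ion-accessible nodes.  The resulting operator is symmetric positive
definite and is solved with Jacobi-preconditioned conjugate gradients after
eliminating the Dirichlet boundary into the right-hand side.

Boundary conditions: zero, single/multiple Debye-Hückel screened-Coulomb
superposition, focusing (trilinear interpolation of a coarser parent
solution), or the analytic transmembrane slab profile for
membrane-potential runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import PhysicalConstants, CONSTANTS_298
from .field_maps import interpolate_at, spread_charges
from .grids import GridSpec, ScalarGrid
from .structure import Structure

__all__ = [
    "SolverSpec",
    "SlabProfileParams",
    "PotentialField",
    "EnergyReport",
    "SolveRecord",
    "LevelMaps",
    "ConvergenceError",
    "assemble_operator",
    "slab_profile",
    "boundary_values",
    "solve",
    "energy",
    "focus_ladder",
]

BOUNDARY_KINDS = (
    "zero",
    "single_debye_huckel",
    "multiple_debye_huckel",
    "focus",
    "membrane_potential",
)


class ConvergenceError(RuntimeError):
    """Linear solver failed to reach the requested residual."""


@dataclass(frozen=True)
class SolverSpec:
    """Grid geometry plus solver controls for one level."""

    nodes: tuple[int, int, int] | int
    lengths: tuple[float, float, float] | float
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    boundary_condition: str = "multiple_debye_huckel"
    tolerance: float = 1e-6
    max_iterations: int = 20000
    temperature: float = 298.15

    def __post_init__(self) -> None:
        nodes = np.broadcast_to(np.asarray(self.nodes, dtype=int), (3,))
        if np.any(nodes < 3):
            raise ValueError("need at least 3 nodes per axis")
        if not (0.0 < self.tolerance < 1.0):
            raise ValueError("tolerance must lie in (0, 1)")
        if self.boundary_condition not in BOUNDARY_KINDS:
            raise ValueError(f"unknown boundary condition {self.boundary_condition!r}")

    @property
    def grid(self) -> GridSpec:
        return GridSpec.from_center_length(self.center, self.lengths, self.nodes)


@dataclass(frozen=True)
class SlabProfileParams:
    """Inputs for the analytic 1-D transmembrane potential profile."""

    V_mV: float  # inner-bath potential; outer bath is 0
    z_bottom: float  # Å
    z_top: float  # Å
    eps_membrane: float
    eps_water: float
    kappa_bulk: float  # Å^-1, solvent-referenced Debye parameter

    def __post_init__(self) -> None:
        if self.z_top <= self.z_bottom:
            raise ValueError("slab top must lie above slab bottom")
        if self.eps_membrane < 1 or self.eps_water < 1:
            raise ValueError("dielectric values must be >= 1")
        if self.kappa_bulk < 0:
            raise ValueError("kappa must be >= 0")


def slab_profile(
    z: np.ndarray | float,
    p: SlabProfileParams,
    consts: PhysicalConstants = CONSTANTS_298,
) -> np.ndarray | float:
    """Reduced potential of a bare dielectric slab under a voltage clamp.

    Piecewise solution of the 1-D linearized PB equation with an
    ion-excluding slab: exponential Debye decay to 0 above the slab,
    exponential approach to the inner-bath value below, and a linear drop
    across the slab, joined continuously with the dielectric-weighted flux
    matching eps_w dphi/dz (water side) = eps_m dphi/dz (membrane side).
    For a symmetric geometry the mid-plane sits at half the applied voltage.
    """
    vbar = p.V_mV * consts.phi_per_mV
    L = p.z_top - p.z_bottom
    if p.kappa_bulk == 0:
        raise ValueError("slab profile requires a screening electrolyte (kappa > 0)")
    # linear-region slope and top-face value
    m = -vbar / (L + 2.0 * p.eps_membrane / (p.eps_water * p.kappa_bulk))
    a_top = -p.eps_membrane * m / (p.eps_water * p.kappa_bulk)
    z = np.asarray(z, dtype=float)
    above = z > p.z_top
    below = z < p.z_bottom
    mid = ~(above | below)
    out = np.empty_like(z)
    out[above] = a_top * np.exp(-p.kappa_bulk * (z[above] - p.z_top))
    out[below] = vbar - a_top * np.exp(p.kappa_bulk * (z[below] - p.z_bottom))
    out[mid] = a_top + m * (z[mid] - p.z_top)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# operator assembly
# ---------------------------------------------------------------------------


def _harmonic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return 2.0 * a * b / (a + b)


@dataclass
class LpbeOperator:
    """Assembled 7-point operator over the interior nodes of a grid."""

    spec: GridSpec
    matrix: sp.csr_matrix  # symmetric positive definite, interior unknowns
    face_cond: tuple[np.ndarray, np.ndarray, np.ndarray]  # Hx, Hy, Hz
    interior_shape: tuple[int, int, int]

    def rhs(
        self,
        charge: ScalarGrid,
        boundary: np.ndarray,
        consts: PhysicalConstants = CONSTANTS_298,
    ) -> np.ndarray:
        """Right-hand side: scaled source plus eliminated Dirichlet fluxes."""
        if not charge.spec.congruent(self.spec):
            raise ValueError("charge grid not congruent with operator grid")
        vol = self.spec.voxel_volume
        rho = charge.values[1:-1, 1:-1, 1:-1]
        b = consts.coulomb_factor * rho * vol
        Hx, Hy, Hz = self.face_cond
        b[0, :, :] += Hx[0, 1:-1, 1:-1] * boundary[0, 1:-1, 1:-1]
        b[-1, :, :] += Hx[-1, 1:-1, 1:-1] * boundary[-1, 1:-1, 1:-1]
        b[:, 0, :] += Hy[1:-1, 0, 1:-1] * boundary[1:-1, 0, 1:-1]
        b[:, -1, :] += Hy[1:-1, -1, 1:-1] * boundary[1:-1, -1, 1:-1]
        b[:, :, 0] += Hz[1:-1, 1:-1, 0] * boundary[1:-1, 1:-1, 0]
        b[:, :, -1] += Hz[1:-1, 1:-1, -1] * boundary[1:-1, 1:-1, -1]
        return b.ravel()


def assemble_operator(
    diel: ScalarGrid,
    kappa: ScalarGrid,
    kbar2: float,
    spec: SolverSpec | None = None,
) -> LpbeOperator:
    """Assemble the symmetric finite-volume LPB operator.

    ``kappa`` is the binary accessibility map; ``kbar2`` the bulk modified
    screening coefficient in Å^-2 (zero for pure Poisson runs).
    """
    if not diel.congruent(kappa):
        raise ValueError("dielectric and kappa grids are not congruent")
    g = diel.spec
    nx, ny, nz = g.shape
    hx, hy, hz = g.spacing
    vol = g.voxel_volume
    eps = diel.values

    # face conductances eps_face * A_face / d_face between node pairs
    Hx = _harmonic(eps[:-1, :, :], eps[1:, :, :]) * (hy * hz / hx)
    Hy = _harmonic(eps[:, :-1, :], eps[:, 1:, :]) * (hx * hz / hy)
    Hz = _harmonic(eps[:, :, :-1], eps[:, :, 1:]) * (hx * hy / hz)

    Ix, Iy, Iz = nx - 2, ny - 2, nz - 2
    n = Ix * Iy * Iz

    diag = (
        Hx[:-1, 1:-1, 1:-1]
        + Hx[1:, 1:-1, 1:-1]
        + Hy[1:-1, :-1, 1:-1]
        + Hy[1:-1, 1:, 1:-1]
        + Hz[1:-1, 1:-1, :-1]
        + Hz[1:-1, 1:-1, 1:]
        + kbar2 * kappa.values[1:-1, 1:-1, 1:-1] * vol
    ).ravel()

    # upper off-diagonals (interior-interior couplings only)
    ex = np.zeros((Ix, Iy, Iz))
    ex[:-1, :, :] = -Hx[1:-1, 1:-1, 1:-1]
    ey = np.zeros((Ix, Iy, Iz))
    ey[:, :-1, :] = -Hy[1:-1, 1:-1, 1:-1]
    ez = np.zeros((Ix, Iy, Iz))
    ez[:, :, :-1] = -Hz[1:-1, 1:-1, 1:-1]

    upper = sp.diags(
        [ez.ravel()[: n - 1], ey.ravel()[: n - Iz], ex.ravel()[: n - Iy * Iz]],
        [1, Iz, Iy * Iz],
        shape=(n, n),
        format="csr",
    )
    A = sp.diags([diag], [0], format="csr") + upper + upper.T
    return LpbeOperator(g, A.tocsr(), (Hx, Hy, Hz), (Ix, Iy, Iz))


# ---------------------------------------------------------------------------
# boundary values
# ---------------------------------------------------------------------------


def _face_index_mask(shape: tuple[int, int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[0], m[-1] = True, True
    m[:, 0], m[:, -1] = True, True
    m[:, :, 0], m[:, :, -1] = True, True
    return m


def _debye_huckel_sum(
    coords: np.ndarray,
    centers: np.ndarray,
    charges: np.ndarray,
    radii: np.ndarray,
    eps_solvent: float,
    kappa: float,
    consts: PhysicalConstants,
) -> np.ndarray:
    """Screened-Coulomb superposition phi = sum_i lB q_i e^{-k(d-a)}/(eps (1+k a) d)."""
    lb = consts.bjerrum_vacuum / eps_solvent
    out = np.zeros(len(coords))
    for start in range(0, len(coords), 8192):
        block = coords[start : start + 8192]
        d = np.linalg.norm(block[:, None, :] - centers[None, :, :], axis=2)
        d = np.maximum(d, 1e-6)
        shield = np.exp(-kappa * np.maximum(d - radii[None, :], 0.0)) / (
            1.0 + kappa * radii[None, :]
        )
        out[start : start + 8192] = (lb * charges[None, :] * shield / d).sum(axis=1)
    return out


@dataclass
class PotentialField:
    """Reduced electrostatic potential on a grid."""

    grid: ScalarGrid
    consts: PhysicalConstants = field(default_factory=lambda: CONSTANTS_298)

    @property
    def spec(self) -> GridSpec:
        return self.grid.spec

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    def to_mV(self) -> np.ndarray:
        """Potential in millivolts."""
        return self.values / self.consts.phi_per_mV

    def interpolator(self):
        from scipy.interpolate import RegularGridInterpolator

        return RegularGridInterpolator(
            self.spec.axes(), self.values, method="linear", bounds_error=True
        )


def boundary_values(
    grid: GridSpec,
    kind: str,
    *,
    structure: Structure | None = None,
    eps_solvent: float = 80.0,
    kappa_bulk: float = 0.0,
    parent: PotentialField | None = None,
    slab: SlabProfileParams | None = None,
    consts: PhysicalConstants = CONSTANTS_298,
) -> np.ndarray:
    """Dirichlet values on the six faces of ``grid`` (full array, interior 0).

    * ``zero``: 0 everywhere.
    * ``single_debye_huckel``: one screened sphere carrying the total charge,
      centered at the charge centroid, radius the largest atom radius.
    * ``multiple_debye_huckel``: per-atom screened-Coulomb superposition.
    * ``focus``: trilinear interpolation of a parent solution that must
      strictly contain this grid.
    * ``membrane_potential``: the analytic slab profile evaluated at node z.
    """
    if kind not in BOUNDARY_KINDS:
        raise ValueError(f"unknown boundary condition {kind!r}")
    out = np.zeros(grid.shape)
    if kind == "zero":
        return out
    mask = _face_index_mask(grid.shape)
    idx = np.argwhere(mask)
    coords = grid.origin + idx * grid.spacing
    if kind in ("single_debye_huckel", "multiple_debye_huckel"):
        if structure is None or len(structure) == 0:
            raise ValueError("Debye-Hückel boundaries require a structure")
        if kind == "single_debye_huckel":
            q = structure.net_charge
            w = np.abs(structure.charges)
            center = (
                structure.positions.T @ w / w.sum()
                if w.sum() > 0
                else structure.positions.mean(axis=0)
            )
            centers = center[None, :]
            charges = np.array([q])
            radii = np.array([float(structure.radii.max())])
        else:
            centers = structure.positions
            charges = structure.charges
            radii = structure.radii
        vals = _debye_huckel_sum(
            coords, centers, charges, radii, eps_solvent, kappa_bulk, consts
        )
    elif kind == "focus":
        if parent is None:
            raise ValueError("focus boundaries require a parent potential field")
        if not parent.spec.contains(grid):
            raise ValueError("child grid is not contained in the parent grid")
        vals = parent.interpolator()(coords)
    else:  # membrane_potential
        if slab is None:
            raise ValueError("membrane-potential boundaries require slab parameters")
        vals = slab_profile(coords[:, 2], slab, consts)
    out[tuple(idx.T)] = vals
    return out


# ---------------------------------------------------------------------------
# linear solve
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolveRecord:
    """Per-solve log entry (grid size, spacing, iterations, residual)."""

    shape: tuple[int, int, int]
    spacing: float
    iterations: int
    relative_residual: float
    boundary_condition: str


def solve(
    op: LpbeOperator,
    charge: ScalarGrid,
    boundary: np.ndarray,
    consts: PhysicalConstants = CONSTANTS_298,
    tol: float = 1e-6,
    max_iterations: int = 20000,
    x0: np.ndarray | None = None,
    bc_label: str = "",
) -> tuple[PotentialField, SolveRecord]:
    """Solve the assembled system; returns the full-grid reduced potential.

    Raises :class:`ConvergenceError` if the relative residual does not reach
    ``tol`` within ``max_iterations`` CG iterations.
    """
    b = op.rhs(charge, boundary, consts)
    A = op.matrix
    inv_diag = 1.0 / A.diagonal()
    M = spla.LinearOperator(A.shape, matvec=lambda v: inv_diag * v)
    iters = 0

    def _count(_):
        nonlocal iters
        iters += 1

    x, info = spla.cg(
        A, b, x0=x0, rtol=tol, atol=0.0, maxiter=max_iterations, M=M, callback=_count
    )
    bnorm = float(np.linalg.norm(b))
    res = float(np.linalg.norm(b - A @ x)) / (bnorm if bnorm > 0 else 1.0)
    if info != 0 or not np.isfinite(res):
        raise ConvergenceError(
            f"CG failed to converge (info={info}, relative residual={res:.3e} "
            f"after {iters} iterations)"
        )
    full = boundary.copy()
    full[1:-1, 1:-1, 1:-1] = x.reshape(op.interior_shape)
    spacing = float(op.spec.spacing.max())
    record = SolveRecord(op.spec.shape, spacing, iters, res, bc_label)
    return PotentialField(ScalarGrid(op.spec, full), consts), record


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnergyReport:
    """An energy in kT with companion kJ/mol and kcal/mol views."""

    kT: float
    consts: PhysicalConstants = field(default_factory=lambda: CONSTANTS_298)
    label: str = ""

    @property
    def kJ_per_mol(self) -> float:
        return self.kT * self.consts.kT_kJ_per_mol

    @property
    def kcal_per_mol(self) -> float:
        return self.kT * self.consts.kT_kcal_per_mol

    def __sub__(self, other: "EnergyReport") -> "EnergyReport":
        return EnergyReport(self.kT - other.kT, self.consts, label=self.label)

    def __add__(self, other: "EnergyReport") -> "EnergyReport":
        return EnergyReport(self.kT + other.kT, self.consts, label=self.label)

    def __str__(self) -> str:
        tag = f"{self.label}: " if self.label else ""
        return (
            f"{tag}{self.kJ_per_mol:.4f} kJ/mol = "
            f"{self.kcal_per_mol:.4f} kcal/mol = {self.kT:.4f} kT"
        )


def energy(
    phi: PotentialField,
    charges: Structure | ScalarGrid,
    consts: PhysicalConstants = CONSTANTS_298,
    total: bool = True,
    label: str = "",
) -> EnergyReport:
    """Electrostatic energy of charges in a potential field.

    With ``total`` True this is the self-consistent total energy
    (1/2) sum q_i phi(r_i) — use it when ``charges`` sourced ``phi``.  With
    ``total`` False it is the interaction energy sum q_i phi(r_i) of charges
    with a foreign field (the gating-charge workflow).  Atom positions are
    evaluated with the same B-spline kernel used for charge spreading.
    """
    if isinstance(charges, Structure):
        e = float(np.dot(charges.charges, interpolate_at(phi.grid, charges)))
    else:
        if not charges.spec.congruent(phi.spec):
            raise ValueError("charge grid not congruent with potential grid")
        e = float(np.sum(charges.values * phi.values)) * charges.spec.voxel_volume
    if total:
        e *= 0.5
    return EnergyReport(e, consts, label=label)


# ---------------------------------------------------------------------------
# focusing
# ---------------------------------------------------------------------------


@dataclass
class LevelMaps:
    """Coefficient maps for one focusing level (congruent grids)."""

    diel: ScalarGrid
    kappa: ScalarGrid
    charge: ScalarGrid

    def __post_init__(self) -> None:
        if not (self.diel.congruent(self.kappa) and self.diel.congruent(self.charge)):
            raise ValueError("level maps must live on congruent grids")

    @property
    def spec(self) -> GridSpec:
        return self.diel.spec


def focus_ladder(
    levels: Sequence[LevelMaps],
    outer_bc: str,
    *,
    kbar2: float,
    structure: Structure | None = None,
    eps_solvent: float = 80.0,
    slab: SlabProfileParams | None = None,
    consts: PhysicalConstants = CONSTANTS_298,
    tol: float = 1e-6,
    max_iterations: int = 20000,
) -> tuple[PotentialField, list[SolveRecord]]:
    """Solve a coarse-to-fine focusing ladder; returns the finest potential.

    The first level uses ``outer_bc`` on its faces; every subsequent level
    takes focus boundaries interpolated from its parent's solution.  Each
    child grid must lie strictly inside its parent.
    """
    if not levels:
        raise ValueError("need at least one focusing level")
    kappa_solvent = math.sqrt(kbar2 / eps_solvent) if kbar2 > 0 else 0.0
    parent_field: PotentialField | None = None
    records: list[SolveRecord] = []
    for k, lvl in enumerate(levels):
        if k == 0:
            bc_kind = outer_bc
        else:
            bc_kind = "focus"
            if not levels[k - 1].spec.contains(lvl.spec):
                raise ValueError(f"level {k} grid is not inside its parent grid")
        bvals = boundary_values(
            lvl.spec,
            bc_kind,
            structure=structure,
            eps_solvent=eps_solvent,
            kappa_bulk=kappa_solvent,
            parent=parent_field,
            slab=slab,
            consts=consts,
        )
        op = assemble_operator(lvl.diel, lvl.kappa, kbar2)
        x0 = None
        if parent_field is not None:
            interior = np.argwhere(np.ones(tuple(n - 2 for n in lvl.spec.shape), bool))
            coords = lvl.spec.origin + (interior + 1) * lvl.spec.spacing
            x0 = parent_field.interpolator()(coords)
        phi, rec = solve(
            op,
            lvl.charge,
            bvals,
            consts,
            tol=tol,
            max_iterations=max_iterations,
            x0=x0,
            bc_label=bc_kind,
        )
        records.append(rec)
        parent_field = phi
    return parent_field, records
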