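"""The three calculation types: protein solvation, ion solvation, gating charge.

Each workflow is a difference of total (or interaction) energies between
states evaluated on *identical* focusing ladders, so that the divergent
grid self-energy of the spread point charges cancels exactly in the
difference and only the physically meaningful reaction-field/interaction
part survives.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import PhysicalConstants, CONSTANTS_298
from .field_maps import (
    IonSpecies,
    SurfaceSpec,
    build_dielectric_map,
    build_kappa_map,
    default_counterions,
    modified_kappa2,
    protein_region_mask,
    spread_charges,
)
from .grids import GridSpec, ScalarGrid
from .membrane import (
    MembraneGeometry,
    add_membrane,
    apply_membrane_source,
    build_inner_space_mask,
)
from .solver import (
    EnergyReport,
    LevelMaps,
    PotentialField,
    SlabProfileParams,
    SolveRecord,
    energy,
    focus_ladder,
)
from .structure import Structure

__all__ = [
    "WorkflowConfig",
    "WorkflowResult",
    "protein_solvation",
    "ion_solvation",
    "gating_charge",
    "convergence_scan",
]


@dataclass
class WorkflowConfig:
    """Everything one calculation needs, minus file plumbing.

    ``nodes`` applies to every level of the focusing ladder; ``lengths``
    lists the cubic side length per level, coarse to fine (1-3 entries).
    ``membrane`` may be None for bulk-only runs.  For gating runs,
    ``V_max_mV`` sets the sweep endpoints and ``sweep_points`` the number of
    equally spaced voltages (including 0 when odd).
    """

    calculation_type: str  # protein_solvation | ion_solvation | gating_charge
    structures: list[Structure]
    nodes: int = 65
    lengths: Sequence[float] = (200.0, 100.0, 50.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    eps_protein: float = 5.0
    eps_solvent: float = 80.0
    membrane: MembraneGeometry | None = None
    surface: SurfaceSpec = field(default_factory=SurfaceSpec)
    ions: list[IonSpecies] = field(default_factory=default_counterions)
    consts: PhysicalConstants = field(default_factory=lambda: CONSTANTS_298)
    outer_bc: str = "multiple_debye_huckel"
    V_max_mV: float = 50.0
    sweep_points: int = 5
    protein_charges_on: bool = True
    charge_residue_range: tuple[int, int] | None = None
    tolerance: float = 1e-6
    max_iterations: int = 20000

    def __post_init__(self) -> None:
        n_required = {"protein_solvation": 1, "ion_solvation": 2, "gating_charge": 2}
        if self.calculation_type not in n_required:
            raise ValueError(f"unknown calculation type {self.calculation_type!r}")
        if len(self.structures) != n_required[self.calculation_type]:
            raise ValueError(
                f"{self.calculation_type} requires {n_required[self.calculation_type]} "
                f"structure(s), got {len(self.structures)}"
            )
        if not 1 <= len(list(self.lengths)) <= 3:
            raise ValueError("focusing ladder must have 1-3 levels")
        if list(self.lengths) != sorted(self.lengths, reverse=True):
            raise ValueError("ladder lengths must decrease coarse to fine")
        if self.calculation_type == "gating_charge" and self.sweep_points < 2:
            raise ValueError("gating sweep needs at least 2 voltages")

    @property
    def grid_specs(self) -> list[GridSpec]:
        return [
            GridSpec.from_center_length(self.center, L, self.nodes)
            for L in self.lengths
        ]

    @property
    def kbar2(self) -> float:
        return modified_kappa2(self.ions, self.consts)


@dataclass
class WorkflowResult:
    """Derived quantity plus per-state components and solver logs."""

    calculation_type: str
    delta: EnergyReport
    components: dict[str, EnergyReport]
    records: dict[str, list[SolveRecord]]
    valence_e: float | None = None
    sweep: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "calculation_type": self.calculation_type,
            "delta": {
                "kJ_per_mol": self.delta.kJ_per_mol,
                "kcal_per_mol": self.delta.kcal_per_mol,
                "kT": self.delta.kT,
            },
            "components": {
                k: {
                    "kJ_per_mol": v.kJ_per_mol,
                    "kcal_per_mol": v.kcal_per_mol,
                    "kT": v.kT,
                }
                for k, v in self.components.items()
            },
        }
        if self.valence_e is not None:
            out["valence_e"] = self.valence_e
        if self.sweep is not None:
            out["sweep"] = self.sweep.to_dict(orient="records")
        return out

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def to_text(self) -> str:
        lines = [f"calculation: {self.calculation_type}"]
        for name, rep in self.components.items():
            lines.append(f"  {name}: {rep}")
        lines.append(f"  result: {self.delta}")
        if self.valence_e is not None:
            lines.append(f"  valence: {self.valence_e:.4f} e")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# map construction shared by all workflows
# ---------------------------------------------------------------------------


def build_state_maps(
    cavity: Structure,
    grids: Sequence[GridSpec],
    cfg: WorkflowConfig,
    *,
    with_membrane: bool,
    charge_source: Structure | None = None,
) -> tuple[list[LevelMaps], list[np.ndarray]]:
    """Dielectric/kappa/charge maps for one state on every ladder level.

    ``cavity`` defines the molecular region; ``charge_source`` (default the
    cavity structure) supplies the spread charges.  Returns the level maps
    and, for membrane states, the inner-space masks per level.
    """
    charge_source = cavity if charge_source is None else charge_source
    levels: list[LevelMaps] = []
    inner_masks: list[np.ndarray] = []
    for g in grids:
        region = protein_region_mask(cavity, g, cfg.surface)
        diel = build_dielectric_map(
            cavity, g, cfg.eps_protein, cfg.eps_solvent, cfg.surface, region=region
        )
        kappa = build_kappa_map(cavity, g, cfg.ions, cfg.consts, protein_region=region)
        if with_membrane:
            if cfg.membrane is None:
                raise ValueError("membrane geometry missing")
            diel, kappa = add_membrane(
                diel, kappa, cfg.membrane, cfg.eps_protein, protein_region=region
            )
            inner_masks.append(build_inner_space_mask(kappa, cfg.membrane))
        charge = spread_charges(charge_source, g)
        levels.append(LevelMaps(diel, kappa, charge))
    return levels, inner_masks


def _run_ladder(
    cfg: WorkflowConfig,
    levels: list[LevelMaps],
    structure: Structure,
    outer_bc: str | None = None,
    slab: SlabProfileParams | None = None,
) -> tuple[PotentialField, list[SolveRecord]]:
    return focus_ladder(
        levels,
        outer_bc or cfg.outer_bc,
        kbar2=cfg.kbar2,
        structure=structure,
        eps_solvent=cfg.eps_solvent,
        slab=slab,
        consts=cfg.consts,
        tol=cfg.tolerance,
        max_iterations=cfg.max_iterations,
    )


def _total_energy(
    cfg: WorkflowConfig, phi: PotentialField, charge: ScalarGrid, label: str
) -> EnergyReport:
    return energy(phi, charge, cfg.consts, total=True, label=label)


# ---------------------------------------------------------------------------
# workflows
# ---------------------------------------------------------------------------


def protein_solvation(cfg: WorkflowConfig) -> WorkflowResult:
    """Transfer energy of a protein from bulk water into the membrane.

    Delta G = G(membrane-embedded) - G(bulk water), both states computed on
    the identical ladder so grid self-energies cancel.
    """
    (s,) = cfg.structures
    grids = cfg.grid_specs
    mem_levels, _ = build_state_maps(s, grids, cfg, with_membrane=True)
    bulk_levels, _ = build_state_maps(s, grids, cfg, with_membrane=False)
    phi_mem, rec_mem = _run_ladder(cfg, mem_levels, s)
    phi_bulk, rec_bulk = _run_ladder(cfg, bulk_levels, s)
    g_mem = _total_energy(cfg, phi_mem, mem_levels[-1].charge, "membrane")
    g_bulk = _total_energy(cfg, phi_bulk, bulk_levels[-1].charge, "bulk water")
    delta = EnergyReport(g_mem.kT - g_bulk.kT, cfg.consts, "solvation energy")
    return WorkflowResult(
        "protein_solvation",
        delta,
        {"membrane": g_mem, "bulk": g_bulk},
        {"membrane": rec_mem, "bulk": rec_bulk},
    )


def ion_solvation(cfg: WorkflowConfig) -> WorkflowResult:
    """Transfer energy of an ion from bulk water into a membrane-embedded
    protein cavity.

    Delta G = G(protein+ion, membrane) - G(protein, membrane) - G(ion, bulk).
    Protein partial charges can be switched off (cavity kept) or restricted
    to a residue range via the config.
    """
    protein, ion = cfg.structures
    grids = cfg.grid_specs

    if cfg.charge_residue_range is not None:
        mask = protein.residue_charge_mask(*cfg.charge_residue_range)
        protein_q = protein.with_charge_mask(mask)
    elif not cfg.protein_charges_on:
        protein_q = protein.with_zero_charges()
    else:
        protein_q = protein

    assembly_cavity = protein + ion
    assembly_q = protein_q + ion

    lv_a, _ = build_state_maps(
        assembly_cavity, grids, cfg, with_membrane=True, charge_source=assembly_q
    )
    lv_b, _ = build_state_maps(
        protein, grids, cfg, with_membrane=True, charge_source=protein_q
    )
    lv_c, _ = build_state_maps(ion, grids, cfg, with_membrane=False)

    phi_a, rec_a = _run_ladder(cfg, lv_a, assembly_q)
    phi_b, rec_b = _run_ladder(cfg, lv_b, protein_q)
    phi_c, rec_c = _run_ladder(cfg, lv_c, ion)

    g_a = _total_energy(cfg, phi_a, lv_a[-1].charge, "protein+ion, membrane")
    g_b = _total_energy(cfg, phi_b, lv_b[-1].charge, "protein, membrane")
    g_c = _total_energy(cfg, phi_c, lv_c[-1].charge, "ion, bulk water")
    delta = EnergyReport(g_a.kT - g_b.kT - g_c.kT, cfg.consts, "ion transfer energy")
    return WorkflowResult(
        "ion_solvation",
        delta,
        {"assembly": g_a, "protein": g_b, "ion_bulk": g_c},
        {"assembly": rec_a, "protein": rec_b, "ion_bulk": rec_c},
    )


def _membrane_potential_interaction(
    cfg: WorkflowConfig, s: Structure, V_mV: float
) -> tuple[EnergyReport, list[SolveRecord]]:
    """Interaction energy of a state's charges with the field phi_mp(V).

    The membrane-potential subproblem zeroes the protein charges, keeps the
    state's dielectric cavity and membrane, installs the inner-bath
    effective source, and imposes the analytic slab profile on the coarse
    boundary; finer levels focus inward.  The returned energy is the pure
    cross term sum_i q_i phi_mp(r_i).
    """
    if cfg.membrane is None:
        raise ValueError("gating calculations require a membrane geometry")
    if cfg.kbar2 == 0.0:
        raise ValueError("gating calculations require a screening electrolyte")
    grids = cfg.grid_specs
    levels, inner_masks = build_state_maps(
        s, grids, cfg, with_membrane=True, charge_source=s.with_zero_charges()
    )
    for lvl, mask in zip(levels, inner_masks):
        lvl.charge = apply_membrane_source(lvl.charge, mask, V_mV, cfg.ions, cfg.consts)
    kappa_solvent = math.sqrt(cfg.kbar2 / cfg.eps_solvent)
    slab = SlabProfileParams(
        V_mV=V_mV,
        z_bottom=cfg.membrane.z_bottom,
        z_top=cfg.membrane.z_top,
        eps_membrane=cfg.membrane.eps_membrane,
        eps_water=cfg.eps_solvent,
        kappa_bulk=kappa_solvent,
    )
    phi, rec = _run_ladder(cfg, levels, s, outer_bc="membrane_potential", slab=slab)
    g = energy(phi, s, cfg.consts, total=False, label=f"V={V_mV:+.1f} mV")
    return g, rec


def gating_charge(cfg: WorkflowConfig) -> WorkflowResult:
    """Voltage-sensor valence of a conformational transition.

    For each voltage V of the sweep, both states' charges are coupled to the
    state-specific transmembrane field phi_mp(V); the valence is the
    least-squares slope of Delta-G = G(state2) - G(state1) against V,
    negated so that moving positive charge from the inner bath (held at V)
    to the outer bath (0) gives a positive valence equal to the fraction of
    the field traversed.
    """
    s1, s2 = cfg.structures
    voltages = np.linspace(-cfg.V_max_mV, cfg.V_max_mV, cfg.sweep_points)
    rows = []
    records: dict[str, list[SolveRecord]] = {}
    for V in voltages:
        g1, rec1 = _membrane_potential_interaction(cfg, s1, float(V))
        g2, rec2 = _membrane_potential_interaction(cfg, s2, float(V))
        records[f"state1@{V:+.1f}mV"] = rec1
        records[f"state2@{V:+.1f}mV"] = rec2
        rows.append(
            {
                "V_mV": float(V),
                "G1_kcal_per_mol": g1.kcal_per_mol,
                "G2_kcal_per_mol": g2.kcal_per_mol,
                "dG_kcal_per_mol": g2.kcal_per_mol - g1.kcal_per_mol,
                "dG_kT": g2.kT - g1.kT,
            }
        )
    table = pd.DataFrame(rows)
    vbar = table["V_mV"].to_numpy() * cfg.consts.phi_per_mV
    dg_kT = table["dG_kT"].to_numpy()
    slope, intercept = np.polyfit(vbar, dg_kT, 1)
    valence = -float(slope)
    # linearity check: lpbe guarantees dG linear in V to solver tolerance
    residual = float(np.max(np.abs(dg_kT - (slope * vbar + intercept)))) if len(vbar) else 0.0
    delta = EnergyReport(float(dg_kT[-1]), cfg.consts, f"dG at {voltages[-1]:+.1f} mV")
    result = WorkflowResult(
        "gating_charge",
        delta,
        {},
        records,
        valence_e=valence,
        sweep=table,
    )
    result.fit_residual_kT = residual
    return result


def run_workflow(cfg: WorkflowConfig) -> WorkflowResult:
    """Dispatch on the configured calculation type."""
    return {
        "protein_solvation": protein_solvation,
        "ion_solvation": ion_solvation,
        "gating_charge": gating_charge,
    }[cfg.calculation_type](cfg)


def convergence_scan(cfg: WorkflowConfig, node_counts: Sequence[int]) -> pd.DataFrame:
    """Re-run a workflow over a list of grid node counts, all else fixed.

    Returns one row per node count with the finest-level spacing, the
    workflow's derived value, and the percent error relative to the result
    at the finest spacing scanned.
    """
    from dataclasses import replace

    rows = []
    for n in node_counts:
        sub = replace(cfg, nodes=int(n))
        res = run_workflow(sub)
        value = res.valence_e if res.valence_e is not None else res.delta.kcal_per_mol
        spacing = min(cfg.lengths) / (int(n) - 1)
        rows.append({"nodes": int(n), "spacing_A": spacing, "value": value})
    df = pd.DataFrame(rows).sort_values("spacing_A", ascending=True).reset_index(drop=True)
    ref = df.loc[0, "value"]
    df["pct_error_vs_finest"] = 100.0 * np.abs((df["value"] - ref) / ref) if ref != 0 else 0.0
    return df
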