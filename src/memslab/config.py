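"""Flat key/value run configurations mirroring the GUI parameter surface.

Configs are TOML files with quoted keys named after the tool's parameter
labels ("Solvent probe radius (srad)", "Z-position of membrane bottom", ...)
so a config is directly diffable against a published parameter table.
Unknown keys are rejected; load/dump round-trips losslessly.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

from .constants import PhysicalConstants
from .field_maps import IonSpecies, SurfaceSpec
from .membrane import MembraneGeometry
from .structure import read_pqr
from .workflows import WorkflowConfig

__all__ = ["RunConfig", "load_config", "dump_config", "packaged_case", "PACKAGED_CASES"]

_CALC_TYPES = {
    "Protein solvation": "protein_solvation",
    "Ion solvation": "ion_solvation",
    "Gating charge": "gating_charge",
}
_BC_NAMES = {
    "Zero": "zero",
    "Single Debye-Huckel": "single_debye_huckel",
    "Multiple Debye-Huckel": "multiple_debye_huckel",
    "Focus": "multiple_debye_huckel",  # coarse level of a focusing ladder
    "Membrane potential": "membrane_potential",
}

PACKAGED_CASES = {
    "case1": "case1_protein_solvation.toml",
    "case2": "case2_ion_solvation.toml",
    "case3": "case3_gating_charge.toml",
}


@dataclass
class RunConfig:
    """One calculation, parameter-for-parameter as the GUI presents it."""

    calculation_type: str  # label form, e.g. "Protein solvation"
    pqr_file_1: str
    pqr_file_2: str | None = None
    grid_dimensions: int = 161
    coarse_grid_lengths: float = 200.0
    medium_grid_lengths: float | None = None
    fine_grid_lengths: float | None = None
    counter_ions: list[list[float]] = field(
        default_factory=lambda: [[1.0, 0.10, 2.0], [-1.0, 0.10, 2.0]]
    )
    protein_dielectric: float = 5.0
    solvent_dielectric: float = 80.0
    membrane_dielectric: float = 2.0
    headgroup_dielectric: float = 80.0
    solution_method: str = "lpbe"
    boundary_condition: str = "Focus"
    solvent_probe_radius: float = 1.4
    surface_sphere_density: float = 10.0
    temperature: float = 298.15
    z_membrane_bottom: float = -21.0
    membrane_thickness: float = 42.0
    headgroup_thickness: float = 0.0
    upper_exclusion_radius: float = 0.0
    lower_exclusion_radius: float = 0.0
    membrane_potential_mV: float = 50.0
    sweep_points: int = 5
    protein_charges: str = "on"
    charge_residue_range: list[int] | None = None

    def validate(self) -> None:
        if self.calculation_type not in _CALC_TYPES:
            raise ValueError(
                f"unknown calculation type {self.calculation_type!r}; "
                f"expected one of {sorted(_CALC_TYPES)}"
            )
        if self.solution_method != "lpbe":
            raise ValueError(
                "only the linearized PB equation (lpbe) is supported"
            )
        if self.boundary_condition not in _BC_NAMES:
            raise ValueError(f"unknown boundary condition {self.boundary_condition!r}")
        if self.membrane_thickness <= 0:
            raise ValueError("membrane thickness must be positive")
        if self.grid_dimensions < 3:
            raise ValueError("grid dimensions must be at least 3")
        needs_two = self.calculation_type in ("Ion solvation", "Gating charge")
        if needs_two and not self.pqr_file_2:
            raise ValueError(f"{self.calculation_type} requires two PQR files")
        if self.protein_charges not in ("on", "off"):
            raise ValueError("protein charges must be 'on' or 'off'")
        for triple in self.counter_ions:
            if len(triple) != 3:
                raise ValueError("counter-ion entries are (valence, molarity, radius)")

    # ------------------------------------------------------------------
    @property
    def ladder_lengths(self) -> list[float]:
        lengths = [self.coarse_grid_lengths]
        for L in (self.medium_grid_lengths, self.fine_grid_lengths):
            if L is not None:
                lengths.append(L)
        return lengths

    def membrane_geometry(self) -> MembraneGeometry:
        return MembraneGeometry(
            z_bottom=self.z_membrane_bottom,
            thickness=self.membrane_thickness,
            eps_membrane=self.membrane_dielectric,
            eps_headgroup=self.headgroup_dielectric,
            headgroup_thickness=self.headgroup_thickness,
            upper_exclusion_radius=self.upper_exclusion_radius,
            lower_exclusion_radius=self.lower_exclusion_radius,
        )

    def to_workflow(self, base_dir: str | Path = ".") -> WorkflowConfig:
        """Resolve PQR paths and build the library-level workflow config."""
        self.validate()
        base = Path(base_dir)
        structures = [read_pqr(base / self.pqr_file_1)]
        if self.pqr_file_2:
            structures.append(read_pqr(base / self.pqr_file_2))
        ions = [IonSpecies(v, c, r) for v, c, r in self.counter_ions]
        consts = PhysicalConstants(temperature=self.temperature)
        return WorkflowConfig(
            calculation_type=_CALC_TYPES[self.calculation_type],
            structures=structures,
            nodes=self.grid_dimensions,
            lengths=self.ladder_lengths,
            eps_protein=self.protein_dielectric,
            eps_solvent=self.solvent_dielectric,
            membrane=self.membrane_geometry(),
            surface=SurfaceSpec(
                solvent_probe_radius=self.solvent_probe_radius,
                surface_sphere_density=self.surface_sphere_density,
            ),
            ions=ions,
            consts=consts,
            outer_bc=_BC_NAMES[self.boundary_condition]
            if self.boundary_condition != "Membrane potential"
            else "multiple_debye_huckel",
            V_max_mV=self.membrane_potential_mV,
            sweep_points=self.sweep_points,
            protein_charges_on=self.protein_charges == "on",
            charge_residue_range=tuple(self.charge_residue_range)
            if self.charge_residue_range
            else None,
        )


# label <-> attribute table; order defines dump order
_FIELDS: list[tuple[str, str]] = [
    ("Calculation type", "calculation_type"),
    ("PQR file 1", "pqr_file_1"),
    ("PQR file 2", "pqr_file_2"),
    ("Grid dimensions", "grid_dimensions"),
    ("Coarse grid lengths", "coarse_grid_lengths"),
    ("Medium grid lengths", "medium_grid_lengths"),
    ("Fine grid lengths", "fine_grid_lengths"),
    ("Counter-ions", "counter_ions"),
    ("Protein dielectric", "protein_dielectric"),
    ("Solvent dielectric", "solvent_dielectric"),
    ("Membrane dielectric", "membrane_dielectric"),
    ("Headgroup dielectric", "headgroup_dielectric"),
    ("Solution method", "solution_method"),
    ("Boundary condition", "boundary_condition"),
    ("Solvent probe radius (srad)", "solvent_probe_radius"),
    ("Surface sphere density (sdens)", "surface_sphere_density"),
    ("Temperature", "temperature"),
    ("Z-position of membrane bottom", "z_membrane_bottom"),
    ("Membrane thickness", "membrane_thickness"),
    ("Head group thickness", "headgroup_thickness"),
    ("Upper exclusion radius", "upper_exclusion_radius"),
    ("Lower exclusion radius", "lower_exclusion_radius"),
    ("Membrane potential (mV)", "membrane_potential_mV"),
    ("Sweep points", "sweep_points"),
    ("Protein charges", "protein_charges"),
    ("Charge residue range", "charge_residue_range"),
]
_LABEL_TO_ATTR = dict(_FIELDS)


def _format_toml_value(v: Any) -> str:
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_format_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)}")


def dump_config(cfg: RunConfig, path: str | Path | None = None) -> str:
    """Serialize to flat TOML with parameter-label keys; returns the text."""
    lines = []
    for label, attr in _FIELDS:
        value = getattr(cfg, attr)
        if value is None:
            continue
        lines.append(f'"{label}" = {_format_toml_value(value)}')
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def _from_mapping(data: dict[str, Any], source: str = "<config>") -> RunConfig:
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        attr = _LABEL_TO_ATTR.get(key)
        if attr is None:
            raise ValueError(f"{source}: unknown configuration key {key!r}")
        kwargs[attr] = value
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a flat TOML run configuration."""
    path = Path(path)
    with path.open("rb") as fh:
        data = tomllib.load(fh)
    return _from_mapping(data, source=str(path))


def packaged_case(name: str) -> RunConfig:
    """One of the bundled worked-example configurations (case1/case2/case3)."""
    if name not in PACKAGED_CASES:
        raise KeyError(f"unknown case {name!r}; choose from {sorted(PACKAGED_CASES)}")
    text = (
        resources.files("memslab").joinpath("cases", PACKAGED_CASES[name]).read_text()
    )
    return _from_mapping(tomllib.loads(text), source=name)
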