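"""Synthetic structure generators.

The flagship fixture is an ideal transmembrane alpha-helix: 27 residues
aligned on z and centered at the origin, hydrophobic throughout except for
a single charged arginine at the central position (residue 14).  Residues
are coarse-grained to five pseudo-atoms (N, CA, C, O plus one side-chain
bead; arginine gets an additional +1 guanidinium bead) with PARSE-like net
charges, so every residue is net-neutral except the charged one.  The
fixture's role is to exercise the full pipeline deterministically, not to
reproduce any particular all-atom result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure import Atom, Structure

__all__ = ["HelixSpec", "build_helix", "build_test_charge_system"]


# name -> (charge e, radius Å, radial offset from CA ring Å) for the
# side-chain bead; PARSE-like magnitudes, coarse-grained.
_SIDECHAINS = {
    "LEU": [("CB", 0.0, 2.3, 1.7)],
    "ALA": [("CB", 0.0, 2.0, 1.2)],
    "VAL": [("CB", 0.0, 2.2, 1.5)],
    "ARG": [("CB", 0.0, 2.2, 1.7), ("CZ", 1.0, 2.2, 4.2)],
}

# backbone pseudo-atoms: (name, charge, radius); amide H folded into N/CA
_BACKBONE = [("N", -0.40, 1.50), ("CA", 0.40, 2.00), ("C", 0.55, 1.70), ("O", -0.55, 1.40)]


@dataclass(frozen=True)
class HelixSpec:
    """Geometry and sequence rule for the ideal helix fixture."""

    residue_count: int = 27
    charged_residue: str = "ARG"
    charged_position: int = 14  # 1-based; 0 disables the charged residue
    default_residue: str = "LEU"
    rise_per_residue: float = 1.5  # Å
    residues_per_turn: float = 3.6
    radius: float = 2.3  # Å, CA helix radius

    def __post_init__(self) -> None:
        if self.residue_count < 1:
            raise ValueError("residue count must be positive")
        if not 0 <= self.charged_position <= self.residue_count:
            raise ValueError("charged position must lie within [1, residue count]")
        for res in (self.charged_residue, self.default_residue):
            if res not in _SIDECHAINS:
                raise ValueError(
                    f"unknown residue {res!r}; known: {sorted(_SIDECHAINS)}"
                )


def build_helix(spec: HelixSpec = HelixSpec()) -> Structure:
    """Construct the ideal z-aligned helix, centered at the origin.

    Net charge equals the charge of the single charged residue (+1 e for
    the default arginine), carried by an outward-pointing side-chain bead.
    """
    atoms: list[Atom] = []
    serial = 1
    dtheta = 2.0 * math.pi / spec.residues_per_turn
    z0 = -(spec.residue_count - 1) * spec.rise_per_residue / 2.0
    for i in range(spec.residue_count):
        resnum = i + 1
        resname = (
            spec.charged_residue
            if resnum == spec.charged_position
            else spec.default_residue
        )
        theta = i * dtheta
        z = z0 + i * spec.rise_per_residue
        ca = np.array(
            [spec.radius * math.cos(theta), spec.radius * math.sin(theta), z]
        )
        u = np.array([math.cos(theta), math.sin(theta), 0.0])  # outward radial
        # backbone: N trails CA along the helix, C/O lead it
        n_theta, c_theta = theta - 0.5, theta + 0.5
        pos_n = np.array(
            [1.6 * math.cos(n_theta), 1.6 * math.sin(n_theta), z - 0.6]
        )
        pos_c = np.array(
            [1.7 * math.cos(c_theta), 1.7 * math.sin(c_theta), z + 0.6]
        )
        pos_o = np.array(
            [2.9 * math.cos(c_theta), 2.9 * math.sin(c_theta), z + 0.6]
        )
        backbone_pos = {"N": pos_n, "CA": ca, "C": pos_c, "O": pos_o}
        for name, q, r in _BACKBONE:
            atoms.append(
                Atom(serial, name, resname, resnum, backbone_pos[name], q, r)
            )
            serial += 1
        for name, q, r, offset in _SIDECHAINS[resname]:
            pos = ca + u * offset
            atoms.append(Atom(serial, name, resname, resnum, pos, q, r))
            serial += 1
    return Structure(atoms, label=f"ideal {spec.residue_count}-residue helix")


def build_test_charge_system(
    z1: float, z2: float, q: float = 1.0, radius: float = 2.0
) -> tuple[Structure, Structure]:
    """Two single-atom structures differing only in z.

    The canonical input pair for gating-valence checks: a probe charge on
    the membrane axis, below the slab in state 1 and elsewhere in state 2.
    """
    def one(z: float, label: str) -> Structure:
        return Structure(
            [Atom(1, "Q", "ION", 1, np.array([0.0, 0.0, z]), q, radius)],
            label=label,
        )

    return one(z1, f"test charge at z={z1:g}"), one(z2, f"test charge at z={z2:g}")
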