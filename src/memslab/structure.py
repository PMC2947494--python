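"""PQR structures: atoms with coordinates, charges, and radii.

The PQR dialect parsed here is the whitespace-delimited PDB2PQR output
convention: ATOM/HETATM records with fields

    ATOM serial name resname [chain] resnum x y z charge radius

The optional chain-ID column is detected by field counting.  Fixed-column
PQR is deliberately not assumed — the format is not standardized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "PQRParseError",
    "read_pqr",
    "write_pqr",
    "net_charge",
]


class PQRParseError(ValueError):
    """Raised when a PQR record cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class Atom:
    """A single atom: position in Å, charge in e, radius in Å."""

    serial: int
    name: str
    residue_name: str
    residue_number: int
    position: np.ndarray  # shape (3,), Å
    charge: float  # e
    radius: float  # Å
    chain: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise ValueError("position components must be finite")
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        object.__setattr__(self, "position", pos)

    def with_charge(self, charge: float) -> "Atom":
        return replace(self, charge=float(charge))


@dataclass
class Structure:
    """An ordered collection of atoms (the content of one PQR file)."""

    atoms: list[Atom] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def __getitem__(self, i: int) -> Atom:
        return self.atoms[i]

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of atomic positions in Å."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum()) if self.atoms else 0.0

    def translated(self, shift: Sequence[float]) -> "Structure":
        shift = np.asarray(shift, dtype=float)
        return Structure(
            [replace(a, position=a.position + shift) for a in self.atoms],
            label=self.label,
        )

    def with_zero_charges(self) -> "Structure":
        """Copy with every partial charge set to zero (cavity shape kept)."""
        return Structure([a.with_charge(0.0) for a in self.atoms], label=self.label)

    def with_charge_mask(self, keep: Iterable[bool]) -> "Structure":
        """Copy keeping charges only where ``keep`` is true (residue subsetting)."""
        keep = list(keep)
        if len(keep) != len(self.atoms):
            raise ValueError("mask length must equal atom count")
        return Structure(
            [a if k else a.with_charge(0.0) for a, k in zip(self.atoms, keep)],
            label=self.label,
        )

    def residue_charge_mask(self, first: int, last: int) -> list[bool]:
        """Boolean mask selecting atoms with residue_number in [first, last]."""
        return [first <= a.residue_number <= last for a in self.atoms]

    def __add__(self, other: "Structure") -> "Structure":
        return Structure(self.atoms + other.atoms, label=self.label)


def _parse_record(tokens: list[str], lineno: int) -> Atom:
    # ATOM serial name resname [chain] resnum x y z q r
    if len(tokens) == 10:
        chain = ""
        resnum_tok = tokens[4]
    elif len(tokens) == 11:
        chain = tokens[4]
        resnum_tok = tokens[5]
    else:
        raise PQRParseError(
            f"line {lineno}: expected 10 or 11 fields, got {len(tokens)}"
        )
    try:
        serial = int(tokens[1])
        resnum = int(resnum_tok)
        x, y, z, q, r = (float(t) for t in tokens[-5:])
    except ValueError as exc:
        raise PQRParseError(f"line {lineno}: unparseable numeric field: {exc}") from exc
    return Atom(
        serial=serial,
        name=tokens[2],
        residue_name=tokens[3],
        residue_number=resnum,
        position=np.array([x, y, z]),
        charge=q,
        radius=r,
        chain=chain,
    )


def read_pqr(path: str | Path, label: str | None = None) -> Structure:
    """Read a whitespace-delimited PQR file.

    Atoms appear in file order; REMARK/TER/END and other non-record lines
    are ignored.  Raises :class:`PQRParseError` on malformed records and on
    structures with no atoms.
    """
    path = Path(path)
    atoms: list[Atom] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or tokens[0] not in ("ATOM", "HETATM"):
                continue
            atoms.append(_parse_record(tokens, lineno))
    if not atoms:
        raise PQRParseError(f"{path}: no ATOM/HETATM records found")
    return Structure(atoms, label=label if label is not None else path.stem)


def write_pqr(s: Structure, path: str | Path) -> None:
    """Write a Structure as whitespace-delimited PQR (4-decimal precision)."""
    if not s.atoms:
        raise ValueError("refusing to write an empty structure")
    path = Path(path)
    with path.open("w") as fh:
        if s.label:
            fh.write(f"REMARK  {s.label}\n")
        for a in s.atoms:
            chain = f" {a.chain}" if a.chain else ""
            fh.write(
                f"ATOM  {a.serial:5d} {a.name:<4s} {a.residue_name:<4s}{chain}"
                f"{a.residue_number:5d} "
                f"{a.position[0]:11.4f} {a.position[1]:11.4f} {a.position[2]:11.4f} "
                f"{a.charge:9.4f} {a.radius:8.4f}\n"
            )
        fh.write("END\n")


def net_charge(s: Structure) -> float:
    """Exact sum of atomic partial charges, in e."""
    return s.net_charge
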