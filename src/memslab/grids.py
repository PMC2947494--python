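"""Regular 3-D scalar grids and OpenDX I/O.

Grids are axis-aligned and node-centered: node (i, j, k) sits at
``origin + (i*hx, j*hy, k*hz)``, 0-based.  Values are stored as a C-ordered
(nx, ny, nz) array, which matches the OpenDX "regular positions, regular
connections" convention of z varying fastest.  On-disk I/O is delegated to
GridDataFormats.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from gridData import Grid as _DXGrid

__all__ = ["GridSpec", "ScalarGrid", "GridFormatError", "read_dx", "write_dx"]


class GridFormatError(ValueError):
    """Raised for malformed or unsupported grid files."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular grid: node counts, origin (Å), spacing (Å)."""

    shape: tuple[int, int, int]
    origin: np.ndarray  # (3,)
    spacing: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        origin = np.asarray(self.origin, dtype=float)
        spacing = np.asarray(self.spacing, dtype=float)
        if len(shape) != 3 or any(n < 2 for n in shape):
            raise ValueError("shape must be three integers >= 2")
        if origin.shape != (3,) or spacing.shape != (3,):
            raise ValueError("origin and spacing must be 3-vectors")
        if np.any(spacing <= 0):
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)

    @classmethod
    def from_center_length(
        cls,
        center: Sequence[float],
        length: float | Sequence[float],
        nodes: int | Sequence[int],
    ) -> "GridSpec":
        """Build from (center, side length, node count) — spacing = L/(n-1)."""
        center = np.asarray(center, dtype=float)
        length = np.broadcast_to(np.asarray(length, dtype=float), (3,)).copy()
        nodes = np.broadcast_to(np.asarray(nodes, dtype=int), (3,)).copy()
        spacing = length / (nodes - 1)
        origin = center - length / 2.0
        return cls(tuple(int(n) for n in nodes), origin, spacing)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    @property
    def lengths(self) -> np.ndarray:
        return (np.array(self.shape) - 1) * self.spacing

    @property
    def center(self) -> np.ndarray:
        return self.origin + self.lengths / 2.0

    @property
    def upper_corner(self) -> np.ndarray:
        return self.origin + self.lengths

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis node coordinate vectors."""
        return tuple(
            self.origin[d] + self.spacing[d] * np.arange(self.shape[d])
            for d in range(3)
        )

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x, y, z = self.axes()
        return np.meshgrid(x, y, z, indexing="ij")

    def congruent(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )

    def contains(self, other: "GridSpec", strict: bool = True) -> bool:
        """Whether ``other``'s domain lies inside this grid's domain."""
        pad = 1e-9 if not strict else -1e-9
        return bool(
            np.all(other.origin >= self.origin - pad)
            and np.all(other.upper_corner <= self.upper_corner + pad)
        )


@dataclass
class ScalarGrid:
    """One scalar value per node of a :class:`GridSpec`."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.spec.shape:
            raise GridFormatError(
                f"value array shape {values.shape} does not match grid shape "
                f"{self.spec.shape}"
            )
        self.values = values

    @classmethod
    def full(cls, spec: GridSpec, fill: float) -> "ScalarGrid":
        return cls(spec, np.full(spec.shape, float(fill)))

    def copy(self) -> "ScalarGrid":
        return ScalarGrid(self.spec, self.values.copy())

    def congruent(self, other: "ScalarGrid") -> bool:
        return self.spec.congruent(other.spec)


def write_dx(g: ScalarGrid, path: str | Path, label: str = "memslab map") -> None:
    """Write an OpenDX scalar grid (regular positions/connections, z fastest)."""
    dx = _DXGrid(g.values, origin=g.spec.origin, delta=g.spec.spacing)
    dx.export(str(path), file_format="DX")


def read_dx(path: str | Path) -> ScalarGrid:
    """Read an OpenDX scalar grid into a :class:`ScalarGrid`.

    Only regular (uniformly spaced, axis-aligned) grids are supported;
    anything else raises :class:`GridFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        dx = _DXGrid(str(path))
    except Exception as exc:  # gridData raises assorted types on bad input
        raise GridFormatError(f"{path}: not a readable OpenDX scalar grid: {exc}") from exc
    delta = np.asarray(dx.delta, dtype=float)
    if delta.ndim == 2:
        if not np.allclose(delta, np.diag(np.diag(delta))):
            raise GridFormatError(f"{path}: non-axis-aligned grid not supported")
        delta = np.diag(delta)
    values = np.asarray(dx.grid, dtype=float)
    spec = GridSpec(values.shape, np.asarray(dx.origin, dtype=float), delta)
    return ScalarGrid(spec, values)
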