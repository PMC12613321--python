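"""Periodic crystal structures built from rigid-molecule placements.

A :class:`CrystalStructure` is a unit cell plus Z symmetry-related rigid
copies of one molecule.  Each copy is stored as a placement (fractional
center of geometry, 3x3 Cartesian rotation — possibly improper for
mirror/inversion images); Cartesian atom coordinates are derived, never
stored authoritatively, so the rigid-body invariant cannot drift.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .chem_core import Molecule
from . import symmetry as _sym

__all__ = ["CrystalStructure", "StructurePool"]


@dataclass(eq=False)
class CrystalStructure:
    """Unit cell + Z rigid molecule copies, tagged with space group and stage."""

    cell: np.ndarray
    sg_number: int
    molecule: Molecule
    placements: list[tuple[np.ndarray, np.ndarray]]
    lattice_system: str | None = None
    tags: dict = field(default_factory=dict)
    energy: float | None = None  # kJ/mol per molecule

    def __post_init__(self) -> None:
        self.cell = np.asarray(self.cell, dtype=float)
        if self.cell.shape != (3, 3):
            raise ValueError("cell must be 3x3")
        if np.linalg.det(self.cell) <= 0:
            raise ValueError("cell must have positive determinant")
        if self.lattice_system is None:
            self.lattice_system = _sym.get_space_group(self.sg_number).crystal_system
        self.placements = [
            (np.asarray(c, float), np.asarray(R, float)) for c, R in self.placements
        ]

    @classmethod
    def from_asym_unit(
        cls,
        cell: np.ndarray,
        sg: "_sym.SpaceGroup | int",
        molecule: Molecule,
        frac_cog: np.ndarray,
        rotation: np.ndarray,
        lattice_system: str | None = None,
        tags: dict | None = None,
    ) -> "CrystalStructure":
        """Build the full cell by applying the group's general operations."""
        if isinstance(sg, int):
            sg = _sym.get_space_group(sg)
        placements = _sym.apply_ops(sg, frac_cog, rotation, cell)
        return cls(
            cell=cell,
            sg_number=sg.number,
            molecule=molecule,
            placements=placements,
            lattice_system=lattice_system,
            tags=dict(tags or {}),
        )

    @property
    def Z(self) -> int:
        return len(self.placements)

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.cell))

    def cartesian_coords(self) -> np.ndarray:
        """Atom coordinates, shape (Z, N_atoms, 3), Angstrom."""
        body = self.molecule.body_frame_coords()
        out = np.empty((self.Z, self.molecule.n_atoms, 3))
        for m, (cog_frac, R) in enumerate(self.placements):
            out[m] = cog_frac @ self.cell + body @ R.T
        return out

    def fractional_coords(self) -> np.ndarray:
        """All-atom fractional coordinates, shape (Z * N_atoms, 3)."""
        cart = self.cartesian_coords().reshape(-1, 3)
        return cart @ np.linalg.inv(self.cell)

    def all_elements(self) -> list[str]:
        return list(self.molecule.elements) * self.Z

    def copy(self) -> "CrystalStructure":
        return CrystalStructure(
            cell=self.cell.copy(),
            sg_number=self.sg_number,
            molecule=self.molecule,
            placements=[(c.copy(), R.copy()) for c, R in self.placements],
            lattice_system=self.lattice_system,
            tags=_copy.deepcopy(self.tags),
            energy=self.energy,
        )


class StructurePool:
    """Ordered collection of structures with pool-level metadata.

    Stage history lives in each structure's ``tags["stages"]`` list; cluster
    labels, energies and provenance ids likewise travel with the structure.
    """

    def __init__(
        self,
        structures: list[CrystalStructure] | None = None,
        metadata: dict | None = None,
    ) -> None:
        self.structures: list[CrystalStructure] = list(structures or [])
        self.metadata: dict = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.structures)

    def __iter__(self) -> Iterator[CrystalStructure]:
        return iter(self.structures)

    def __getitem__(self, i):
        return self.structures[i]

    def append(self, s: CrystalStructure) -> None:
        self.structures.append(s)

    def energies(self) -> np.ndarray:
        vals = [s.energy for s in self.structures]
        if any(v is None for v in vals):
            missing = [s.tags.get("id", i) for i, s in enumerate(self) if s.energy is None]
            raise ValueError(f"structures missing energies: {missing[:5]}")
        return np.array(vals, dtype=float)

    def subset(self, indices) -> "StructurePool":
        """New pool of copies of the selected structures (stage operations
        tag their outputs, so sharing objects across pools would leak)."""
        return StructurePool(
            [self.structures[i].copy() for i in indices], metadata=dict(self.metadata)
        )
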