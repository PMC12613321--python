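"""Synthetic test inputs: parametric toy molecules and perturbation helpers.

Everything here is generated programmatically and deterministically under a
fixed seed; no downloads, no bundled geometry files.  Toy molecules use real
elements (C, H, N, O) so the vdW table and hydrogen-bond tagging paths are
exercised by the same code that handles real molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .chem_core import Molecule, load_vdw_table
from .structures import CrystalStructure

__all__ = ["ToyMoleculeSpec", "single_sphere", "make_toy_molecule", "perturb"]

#: covalent radii (Angstrom) for the non-self-overlap invariant
_COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66}

_SHAPES = ("sphere-cluster", "rod", "planar-ring")


@dataclass
class ToyMoleculeSpec:
    n_atoms: int = 3
    shape: str = "rod"
    elements: tuple[str, ...] = ("C", "O", "N", "H")
    spacing: float = 1.5  # rod inter-atom / ring radius scale, Angstrom
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}")
        if self.shape == "planar-ring" and self.n_atoms < 3:
            raise ValueError("a ring needs at least 3 atoms")


def single_sphere(element: str = "C") -> Molecule:
    """One-atom molecule (enclosing diameter zero) for closed-form tests."""
    table = load_vdw_table()
    return Molecule(
        [element], np.zeros((1, 3)), np.array([table[element]]), name=f"sphere-{element}"
    )


def make_toy_molecule(spec: ToyMoleculeSpec) -> Molecule:
    """Deterministic rigid toy molecule; atoms never closer than 0.9x the
    sum of their covalent radii."""
    rng = np.random.default_rng(spec.seed)
    elements = [spec.elements[i % len(spec.elements)] for i in range(spec.n_atoms)]
    if spec.shape == "rod":
        coords = np.zeros((spec.n_atoms, 3))
        coords[:, 0] = np.arange(spec.n_atoms) * spec.spacing
    elif spec.shape == "planar-ring":
        ang = 2 * np.pi * np.arange(spec.n_atoms) / spec.n_atoms
        r = spec.spacing
        # ensure neighbors respect the covalent-overlap invariant
        min_sep = 0.9 * 2 * max(_COVALENT_RADII[e] for e in set(elements))
        chord = 2 * r * np.sin(np.pi / spec.n_atoms)
        if chord < min_sep:
            r = min_sep / (2 * np.sin(np.pi / spec.n_atoms))
        coords = np.stack([r * np.cos(ang), r * np.sin(ang), np.zeros_like(ang)], axis=1)
    else:  # sphere-cluster: rejection-sampled points in a ball
        coords = np.zeros((spec.n_atoms, 3))
        radius = spec.spacing * max(1.0, spec.n_atoms ** (1 / 3))
        for i in range(1, spec.n_atoms):
            for _ in range(10_000):
                p = rng.uniform(-radius, radius, size=3)
                if np.linalg.norm(p) > radius:
                    continue
                d = np.linalg.norm(coords[:i] - p, axis=1)
                limits = np.array(
                    [
                        0.9 * (_COVALENT_RADII[elements[i]] + _COVALENT_RADII[elements[j]])
                        for j in range(i)
                    ]
                )
                if np.all(d > limits):
                    coords[i] = p
                    break
            else:
                raise RuntimeError("could not place sphere-cluster atom")
    table = load_vdw_table()
    radii = np.array([table[e] for e in elements])
    name = f"toy-{spec.shape}-{spec.n_atoms}"
    return Molecule(elements, coords, radii, name=name)


def perturb(
    structure: CrystalStructure,
    magnitude: float,
    rng: np.random.Generator | None = None,
) -> CrystalStructure:
    """Origin-shifted, slightly strained and rotated copy of a structure.

    magnitude 0 returns an identical copy; magnitude ~1 stays well within
    the default duplicate-match tolerances (strain entries <= 2% * magnitude,
    per-molecule rotations <= 0.05 * magnitude rad, COG jitter <= 0.5% of a
    fractional unit * magnitude, plus a uniform origin shift scaled by
    magnitude).  Useful for building dedup positive/negative test pairs.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    out = structure.copy()
    if magnitude == 0:
        return out
    rng = rng or np.random.default_rng(0)
    strain = magnitude * 0.02 * rng.uniform(-1, 1, size=(3, 3))
    strain = 0.5 * (strain + strain.T)
    out.cell = structure.cell @ (np.eye(3) + strain)
    origin = magnitude * rng.uniform(0, 1, size=3)
    new_placements = []
    for cog, R in out.placements:
        jitter = magnitude * 0.005 * rng.uniform(-1, 1, size=3)
        axis_angle = magnitude * 0.05 * rng.uniform(-1, 1, size=3)
        dR = Rotation.from_rotvec(axis_angle).as_matrix()
        new_placements.append((((cog + origin + jitter) % 1.0), dR @ R))
    out.placements = new_placements
    out.tags["perturbed"] = magnitude
    return out
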