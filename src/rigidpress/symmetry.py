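"""Space-group data, Z-compatibility, lattice parameterization, detection.

Conventions fixed throughout the package:

* cell matrices are row-vector 3x3 arrays (rows a, b, c) with a along x and
  b in the xy-plane; Cartesian = fractional @ cell;
* symmetry operations act on column fractional coordinates, f' = W f + w;
* monoclinic groups use unique axis b (free angle beta); trigonal groups use
  the hexagonal setting;
* only general positions are considered (Z' = 1), so a space group is
  compatible with Z exactly when its general-position multiplicity equals Z.

The operation table for the 230 groups in their standard settings is read
from gemmi.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import gemmi
import numpy as np

__all__ = [
    "SpaceGroup",
    "LatticeParams",
    "FREE_PARAM_COUNT",
    "get_space_group",
    "compatible_space_groups",
    "build_cell",
    "cell_to_params",
    "lattice_params_from_cell",
    "apply_ops",
    "detect_space_group",
    "cartesian_rotation",
]

CRYSTAL_SYSTEMS = (
    "triclinic",
    "monoclinic",
    "orthorhombic",
    "tetragonal",
    "trigonal",
    "hexagonal",
    "cubic",
)

#: number of independent cell parameters per crystal system
FREE_PARAM_COUNT = {
    "triclinic": 6,
    "monoclinic": 4,
    "orthorhombic": 3,
    "tetragonal": 2,
    "trigonal": 2,
    "hexagonal": 2,
    "cubic": 1,
}


@dataclass(frozen=True)
class SpaceGroup:
    """One of the 230 space groups in its standard setting."""

    number: int
    symbol: str
    crystal_system: str
    rotations: np.ndarray  # (m, 3, 3) integer
    translations: np.ndarray  # (m, 3) fractional

    @property
    def multiplicity(self) -> int:
        """General-position multiplicity (centering included)."""
        return len(self.rotations)

    @property
    def is_sohncke(self) -> bool:
        return bool(np.all(np.linalg.det(self.rotations) > 0))


@dataclass
class LatticeParams:
    """The independent cell parameters of a crystal system.

    free_values order: lengths first (Angstrom), then free angles (degrees) —
    triclinic (a,b,c,alpha,beta,gamma); monoclinic (a,b,c,beta);
    orthorhombic (a,b,c); tetragonal (a,c); trigonal/hexagonal (a,c);
    cubic (a,).
    """

    crystal_system: str
    free_values: np.ndarray

    def __post_init__(self) -> None:
        if self.crystal_system not in FREE_PARAM_COUNT:
            raise ValueError(f"unknown crystal system {self.crystal_system!r}")
        self.free_values = np.asarray(self.free_values, dtype=float)
        n = FREE_PARAM_COUNT[self.crystal_system]
        if self.free_values.shape != (n,):
            raise ValueError(
                f"{self.crystal_system} needs {n} free parameters, "
                f"got shape {self.free_values.shape}"
            )

    def full_parameters(self) -> tuple[float, float, float, float, float, float]:
        """Expand to (a, b, c, alpha, beta, gamma)."""
        v = self.free_values
        sys = self.crystal_system
        if sys == "triclinic":
            return tuple(v)
        if sys == "monoclinic":
            return (v[0], v[1], v[2], 90.0, v[3], 90.0)
        if sys == "orthorhombic":
            return (v[0], v[1], v[2], 90.0, 90.0, 90.0)
        if sys == "tetragonal":
            return (v[0], v[0], v[1], 90.0, 90.0, 90.0)
        if sys in ("trigonal", "hexagonal"):
            return (v[0], v[0], v[1], 90.0, 90.0, 120.0)
        return (v[0], v[0], v[0], 90.0, 90.0, 90.0)  # cubic


@lru_cache(maxsize=None)
def get_space_group(number: int) -> SpaceGroup:
    """Standard-setting space group by International Tables number (1-230)."""
    if not 1 <= number <= 230:
        raise ValueError(f"space group number out of range: {number}")
    sg = gemmi.find_spacegroup_by_number(number)
    ops = list(sg.operations())
    den = float(gemmi.Op.DEN)
    rot = np.array([op.rot for op in ops], dtype=float) / den
    tran = np.array([op.tran for op in ops], dtype=float) / den
    if not np.allclose(rot, np.round(rot)):
        raise RuntimeError(f"non-integer rotation parts for group {number}")
    # identity operation first: downstream code treats copy 0 as the
    # asymmetric unit's own image
    tran = tran % 1.0
    is_id = [
        np.array_equal(np.round(r), np.eye(3)) and np.allclose(t, 0)
        for r, t in zip(rot, tran)
    ]
    order = sorted(range(len(ops)), key=lambda i: not is_id[i])
    rot, tran = rot[order], tran[order]
    return SpaceGroup(
        number=number,
        symbol=sg.hm,
        crystal_system=sg.crystal_system_str(),
        rotations=np.round(rot).astype(int),
        translations=tran,
    )


@lru_cache(maxsize=None)
def _multiplicity_table() -> tuple[tuple[int, int], ...]:
    return tuple((n, get_space_group(n).multiplicity) for n in range(1, 231))


def compatible_space_groups(Z: int, sohncke_only: bool = False) -> list[SpaceGroup]:
    """All space groups whose general-position multiplicity equals Z.

    Z' = 1 with the molecule on a general position, so the multiplicity must
    match the requested number of molecules per cell exactly.  An empty list
    (e.g. Z = 5) is a valid result, not an error.
    """
    if Z < 1:
        raise ValueError("Z must be >= 1")
    groups = [get_space_group(n) for n, m in _multiplicity_table() if m == Z]
    if sohncke_only:
        groups = [g for g in groups if g.is_sohncke]
    return groups


def build_cell(params: LatticeParams, det_tol: float = 1e-10) -> np.ndarray:
    """Row-vector cell matrix from lattice parameters (a along x, b in xy)."""
    a, b, c, alpha, beta, gamma = params.full_parameters()
    if min(a, b, c) <= 0:
        raise ValueError("cell lengths must be positive")
    for ang in (alpha, beta, gamma):
        if not 0.0 < ang < 180.0:
            raise ValueError(f"cell angle out of (0, 180): {ang}")
    al, be, ga = np.radians([alpha, beta, gamma])
    cx = c * np.cos(be)
    cy = c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
    cz_sq = c * c - cx * cx - cy * cy
    if cz_sq <= 0:
        raise ValueError("degenerate cell: incompatible angles")
    cell = np.array(
        [
            [a, 0.0, 0.0],
            [b * np.cos(ga), b * np.sin(ga), 0.0],
            [cx, cy, np.sqrt(cz_sq)],
        ]
    )
    if np.linalg.det(cell) <= det_tol:
        raise ValueError("degenerate cell: determinant too small")
    return cell


def cell_to_params(cell: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """(a, b, c, alpha, beta, gamma) of a row-vector cell matrix."""
    cell = np.asarray(cell, dtype=float)
    a, b, c = np.linalg.norm(cell, axis=1)
    alpha = np.degrees(np.arccos(np.clip(cell[1] @ cell[2] / (b * c), -1, 1)))
    beta = np.degrees(np.arccos(np.clip(cell[0] @ cell[2] / (a * c), -1, 1)))
    gamma = np.degrees(np.arccos(np.clip(cell[0] @ cell[1] / (a * b), -1, 1)))
    return (a, b, c, alpha, beta, gamma)


def lattice_params_from_cell(cell: np.ndarray, crystal_system: str) -> LatticeParams:
    """Extract the free parameters of ``crystal_system`` from a cell matrix."""
    a, b, c, alpha, beta, gamma = cell_to_params(cell)
    sys = crystal_system
    if sys == "triclinic":
        free = [a, b, c, alpha, beta, gamma]
    elif sys == "monoclinic":
        free = [a, b, c, beta]
    elif sys == "orthorhombic":
        free = [a, b, c]
    elif sys in ("tetragonal", "trigonal", "hexagonal"):
        free = [a, c]
    elif sys == "cubic":
        free = [a]
    else:
        raise ValueError(f"unknown crystal system {sys!r}")
    return LatticeParams(sys, np.array(free))


def cartesian_rotation(W: np.ndarray, cell: np.ndarray) -> np.ndarray:
    """Cartesian operator of the fractional rotation part W in this cell.

    R = A_col W A_col^-1 with A_col = cell.T; orthogonal (det +-1) whenever
    the cell metric is compatible with the operation.
    """
    A = cell.T
    return A @ W @ np.linalg.inv(A)


def apply_ops(
    sg: SpaceGroup,
    asym_frac_cog: np.ndarray,
    asym_rotation: np.ndarray,
    cell: np.ndarray,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Generate all Z symmetry copies of the asymmetric unit's placement.

    Returns one (fractional COG wrapped to [0,1), Cartesian rotation matrix)
    per general operation; the rotation may be improper for mirror/inversion
    operations.
    """
    out = []
    for W, w in zip(sg.rotations, sg.translations):
        cog = (W @ np.asarray(asym_frac_cog, float) + w) % 1.0
        R = cartesian_rotation(W, cell) @ asym_rotation
        out.append((cog, R))
    return out


@lru_cache(maxsize=1)
def _unimodular_candidates() -> np.ndarray:
    """All 3x3 integer matrices with entries in -1..1 and determinant +-1."""
    Ws = np.array(list(itertools.product((-1, 0, 1), repeat=9)), dtype=float)
    Ws = Ws.reshape(-1, 3, 3)
    dets = np.round(np.linalg.det(Ws))
    return Ws[np.abs(dets) == 1].astype(int)


def _candidate_rotations(cell: np.ndarray, tol: float) -> np.ndarray:
    """Integer matrices W (entries -1..1, det +-1) preserving the cell metric."""
    G = cell @ cell.T  # metric tensor (row convention; equals A_col^T A_col)
    Ws = _unimodular_candidates()
    M = np.einsum("nji,jk,nkl->nil", Ws, G, Ws)  # W^T G W for every candidate
    keep = np.abs(M - G).max(axis=(1, 2)) < tol * np.abs(G).max()
    return Ws[keep]


def detect_space_group(structure, tol: float = 1e-5) -> int:
    """Detect the space-group number of a periodic structure.

    Finds all operations (W, w) mapping the atom set onto itself (elements
    respected, Cartesian displacement below ``tol`` Angstrom after minimum
    image), snaps translations to the nearest 1/12, and identifies the group
    from the operation set.  Deterministic for fixed input and tolerance; the
    stored space-group label of the structure is never consulted.
    """
    cell = structure.cell
    frac = structure.fractional_coords() % 1.0  # (n, 3) all atoms
    elements = np.array(list(structure.molecule.elements) * structure.Z)
    ops_found: list[gemmi.Op] = []
    seen: set[tuple] = set()
    ref = 0  # index of reference atom
    same_el = np.flatnonzero(elements == elements[ref])
    den = gemmi.Op.DEN
    for W in _candidate_rotations(cell, tol=1e-6):
        mapped_ref = W @ frac[ref]
        # centered groups pair one rotation with several translations, so
        # every same-element target atom is tried and all hits are kept
        for j in same_el:
            w = (frac[j] - mapped_ref) % 1.0
            key = (W.tobytes(), tuple(np.round(w * den).astype(int) % den))
            if key in seen:
                continue
            if _is_symmetry_op(W, w, frac, elements, cell, tol):
                seen.add(key)
                ops_found.append(_to_gemmi_op(W, w))
    if not ops_found:
        raise RuntimeError("symmetry detection failed: no operations found")
    group_ops = gemmi.GroupOps(ops_found)
    sg = gemmi.find_spacegroup_by_ops(group_ops)
    if sg is None:
        raise RuntimeError(
            f"could not identify a space group from {len(ops_found)} operations"
        )
    return sg.number


def _is_symmetry_op(W, w, frac, elements, cell, tol) -> bool:
    mapped = (frac @ W.T + w) % 1.0
    for el in np.unique(elements):
        sel = elements == el
        delta = mapped[sel][:, None, :] - frac[sel][None, :, :]
        delta -= np.round(delta)
        dist = np.linalg.norm(delta @ cell, axis=-1)
        # every mapped atom must land on a distinct original atom
        if dist.min(axis=1).max() > tol:
            return False
        if len(set(dist.argmin(axis=1))) != sel.sum():
            return False
    return True


def _to_gemmi_op(W: np.ndarray, w: np.ndarray) -> gemmi.Op:
    den = gemmi.Op.DEN
    op = gemmi.Op()
    op.rot = [[int(x) * den for x in row] for row in W]
    op.tran = [int(round(x * den)) % den for x in w]
    return op
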