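"""Rigid-molecule representation and hard-sphere contact geometry.

A molecule is treated as a rigid body throughout: internal coordinates are
frozen and only its placement (center of geometry, orientation) changes
downstream.  Each atom carries a van der Waals radius; the minimum physically
acceptable distance between intermolecular atoms i and j is a fraction s_r of
the sum of their radii, sigma_ij = s_r * (r_i + r_j).  Strong hydrogen-bond
pairs (donor H on N/O/F against an N/O/F acceptor) are allowed to approach
closer and get their own s_r.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "Molecule",
    "PairDiameterTable",
    "load_vdw_table",
    "load_molecule",
    "center_of_geometry",
    "enclosing_diameter",
    "pair_diameters",
    "tag_hbond_pairs",
    "HBOND_CLASS",
]

#: pair-class label used for donor-H...acceptor contacts
HBOND_CLASS = "hbond"

_DONOR_ACCEPTOR_ELEMENTS = frozenset({"N", "O", "F"})
#: an H within this distance of N/O/F is considered covalently bonded to it
_DONOR_BOND_CUTOFF = 1.2


def load_vdw_table(path: str | Path | None = None) -> dict[str, float]:
    """Element -> van der Waals radius (Angstrom).

    The bundled table holds Bondi-style radii for the common elements; pass
    ``path`` to substitute your own JSON mapping.
    """
    if path is None:
        text = resources.files("rigidpress.data").joinpath("vdw_radii.json").read_text()
    else:
        text = Path(path).read_text()
    table = json.loads(text)
    for el, r in table.items():
        if not (isinstance(r, (int, float)) and r > 0):
            raise ValueError(f"invalid vdW radius for element {el!r}: {r}")
    return table


@dataclass
class Molecule:
    """A rigid molecule: elements, Cartesian coordinates (Angstrom), vdW radii."""

    elements: list[str]
    coords: np.ndarray
    vdw_radii: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.vdw_radii = np.asarray(self.vdw_radii, dtype=float)
        n = len(self.elements)
        if n < 1:
            raise ValueError("molecule must have at least one atom")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if self.vdw_radii.shape != (n,):
            raise ValueError("one vdW radius per atom required")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if not np.all(self.vdw_radii > 0):
            raise ValueError("all vdW radii must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def body_frame_coords(self) -> np.ndarray:
        """Coordinates relative to the center of geometry."""
        return self.coords - center_of_geometry(self)


@dataclass
class PairDiameterTable:
    """Hard-sphere diameters sigma_ij for every intermolecular atom pair.

    Both molecules are copies of the same rigid molecule, so the table is
    N_atoms x N_atoms and symmetric.  Tagged pair classes (hydrogen bonds)
    use their own s_r fraction.
    """

    sr_default: float
    sr_special: dict[str, float]
    sigma: np.ndarray
    max_sigma: float = field(init=False)

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("sigma table must be symmetric")
        if not np.all(self.sigma > 0):
            raise ValueError("sigma table must be strictly positive")
        self.max_sigma = float(self.sigma.max())


def load_molecule(
    path: str | Path,
    fmt: str | None = None,
    vdw_table: dict[str, float] | None = None,
) -> Molecule:
    """Read a molecule from an XYZ (or CIF-embedded Cartesian) file.

    Radii are assigned per element from the configured vdW table; an element
    missing from the table is an explicit error.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "xyz"
    if fmt == "xyz":
        elements, coords = _read_xyz(path)
    elif fmt == "cif":
        elements, coords = _read_cif_cartesian(path)
    else:
        raise ValueError(f"unsupported molecule format: {fmt!r}")
    table = vdw_table if vdw_table is not None else load_vdw_table()
    radii = []
    for el in elements:
        if el not in table:
            raise KeyError(f"no van der Waals radius for element {el!r}")
        radii.append(table[el])
    return Molecule(elements, np.asarray(coords), np.asarray(radii), name=path.stem)


def _read_xyz(path: Path) -> tuple[list[str], list[list[float]]]:
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"empty XYZ file: {path}")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"malformed XYZ header in {path}: {lines[0]!r}") from exc
    body = lines[2 : 2 + n]
    if len(body) < n:
        raise ValueError(f"XYZ file {path} promises {n} atoms, has {len(body)}")
    elements, coords = [], []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"malformed XYZ atom line: {ln!r}")
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return elements, coords


def _read_cif_cartesian(path: Path) -> tuple[list[str], list[list[float]]]:
    import gemmi

    doc = gemmi.cif.read_file(str(path))
    block = doc.sole_block()
    st = gemmi.SmallStructure.from_cif_block(block)
    elements, coords = [], []
    for site in st.sites:
        pos = st.cell.orthogonalize(site.fract)
        elements.append(site.type_symbol)
        coords.append([pos.x, pos.y, pos.z])
    if not elements:
        raise ValueError(f"no atom sites found in CIF {path}")
    return elements, coords


def center_of_geometry(mol: Molecule) -> np.ndarray:
    """Unweighted mean of the atomic coordinates."""
    return mol.coords.mean(axis=0)


def enclosing_diameter(mol: Molecule) -> float:
    """Diameter l_mol of the smallest COG-centered sphere enclosing the molecule.

    Defined as twice the maximum distance from the center of geometry to any
    atom; zero for a single atom.
    """
    d = np.linalg.norm(mol.coords - center_of_geometry(mol), axis=1)
    return 2.0 * float(d.max())


def tag_hbond_pairs(
    mol: Molecule,
    donor_bond_cutoff: float = _DONOR_BOND_CUTOFF,
) -> set[tuple[int, int]]:
    """Atom index pairs (i, j) to treat as strong hydrogen-bond contacts.

    Rule: an H covalently bonded (distance < ``donor_bond_cutoff``) to N/O/F
    is a donor-H; any N/O/F atom is an acceptor.  Every (donor-H, acceptor)
    pair across two molecule copies is tagged, both orderings.  Returns an
    empty set when the molecule has no donors or acceptors.
    """
    donors_h = []
    acceptors = []
    for i, el in enumerate(mol.elements):
        if el in _DONOR_ACCEPTOR_ELEMENTS:
            acceptors.append(i)
    for i, el in enumerate(mol.elements):
        if el != "H":
            continue
        d = np.linalg.norm(mol.coords[acceptors] - mol.coords[i], axis=1) if acceptors else []
        if len(d) and d.min() < donor_bond_cutoff:
            donors_h.append(i)
    pairs: set[tuple[int, int]] = set()
    for h in donors_h:
        for a in acceptors:
            pairs.add((h, a))
            pairs.add((a, h))
    return pairs


def pair_diameters(
    mol: Molecule,
    sr_default: float = 0.85,
    sr_special: dict[str, float] | None = None,
    hbond_pairs: set[tuple[int, int]] | None = None,
) -> PairDiameterTable:
    """Build the full sigma_ij table for intermolecular atom pairs.

    sigma_ij = s_r * (r_i + r_j), with ``sr_special[HBOND_CLASS]`` applied to
    tagged hydrogen-bond pairs.  When ``hbond_pairs`` is None the pairs are
    derived from :func:`tag_hbond_pairs`.
    """
    sr_special = dict(sr_special or {})
    for label, sr in [("default", sr_default), *sr_special.items()]:
        if not (0 < sr <= 1):
            raise ValueError(f"s_r ({label}) must be in (0, 1], got {sr}")
    r = mol.vdw_radii
    sigma = sr_default * (r[:, None] + r[None, :])
    sr_hb = sr_special.get(HBOND_CLASS)
    if sr_hb is not None:
        if hbond_pairs is None:
            hbond_pairs = tag_hbond_pairs(mol)
        for i, j in hbond_pairs:
            sigma[i, j] = sr_hb * (r[i] + r[j])
    return PairDiameterTable(sr_default, sr_special, sigma)
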