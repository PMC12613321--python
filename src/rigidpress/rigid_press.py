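"""Rigid Press: hard-sphere compaction of molecular crystals.

Minimizes F(s) = V(s) + P_contact(s) over a symmetry-reduced state vector
s = (free lattice parameters, asymmetric-unit center of geometry, Euler
angles) with BFGS, keeping molecules rigid and the space group fixed.  V is
the unit-cell volume and P_contact a regularized hard-sphere penalty summed
over all interacting molecular pairs: zero beyond the interaction cutoff D,
w*(D-d)/(d-sigma) for sigma < d < D, and (numerically capped) infinity at
hard overlap d <= sigma.  No energy evaluation of any kind is involved;
compaction is purely geometric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .chem_core import (
    Molecule,
    PairDiameterTable,
    enclosing_diameter,
    pair_diameters,
)
from .structures import CrystalStructure, StructurePool
from . import symmetry as _sym

__all__ = [
    "StateVector",
    "PressConfig",
    "PairInteractionSet",
    "StateCodec",
    "interaction_cutoff",
    "penalty_weight",
    "pair_penalty",
    "find_pairs",
    "pair_distances",
    "contact_penalty",
    "PressContext",
    "objective",
    "objective_gradient",
    "rigid_press",
    "press_pool",
]


@dataclass
class StateVector:
    """Reduced optimization coordinates of a symmetry-constrained crystal."""

    lattice: _sym.LatticeParams
    cog_frac: np.ndarray  # 3, fractional
    euler: np.ndarray  # 3, radians, intrinsic Z-Y-Z

    def to_array(self) -> np.ndarray:
        return np.concatenate([self.lattice.free_values, self.cog_frac, self.euler])

    @classmethod
    def from_array(cls, x: np.ndarray, crystal_system: str) -> "StateVector":
        nfree = _sym.FREE_PARAM_COUNT[crystal_system]
        if len(x) != nfree + 6:
            raise ValueError(f"state length {len(x)} != {nfree} + 6")
        return cls(
            lattice=_sym.LatticeParams(crystal_system, x[:nfree]),
            cog_frac=np.asarray(x[nfree : nfree + 3], float),
            euler=np.asarray(x[nfree + 3 :], float),
        )


@dataclass
class PressConfig:
    """Tunables of the compaction.  k balances penalty against volume;
    sr sets the hard-sphere diameters as a fraction of summed vdW radii."""

    k: float = 0.1
    sr: float = 0.85
    sr_special: dict | None = None
    grad_tol: float = 0.01
    max_iter: int = 5000
    record_trajectory: bool = False
    symmetry_constrained: bool = True
    fd_step_rel: float = 1e-6
    fd_step_abs: float = 1e-8
    cap_factor: float = 1e12

    def __post_init__(self) -> None:
        if self.k <= 0 or self.grad_tol <= 0 or self.max_iter < 1:
            raise ValueError("require k > 0, grad_tol > 0, max_iter >= 1")


@dataclass
class PairInteractionSet:
    """Molecular pairs (A, B, integer image translation) that may interact.

    Enumerated with A <= B; the identity pair (A == B, n == 0) is excluded;
    for A == B only the lexicographically positive half of translations is
    kept (each physical pair class counted once per unit cell).  The set is a
    superset of the exact contact set by construction.
    """

    idx_a: np.ndarray  # (P,) int
    idx_b: np.ndarray  # (P,) int
    images: np.ndarray  # (P, 3) int

    def __len__(self) -> int:
        return len(self.idx_a)


def interaction_cutoff(mol: Molecule, table: PairDiameterTable) -> float:
    """D = l_mol + 2 * max(sigma_ij): beyond this no atom pair can interact."""
    return enclosing_diameter(mol) + 2.0 * table.max_sigma


def penalty_weight(mol: Molecule, k: float = 0.1) -> float:
    """w = k / N_atoms^2, normalizing the penalty across molecular sizes."""
    if k <= 0:
        raise ValueError("k must be positive")
    return k / mol.n_atoms**2


def pair_penalty(d, sigma, D: float, w: float, cap_factor: float = 1e12):
    """Piecewise regularized hard-sphere penalty for atom-pair distances.

    0 for d >= D; w*(D-d)/(d-sigma) for sigma < d < D; the divergent branch
    at d <= sigma is represented by the finite cap w*cap_factor so that
    optimizer line searches always see finite values.
    """
    d = np.asarray(d, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma >= D):
        raise ValueError("pair_penalty requires sigma < D")
    cap = w * cap_factor
    denom = np.where(d > sigma, d - sigma, 1.0)
    raw = np.minimum(w * (D - d) / denom, cap)
    val = np.where(d >= D, 0.0, np.where(d <= sigma, cap, raw))
    return val if val.shape else float(val)


def _half_space_mask(ns: np.ndarray) -> np.ndarray:
    """Lexicographically positive translations (excludes n == 0 and -n twins)."""
    return (ns[:, 0] > 0) | (
        (ns[:, 0] == 0) & ((ns[:, 1] > 0) | ((ns[:, 1] == 0) & (ns[:, 2] > 0)))
    )


def find_pairs(
    structure: CrystalStructure, D: float, margin: float = 1.1
) -> PairInteractionSet:
    """Enumerate molecular pairs possibly within atom-pair distance D.

    Per-axis image bounds come from the interplanar spacings; intra-cell
    (n = 0) pairs are always included, image pairs are kept when the COG
    distance is below margin*D + l_mol (a rigorous superset of the contact
    set, with slack for cell drift between rebuilds).
    """
    cell = structure.cell
    l_mol = enclosing_diameter(structure.molecule)
    recip = np.linalg.inv(cell.T)  # rows: reciprocal lattice vectors
    spacing = 1.0 / np.linalg.norm(recip, axis=1)
    reach = margin * D + l_mol
    bound = np.ceil(reach / spacing).astype(int)
    axes = [np.arange(-b, b + 1) for b in bound]
    ns = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    nz = ~np.all(ns == 0, axis=1)
    half = _half_space_mask(ns)
    shifts = ns @ cell
    cogs = np.array([p[0] for p in structure.placements]) @ cell
    Z = len(cogs)
    ia, ib, im = [], [], []
    for A in range(Z):
        for B in range(A, Z):
            sel = half if A == B else nz
            d_cog = np.linalg.norm(cogs[B] + shifts[sel] - cogs[A], axis=1)
            keep = ns[sel][d_cog <= reach]
            if A < B:  # intra-cell pair kept unconditionally
                keep = np.vstack([np.zeros((1, 3), dtype=int), keep])
            ia.extend([A] * len(keep))
            ib.extend([B] * len(keep))
            im.append(keep)
    images = np.vstack(im) if im else np.zeros((0, 3), dtype=int)
    return PairInteractionSet(
        idx_a=np.array(ia, dtype=int), idx_b=np.array(ib, dtype=int), images=images
    )


def pair_distances(
    structure: CrystalStructure, pairs: PairInteractionSet
) -> np.ndarray:
    """Atom-pair distances, shape (n_pairs, N_atoms, N_atoms).

    Entry [p, i, j] is |r_i^A - (r_j^B + n.cell)| for pair p = (A, B, n);
    image shifts use the structure's current cell, so a cached pair set
    remains usable while the cell deforms.
    """
    coords = structure.cartesian_coords()
    shifts = pairs.images @ structure.cell
    a = coords[pairs.idx_a]
    b = coords[pairs.idx_b] + shifts[:, None, :]
    diff = a[:, :, None, :] - b[:, None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def contact_penalty(
    structure: CrystalStructure,
    table: PairDiameterTable,
    D: float,
    w: float,
    pairs: PairInteractionSet | None = None,
    cap_factor: float = 1e12,
) -> float:
    """P_contact: sum of pair penalties over all interacting molecular pairs."""
    if pairs is None:
        pairs = find_pairs(structure, D)
    if len(pairs) == 0:
        return 0.0
    d = pair_distances(structure, pairs)
    return float(np.sum(pair_penalty(d, table.sigma[None, :, :], D, w, cap_factor)))


class StateCodec:
    """Encode a crystal to its reduced state vector and decode back.

    The asymmetric unit is the first placement (the group's identity
    operation); decode rebuilds the full cell through apply_ops, which is
    what enforces the space-group constraint at every optimizer step.
    """

    def __init__(self, structure: CrystalStructure):
        self.sg = _sym.get_space_group(structure.sg_number)
        self.molecule = structure.molecule
        self.lattice_system = structure.lattice_system
        self.tags = dict(structure.tags)

    def encode(self, structure: CrystalStructure) -> np.ndarray:
        lat = _sym.lattice_params_from_cell(structure.cell, self.lattice_system)
        cog, R = structure.placements[0]
        if np.linalg.det(R) < 0:
            raise ValueError("asymmetric-unit rotation must be proper")
        with warnings.catch_warnings():
            # gimbal-lock degeneracy is benign: any angle triple that
            # reproduces the matrix is an equally valid starting state
            warnings.simplefilter("ignore", UserWarning)
            euler = Rotation.from_matrix(R).as_euler("ZYZ")
        return StateVector(lat, cog.copy(), euler).to_array()

    def decode(self, x: np.ndarray) -> CrystalStructure:
        sv = StateVector.from_array(x, self.lattice_system)
        cell = _sym.build_cell(sv.lattice)
        R = Rotation.from_euler("ZYZ", sv.euler).as_matrix()
        return CrystalStructure.from_asym_unit(
            cell,
            self.sg,
            self.molecule,
            sv.cog_frac % 1.0,
            R,
            lattice_system=self.lattice_system,
            tags=self.tags,
        )


class _P1Codec:
    """State codec for the unsymmetrized variant: all Z placements free in P1."""

    def __init__(self, structure: CrystalStructure):
        self.molecule = structure.molecule
        self.Z = structure.Z
        self.lattice_system = "triclinic"
        self.tags = dict(structure.tags)
        # improper placements (inversion/mirror copies) carry a fixed parity
        # sign; the optimizer only ever moves the proper rotation part
        self.signs = [
            1.0 if np.linalg.det(R) > 0 else -1.0 for _, R in structure.placements
        ]

    def encode(self, structure: CrystalStructure) -> np.ndarray:
        lat = _sym.lattice_params_from_cell(structure.cell, "triclinic")
        parts = [lat.free_values]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for (cog, R), sign in zip(structure.placements, self.signs):
                parts.append(cog)
                parts.append(Rotation.from_matrix(sign * R).as_euler("ZYZ"))
        return np.concatenate(parts)

    def decode(self, x: np.ndarray) -> CrystalStructure:
        lat = _sym.LatticeParams("triclinic", x[:6])
        cell = _sym.build_cell(lat)
        placements = []
        for m in range(self.Z):
            off = 6 + 6 * m
            cog = x[off : off + 3] % 1.0
            R = self.signs[m] * Rotation.from_euler(
                "ZYZ", x[off + 3 : off + 6]
            ).as_matrix()
            placements.append((cog, R))
        return CrystalStructure(
            cell=cell,
            sg_number=1,
            molecule=self.molecule,
            placements=placements,
            lattice_system="triclinic",
            tags=self.tags,
        )


class PressContext:
    """Objective evaluation context: constants, codec, and the pair cache.

    The pair set is rebuilt whenever any free lattice parameter has changed
    by more than 1% or the asymmetric COG has moved more than 4% of D since
    the last build; the 1.1*D margin in find_pairs keeps the cached set a
    superset of the true contact set in between.
    """

    BIG = 1e15  # objective value for undecodable (degenerate-cell) states

    def __init__(self, structure: CrystalStructure, cfg: PressConfig):
        self.cfg = cfg
        mol = structure.molecule
        self.table = pair_diameters(mol, cfg.sr, cfg.sr_special)
        self.D = interaction_cutoff(mol, self.table)
        self.w = penalty_weight(mol, cfg.k)
        self.codec = (
            StateCodec(structure) if cfg.symmetry_constrained else _P1Codec(structure)
        )
        self.nfree = _sym.FREE_PARAM_COUNT[self.codec.lattice_system]
        self._pairs: PairInteractionSet | None = None
        self._pairs_lattice: np.ndarray | None = None
        self._pairs_cog: np.ndarray | None = None
        self.diagnostics: dict = {"capped_evals": 0, "pair_rebuilds": 0}

    def _get_pairs(self, structure: CrystalStructure, x: np.ndarray) -> PairInteractionSet:
        lat = x[: self.nfree]
        cog = np.array([p[0] for p in structure.placements]) @ structure.cell
        stale = self._pairs is None
        if not stale:
            rel = np.abs(lat - self._pairs_lattice) / np.maximum(
                np.abs(self._pairs_lattice), 1e-12
            )
            stale = rel.max() > 0.01
        if not stale and self._pairs_cog is not None:
            if self._pairs_cog.shape == cog.shape:
                stale = np.linalg.norm(cog - self._pairs_cog, axis=1).max() > 0.04 * self.D
            else:
                stale = True
        if stale:
            self._pairs = find_pairs(structure, self.D, margin=1.1)
            self._pairs_lattice = lat.copy()
            self._pairs_cog = cog
            self.diagnostics["pair_rebuilds"] += 1
        return self._pairs

    def decompose(self, x: np.ndarray) -> tuple[float, float]:
        """(volume, penalty) at state x; raises on undecodable states."""
        structure = self.codec.decode(x)
        pairs = self._get_pairs(structure, x)
        P = contact_penalty(
            structure, self.table, self.D, self.w, pairs, self.cfg.cap_factor
        )
        return structure.volume, P

    def __call__(self, x: np.ndarray) -> float:
        try:
            V, P = self.decompose(x)
        except (ValueError, FloatingPointError):
            self.diagnostics["capped_evals"] += 1
            return self.BIG
        F = V + P
        if not np.isfinite(F):
            self.diagnostics["capped_evals"] += 1
            return self.BIG
        return F


def objective(x: np.ndarray, context: PressContext) -> float:
    """F(s) = V(s) + P_contact(s); capped large value on degenerate cells."""
    return context(x)


def objective_gradient(
    x: np.ndarray,
    context: PressContext,
    step_rel: float | None = None,
    step_abs: float | None = None,
) -> np.ndarray:
    """Central finite-difference gradient of the objective.

    Per-component step max(step_rel*|x_i|, step_abs); deterministic.  The
    objective is the single source of truth; no analytic shortcut.
    """
    step_rel = context.cfg.fd_step_rel if step_rel is None else step_rel
    step_abs = context.cfg.fd_step_abs if step_abs is None else step_abs
    g = np.empty_like(x)
    for i in range(len(x)):
        h = max(step_rel * abs(x[i]), step_abs)
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (context(xp) - context(xm)) / (2.0 * h)
    return g


def rigid_press(
    structure: CrystalStructure, cfg: PressConfig | None = None
) -> tuple[CrystalStructure, list[dict]]:
    """Compact a crystal by BFGS minimization of volume + contact penalty.

    The full crystal is rebuilt from the state vector via the space-group
    operations at every evaluation, so the group is preserved exactly.
    Stops at gradient norm < grad_tol or after max_iter iterations.  Returns
    the optimized structure and a per-accepted-iterate trajectory of
    (iteration, V, P, F[, grad_norm]).  A structure whose starting objective
    is capped/non-finite is returned unchanged, tagged ``press_failed``.
    """
    cfg = cfg or PressConfig()
    ctx = PressContext(structure, cfg)
    x0 = ctx.codec.encode(structure)
    f0 = ctx(x0)
    if f0 >= ctx.BIG:
        out = structure.copy()
        out.tags["press_failed"] = True
        return out, []

    trajectory: list[dict] = []

    def record(xk, it):
        try:
            V, P = ctx.decompose(xk)
        except ValueError:
            return
        entry = {"iteration": it, "V": V, "P": P, "F": V + P}
        if cfg.record_trajectory:
            entry["grad_norm"] = float(
                np.linalg.norm(objective_gradient(xk, ctx))
            )
        trajectory.append(entry)

    record(x0, 0)
    it_counter = {"n": 0}

    def callback(xk):
        it_counter["n"] += 1
        record(xk, it_counter["n"])

    res = minimize(
        lambda x: objective(x, ctx),
        x0,
        jac=lambda x: objective_gradient(x, ctx),
        method="BFGS",
        callback=callback,
        options={"gtol": cfg.grad_tol, "maxiter": cfg.max_iter},
    )
    x_final, f_final = (res.x, res.fun) if res.fun <= f0 else (x0, f0)
    out = ctx.codec.decode(x_final)
    out.tags = dict(structure.tags)
    out.tags.update(
        press_iters=int(res.nit),
        press_converged=bool(res.nit == 0 or res.status == 0),
        press_v0=structure.volume,
        press_v=out.volume,
    )
    out.energy = structure.energy
    return out, trajectory


def press_pool(
    pool: StructurePool, cfg: PressConfig | None = None, verbose: bool = False
) -> StructurePool:
    """Apply rigid_press to every structure; failed ones are dropped."""
    cfg = cfg or PressConfig()
    kept = []
    for s in pool:
        pressed, _ = rigid_press(s, cfg)
        if pressed.tags.get("press_failed"):
            continue
        pressed.tags.setdefault("stages", list(s.tags.get("stages", [])))
        pressed.tags["stages"] = list(pressed.tags.get("stages", [])) + ["press"]
        kept.append(pressed)
    meta = dict(pool.metadata)
    meta["press_dropped"] = len(pool) - len(kept)
    return StructurePool(kept, metadata=meta)
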