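"""Random generation of symmetric, proximity-valid crystal structures.

For each space group compatible with the requested Z, unit cells are drawn
with volumes normally distributed around an inflated target (1.5x a
geometric estimate by default — the inflation makes random placement of
molecules feasible and leaves the compaction step to close the gap), the
asymmetric unit is placed uniformly at random with a uniform random
orientation, the remaining copies follow from the group operations, and
candidates failing the intermolecular proximity check (d_ij >= s_r *
(r_i + r_j), s_r = 0.95 by default) are discarded and retried.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .chem_core import Molecule, PairDiameterTable, pair_diameters
from .structures import CrystalStructure, StructurePool
from .rigid_press import find_pairs as _find_pairs, pair_distances as _pair_distances
from . import symmetry as _sym

__all__ = [
    "GenerationConfig",
    "estimate_target_volume",
    "sample_cell",
    "random_rotation",
    "proximity_check",
    "generate_pool",
]


@dataclass
class GenerationConfig:
    n_per_sg: int = 4000
    volume_inflation: float = 1.5
    volume_sigma_frac: float = 0.075
    sr_check: float = 0.95
    sr_special: dict | None = None
    packing_coefficient: float = 0.55
    max_attempts_per_structure: int = 1000
    rng_seed: int = 0
    max_aspect: float = 4.0
    angle_bounds: tuple[float, float] = (60.0, 120.0)
    sohncke_only: bool = False

    def __post_init__(self) -> None:
        if min(self.volume_inflation, self.volume_sigma_frac, self.sr_check) <= 0:
            raise ValueError("generation factors must be positive")
        if self.sr_check > 1:
            raise ValueError("sr_check must be in (0, 1]")


def estimate_target_volume(
    mol: Molecule, Z: int, packing_coefficient: float = 0.55
) -> float:
    """Geometric unit-cell volume estimate: Z * (sum of vdW sphere volumes)
    divided by the packing coefficient (0.55 is typical for organic
    molecular crystals)."""
    if not 0 < packing_coefficient < 1:
        raise ValueError("packing_coefficient must be in (0, 1)")
    spheres = float(np.sum(4.0 / 3.0 * np.pi * mol.vdw_radii**3))
    return Z * spheres / packing_coefficient


def sample_cell(
    sg: "_sym.SpaceGroup | str",
    target_volume: float,
    cfg: GenerationConfig,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> _sym.LatticeParams:
    """Draw free lattice parameters of the group's crystal system.

    The cell volume is Normal(target * inflation, sigma_frac * that mean),
    truncated positive; aspect ratios are log-uniform within 1/max_aspect..
    max_aspect, free angles uniform within angle_bounds; lengths are then
    rescaled so the built cell hits the drawn volume exactly.
    """
    if target_volume <= 0:
        raise ValueError("target_volume must be positive")
    system = sg if isinstance(sg, str) else sg.crystal_system
    mean = target_volume * cfg.volume_inflation
    sd = cfg.volume_sigma_frac * mean
    lo, hi = cfg.angle_bounds
    log_aspect = np.log(cfg.max_aspect)

    for _ in range(max_retries):
        vol = rng.normal(mean, sd)
        if vol <= 0:
            continue
        ratios = np.exp(rng.uniform(-log_aspect, log_aspect, size=2))
        if system == "triclinic":
            angles = rng.uniform(lo, hi, size=3)
            free = [1.0, ratios[0], ratios[1], *angles]
        elif system == "monoclinic":
            free = [1.0, ratios[0], ratios[1], rng.uniform(lo, hi)]
        elif system == "orthorhombic":
            free = [1.0, ratios[0], ratios[1]]
        elif system in ("tetragonal", "trigonal", "hexagonal"):
            free = [1.0, ratios[0]]
        elif system == "cubic":
            free = [1.0]
        else:
            raise ValueError(f"unknown crystal system {system!r}")
        params = _sym.LatticeParams(system, np.array(free))
        try:
            v_unit = np.linalg.det(_sym.build_cell(params))
        except ValueError:
            continue  # incompatible random angles; redraw
        n_len = {"triclinic": 3, "monoclinic": 3, "orthorhombic": 3}.get(system, 2)
        n_len = 1 if system == "cubic" else n_len
        scale = (vol / v_unit) ** (1.0 / 3.0)
        params.free_values[:n_len] *= scale
        return params
    raise RuntimeError(f"could not sample a valid {system} cell in {max_retries} tries")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (random unit quaternion)."""
    return Rotation.random(rng=rng).as_matrix()


def proximity_check(
    structure: CrystalStructure,
    table: PairDiameterTable | None = None,
    sr_check: float = 0.95,
    sr_special: dict | None = None,
) -> bool:
    """True iff every intermolecular atom pair keeps its minimum distance.

    All pairs of distinct molecules and all periodic images — including a
    molecule against its own images — must satisfy d_ij >= sigma_ij, where
    sigma_ij comes from ``table`` (built at ``sr_check`` with any special
    hydrogen-bond fractions when not supplied).
    """
    if table is None:
        table = pair_diameters(structure.molecule, sr_check, sr_special)
    cutoff = table.max_sigma
    pairs = _find_pairs(structure, cutoff, margin=1.0)
    if len(pairs) == 0:
        return True
    d = _pair_distances(structure, pairs)
    return bool(np.all(d + 1e-12 >= table.sigma[None, :, :]))


def _generate_one(
    mol: Molecule,
    sg: _sym.SpaceGroup,
    target_volume: float,
    cfg: GenerationConfig,
    table: PairDiameterTable,
    rng: np.random.Generator,
) -> CrystalStructure | None:
    for _ in range(cfg.max_attempts_per_structure):
        params = sample_cell(sg, target_volume, cfg, rng)
        cell = _sym.build_cell(params)
        cog = rng.uniform(0.0, 1.0, size=3)
        rot = random_rotation(rng)
        s = CrystalStructure.from_asym_unit(cell, sg, mol, cog, rot)
        if proximity_check(s, table):
            return s
    return None


def generate_pool(
    mol: Molecule, Z: int, cfg: GenerationConfig | None = None
) -> StructurePool:
    """Generate n_per_sg proximity-valid structures in each compatible group.

    Reproducible: each structure draws from its own rng seeded by
    (rng_seed, group number, index), so pools are identical for a fixed seed
    regardless of scheduling.  Groups whose attempt budget runs dry
    contribute a partial count, recorded in the pool metadata with a warning.
    """
    cfg = cfg or GenerationConfig()
    groups = _sym.compatible_space_groups(Z, sohncke_only=cfg.sohncke_only)
    if not groups:
        raise ValueError(f"no space group has general-position multiplicity {Z}")
    table = pair_diameters(mol, cfg.sr_check, cfg.sr_special)
    target = estimate_target_volume(mol, Z, cfg.packing_coefficient)
    pool = StructurePool(
        metadata={
            "molecule": mol.name,
            "Z": Z,
            "target_volume": target,
            "rng_seed": cfg.rng_seed,
            "per_group_counts": {},
        }
    )
    for sg in groups:
        accepted = 0
        for i in range(cfg.n_per_sg):
            seq = np.random.SeedSequence([cfg.rng_seed, sg.number, i])
            rng = np.random.default_rng(seq)
            s = _generate_one(mol, sg, target, cfg, table, rng)
            if s is None:
                continue
            s.tags.update(
                id=f"sg{sg.number:03d}-{i:05d}",
                sg_symbol=sg.symbol,
                stages=["generate"],
            )
            pool.append(s)
            accepted += 1
        pool.metadata["per_group_counts"][sg.number] = accepted
        if accepted < cfg.n_per_sg:
            warnings.warn(
                f"group {sg.number} ({sg.symbol}): {accepted}/{cfg.n_per_sg} "
                "structures within the attempt budget"
            )
    return pool
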