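"""Staged down-selection workflow, calculator contract, checkpointing, I/O.

A workflow is an ordered list of stages (generate, press, dedup, spe, relax,
cluster_select) applied to a structure pool, with a self-contained
checkpoint written after every stage so an interrupted run resumes to an
identical result.  Energy backends are pluggable through
:class:`CalculatorContract`; a Lennard-Jones :class:`ToyCalculator` ships
for tests and demos, registered in two tiers ("toy-cheap", "toy-expensive")
to mirror the common MLIP-then-DFT staging without naming any backend.
"""

from __future__ import annotations

import base64
import json
import re
import warnings
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import yaml
from scipy.optimize import minimize

from .chem_core import Molecule, load_molecule, load_vdw_table
from .structures import CrystalStructure, StructurePool
from . import symmetry as _sym
from .rigid_press import PressConfig, StateCodec, find_pairs, pair_distances, press_pool
from .generation import GenerationConfig, generate_pool
from .dedup import MatchTolerances, remove_duplicates
from .cluster_select import (
    fingerprint_pool,
    select_energy_window,
    select_lowest_per_cluster,
    tune_preference,
)

__all__ = [
    "CalculatorContract",
    "ToyCalculator",
    "register_calculator",
    "get_calculator",
    "WorkflowConfig",
    "template_stages",
    "run_workflow",
    "checkpoint",
    "restore",
    "read_structure",
    "write_structure",
]

STAGE_TYPES = ("generate", "press", "dedup", "spe", "relax", "cluster_select")


# ---------------------------------------------------------------------------
# calculator contract


class CalculatorContract(ABC):
    """Interface any energy backend must satisfy.

    ``spe`` returns the energy in kJ/mol per molecule and must be
    deterministic for a fixed structure; ``relax`` performs a
    symmetry-constrained cell + placement relaxation and returns the relaxed
    structure with its energy.  When the symmetry constraint is enabled the
    relaxed structure's detected space group equals the input's.
    """

    @abstractmethod
    def spe(self, structure: CrystalStructure) -> float: ...

    @abstractmethod
    def relax(self, structure: CrystalStructure) -> tuple[CrystalStructure, float]: ...


#: default per-element LJ well depths, kJ/mol (toy values)
_TOY_EPSILON = {"H": 0.3, "C": 1.0, "N": 1.2, "O": 1.5}


class ToyCalculator(CalculatorContract):
    """Shifted Lennard-Jones pair potential on atoms, for tests and demos.

    sigma_ij places the LJ minimum at the summed vdW radii; epsilon mixes by
    the geometric rule.  Only intermolecular pairs (including periodic
    images) contribute, so the rigid intramolecular geometry adds a constant
    that is simply omitted.  Translation/rotation invariant and finite for
    non-overlapping structures.  ``relax`` is a BFGS minimization of the
    energy over the same symmetry-reduced state vector used by the
    compaction step, so the space group is preserved by construction.
    """

    def __init__(
        self,
        cutoff: float = 8.0,
        epsilon: dict[str, float] | None = None,
        grad_tol: float = 0.96,  # ~0.01 eV/Angstrom in kJ/mol/Angstrom
        max_iter: int = 500,
    ) -> None:
        self.cutoff = cutoff
        self.epsilon = dict(epsilon or _TOY_EPSILON)
        self.grad_tol = grad_tol
        self.max_iter = max_iter
        self._vdw = load_vdw_table()

    def _params(self, mol: Molecule) -> tuple[np.ndarray, np.ndarray]:
        eps = np.array([self.epsilon.get(e, 1.0) for e in mol.elements])
        r = mol.vdw_radii
        eps_ij = np.sqrt(eps[:, None] * eps[None, :])
        # LJ minimum at r_i + r_j
        sig_ij = (r[:, None] + r[None, :]) * 2.0 ** (-1.0 / 6.0)
        return eps_ij, sig_ij

    def _energy_cell(self, structure: CrystalStructure) -> float:
        eps_ij, sig_ij = self._params(structure.molecule)
        pairs = find_pairs(structure, self.cutoff, margin=1.0)
        if len(pairs) == 0:
            return 0.0
        d = pair_distances(structure, pairs)
        d = np.maximum(d, 0.3)  # keep the toy potential finite at overlap
        s6 = (sig_ij[None, :, :] / d) ** 6
        e = 4.0 * eps_ij[None, :, :] * (s6 * s6 - s6)
        s6c = (sig_ij[None, :, :] / self.cutoff) ** 6
        shift = 4.0 * eps_ij[None, :, :] * (s6c * s6c - s6c)
        return float(np.sum(np.where(d < self.cutoff, e - shift, 0.0)))

    def spe(self, structure: CrystalStructure) -> float:
        return self._energy_cell(structure) / structure.Z

    def relax(self, structure: CrystalStructure) -> tuple[CrystalStructure, float]:
        codec = StateCodec(structure)
        x0 = codec.encode(structure)

        def fun(x: np.ndarray) -> float:
            try:
                s = codec.decode(x)
            except ValueError:
                return 1e12
            return self.spe(s)

        def grad(x: np.ndarray) -> np.ndarray:
            g = np.empty_like(x)
            for i in range(len(x)):
                h = max(1e-6 * abs(x[i]), 1e-8)
                xp, xm = x.copy(), x.copy()
                xp[i] += h
                xm[i] -= h
                g[i] = (fun(xp) - fun(xm)) / (2 * h)
            return g

        res = minimize(
            fun,
            x0,
            jac=grad,
            method="BFGS",
            options={"gtol": self.grad_tol, "maxiter": self.max_iter},
        )
        x = res.x if res.fun <= fun(x0) else x0
        out = codec.decode(x)
        out.tags = dict(structure.tags)
        out.energy = float(fun(x))
        return out, out.energy


_REGISTRY: dict[str, CalculatorContract] = {}


def register_calculator(name: str, calc: CalculatorContract) -> None:
    _REGISTRY[name] = calc


def get_calculator(name: str) -> CalculatorContract:
    if name not in _REGISTRY:
        _default_registry()
    if name not in _REGISTRY:
        raise KeyError(f"no calculator registered under {name!r}")
    return _REGISTRY[name]


def _default_registry() -> None:
    _REGISTRY.setdefault("toy-cheap", ToyCalculator(cutoff=6.0))
    _REGISTRY.setdefault("toy-expensive", ToyCalculator(cutoff=10.0))


# ---------------------------------------------------------------------------
# structure I/O


def _structure_meta(s: CrystalStructure) -> dict:
    return {
        "sg_number": s.sg_number,
        "lattice_system": s.lattice_system,
        "energy": s.energy,
        "tags": s.tags,
        "cell": s.cell.tolist(),
        "molecule": {
            "elements": list(s.molecule.elements),
            "coords": s.molecule.coords.tolist(),
            "vdw_radii": s.molecule.vdw_radii.tolist(),
            "name": s.molecule.name,
        },
        "placements": [
            {"cog": c.tolist(), "rot": R.tolist()} for c, R in s.placements
        ],
    }


def _structure_from_meta(meta: dict) -> CrystalStructure:
    m = meta["molecule"]
    mol = Molecule(
        m["elements"], np.array(m["coords"]), np.array(m["vdw_radii"]), m.get("name", "")
    )
    placements = [
        (np.array(p["cog"]), np.array(p["rot"])) for p in meta["placements"]
    ]
    return CrystalStructure(
        cell=np.array(meta["cell"]),
        sg_number=meta["sg_number"],
        molecule=mol,
        placements=placements,
        lattice_system=meta.get("lattice_system"),
        tags=dict(meta.get("tags", {})),
        energy=meta.get("energy"),
    )


def _op_triplets(sg_number: int) -> list[str]:
    sg = gemmi.find_spacegroup_by_number(sg_number)
    return [op.triplet() for op in sg.operations()]


def write_structure(structure: CrystalStructure, path: str | Path, fmt: str | None = None) -> None:
    """Write a structure as CIF or extended XYZ.

    Both formats carry the cell, symmetry, all-atom coordinates and — in a
    reserved ``rigidpress`` field — the exact placements and molecule, so a
    read-back reproduces the structure to full float precision.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    meta_json = json.dumps(_structure_meta(structure), sort_keys=True)
    a, b, c, al, be, ga = _sym.cell_to_params(structure.cell)
    frac = structure.fractional_coords() % 1.0
    elements = structure.all_elements()
    if fmt == "cif":
        lines = [f"data_{structure.tags.get('id', 'structure')}"]
        for key, val in zip(
            ("a", "b", "c"), (a, b, c)
        ):
            lines.append(f"_cell_length_{key} {val:.12f}")
        for key, val in zip(("alpha", "beta", "gamma"), (al, be, ga)):
            lines.append(f"_cell_angle_{key} {val:.12f}")
        lines.append(f"_symmetry_Int_Tables_number {structure.sg_number}")
        lines.append("loop_")
        lines.append("_symmetry_equiv_pos_as_xyz")
        for trip in _op_triplets(structure.sg_number):
            lines.append(f"'{trip}'")
        lines.append("loop_")
        lines += [
            "_atom_site_label",
            "_atom_site_type_symbol",
            "_atom_site_fract_x",
            "_atom_site_fract_y",
            "_atom_site_fract_z",
        ]
        for i, (el, f) in enumerate(zip(elements, frac)):
            lines.append(
                f"{el}{i + 1} {el} {f[0]:.12f} {f[1]:.12f} {f[2]:.12f}"
            )
        lines.append("_rigidpress_meta")
        lines.append(";")
        lines.append(meta_json)
        lines.append(";")
        path.write_text("\n".join(lines) + "\n")
    elif fmt in ("extxyz", "xyz"):
        cart = frac @ structure.cell
        cellflat = " ".join(f"{v:.12f}" for v in structure.cell.ravel())
        b64 = base64.b64encode(meta_json.encode()).decode()
        comment = (
            f'Lattice="{cellflat}" Properties=species:S:1:pos:R:3 '
            f"sg_number={structure.sg_number} rigidpress_meta={b64}"
        )
        lines = [str(len(elements)), comment]
        for el, x in zip(elements, cart):
            lines.append(f"{el} {x[0]:.12f} {x[1]:.12f} {x[2]:.12f}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unsupported structure format {fmt!r}")


def read_structure(path: str | Path, fmt: str | None = None) -> CrystalStructure:
    """Read a structure written by :func:`write_structure` or a foreign file.

    Files carrying the reserved ``rigidpress`` field round-trip exactly.  A
    foreign P1 file (no symmetry information) is read as a Z = 1 structure
    whose "molecule" is the full cell contents; vdW radii are assigned from
    the bundled element table.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "cif":
        try:
            doc = gemmi.cif.read_file(str(path))
            block = doc.sole_block()
        except (RuntimeError, ValueError) as exc:
            raise ValueError(f"malformed CIF {path}: {exc}") from exc
        meta_raw = block.find_value("_rigidpress_meta")
        if meta_raw is not None:
            return _structure_from_meta(json.loads(gemmi.cif.as_string(meta_raw)))
        return _read_foreign_cif(block, path)
    if fmt in ("extxyz", "xyz"):
        return _read_extxyz(path)
    raise ValueError(f"unsupported structure format {fmt!r}")


def _read_foreign_cif(block, path: Path) -> CrystalStructure:
    def val(tag):
        v = block.find_value(tag)
        if v is None:
            raise ValueError(f"CIF {path} missing {tag}")
        return float(gemmi.cif.as_number(v))

    params = _sym.LatticeParams(
        "triclinic",
        np.array(
            [
                val("_cell_length_a"),
                val("_cell_length_b"),
                val("_cell_length_c"),
                val("_cell_angle_alpha"),
                val("_cell_angle_beta"),
                val("_cell_angle_gamma"),
            ]
        ),
    )
    cell = _sym.build_cell(params)
    table = block.find(
        "_atom_site_",
        ["type_symbol", "fract_x", "fract_y", "fract_z"],
    )
    if len(table) == 0:
        raise ValueError(f"CIF {path} has no atom sites")
    elements, fracs = [], []
    for row in table:
        elements.append(gemmi.cif.as_string(row[0]))
        fracs.append([gemmi.cif.as_number(row[i]) for i in (1, 2, 3)])
    frac = np.array(fracs)
    cart = frac @ cell
    vdw = load_vdw_table()
    radii = np.array([vdw[e] for e in elements])
    mol = Molecule(elements, cart, radii, name=path.stem)
    cog_frac = frac.mean(axis=0)
    declared = block.find_value("_symmetry_Int_Tables_number") or block.find_value(
        "_space_group_IT_number"
    )
    tags = {"source": str(path)}
    if declared is not None:
        tags["declared_sg"] = int(gemmi.cif.as_number(declared))
    return CrystalStructure(
        cell=cell,
        sg_number=1,
        molecule=mol,
        placements=[(cog_frac, np.eye(3))],
        lattice_system="triclinic",
        tags=tags,
    )


def _read_extxyz(path: Path) -> CrystalStructure:
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise ValueError(f"malformed extxyz {path}: too short")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"malformed extxyz header in {path}") from exc
    comment = lines[1]
    m = re.search(r"rigidpress_meta=(\S+)", comment)
    if m:
        return _structure_from_meta(json.loads(base64.b64decode(m.group(1))))
    lat = re.search(r'Lattice="([^"]+)"', comment)
    if not lat:
        raise ValueError(f"extxyz {path} lacks a Lattice field")
    cell = np.array([float(x) for x in lat.group(1).split()]).reshape(3, 3)
    elements, carts = [], []
    for ln in lines[2 : 2 + n]:
        parts = ln.split()
        elements.append(parts[0])
        carts.append([float(x) for x in parts[1:4]])
    cart = np.array(carts)
    vdw = load_vdw_table()
    radii = np.array([vdw[e] for e in elements])
    mol = Molecule(elements, cart, radii, name=path.stem)
    cog_frac = (cart @ np.linalg.inv(cell)).mean(axis=0)
    return CrystalStructure(
        cell=cell,
        sg_number=1,
        molecule=mol,
        placements=[(cog_frac, np.eye(3))],
        lattice_system="triclinic",
        tags={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# checkpointing


def checkpoint(pool: StructurePool, stage_id: str, directory: str | Path) -> None:
    """Self-contained pool snapshot: one CIF per structure + JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(pool):
        sid = str(s.tags.get("id", f"s{i:06d}"))
        fname = f"{sid}.cif"
        write_structure(s, directory / fname, fmt="cif")
        entries.append(
            {
                "id": sid,
                "file": fname,
                "sg_number": s.sg_number,
                "volume": s.volume,
                "energy": s.energy,
            }
        )
    manifest = {
        "stage_id": stage_id,
        "metadata": pool.metadata,
        "structures": entries,
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1)
    )


def restore(directory: str | Path) -> tuple[StructurePool, str]:
    """Rebuild the in-memory pool from a checkpoint directory."""
    directory = Path(directory)
    mpath = directory / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest in {directory}")
    try:
        manifest = json.loads(mpath.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupted manifest in {directory}: {exc}") from exc
    structures = []
    for entry in manifest["structures"]:
        f = directory / entry["file"]
        if not f.exists():
            raise FileNotFoundError(
                f"checkpoint integrity error: structure {entry['id']!r} "
                f"missing its file {entry['file']}"
            )
        structures.append(read_structure(f, fmt="cif"))
    return StructurePool(structures, metadata=manifest.get("metadata", {})), manifest[
        "stage_id"
    ]


# ---------------------------------------------------------------------------
# workflow


@dataclass
class WorkflowConfig:
    """Declarative stage list plus global inputs.

    ``stages`` entries are dicts with a ``type`` key (one of STAGE_TYPES)
    and stage-specific parameters; referenced calculators must be registered.
    """

    Z: int
    stages: list[dict]
    workdir: str | Path
    molecule: Molecule | str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for st in self.stages:
            if st.get("type") not in STAGE_TYPES:
                raise ValueError(f"unknown stage type in {st!r}")
            if st["type"] in ("spe", "relax"):
                get_calculator(st.get("calculator", "toy-cheap"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            Z=int(raw["Z"]),
            stages=list(raw["stages"]),
            workdir=raw.get("workdir", "workflow_out"),
            molecule=raw.get("molecule"),
            seed=int(raw.get("seed", 0)),
        )


def template_stages(
    n_per_sg: int = 4000,
    cheap: str = "toy-cheap",
    expensive: str = "toy-expensive",
) -> list[dict]:
    """The default down-selection pipeline.

    generate -> press -> per-group dedup -> cheap SPE -> cluster to 10% of
    the pool keeping each cluster's minimum -> cheap relax -> dedup ->
    cluster to 100 keeping up to 5 within 10 kJ/mol -> expensive SPE ->
    cluster to 100 keeping all within 10 kJ/mol -> expensive relax -> dedup.
    Cluster counts and windows are user-configurable choices, not claims.
    """
    return [
        {"type": "generate", "n_per_sg": n_per_sg},
        {"type": "press"},
        {"type": "dedup", "group_by": "space_group"},
        {"type": "spe", "calculator": cheap},
        {"type": "cluster_select", "target_k": "10%", "mode": "lowest"},
        {"type": "relax", "calculator": cheap},
        {"type": "dedup", "group_by": "none"},
        {
            "type": "cluster_select",
            "target_k": 100,
            "mode": "window",
            "window": 10.0,
            "max_per_cluster": 5,
        },
        {"type": "spe", "calculator": expensive},
        {
            "type": "cluster_select",
            "target_k": 100,
            "mode": "window",
            "window": 10.0,
            "max_per_cluster": None,
        },
        {"type": "relax", "calculator": expensive},
        {"type": "dedup", "group_by": "none"},
    ]


def _resolve_target_k(raw, n: int) -> int:
    if isinstance(raw, str) and raw.endswith("%"):
        return max(2, round(n * float(raw[:-1]) / 100.0))
    k = int(raw)
    return k


def _stage_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def _run_stage(
    stage: dict, pool: StructurePool | None, cfg: WorkflowConfig, index: int
) -> StructurePool:
    kind = stage["type"]
    params = {k: v for k, v in stage.items() if k != "type"}
    if kind == "generate":
        mol = cfg.molecule
        if isinstance(mol, (str, Path)):
            mol = load_molecule(mol)
        if mol is None:
            raise ValueError("generate stage requires a molecule")
        gen_cfg = GenerationConfig(
            rng_seed=_stage_seed(cfg.seed, index),
            **{k: v for k, v in params.items() if k != "seed"},
        )
        return generate_pool(mol, cfg.Z, gen_cfg)
    if pool is None:
        raise ValueError(f"stage {kind!r} needs an input pool")
    if kind == "press":
        return press_pool(pool, PressConfig(**params))
    if kind == "dedup":
        group_by = params.pop("group_by", "space_group")
        tol = MatchTolerances(**params) if params else MatchTolerances()
        return remove_duplicates(pool, tol, group_by=group_by)
    if kind in ("spe", "relax"):
        calc = get_calculator(params.get("calculator", "toy-cheap"))
        out = StructurePool(metadata=dict(pool.metadata))
        for s in pool:
            if kind == "spe":
                s2 = s.copy()
                s2.energy = calc.spe(s2)
            else:
                s2, _ = calc.relax(s)
            s2.tags["stages"] = list(s2.tags.get("stages", [])) + [kind]
            out.append(s2)
        return out
    if kind == "cluster_select":
        n = len(pool)
        target_k = _resolve_target_k(params.get("target_k", "10%"), n)
        if n < 3 or not 2 <= target_k < n:
            warnings.warn(
                f"cluster_select skipped: pool size {n} incompatible with "
                f"target_k {target_k}"
            )
            return pool
        fps = fingerprint_pool(pool)
        clustering = tune_preference(fps, target_k)
        mode = params.get("mode", "lowest")
        if mode == "lowest":
            out = select_lowest_per_cluster(pool, clustering)
        elif mode == "window":
            out = select_energy_window(
                pool,
                clustering,
                window=float(params.get("window", 10.0)),
                max_per_cluster=params.get("max_per_cluster", 5),
            )
        else:
            raise ValueError(f"unknown selection mode {mode!r}")
        for s in out:
            s.tags["stages"] = list(s.tags.get("stages", [])) + ["cluster_select"]
        return out
    raise ValueError(f"unknown stage type {kind!r}")


def run_workflow(
    cfg: WorkflowConfig,
    initial_pool: StructurePool | None = None,
    resume: bool = True,
) -> StructurePool:
    """Execute the stages in order with a checkpoint after each one.

    With ``resume`` (default) any stage whose checkpoint already exists in
    the working directory is loaded instead of recomputed, so re-running
    after an interruption reproduces the uninterrupted result exactly
    (per-stage seeds derive from (workflow seed, stage index), never from
    consumed generator state).  An empty stage list returns the input pool
    unchanged.
    """
    workdir = Path(cfg.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    log_path = workdir / "funnel.jsonl"
    pool = initial_pool
    for i, stage in enumerate(cfg.stages):
        stage_dir = workdir / f"stage_{i:02d}_{stage['type']}"
        if resume and (stage_dir / "manifest.json").exists():
            pool, _ = restore(stage_dir)
            continue
        n_in = None if pool is None else len(pool)
        pool = _run_stage(stage, pool, cfg, i)
        checkpoint(pool, f"{i:02d}_{stage['type']}", stage_dir)
        with log_path.open("a") as fh:
            fh.write(
                json.dumps(
                    {
                        "stage": i,
                        "type": stage["type"],
                        "n_in": n_in,
                        "n_out": len(pool),
                    },
                    sort_keys=True,
                )
                + "\n"
            )
    if pool is None:
        pool = StructurePool()
    return pool
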