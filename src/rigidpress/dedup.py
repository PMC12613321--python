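"""Duplicate detection and removal at loose geometric tolerances.

Raw pools contain many near-identical packings; removing them early with
deliberately loose tolerances (50% on lattice lengths, 10 degrees on
angles, half an average interatomic spacing on sites) keeps the expensive
energy stages small.  Matching compares Niggli-reduced cells, then sites by
optimal origin alignment and assignment; equivalence classes are connected
components of the pairwise match graph, because pairwise matching is not
transitive at loose tolerances.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .structures import CrystalStructure, StructurePool
from .symmetry import cell_to_params

__all__ = ["MatchTolerances", "structures_match", "remove_duplicates"]


@dataclass
class MatchTolerances:
    """ltol: fractional length tolerance; stol: site tolerance as a fraction
    of the average free length (V/n)^(1/3); angle_tol: degrees."""

    ltol: float = 0.5
    stol: float = 0.5
    angle_tol: float = 10.0

    def __post_init__(self) -> None:
        if min(self.ltol, self.stol, self.angle_tol) <= 0:
            raise ValueError("all tolerances must be positive")


def _niggli_params(cell: np.ndarray) -> tuple[float, ...]:
    a, b, c, al, be, ga = cell_to_params(cell)
    gv = gemmi.GruberVector(gemmi.UnitCell(a, b, c, al, be, ga), None)
    gv.niggli_reduce()
    return gv.cell_parameters()


def _cells_match(s1: CrystalStructure, s2: CrystalStructure, tol: MatchTolerances) -> bool:
    p1, p2 = _niggli_params(s1.cell), _niggli_params(s2.cell)
    for l1, l2 in zip(p1[:3], p2[:3]):
        if abs(l1 - l2) / min(l1, l2) > tol.ltol:
            return False
    for a1, a2 in zip(p1[3:], p2[3:]):
        # near 90 degrees the reduction may land on either the acute or the
        # obtuse Niggli branch; alpha and 180 - alpha describe the same
        # lattice with one axis flipped
        if min(abs(a1 - a2), abs(180.0 - a1 - a2)) > tol.angle_tol:
            return False
    return True


def _sites_match_directional(
    s1: CrystalStructure, s2: CrystalStructure, tol: MatchTolerances
) -> bool:
    """Try to overlay s2's sites on s1's, testing candidate origin shifts."""
    cell = s1.cell
    f1 = s1.fractional_coords() % 1.0
    f2 = s2.fractional_coords() % 1.0
    el1 = np.array(s1.all_elements())
    el2 = np.array(s2.all_elements())
    n = len(f1)
    cutoff = tol.stol * (s1.volume / n) ** (1.0 / 3.0)
    ref_el = el1[0]
    candidates = np.flatnonzero(el2 == ref_el)
    by_el = {el: (np.flatnonzero(el1 == el), np.flatnonzero(el2 == el)) for el in set(el1)}

    for j in candidates:
        shift = f1[0] - f2[j]
        total_sq, total_n, ok = 0.0, 0, True
        for el, (i1, i2) in by_el.items():
            delta = f1[i1][:, None, :] - (f2[i2] + shift)[None, :, :]
            delta -= np.round(delta)
            dist = np.linalg.norm(delta @ cell, axis=-1)
            row, col = linear_sum_assignment(dist)
            d = dist[row, col]
            if d.max() > 3.0 * cutoff:  # hopeless assignment, try next shift
                ok = False
                break
            total_sq += float(np.sum(d**2))
            total_n += len(d)
        if ok and np.sqrt(total_sq / total_n) <= cutoff:
            return True
    return False


def structures_match(
    s1: CrystalStructure, s2: CrystalStructure, tol: MatchTolerances | None = None
) -> bool:
    """True iff the two periodic structures overlay within the tolerances.

    Composition (element multiset) must agree exactly; lattices are compared
    after Niggli reduction; sites by RMS displacement after optimal origin
    alignment and per-element assignment, threshold stol*(V/n)^(1/3).
    Symmetric and reflexive by construction.
    """
    tol = tol or MatchTolerances()
    if Counter(s1.all_elements()) != Counter(s2.all_elements()):
        return False
    if not _cells_match(s1, s2, tol):
        return False
    return _sites_match_directional(s1, s2, tol) or _sites_match_directional(
        s2, s1, tol
    )


def remove_duplicates(
    pool: StructurePool,
    tol: MatchTolerances | None = None,
    group_by: str = "space_group",
) -> StructurePool:
    """Keep one representative per match-equivalence class.

    Classes are connected components of the pairwise match graph within each
    ``group_by`` bucket ("space_group" or "none").  The representative is the
    lowest-energy member when energies are attached, else the first in pool
    order.  Removal counts land in the output pool's metadata; idempotent.
    """
    tol = tol or MatchTolerances()
    if group_by not in ("space_group", "none"):
        raise ValueError("group_by must be 'space_group' or 'none'")
    n = len(pool)
    buckets: dict = {}
    for i, s in enumerate(pool):
        key = s.sg_number if group_by == "space_group" else 0
        buckets.setdefault(key, []).append(i)

    keep: list[int] = []
    for idxs in buckets.values():
        m = len(idxs)
        vols = np.array([pool[i].volume for i in idxs])
        rows, cols = [], []
        for a in range(m):
            for b in range(a + 1, m):
                # volume is match-invariant within tolerance: prune safely
                if abs(vols[a] - vols[b]) > 3 * tol.ltol * max(vols[a], vols[b]):
                    continue
                if structures_match(pool[idxs[a]], pool[idxs[b]], tol):
                    rows.append(a)
                    cols.append(b)
        graph = csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(m, m)
        )
        n_comp, labels = connected_components(graph, directed=False)
        for comp in range(n_comp):
            members = [idxs[k] for k in np.flatnonzero(labels == comp)]
            energies = [pool[i].energy for i in members]
            if all(e is not None for e in energies):
                rep = members[int(np.argmin(energies))]
            else:
                rep = min(members)
            keep.append(rep)

    keep.sort()
    out = pool.subset(keep)
    out.metadata["dedup_removed"] = n - len(keep)
    for s in out:
        s.tags["stages"] = list(s.tags.get("stages", [])) + ["dedup"]
    return out
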