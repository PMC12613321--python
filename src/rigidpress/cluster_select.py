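"""Structure fingerprints, affinity-propagation clustering, selection rules.

Down-selection balances diversity against stability: structures are
described by a smoothed element-pair radial-distribution fingerprint,
clustered by affinity propagation (AP) with the preference hyperparameter
tuned automatically to hit a target cluster count, and then reduced by
per-cluster energy rules (the single lowest, or up to a few structures
within an energy window measured from each cluster's own minimum).

The cluster-relative window has a useful guarantee: the pool's global
minimum is the minimum of its own cluster, so it survives every selection
stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structures import CrystalStructure, StructurePool

__all__ = [
    "FingerprintConfig",
    "ClusteringResult",
    "fingerprint",
    "fingerprint_pool",
    "similarity_matrix",
    "affinity_propagation",
    "tune_preference",
    "select_lowest_per_cluster",
    "select_energy_window",
]


@dataclass
class FingerprintConfig:
    """Element-pair RDF descriptor: Gaussian-broadened interatomic distance
    histogram up to ``cutoff`` Angstrom, ``n_bins`` bins, volume-normalized
    so that supercells of the same motif give the same vector."""

    cutoff: float = 8.0
    n_bins: int = 40
    broadening: float = 0.25  # Angstrom


@dataclass
class ClusteringResult:
    labels: np.ndarray  # per-structure cluster id (0..k-1)
    exemplars: np.ndarray  # per-cluster exemplar index into the pool
    preference: float
    converged: bool = True
    trace: list = field(default_factory=list)  # (preference, n_clusters) pairs

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)


def fingerprint(
    structure: CrystalStructure, cfg: FingerprintConfig | None = None
) -> np.ndarray:
    """Deterministic, translation/origin-invariant crystal descriptor.

    For each unordered element pair (a, b): the Gaussian-broadened histogram
    of distances from the central-cell atoms of species a to all periodic
    copies of species b, scaled by V/(N_a*N_b); blocks are concatenated in
    sorted element-pair order.
    """
    cfg = cfg or FingerprintConfig()
    cell = structure.cell
    frac = structure.fractional_coords() % 1.0
    cart = frac @ cell
    elements = np.array(structure.all_elements())
    V = structure.volume

    recip = np.linalg.inv(cell.T)
    spacing = 1.0 / np.linalg.norm(recip, axis=1)
    bound = np.ceil(cfg.cutoff / spacing).astype(int) + 1
    axes = [np.arange(-b, b + 1) for b in bound]
    ns = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    shifts = ns @ cell  # (M, 3)

    centers = (np.arange(cfg.n_bins) + 0.5) * (cfg.cutoff / cfg.n_bins)
    uniq = sorted(set(elements))
    blocks = []
    for ai, a in enumerate(uniq):
        xa = cart[elements == a]
        for b in uniq[ai:]:
            xb = cart[elements == b]
            # distances from central-cell a-atoms to every image of b-atoms
            diff = (
                xa[:, None, None, :]
                - xb[None, :, None, :]
                - shifts[None, None, :, :]
            )
            d = np.sqrt(np.sum(diff * diff, axis=-1)).ravel()
            d = d[(d > 1e-8) & (d < cfg.cutoff + 4 * cfg.broadening)]
            g = np.exp(
                -((centers[None, :] - d[:, None]) ** 2) / (2 * cfg.broadening**2)
            ).sum(axis=0)
            blocks.append(g * V / (len(xa) * len(xb)))
    return np.concatenate(blocks)


def fingerprint_pool(
    pool: StructurePool, cfg: FingerprintConfig | None = None
) -> np.ndarray:
    return np.array([fingerprint(s, cfg) for s in pool])


def similarity_matrix(fingerprints: np.ndarray) -> np.ndarray:
    """Negative squared Euclidean distances (the standard AP similarity)."""
    fp = np.asarray(fingerprints, dtype=float)
    sq = np.sum(fp**2, axis=1)
    return -(sq[:, None] + sq[None, :] - 2.0 * fp @ fp.T)


def affinity_propagation(
    S: np.ndarray,
    preference: float,
    damping: float = 0.7,
    max_iter: int = 1000,
    convergence_iter: int = 15,
) -> ClusteringResult:
    """Affinity propagation by responsibility/availability message passing.

    Deterministic for fixed inputs (no tie-breaking noise is injected).
    Stops when the exemplar set is stable for ``convergence_iter`` sweeps or
    at ``max_iter``; a non-converged run is flagged but still returns the
    best-effort labels.
    """
    S = np.array(S, dtype=float)
    n = S.shape[0]
    if n < 2 or S.shape != (n, n):
        raise ValueError("similarity matrix must be square with n >= 2")
    if not 0.5 <= damping < 1:
        raise ValueError("damping must be in [0.5, 1)")
    idx = np.arange(n)
    S[idx, idx] = preference
    R = np.zeros((n, n))
    A = np.zeros((n, n))
    E_old = None
    stable = 0
    converged = False
    for _ in range(max_iter):
        # responsibilities
        AS = A + S
        max1 = AS.max(axis=1)
        argmax1 = AS.argmax(axis=1)
        AS_mask = AS.copy()
        AS_mask[idx, argmax1] = -np.inf
        max2 = AS_mask.max(axis=1)
        Rnew = S - max1[:, None]
        Rnew[idx, argmax1] = S[idx, argmax1] - max2
        R = damping * R + (1 - damping) * Rnew
        # availabilities
        Rp = np.maximum(R, 0)
        Rp[idx, idx] = R[idx, idx]
        colsum = Rp.sum(axis=0)
        Anew = np.minimum(0, colsum[None, :] - Rp)
        Anew[idx, idx] = colsum - Rp[idx, idx]
        A = damping * A + (1 - damping) * Anew
        E = (np.diag(A) + np.diag(R)) > 0
        if E_old is not None and np.array_equal(E, E_old):
            stable += 1
            if stable >= convergence_iter and E.any():
                converged = True
                break
        else:
            stable = 0
        E_old = E

    exemplars = np.flatnonzero((np.diag(A) + np.diag(R)) > 0)
    if len(exemplars) == 0:  # degenerate: everything in one cluster
        exemplars = np.array([int(np.argmax(S.sum(axis=0)))])
    # refine exemplars within their clusters (standard final sweep)
    c = np.argmax(S[:, exemplars], axis=1)
    c[exemplars] = np.arange(len(exemplars))
    for k in range(len(exemplars)):
        members = np.flatnonzero(c == k)
        j = np.argmax(S[np.ix_(members, members)].sum(axis=0))
        exemplars[k] = members[j]
    c = np.argmax(S[:, exemplars], axis=1)
    c[exemplars] = np.arange(len(exemplars))
    return ClusteringResult(
        labels=c, exemplars=exemplars, preference=preference, converged=converged
    )


def tune_preference(
    fingerprints: np.ndarray,
    target_k: int,
    tolerance_frac: float = 0.1,
    damping: float = 0.7,
    max_iter: int = 1000,
    max_bisect: int = 30,
) -> ClusteringResult:
    """Bisection on the AP preference toward a target cluster count.

    The preference is searched between the minimum and maximum pairwise
    similarity (higher preference -> more clusters); accepted when the
    achieved count is within +-tolerance_frac of target_k, else the closest
    clustering found within ``max_bisect`` evaluations is returned with a
    warning.
    """
    S = similarity_matrix(fingerprints)
    n = S.shape[0]
    if not 2 <= target_k < n:
        raise ValueError(f"need 2 <= target_k < n, got k={target_k}, n={n}")
    off = S[~np.eye(n, dtype=bool)]
    lo, hi = float(off.min()), float(off.max())
    tol_lo = int(np.floor(target_k * (1 - tolerance_frac)))
    tol_hi = int(np.ceil(target_k * (1 + tolerance_frac)))
    trace: list[tuple[float, int]] = []
    best: ClusteringResult | None = None
    for _ in range(max_bisect):
        mid = 0.5 * (lo + hi)
        res = affinity_propagation(S, mid, damping=damping, max_iter=max_iter)
        trace.append((mid, res.n_clusters))
        if best is None or abs(res.n_clusters - target_k) < abs(
            best.n_clusters - target_k
        ):
            best = res
        if tol_lo <= res.n_clusters <= tol_hi:
            res.trace = trace
            return res
        if res.n_clusters > target_k:
            hi = mid
        else:
            lo = mid
    warnings.warn(
        f"preference tuning hit the iteration cap; closest achieved "
        f"{best.n_clusters} clusters for target {target_k}"
    )
    best.trace = trace
    best.converged = False
    return best


def _cluster_members(clustering: ClusteringResult) -> dict[int, np.ndarray]:
    return {
        k: np.flatnonzero(clustering.labels == k)
        for k in range(clustering.n_clusters)
    }


def select_lowest_per_cluster(
    pool: StructurePool, clustering: ClusteringResult
) -> StructurePool:
    """One survivor per non-empty cluster: its minimum-energy member
    (ties broken by pool order)."""
    energies = pool.energies()
    keep = []
    for k, members in _cluster_members(clustering).items():
        if len(members) == 0:
            continue
        keep.append(int(members[np.argmin(energies[members])]))
    keep.sort()
    out = pool.subset(keep)
    out.metadata["selected_clusters"] = clustering.n_clusters
    return out


def select_energy_window(
    pool: StructurePool,
    clustering: ClusteringResult,
    window: float = 10.0,
    max_per_cluster: int | None = 5,
) -> StructurePool:
    """Per cluster: members within ``window`` kJ/mol of the *cluster's own*
    minimum, sorted ascending, truncated to ``max_per_cluster`` (None means
    unlimited).  Because the window is cluster-relative, the pool's global
    minimum always survives."""
    energies = pool.energies()
    keep = []
    for k, members in _cluster_members(clustering).items():
        if len(members) == 0:
            continue
        e = energies[members]
        order = members[np.argsort(e, kind="stable")]
        e_min = energies[order[0]]
        sel = [int(i) for i in order if energies[i] - e_min <= window]
        if max_per_cluster is not None:
            sel = sel[:max_per_cluster]
        keep.extend(sel)
    keep.sort()
    out = pool.subset(keep)
    out.metadata["selected_clusters"] = clustering.n_clusters
    return out
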