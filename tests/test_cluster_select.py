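import numpy as np
import pytest

from rigidpress.cluster_select import (
    FingerprintConfig,
    affinity_propagation,
    fingerprint,
    fingerprint_pool,
    select_energy_window,
    select_lowest_per_cluster,
    similarity_matrix,
    tune_preference,
)
from rigidpress.structures import CrystalStructure, StructurePool


def _blobs(n_blobs=20, per_blob=10, dim=8, seed=0, spread=0.05):
    rng = np.random.default_rng(seed)
    centers = rng.uniform(-5, 5, size=(n_blobs, dim))
    pts = np.concatenate(
        [c + spread * rng.normal(size=(per_blob, dim)) for c in centers]
    )
    return pts


def test_fingerprint_deterministic_and_origin_invariant(small_pool):
    s = small_pool[0]
    f1 = fingerprint(s)
    f2 = fingerprint(s)
    assert np.array_equal(f1, f2)
    shifted = s.copy()
    shifted.placements = [
        ((c + np.array([0.21, 0.43, 0.65])) % 1.0, R) for c, R in s.placements
    ]
    assert np.abs(fingerprint(shifted) - f1).max() < 1e-9


def test_fingerprint_supercell_consistent(small_pool):
    """A 2x1x1 supercell of the same motif yields the same descriptor."""
    s = small_pool[0]
    doubled = CrystalStructure(
        cell=np.diag([2.0, 1.0, 1.0]) @ s.cell,
        sg_number=1,
        molecule=s.molecule,
        placements=[
            ((c + np.array([off, 0, 0])) / np.array([2.0, 1.0, 1.0]), R)
            for off in (0.0, 1.0)
            for c, R in s.placements
        ],
        lattice_system="triclinic",
    )
    f1 = fingerprint(s)
    f2 = fingerprint(doubled)
    scale = np.abs(f1).max()
    assert np.abs(f2 - f1).max() < 1e-6 * max(scale, 1.0)


def test_fingerprints_same_length_across_pool(small_pool):
    fps = fingerprint_pool(small_pool)
    assert fps.ndim == 2 and fps.shape[0] == len(small_pool)


def test_ap_two_separated_clouds():
    rng = np.random.default_rng(1)
    pts = np.concatenate(
        [rng.normal(0, 0.05, size=(10, 2)), rng.normal(10, 0.05, size=(10, 2))]
    )
    S = similarity_matrix(pts)
    med = np.median(S[~np.eye(20, dtype=bool)])
    res = affinity_propagation(S, preference=med)
    assert res.n_clusters == 2
    assert set(res.labels[:10]) != set(res.labels[10:])


def test_ap_identical_points_single_cluster():
    pts = np.ones((8, 3))
    S = similarity_matrix(pts)
    res = affinity_propagation(S, preference=-1.0)
    assert res.n_clusters == 1


def test_ap_exemplar_invariant():
    pts = _blobs(n_blobs=5, per_blob=6, seed=3)
    res = affinity_propagation(similarity_matrix(pts), preference=-30.0)
    for k, e in enumerate(res.exemplars):
        assert res.labels[e] == k


def test_ap_agrees_with_reference_implementation():
    """Partitions match scikit-learn's AP on random 50-point problems."""
    from sklearn.cluster import AffinityPropagation

    agreements = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        centers = rng.uniform(-8, 8, size=(8, 4))
        pts = np.concatenate(
            [c + 0.3 * rng.normal(size=(7, 4)) for c in centers]
        )[:50]
        S = similarity_matrix(pts)
        pref = float(np.median(S[~np.eye(50, dtype=bool)]))
        ours = affinity_propagation(S, pref, damping=0.7, max_iter=1000)
        ref = AffinityPropagation(
            damping=0.7,
            max_iter=1000,
            preference=pref,
            affinity="precomputed",
            random_state=0,
        ).fit(S)
        # compare induced partitions, not label numbering
        ours_parts = {
            frozenset(np.flatnonzero(ours.labels == k)) for k in set(ours.labels)
        }
        ref_parts = {
            frozenset(np.flatnonzero(ref.labels_ == k)) for k in set(ref.labels_)
        }
        assert ours_parts == ref_parts, f"partition mismatch at seed {seed}"
        agreements += 1
    assert agreements == 10


def test_tune_preference_hits_target_on_blobs():
    pts = _blobs(n_blobs=20, per_blob=10, seed=7)
    res = tune_preference(pts, target_k=20)
    assert abs(res.n_clusters - 20) <= 2


def test_tune_preference_high_end_limit():
    rng = np.random.default_rng(11)
    pts = rng.uniform(-5, 5, size=(12, 3))
    res = tune_preference(pts, target_k=11, tolerance_frac=0.1)
    assert res.n_clusters >= 9


def test_tune_preference_trace_monotone():
    """On the bisection trace, a higher preference never yields fewer
    clusters (probed on well-separated blobs)."""
    pts = _blobs(n_blobs=10, per_blob=8, seed=13)
    res = tune_preference(pts, target_k=10)
    by_pref = sorted(res.trace)
    counts = [k for _, k in by_pref]
    assert all(a <= b for a, b in zip(counts, counts[1:]))


def test_tune_preference_validates_target():
    pts = _blobs(n_blobs=3, per_blob=3, seed=1)
    with pytest.raises(ValueError):
        tune_preference(pts, target_k=1)
    with pytest.raises(ValueError):
        tune_preference(pts, target_k=9)


def _pool_with_energies(small_pool, seed):
    rng = np.random.default_rng(seed)
    pool = StructurePool([s.copy() for s in small_pool])
    for s in pool:
        s.energy = float(rng.uniform(-50, 0))
    return pool


def test_select_lowest_per_cluster(small_pool):
    pool = _pool_with_energies(small_pool, 17)
    fps = fingerprint_pool(pool)
    clustering = tune_preference(fps, target_k=5)
    out = select_lowest_per_cluster(pool, clustering)
    assert len(out) == clustering.n_clusters
    # brute-force per-cluster argmin oracle
    energies = pool.energies()
    expect = set()
    for k in range(clustering.n_clusters):
        members = np.flatnonzero(clustering.labels == k)
        expect.add(members[int(np.argmin(energies[members]))])
    got_ids = {s.tags.get("id") for s in out}
    expect_ids = {pool[i].tags.get("id") for i in expect}
    assert got_ids == expect_ids


def test_select_lowest_missing_energy_names_structure(small_pool):
    pool = StructurePool([s.copy() for s in small_pool])
    pool[0].tags["id"] = "culprit"
    with pytest.raises(ValueError, match="culprit"):
        pool.energies()


def test_select_window_cluster_relative(small_pool):
    """A structure far above the pool minimum but near its own cluster
    minimum is retained; truncation caps each cluster."""
    pool = StructurePool([s.copy() for s in small_pool])
    fps = fingerprint_pool(pool)
    clustering = tune_preference(fps, target_k=5)
    # construct energies: cluster 0 low, the others offset by +19.3
    for i, s in enumerate(pool):
        base = 0.0 if clustering.labels[i] == 0 else 19.3
        s.energy = base + 0.5 * (i % 8)
    label_of = {s.tags["id"]: clustering.labels[i] for i, s in enumerate(pool)}
    out = select_energy_window(pool, clustering, window=10.0, max_per_cluster=5)
    labels_kept = [label_of[s.tags["id"]] for s in out]
    assert set(labels_kept) == set(range(clustering.n_clusters))
    for k in range(clustering.n_clusters):
        assert labels_kept.count(k) <= 5
    # cluster-relative: members of offset clusters within 10 of their own
    # minimum survive although they are ~19 above the pool minimum
    assert any(s.energy > 15.0 for s in out)


def test_window_truncation_keeps_five_lowest():
    from rigidpress.cluster_select import ClusteringResult

    mol_pool = StructurePool()
    from rigidpress.chem_core import Molecule

    for i in range(8):
        m = Molecule(["C"], np.zeros((1, 3)), np.array([1.7]))
        s = CrystalStructure(
            cell=np.eye(3) * (5 + i), sg_number=1, molecule=m,
            placements=[(np.zeros(3), np.eye(3))],
        )
        s.energy = float(i)
        s.tags["id"] = f"s{i}"
        mol_pool.append(s)
    clustering = ClusteringResult(
        labels=np.zeros(8, dtype=int), exemplars=np.array([0]), preference=0.0
    )
    out = select_energy_window(mol_pool, clustering, window=10.0, max_per_cluster=5)
    assert [s.tags["id"] for s in out] == ["s0", "s1", "s2", "s3", "s4"]
    unlimited = select_energy_window(
        mol_pool, clustering, window=10.0, max_per_cluster=None
    )
    assert len(unlimited) == 8


def test_global_minimum_always_survives(small_pool):
    for seed in range(5):
        pool = _pool_with_energies(small_pool, seed)
        fps = fingerprint_pool(pool)
        clustering = tune_preference(fps, target_k=5)
        emin = pool.energies().min()
        for out in (
            select_lowest_per_cluster(pool, clustering),
            select_energy_window(pool, clustering, 10.0, 5),
        ):
            assert any(s.energy == emin for s in out)
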