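# Methods

## Problem setting

`rigidpress` treats a molecule as a rigid body: internal coordinates are
frozen everywhere, and a crystal is a unit cell plus Z symmetry-related
placements (fractional center of geometry + 3×3 rotation, improper for
mirror/inversion images). Only Z′ = 1 on general positions is supported, so
a space group is "compatible with Z" exactly when its general-position
multiplicity (centering included) equals Z. Special Wyckoff positions,
conformational flexibility and multi-component crystals are out of scope.

Conventions, fixed throughout: row-vector cells (a along x, b in the
xy-plane), monoclinic unique axis b, hexagonal setting for trigonal groups,
symmetry operations acting on column fractional coordinates, energies in
kJ/mol **per molecule**. Space-group operations come from gemmi's
standard-setting tables.

## Generation

The target cell volume is a deliberately coarse geometric estimate,
Z·Σ(4π/3)r³ / c with packing coefficient c = 0.55 by default. Free vdW
spheres overlap when atoms are bonded, so this overshoots real molecular
volumes — harmlessly, because the estimate is inflated by a further factor
1.5 anyway and the compaction step closes whatever gap remains. Volumes are
drawn from a normal distribution around the inflated target; its width is
not prescribed by the method, so we chose 7.5% of the mean as a realistic
scatter (configurable). Cell shapes use log-uniform aspect ratios capped at
4 and free angles uniform in 60–120°; both bounds exist only to exclude
pathological cells. Placements are uniform in fractional coordinates with
uniform random orientations (random unit quaternions).

A candidate is accepted when every intermolecular atom pair — across
distinct molecules and all periodic images, including a molecule against
its own images — satisfies d ≥ s_r(r_i + r_j) with s_r = 0.95 at generation
time. Hydrogen-bond pairs (an H within 1.2 Å of N/O/F versus any N/O/F
acceptor) may use a smaller special fraction, default 0.75; this number is
an overridable placeholder, not a statistical claim. The bundled vdW radii
are Bondi-style values keyed by element and user-replaceable.

Reproducibility: every structure draws from `SeedSequence([seed, group,
index])`, so pools are bit-identical for a fixed seed regardless of
scheduling or partial failures. A structure that exhausts its attempt
budget (default 1000) is skipped with a warning and a partial count in the
pool metadata.

## Rigid Press

The compaction minimizes F(s) = V(s) + P_contact(s) with BFGS
(scipy), stopping at gradient norm < 0.01 or 5000 iterations. The state
vector holds the crystal system's free lattice parameters (lengths in Å,
angles in degrees), the asymmetric unit's fractional center of geometry,
and intrinsic Z-Y-Z Euler angles (radians, unbounded — gimbal-lock states
are measure-zero and finite differences tolerate them). The full crystal is
rebuilt through the group operations at every evaluation, which is what
enforces the symmetry constraint: the group cannot drift because it is
applied, not monitored.

The pair penalty is φ(d) = 0 for d ≥ D, w(D−d)/(d−σ) for σ < d < D, and a
finite cap w·10¹² for d ≤ σ (the divergent branch is not representable and
BFGS line searches need finite trial values; capped states are effectively
always rejected by the line search). D = l_mol + 2·max σ_ij with l_mol
twice the maximal COG-to-atom distance; w = k/N²_atoms with k = 0.1 by
default — k balances the penalty against the volume term, and the hard-wall
tests sweep it down to 10⁻⁴.

Pair bookkeeping: interacting molecule pairs (A, B, image translation n)
are enumerated with A ≤ B, identity excluded, and only the
lexicographically positive half of self-image translations, so each
physical pair class is counted exactly once per unit cell (this fixes the
absolute scale of P_contact). Intra-cell pairs are always kept; image pairs
are kept when the COG distance is below 1.1·D + l_mol, a rigorous superset
of the contact set. The set is cached and rebuilt when any lattice
parameter changes by >1% or the asymmetric COG moves by >4% of D; the 10%
margin covers the drift in between.

Gradients are central finite differences (relative step 10⁻⁶, absolute
floor 10⁻⁸) so the objective remains the single source of truth; tests
cross-check against a second stencil at a different step. Note that φ is
continuous but not differentiable at d = D; states with a pair distance
within ~10⁻³ Å of that breakpoint are excluded from gradient-agreement
tests because no finite difference is meaningful across a kink. Degenerate
cells during line search return a large capped objective instead of
raising.

An unsymmetrized variant optimizes all Z placements independently in P1
through the same objective code path; improper input placements contribute
a fixed parity sign so only proper rotations are optimized.

## Duplicate removal

Matching is deliberately loose (defaults: 0.5 fractional length tolerance,
0.5 site tolerance as a fraction of (V/n)^{1/3}, 10° angle tolerance):
the goal is to collapse redundancy cheaply before any energy is spent.
Cells are compared after Niggli reduction (gemmi), with lengths normalized
by the smaller value and angles compared modulo the acute/obtuse branch
flip (α and 180°−α describe the same lattice near 90°). Sites are compared
by RMS displacement after testing candidate origin shifts (each
same-element atom aligned to a reference atom) with per-element Hungarian
assignment. Equivalence classes are connected components of the match
graph — pairwise matching is not transitive at these tolerances — and the
representative is the lowest-energy member when energies exist, else the
first in pool order, making the class set order-independent. The matcher
does not search alternative lattice bases beyond Niggli reduction; for
structures whose reduced settings differ by an axis permutation
(near-degenerate lengths) it can return a false negative, which for
deduplication is the safe direction.

## Fingerprints, clustering, selection

The structure descriptor is a smoothed element-pair radial distribution:
for each unordered element pair, a Gaussian-broadened (0.25 Å) histogram of
distances from central-cell atoms to all periodic neighbors within 8 Å in
40 bins, scaled by V/(N_a·N_b). This makes it invariant to translation,
origin choice and supercell convention. It is a documented stand-in with
the required invariances, not a claim about any particular published
descriptor.

Affinity propagation is implemented as standard responsibility/availability
message passing with damping 0.7, convergence window 15 sweeps, cap 1000,
no tie-breaking noise (deterministic), and the usual final exemplar
refinement; tests require partition-level agreement with scikit-learn's
implementation on structured problems. Similarity is negative squared
Euclidean distance. The preference is tuned by bisection between the
minimum and maximum pairwise similarity until the cluster count is within
±10% of the target (cap 30 evaluations; the closest clustering is returned
with a warning otherwise).

Selection rules: "lowest" keeps each cluster's energy minimum;
"window" keeps up to 5 structures within 10 kJ/mol of **each cluster's own
minimum** (unlimited mode drops the cap). The window is cluster-relative,
not pool-relative, which yields a retention guarantee — the pool's global
minimum is the minimum of its own cluster and therefore survives every
selection stage — and lets a structure far above the global minimum survive
when it ranks high within its own cluster.

## Workflow and I/O

A workflow is a declarative stage list (generate, press, dedup, spe, relax,
cluster_select) run over a pool, with a self-contained checkpoint (one CIF
per structure + JSON manifest) after every stage. Per-stage seeds derive
from (workflow seed, stage index), never from consumed generator state, so
resuming from any checkpoint reproduces the uninterrupted run byte-for-byte
in the manifests. Energy backends implement a two-method contract
(single-point energy; symmetry-constrained relaxation); the shipped toy
calculator is a shifted Lennard-Jones potential with its minimum at the
summed vdW radii, registered in two tiers with different cutoffs (6 and
10 Å) so tests exercise re-ranking between a cheap and an expensive stage.
Its relaxation reuses the same symmetry-reduced state vector as the press,
with a gradient-norm threshold of 0.96 kJ/mol/Å (≈0.01 eV/Å). CIF files
written by the package carry the exact placements and molecule in a
reserved `_rigidpress_meta` field, so read-back is exact to float
precision; foreign P1 CIFs and extended-XYZ files are read as Z = 1
structures whose "molecule" is the full cell contents.

## What the toy inputs do and do not show

All tests and the acceptance script run on programmatically generated
molecules (rods, rings, random clusters of C/H/N/O). These exercise every
code path — symmetry, image bookkeeping, hydrogen-bond tagging, energy
staging — at sizes where brute-force oracles are affordable (problem sizes:
ensembles of 100–500 structures, molecules of 1–5 atoms, Z ≤ 4). They do
not demonstrate chemical accuracy of any energy model (the toy calculator
is deliberately fictitious) or descriptor quality on real polymorph
landscapes. One genuine finding from the toy runs: highly symmetric toy
molecules (a 2-atom rod) can compact into *genuinely* higher-symmetry
packings — extra mirrors or even translational merging of molecules — so
symmetry-equality tests use an asymmetric 4-atom cluster, which behaves
like real molecules in this respect.

## Known limitations

* Z′ = 1, general positions only; Z values with no matching general
  multiplicity (e.g. 5) yield an empty compatible-group list.
* Finite-difference gradients cost 2·dim objective evaluations per
  iteration; fine for desk-scale molecules, not tuned for production scale.
* The duplicate matcher is a reimplementation of the loose-tolerance
  contract, not a full structure-matching engine (no basis-permutation
  search).
* Symmetry detection identifies groups through gemmi's settings table; op
  sets arising from accidental sublattice symmetry (non-crystallographic
  centerings) raise an explicit error rather than guessing.
* The volume estimate is order-of-magnitude by design; anything finer
  belongs to a learned volume model, which is intentionally not part of
  this package.
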