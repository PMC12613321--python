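"""The hard-wall limit of the contact penalty.

A single-sphere crystal in a cubic P1 cell is compacted for decreasing
penalty constants k.  As k -> 0 the optimal lattice constant approaches the
hard-sphere diameter sigma = s_r * 2r from above: the penalty turns into a
true hard wall and the cell closes onto touching spheres.
"""

import numpy as np

from rigidpress import PressConfig, rigid_press
from rigidpress.fixtures import single_sphere
from rigidpress.structures import CrystalStructure

mol = single_sphere("C")
sigma = 0.85 * 2 * float(mol.vdw_radii[0])
print(f"hard-sphere diameter sigma = {sigma:.3f} A")
print(f"{'k':>8}  {'a (A)':>8}  {'a/sigma':>8}")
for k in (1e-1, 1e-2, 1e-3, 1e-4):
    start = CrystalStructure(
        cell=np.eye(3) * 3 * sigma,
        sg_number=1,
        molecule=mol,
        placements=[(np.zeros(3), np.eye(3))],
        lattice_system="cubic",
    )
    out, _ = rigid_press(start, PressConfig(k=k))
    a = out.volume ** (1 / 3)
    print(f"{k:8.0e}  {a:8.4f}  {a / sigma:8.4f}")
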