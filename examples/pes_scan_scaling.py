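"""Dimer approach PES and selective Lennard-Jones epsilon scaling.

Scans the rigid cofacial approach of two dye templates, dE(rCC) =
E(rCC) - E(40 A): two cations must climb a Coulomb barrier before the
van der Waals well binds them.  Doubling the LJ well depths of the
chromophore-plane atoms only (the epsilon-scaled subset) deepens the
dimer well; fit_scale_factor then recovers that factor from the scanned
curve alone.
"""

import numpy as np

from dyestack import fit_scale_factor, scan_pes
from dyestack.synthetic import default_dye_template, parameterized_molecule

mol = parameterized_molecule(default_dye_template())
distances = np.arange(3.2, 15.0, 0.2)
axis = (0.0, 0.0, 1.0)  # approach along the plane normal
solvent = {"dielectric": 80.0}  # water-like screening of the +1/+1 repulsion

for s in (1.0, 2.0):
    scan = scan_pes(mol, mol, axis, distances, scale_factor=s, **solvent)
    print(
        f"scale_factor={s:.1f}: well {scan.well_depth:7.2f} kcal/mol at "
        f"{scan.r_min_location:.1f} A, outer barrier {scan.barrier_height:5.2f} kcal/mol"
    )

reference = scan_pes(mol, mol, axis, distances, scale_factor=2.0, **solvent)
recovered = fit_scale_factor(reference, mol, mol, axis, **solvent)
print(f"scale factor refit against the s=2 curve: {recovered:.3f}")

print(
    "\nDoubling epsilon over the plane atoms roughly doubles the well depth "
    "while the barrier (pure Coulomb, untouched by the scaling) stays put; "
    "the refit recovers the generating factor to three decimals."
)
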