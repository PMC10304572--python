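"""Refit cosine-series dihedral terms against a reference torsion scan.

Takes the packaged three-well reference profile (10-degree grid), a zero
MM baseline (torsion terms removed), and fits the AMBER-form cosine
series up to n = 4 by linear least squares.  Convergence requires the
fit to track the reference within 0.2 kcal/mol inside the minima
regions, where the thermally relevant conformers live.
"""

from dyestack import fit_torsion
from dyestack.synthetic import make_reference_torsion_profile, zero_mm_profile

reference = make_reference_torsion_profile()
report = fit_torsion(reference, zero_mm_profile(), max_n=4, tolerance=0.2)

print("fitted dihedral terms (V_n kcal/mol, n, gamma deg):")
for v, n, g in report.series.terms:
    print(f"  V{n} = {v:6.3f}   gamma = {g:5.1f}")
print(f"offset = {report.series.offset:.3f} kcal/mol")
print(f"minima regions (deg): {report.minima_regions}")
print(f"max deviation in minima regions : {report.max_dev_minima:.4f} kcal/mol")
print(f"max deviation anywhere          : {report.max_dev_global:.4f} kcal/mol")
print(f"converged at 0.2 kcal/mol       : {report.converged}")
print()
print(report.series.to_frcmod_text("c3-ca-ca-c3"))
print(
    "\nThe residual left after the n<=4 fit is the deliberately out-of-basis "
    "perturbation of the fixture (a few hundredths of a kcal/mol), far inside "
    "the 0.2 kcal/mol acceptance band around the minima."
)
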