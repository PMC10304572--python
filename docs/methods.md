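# Methods

`dyestack` analyzes the self-assembly of cationic xanthene dyes (rhodamine-type
chromophores) driven by their counterions.  The experimental picture it serves:
bulky hydrophobic anions such as tetraphenylborate derivatives act as spacers
that pull dye cations into large mixed aggregates while preventing the tight
cofacial (H-type) dimerization that quenches fluorescence, whereas small ions
such as iodide leave the dyes dispersed.  The package provides the geometric
dimer taxonomy, the aggregation observables, the nonbonded energetics used to
rationalize dimer formation, a torsion-refitting tool, and a synthetic
generator that reproduces the two regimes at desk scale.

## Chromophore frames and dimer geometry

Each dye's xanthene core is treated as a rigid plane.  Its local frame is:

* **center** — centroid of the configured `xanthene_atoms`;
* **ẑ** — normal of the least-squares plane (smallest singular direction of
  the centered coordinates); degenerate (collinear) inputs are rejected when
  the two smallest singular values coincide within 1e-10;
* **x̂** — the vector between the two `long_axis_atoms` (the amine nitrogens
  in the bundled template), projected into the plane.  This is the proxy for
  the transition dipole moment, which lies in the xanthene plane along its
  long axis.  The projected atom-pair vector is used instead of a planar
  inertia axis because it is robust to thermal bending of the scaffold;
* **ŷ = ẑ × x̂** completes the right-handed triad.

For a pair (A, B), the center–center vector r_CC = center(B) − center(A) is
taken under the minimum-image convention when a periodic box is present;
probe atoms are shifted with their molecule's image so molecules are never
split.  Derived quantities:

* **θ** — angle between x̂_A and x̂_B, folded into [0°, 90°] because molecular
  axes are directionless;
* **α** — angle between r_CC and the sign-aligned mean of the two long axes,
  also folded.  The mean-axis convention matters only for near-parallel pairs
  (θ ≤ 12°), where the two per-molecule choices nearly coincide;
* **(r_x, r_y, r_z)** — |components| of r_CC in each molecule's frame (both
  orderings kept);
* **probe-plane distances** — perpendicular distances of each molecule's four
  `stack_probe_atoms` from the partner's plane.

## Dimer classification

A pair is **interacting** when r_CC < 6 Å, a separation at which the stacked
dimer interaction is already attractive and which excludes counterion-bridged
pairs.  Interacting pairs are **crossed-J** when θ ≥ 12°, otherwise **H** when
α > 54.7° (the magic angle, arccos(1/√3), where the excitonic coupling changes
sign) and **J** otherwise.  Boundaries are closed on the lower side: θ = 12°
is crossed-J, α = 54.7° is J, r_CC = 6 Å is non-interacting; the underlying
intervals are open in their usual statement, so these measure-zero choices are
the package's own.

**π-stacking** is a separate flag.  Ordering m describes the partner relative
to molecule m's plane: r_x < 4 Å and r_y < 2 Å in m's frame (cutoffs tied to
the hexagon dimensions of the xanthene plane; one textual variant gives
r_x < 5 Å, available via `stack_rx_cut=5.0`) AND all four probe atoms of the
partner within 4.5 Å of m's plane.  The two orderings are OR-combined.
Pairing the lateral criterion and the plane-distance criterion to the *same*
plane owner is essential: pairing each molecule's own probes with its own
frame components would flag T-shaped (perpendicular-plane) contacts as
stacked, because the flat partner's probes sit trivially close to the upright
molecule's plane.  The implemented pairing rejects T-shapes and leaves all
cofacial cases unchanged.

The identity of the four probe atoms is a user choice declared in the
topology config; the bundled template uses the four central ring-junction
carbons (C3, C4, C9, C10), an illustrative but documented pick.

## Aggregation metrics

* **Per-frame counts** — interacting pairs, and stacked pairs sub-classified
  as H / J / crossed-J (so "stacked H" time series can be plotted alongside
  the total dimer count).  All unordered pairs are counted; a dye appearing
  in two pairs contributes twice (the alternative, mutually exclusive
  pairings, is not used and not needed for these observables).
* **Σ r_CC** — the raw sum (Å) of all dye–dye center distances, a scalar that
  drops when large aggregates form.  No normalization is applied.
* **Clusters** — connected components of the graph whose nodes are dye and
  counterion molecules and whose edges join molecules with minimum heavy-atom
  distance < 4.5 Å (minimum image).  This criterion is an invention of the
  package: aggregates are otherwise only assessed visually or through Σ r_CC.
  Counterions are nodes, so counterion-bridged aggregates count as one
  cluster; a **full aggregate** is a cluster containing every dye.
* **Block averages** — non-overlapping windows (default 0.1 ns) starting at
  the first sample; each output is (window midpoint, mean).  A trailing
  partial window is averaged and flagged, not dropped.
* **RDFs** — center-to-center g(r) for dye–dye (xanthene centroids) and
  dye–counterion (counterion centroid) pairs, averaged over the trailing
  1 ns by default (when aggregates, if any, are formed), normalized per frame
  by the ideal-gas shell count.  Requires a periodic box and
  r_max ≤ min(box)/2.

## Nonbonded energetics and the approach PES

Pair energies use the AMBER R_min/ε convention with standard combining rules
(geometric ε, additive R_min/2; σ-form inputs convertible via
`sigma_to_rmin_half`), Coulomb constant k_C = 332.0636 kcal·Å/(mol·e²),
vacuum electrostatics by default (dielectric 1, no cutoffs).  A configurable
subset of atoms — the xanthene moiety in the intended use — can have its ε
values scaled; the scale applies when **both** pair members are in the subset
(a per-atom √s convention is available behind a flag) and touches only ε,
never R_min or charges.  Doubling the subset ε is the canonical correction
that deepens an underbound stacked-dimer well to a dispersion-corrected
reference.

The approach PES rigidly translates molecule B along an axis until the
subset-centroid separation equals each scan distance, and reports
ΔE(r_CC) = E(r_CC) − E(40 Å).  Scan points with interatomic contacts below
0.1 Å are rejected as steric overlap.  `fit_scale_factor` recovers the ε
scale that best reproduces a reference ΔE curve by bounded 1-D least squares
on s ∈ [0.5, 5] (tolerance 1e-4); it requires the reference to have a well.
Note that two +1 monomers in true vacuum with the toy template parameters
have no well — examples and tests therefore pass `dielectric=80` (water-like
screening) when a well is needed.

## Torsion refitting

Dihedral terms use V(φ) = offset + Σ (V_n/2)(1 + cos(nφ − γ_n)) with
γ ∈ {0°, 180°}, which keeps the fit linear: the residual
(reference − MM-without-torsion) is expanded in {1, cos nφ}, n ≤ 4 by
default, and negative coefficients map to γ = 180° (equivalently, negative
V_n are permitted).  Convergence is judged where it matters physically: the
maximum |fit − reference| inside the **minima regions** must be ≤ 0.2
kcal/mol.  A minima region is the contiguous set of grid points within 1.0
kcal/mol (configurable) of a local minimum, detected on the periodic
continuation when the grid covers 360°; monotone non-periodic profiles are
rejected.  Profiles are min-shifted to zero on construction, so constant
offsets in the reference move only the fitted offset.

This is direct potential-profile fitting.  The free-energy route (matching
MM free-energy profiles from adaptive-biasing-force sampling against the
reference scan) requires an MD engine and is out of scope; the 0.2 kcal/mol
minima criterion is retained as the convergence test.  The L∞ deviation is
not guaranteed to improve for adversarial inputs (least squares minimizes
L2), but it does for realistic profiles dominated by in-basis structure, and
the property suite checks exactly that regime.

## Synthetic study systems

The generator emulates the study conditions: 10 dye cations + 10 counterions
in an 85 Å periodic cube, initially dispersed with all dye–dye center
distances above 12 Å (comfortably beyond the 6 Å interacting cutoff), run to
either aggregation or dispersion depending on the counterion.

* **Dye template** — a rigid planar 19-atom stand-in: 17 in-plane atoms
  (twelve ring carbons, two bridgeheads, one oxygen, two long-axis
  nitrogens), four central probe carbons, two out-of-plane pendant carbons,
  net charge +1e, toy GAFF-like ε/R_min values.  It carries the correct
  topology *roles*, not a claim about the real molecule's geometry or
  charges.
* **Counterions** — a bulky five-site tetrahedral anion (−1e, large excluded
  volume, able to sit between stacked dyes) and a small monatomic anion.
* **Planted dimers** — `make_planted_dimer` inverts the dimer-geometry map:
  both long axes at ∓θ/2 about a common normal, r_CC =
  (r cos α, r_y, plane_sep).  Infeasible requests (plane_sep > r_CC or
  > r_CC·sin α) are rejected.  Recovery of (θ, α, r_CC) is exact to 1e-6.
* **Monte Carlo** — rigid-body Metropolis sampling at 300 K over one coarse
  site per molecule.  The Hamiltonian is the package's own pair kernel:
  screened Coulomb (uniform dielectric 40, Debye length 10 Å — the
  implicit-solvent replacement for the ~20,800 explicit waters of the
  emulated setup) plus LJ with per-type wells: dye–dye ε 0.25 kcal/mol at
  R_min 6 Å (net slightly repulsive with the +1/+1 Coulomb term), ion–ion
  weakly repulsive, and dye–counterion ε = `attraction_scale` (default 3
  kcal/mol ≈ 5 k_BT, floored at a 0.1 kcal/mol core) in the bulky mode with
  R_min 7 Å, versus a bare core in the small-ion mode.  Moves: local
  translations ≤ 0.5 Å, free orientational diffusion ≤ 10° (one-site
  molecules carry no torque), and with probability 0.1 a box-uniform
  relocation.  The relocation move is Metropolis-symmetric and therefore
  exact, and it is what makes a desk-scale run cross an 85 Å box: the model
  then *equilibrates* rather than merely diffusing, so the two regimes are
  equilibrium statements (condensed cluster vs ionic gas), robust to seed.
  Defaults: 20,000 sweeps, a frame every 100 sweeps, nominal time labels of
  0.001 ns/sweep (20 ns total, so 0.1 ns block averaging is meaningful).
  Identical configurations (including the seed) give byte-identical
  trajectories.

What the generator does *not* emulate: explicit solvent, realistic internal
flexibility, kinetics (relocation moves destroy the dynamical pathway),
force-field-accurate energetics, and orientation-dependent dye–dye forces
(one-site molecules), so stacked-dimer statistics in generated trajectories
come from packing plus random orientation rather than anisotropic
interactions.  Passing the contrast tests therefore demonstrates that the
*analysis* stack distinguishes the two regimes and that the generator's
equilibrium physics is qualitatively right — not that real trajectories were
reproduced.

## Problem sizes and numerical choices

The bundled analyses run at the study composition (10 + 10 molecules); the
contrast checks use 5 seeds per counterion mode at the default 20,000 sweeps
(~15 s per run).  RDF comparisons for the contrast use 1 Å bins over a 5 ns
trailing window so the dispersed (nearly flat) g(r) is well enough sampled
for a peak-position ordering.  Other numerical choices: plane-fit degeneracy
at 1e-10; frame orthonormality at 1e-8; PES overlap rejection at 0.1 Å;
scale-factor fit tolerance 1e-4 on s; torsion basis rank checked before
solving; classifier boundary behaviour as stated above.

## Known limitations

* PDB frames carry no time metadata; they are labeled by frame index.
  Extended-XYZ output stores `time=` and `Lattice=` in the comment line and
  round-trips both.
* Orthorhombic boxes only.
* α is folded and measured against the mean long axis; for strongly
  non-parallel pairs its value is reported but not used by the classifier.
* The cluster contact cutoff (4.5 Å heavy-atom minimum distance) is a
  package convention, not a community standard; vary `contact_cut` to test
  sensitivity.
* `fit_scale_factor` assumes the reference and the model share monomer
  geometries and charges; it compensates only through the subset ε.
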