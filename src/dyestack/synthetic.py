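"""Synthetic study systems: planted dimers, dispersed boxes, MC aggregation.

This module generates every input the analysis stack consumes, emulating
the study conditions of counterion-driven rhodamine aggregation: N dye
cations plus N counterions (10 + 10 by default) in a periodic cubic box
of 85 angstrom side, initially dispersed with all dye-dye center
distances well above the 6 angstrom interacting cutoff, evolving toward
an aggregated or a dispersed state depending on the counterion.

The dye is a rigid planar stand-in for a xanthene chromophore -- correct
topology roles (plane atoms, long-axis nitrogens, four central stack-
probe carbons, net charge +1e) and toy nonbonded parameters, not a claim
about the real molecule's geometry or charges.  Two counterions are
provided: a bulky hydrophobic anion (a tetrahedral five-site cluster
with a large excluded-volume radius, able to sit between stacked dyes)
and a small monatomic anion.

``run_aggregation`` is a rigid-body Metropolis Monte Carlo sampler over
coarse one-site-per-molecule interactions: screened Coulomb (uniform
dielectric + Debye factor, the implicit-solvent replacement for the
~20,800 explicit waters of the emulated setup) plus Lennard-Jones, with
the dye-counterion well depth set by ``attraction_scale`` in the bulky
mode.  In that mode the equilibrium state is a single dye/counterion
aggregate; in the small-ion mode (or at zero attraction) the system
stays a dispersed ionic gas.  Identical configurations (including the
seed) yield byte-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np

from .energetics import COULOMB_CONSTANT, NonbondedAtom, ParameterizedMolecule
from .torsionfit import CosineSeries, TorsionProfile
from .trajio import AtomRecord, Frame, SystemTopology, assign_molecule_ids

__all__ = [
    "SyntheticConfig",
    "RigidDyeTemplate",
    "default_dye_template",
    "bulky_counterion_template",
    "small_counterion_template",
    "default_topology",
    "make_planted_dimer",
    "make_dispersed_frame",
    "run_aggregation",
    "make_reference_torsion_profile",
    "zero_mm_profile",
    "parameterized_molecule",
    "mc_site_parameters",
]

KB_KCAL = 0.0019872041  # Boltzmann constant, kcal/(mol K)

COUNTERION_MODES = ("bulky_hydrophobic", "small_ionic")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic generators.

    The composition defaults (10 dyes + 10 counterions, 85 angstrom cubic
    box) are the emulated study conditions.  ``attraction_scale`` is the
    dye-counterion LJ well depth (kcal/mol) applied in the bulky-
    hydrophobic mode; the small-ionic mode keeps only a thin repulsive
    core.  ``timestep_label`` maps MC sweeps to nominal nanoseconds purely
    for labeling, so 0.1 ns block averaging downstream is meaningful.
    """

    n_dye: int = 10
    n_counterion: int = 10
    box_side: float = 85.0
    seed: int = 0
    counterion_mode: str = "bulky_hydrophobic"
    attraction_scale: float = 3.0
    n_steps: int = 20000
    frame_stride: int = 100
    timestep_label: float = 0.001
    temperature: float = 300.0
    dielectric: float = 40.0
    debye_length: float = 10.0
    max_translation: float = 0.5
    max_rotation_deg: float = 10.0
    relocation_prob: float = 0.1
    min_separation: float = 12.0

    def __post_init__(self) -> None:
        if self.n_dye < 0 or self.n_counterion < 0:
            raise ValueError("molecule counts must be >= 0")
        if self.box_side <= 0:
            raise ValueError("box_side must be > 0")
        if self.counterion_mode not in COUNTERION_MODES:
            raise ValueError(
                f"counterion_mode must be one of {COUNTERION_MODES}, got {self.counterion_mode!r}"
            )
        if self.attraction_scale < 0:
            raise ValueError("attraction_scale must be >= 0")
        if self.n_steps < 0 or self.frame_stride < 1:
            raise ValueError("n_steps must be >= 0 and frame_stride >= 1")
        if not (0.0 <= self.relocation_prob <= 1.0):
            raise ValueError("relocation_prob must be in [0, 1]")

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class RigidDyeTemplate:
    """A rigid molecular template: names, elements, local coordinates, parameters."""

    residue_name: str
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray
    nonbonded: tuple[NonbondedAtom, ...]
    xanthene_atoms: tuple[str, ...] = ()
    long_axis_atoms: tuple[str, str] | None = None
    probe_atoms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float).reshape(-1, 3))
        n = len(self.atom_names)
        if not (len(self.elements) == len(self.coords) == len(self.nonbonded) == n):
            raise ValueError("template arrays must have equal length")
        if self.xanthene_atoms:
            idx = [self.atom_names.index(a) for a in self.xanthene_atoms]
            plane = self.coords[idx]
            centered = plane - plane.mean(axis=0)
            s = np.linalg.svd(centered, compute_uv=False)
            if s[2] > 1e-6:
                raise ValueError("xanthene atoms of the template are not planar")

    @property
    def net_charge(self) -> float:
        return float(sum(p.charge for p in self.nonbonded))

    def instantiate(
        self,
        position: Sequence[float],
        rotation: np.ndarray | None = None,
        residue_id: int = 1,
        molecule_id: int = -1,
    ) -> list[AtomRecord]:
        rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        coords = self.coords @ rot.T + np.asarray(position, dtype=float)
        return [
            AtomRecord(
                atom_name=self.atom_names[i],
                element=self.elements[i],
                coords=coords[i],
                residue_name=self.residue_name,
                residue_id=residue_id,
                molecule_id=molecule_id,
            )
            for i in range(len(self.atom_names))
        ]


def parameterized_molecule(
    template: RigidDyeTemplate,
    position: Sequence[float] = (0.0, 0.0, 0.0),
    rotation: np.ndarray | None = None,
) -> ParameterizedMolecule:
    """A template instance as a :class:`ParameterizedMolecule` for energetics."""
    rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    coords = template.coords @ rot.T + np.asarray(position, dtype=float)
    return ParameterizedMolecule(
        coords,
        [p.charge for p in template.nonbonded],
        [p.epsilon for p in template.nonbonded],
        [p.rmin_half for p in template.nonbonded],
        [p.scaled_subset for p in template.nonbonded],
    )


def default_dye_template() -> RigidDyeTemplate:
    """Planar xanthene-like dye stand-in: 17 in-plane atoms + 2 pendant carbons.

    The plane lies in z = 0 with the long axis along x; the two nitrogens
    cap the long axis and the four central ring-junction carbons (C3, C4,
    C9, C10) are the stack-probe atoms.  Net charge +1e; the in-plane
    atoms form the epsilon-scaled subset.
    """
    names: list[str] = []
    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    xs = [-3.5, -2.1, -0.7, 0.7, 2.1, 3.5]
    for i, x in enumerate(xs, start=1):  # C1..C6: top edge
        names.append(f"C{i}")
        elements.append("C")
        coords.append((x, 1.21, 0.0))
    for i, x in enumerate(xs, start=7):  # C7..C12: bottom edge
        names.append(f"C{i}")
        elements.append("C")
        coords.append((x, -1.21, 0.0))
    names += ["C13", "C14", "O1", "N1", "N2"]
    elements += ["C", "C", "O", "N", "N"]
    coords += [(-4.2, 0.0, 0.0), (4.2, 0.0, 0.0), (0.0, 0.0, 0.0),
               (-5.6, 0.0, 0.0), (5.6, 0.0, 0.0)]
    # pendant phenyl stub, out of plane, outside the scaled subset
    names += ["CP1", "CP2"]
    elements += ["C", "C"]
    coords += [(0.0, -2.0, 1.0), (0.0, -2.9, 2.1)]

    plane_atoms = tuple(names[:17])
    charge = {"N1": 0.4, "N2": 0.4, "O1": -0.2, "C13": 0.2, "C14": 0.2}
    eps = {"N": 0.17, "O": 0.21, "C": 0.086}
    rmin = {"N": 1.824, "O": 1.661, "C": 1.908}
    nb = tuple(
        NonbondedAtom(
            charge=charge.get(n, 0.0),
            epsilon=eps[e],
            rmin_half=rmin[e],
            scaled_subset=n in plane_atoms,
        )
        for n, e in zip(names, elements)
    )
    return RigidDyeTemplate(
        residue_name="RBD",
        atom_names=tuple(names),
        elements=tuple(elements),
        coords=np.array(coords),
        nonbonded=nb,
        xanthene_atoms=plane_atoms,
        long_axis_atoms=("N1", "N2"),
        probe_atoms=("C3", "C4", "C9", "C10"),
    )


def bulky_counterion_template() -> RigidDyeTemplate:
    """Bulky hydrophobic anion stand-in: central boron + 4 tetrahedral arms, -1e."""
    dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3.0)
    coords = np.vstack([[0.0, 0.0, 0.0], 2.6 * dirs])
    names = ("B1", "F1", "F2", "F3", "F4")
    elements = ("B", "F", "F", "F", "F")
    nb = tuple(
        NonbondedAtom(charge=-0.2, epsilon=0.1, rmin_half=2.0) for _ in names
    )
    return RigidDyeTemplate(
        residue_name="FTB", atom_names=names, elements=elements, coords=coords, nonbonded=nb
    )


def small_counterion_template() -> RigidDyeTemplate:
    """Small monatomic anion stand-in (iodide-like), -1e."""
    return RigidDyeTemplate(
        residue_name="IOD",
        atom_names=("I1",),
        elements=("I",),
        coords=np.zeros((1, 3)),
        nonbonded=(NonbondedAtom(charge=-1.0, epsilon=0.4, rmin_half=2.35),),
    )


def default_topology() -> SystemTopology:
    """Topology/role configuration matching the synthetic templates.

    The choice of the four stack-probe atoms is illustrative: the central
    ring-junction carbons of the scaffold (C3, C4, C9, C10), which probe
    the region above the middle ring where cofacial stacking is tightest.
    """
    dye = default_dye_template()
    return SystemTopology(
        role_map={"RBD": "dye", "FTB": "counterion", "IOD": "counterion",
                  "HOH": "solvent", "TIP3": "solvent", "WAT": "solvent"},
        xanthene_atoms=list(dye.xanthene_atoms),
        long_axis_atoms=dye.long_axis_atoms,
        stack_probe_atoms=list(dye.probe_atoms),
    )


def _rotz(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_planted_dimer(
    theta: float,
    alpha: float,
    rcc: float,
    plane_sep: float = 3.6,
    template: RigidDyeTemplate | None = None,
) -> Frame:
    """Two template copies planted at an exact dimer geometry.

    The two long axes are rotated by ``-theta/2`` and ``+theta/2`` about
    the common plane normal, so the inter-axis angle is ``theta`` and the
    sign-aligned mean axis is the laboratory x direction; the center-
    center vector is then ``(rcc cos(alpha), ry, plane_sep)`` with ``ry``
    fixed by ``|rCC| = rcc``.  Raises ``ValueError`` for infeasible
    combinations (``plane_sep`` exceeding ``rcc`` or ``rcc sin(alpha)``).
    """
    if not (0.0 <= theta <= 90.0) or not (0.0 <= alpha <= 90.0):
        raise ValueError("theta and alpha must lie in [0, 90] degrees")
    if rcc <= 0:
        raise ValueError("rcc must be > 0")
    if plane_sep < 0:
        raise ValueError("plane_sep must be >= 0")
    if plane_sep > rcc + 1e-9:
        raise ValueError(f"infeasible: plane_sep {plane_sep} exceeds rcc {rcc}")
    reach = rcc * np.sin(np.radians(alpha))
    if plane_sep > reach + 1e-9:
        raise ValueError(
            f"infeasible: plane_sep {plane_sep} exceeds rcc*sin(alpha) = {reach:.6f}"
        )
    template = template or default_dye_template()

    x = rcc * np.cos(np.radians(alpha))
    ry2 = rcc * rcc - x * x - plane_sep * plane_sep
    ry = float(np.sqrt(max(ry2, 0.0)))
    rcc_vec = np.array([x, ry, plane_sep])

    atoms = template.instantiate((0.0, 0.0, 0.0), _rotz(-theta / 2.0), residue_id=1)
    atoms += template.instantiate(rcc_vec, _rotz(+theta / 2.0), residue_id=2)
    assign_molecule_ids(atoms)
    return Frame(time=0.0, atoms=atoms, box=None)


# ---------------------------------------------------------------------------
# dispersed initial states


def _counterion_template(config: SyntheticConfig) -> RigidDyeTemplate:
    if config.counterion_mode == "bulky_hydrophobic":
        return bulky_counterion_template()
    return small_counterion_template()


def _random_unit_quats(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random rotations as xyzw quaternions (Shoemake's method)."""
    u1, u2, u3 = rng.random(n), rng.random(n), rng.random(n)
    a, b = np.sqrt(1 - u1), np.sqrt(u1)
    return np.stack(
        [a * np.sin(2 * np.pi * u2), a * np.cos(2 * np.pi * u2),
         b * np.sin(2 * np.pi * u3), b * np.cos(2 * np.pi * u3)], axis=1
    )


def _quat_multiply(q: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Hamilton product of xyzw quaternion stacks (rotation q applied after p)."""
    qx, qy, qz, qw = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    px, py, pz, pw = p[..., 0], p[..., 1], p[..., 2], p[..., 3]
    return np.stack(
        [
            qw * px + qx * pw + qy * pz - qz * py,
            qw * py - qx * pz + qy * pw + qz * px,
            qw * pz + qx * py - qy * px + qz * pw,
            qw * pw - qx * px - qy * py - qz * pz,
        ],
        axis=-1,
    )


def _dispersed_state(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random non-overlapping centers and orientations: dyes first, then ions."""
    n = config.n_dye + config.n_counterion
    box = np.full(3, config.box_side)
    sep = config.min_separation
    ion_sep = 6.0  # keep ions clear of everything at placement time
    packing = n * (4.0 / 3.0) * np.pi * (sep / 2.0) ** 3
    if packing >= box.prod():
        raise ValueError("infeasible packing density for the requested separation")

    positions = np.empty((n, 3))
    for i in range(n):
        # dyes are placed first and must stay `sep` apart from each other;
        # everything else only avoids hard overlap at `ion_sep`
        limit = np.full(i, ion_sep)
        if i < config.n_dye:
            limit[:] = sep
        for _ in range(20000):
            trial = rng.random(3) * box
            if i == 0:
                positions[0] = trial
                break
            d = positions[:i] - trial
            d -= box * np.round(d / box)
            if np.all((d * d).sum(axis=1) > limit * limit):
                positions[i] = trial
                break
        else:
            raise RuntimeError("rejection sampling failed to place all molecules")
    quats = _random_unit_quats(rng, n)
    return positions, quats


def _build_frame(
    positions: np.ndarray,
    quats: np.ndarray,
    config: SyntheticConfig,
    time: float,
) -> Frame:
    from scipy.spatial.transform import Rotation

    dye = default_dye_template()
    ion = _counterion_template(config)
    mats = Rotation.from_quat(quats).as_matrix()
    box = np.full(3, config.box_side)
    wrapped = np.mod(positions, box)
    atoms: list[AtomRecord] = []
    for i in range(config.n_dye):
        atoms += dye.instantiate(wrapped[i], mats[i], residue_id=i + 1)
    for j in range(config.n_counterion):
        i = config.n_dye + j
        atoms += ion.instantiate(wrapped[i], mats[i], residue_id=config.n_dye + j + 1)
    assign_molecule_ids(atoms)
    return Frame(time=time, atoms=atoms, box=box.copy())


def make_dispersed_frame(config: SyntheticConfig | None = None) -> Frame:
    """One frame of dispersed dyes and counterions in the periodic box.

    All dye-dye center distances exceed ``config.min_separation`` (default
    12 angstrom, comfortably above the 6 angstrom interacting cutoff).
    Reproducible: the same seed yields a bit-identical frame.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    positions, quats = _dispersed_state(config, rng)
    return _build_frame(positions, quats, config, time=0.0)


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo aggregation


def mc_site_parameters(config: SyntheticConfig) -> tuple[list[NonbondedAtom], np.ndarray]:
    """Coarse one-site-per-molecule parameters and the pairwise epsilon table.

    Dyes carry +1e; counterions -1e.  Same-type well depths follow the
    geometric combining rule; the dye-counterion well depth is overridden:
    ``attraction_scale`` in the bulky mode (floored at a 0.1 kcal/mol
    repulsive core), a bare 0.1 kcal/mol core otherwise.
    """
    bulky = config.counterion_mode == "bulky_hydrophobic"
    dye = NonbondedAtom(charge=1.0, epsilon=0.25, rmin_half=3.0)
    if bulky:
        ion = NonbondedAtom(charge=-1.0, epsilon=0.2, rmin_half=4.0)
        eps_cross = max(config.attraction_scale, 0.1)
    else:
        ion = NonbondedAtom(charge=-1.0, epsilon=0.1, rmin_half=1.5)
        eps_cross = 0.1
    sites = [dye] * config.n_dye + [ion] * config.n_counterion
    n = len(sites)
    eps = np.empty((n, n))
    is_dye = np.array([s.charge > 0 for s in sites])
    same = np.equal.outer(is_dye, is_dye)
    base = np.sqrt(np.outer([s.epsilon for s in sites], [s.epsilon for s in sites]))
    eps[:] = np.where(same, base, eps_cross)
    return sites, eps


def _pair_tables(config: SyntheticConfig):
    sites, eps = mc_site_parameters(config)
    q = np.array([s.charge for s in sites])
    rh = np.array([s.rmin_half for s in sites])
    qq = COULOMB_CONSTANT * np.outer(q, q) / config.dielectric
    rmin = rh[:, None] + rh[None, :]
    np.fill_diagonal(eps, 0.0)
    np.fill_diagonal(qq, 0.0)
    return qq, eps, rmin


def _site_energy(
    i: int,
    pos_i: np.ndarray,
    positions: np.ndarray,
    qq: np.ndarray,
    eps: np.ndarray,
    rmin: np.ndarray,
    box: np.ndarray,
    debye: float,
) -> float:
    d = positions - pos_i
    d -= box * np.round(d / box)
    r2 = (d * d).sum(axis=1)
    r2[i] = np.inf
    r = np.sqrt(r2)
    coulomb = qq[i] / r * np.exp(-r / debye)
    x = (rmin[i] * rmin[i] / r2) ** 3
    lj = eps[i] * (x * x - 2.0 * x)
    return float(coulomb.sum() + lj.sum())


def run_aggregation(config: SyntheticConfig | None = None) -> list[Frame]:
    """Rigid-body Metropolis MC trajectory of the dye/counterion box.

    Each sweep attempts one translation per molecule (a local step of at
    most ``max_translation`` angstrom or, with probability
    ``relocation_prob``, a box-uniform relocation that lets a desk-scale
    run cross the 85 angstrom box) plus a free orientational diffusion
    step of at most ``max_rotation_deg`` (coarse sites carry no torque).
    Frames are emitted every ``frame_stride`` sweeps with times
    ``sweep * timestep_label`` ns.  ``n_steps = 0`` returns the initial
    frame only.  Deterministic for a fixed configuration.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    positions, quats = _dispersed_state(config, rng)
    n = config.n_dye + config.n_counterion
    box = np.full(3, config.box_side)
    qq, eps, rmin = _pair_tables(config)
    kt = KB_KCAL * config.temperature
    max_rot = np.radians(config.max_rotation_deg)

    frames = [_build_frame(positions, quats, config, time=0.0)]
    for sweep in range(1, config.n_steps + 1):
        for i in range(n):
            if rng.random() < config.relocation_prob:
                trial = rng.random(3) * box
            else:
                trial = positions[i] + (rng.random(3) * 2.0 - 1.0) * config.max_translation
            de = _site_energy(i, trial, positions, qq, eps, rmin, box, config.debye_length) - \
                _site_energy(i, positions[i], positions, qq, eps, rmin, box, config.debye_length)
            if de <= 0.0 or rng.random() < np.exp(-de / kt):
                positions[i] = np.mod(trial, box)
        # orientational diffusion, energy-free for one-site molecules
        axes = rng.normal(size=(n, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        angles = rng.uniform(-max_rot, max_rot, size=n)
        dq = np.concatenate(
            [np.sin(angles / 2)[:, None] * axes, np.cos(angles / 2)[:, None]], axis=1
        )
        quats = _quat_multiply(dq, quats)
        quats /= np.linalg.norm(quats, axis=1, keepdims=True)
        if sweep % config.frame_stride == 0 or sweep == config.n_steps:
            frames.append(
                _build_frame(positions, quats, config, time=sweep * config.timestep_label)
            )
    return frames


# ---------------------------------------------------------------------------
# torsion fixture


def make_reference_torsion_profile() -> TorsionProfile:
    """Fixture reference scan: a periodic three-well profile on a 10-degree grid.

    Constructed from a cosine series inside the n <= 4 fitting basis
    (V1 = 0.6, V3 = 2.4 kcal/mol, phases 0) plus a small out-of-basis
    perturbation (0.025 cos 5phi + 0.015 cos 6phi, well under 0.05
    kcal/mol) standing in for the anharmonic content of a quantum scan.
    Wells sit near -60, 60 and 180 degrees.
    """
    angles = np.arange(-180.0, 180.0, 10.0)
    base = CosineSeries(terms=[(0.6, 1, 0.0), (2.4, 3, 0.0)]).evaluate(angles)
    phi = np.radians(angles)
    perturbation = 0.025 * np.cos(5 * phi) + 0.015 * np.cos(6 * phi)
    return TorsionProfile(angles=angles, energies=base + perturbation)


def zero_mm_profile(angles: np.ndarray | None = None) -> TorsionProfile:
    """A zero MM baseline on the fixture grid (torsion terms removed entirely)."""
    if angles is None:
        angles = np.arange(-180.0, 180.0, 10.0)
    return TorsionProfile(angles=np.asarray(angles, dtype=float), energies=np.zeros(len(angles)))
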