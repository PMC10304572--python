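"""Rigid two-molecule nonbonded energies and the dimer approach PES.

The interaction of two rigid molecules is the pairwise sum of a Coulomb
term and a 12-6 Lennard-Jones term in the AMBER ``Rmin``/``epsilon``
convention with the standard combining rules (geometric mean for
``epsilon``, additive ``Rmin/2``)::

    E = sum_ij  k_C q_i q_j / r_ij
              + eps_ij [ (Rmin_ij / r_ij)^12 - 2 (Rmin_ij / r_ij)^6 ]

with ``k_C = 332.0636 kcal A / (mol e^2)``.  Energies are kcal/mol,
distances angstrom, charges elementary charges.  The default contract is
vacuum electrostatics (dielectric 1, no cutoffs); the optional
``dielectric``, ``debye_length`` and ``box`` keywords add a uniform
relative permittivity, Debye screening ``exp(-r/lambda)`` and a periodic
minimum-image convention for use as an implicit-solvent toy Hamiltonian.

A subset of atoms (the xanthene moiety in the intended use) can have its
LJ well depths scaled: ``scale_factor`` multiplies ``eps_ij`` when both
partners are members of the subset.  Doubling these epsilons is the
correction that brings a GAFF-level stacked-dimer well into agreement
with a dispersion-corrected DFT reference; only ``epsilon`` is touched,
never ``Rmin`` or the charges.  An alternative per-atom ``sqrt(s)``
convention is available behind a flag.

The approach PES is reported relative to a far-separated reference,
``dE(rCC) = E(rCC) - E(reference)``, with the reference at 40 angstrom
by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "COULOMB_CONSTANT",
    "NonbondedAtom",
    "ParameterizedMolecule",
    "PesScan",
    "pair_energy",
    "scan_pes",
    "fit_scale_factor",
    "sigma_to_rmin_half",
]

COULOMB_CONSTANT = 332.0636
"""Coulomb prefactor in kcal*angstrom/(mol*e^2)."""

_OVERLAP_R = 0.1


@dataclass(frozen=True)
class NonbondedAtom:
    """Per-atom nonbonded parameters.

    ``scaled_subset`` marks membership of the epsilon-scaled set (the
    xanthene atoms in the intended use).
    """

    charge: float
    epsilon: float
    rmin_half: float
    scaled_subset: bool = False

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.rmin_half <= 0:
            raise ValueError("rmin_half must be > 0")


def sigma_to_rmin_half(sigma: float) -> float:
    """Convert a sigma-form LJ size parameter to ``Rmin/2 = 2^(1/6) sigma / 2``."""
    return 2.0 ** (1.0 / 6.0) * sigma / 2.0


class ParameterizedMolecule:
    """Coordinates plus nonbonded parameters, as flat arrays.

    Constructed from a list of ``(coords, NonbondedAtom)`` pairs (the
    operation-level interface) or directly from arrays.
    """

    def __init__(
        self,
        coords: np.ndarray,
        charge: np.ndarray,
        epsilon: np.ndarray,
        rmin_half: np.ndarray,
        scaled: np.ndarray,
    ):
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        self.charge = np.asarray(charge, dtype=float).reshape(n)
        self.epsilon = np.asarray(epsilon, dtype=float).reshape(n)
        self.rmin_half = np.asarray(rmin_half, dtype=float).reshape(n)
        self.scaled = np.asarray(scaled, dtype=bool).reshape(n)
        if np.any(self.epsilon < 0) or np.any(self.rmin_half <= 0):
            raise ValueError("epsilon must be >= 0 and rmin_half > 0")

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[Sequence[float], NonbondedAtom]]
    ) -> "ParameterizedMolecule":
        pairs = list(pairs)
        if not pairs:
            raise ValueError("molecule needs at least one atom")
        coords = np.array([p[0] for p in pairs], dtype=float)
        return cls(
            coords,
            [p[1].charge for p in pairs],
            [p[1].epsilon for p in pairs],
            [p[1].rmin_half for p in pairs],
            [p[1].scaled_subset for p in pairs],
        )

    def translated(self, shift: np.ndarray) -> "ParameterizedMolecule":
        return ParameterizedMolecule(
            self.coords + np.asarray(shift, dtype=float),
            self.charge,
            self.epsilon,
            self.rmin_half,
            self.scaled,
        )

    def center(self) -> np.ndarray:
        """Centroid of the scaled subset if non-empty, else of all atoms."""
        if self.scaled.any():
            return self.coords[self.scaled].mean(axis=0)
        return self.coords.mean(axis=0)

    def __len__(self) -> int:
        return len(self.coords)


Moleculelike = "ParameterizedMolecule | Iterable[tuple[Sequence[float], NonbondedAtom]]"


def _coerce(mol) -> ParameterizedMolecule:
    if isinstance(mol, ParameterizedMolecule):
        return mol
    return ParameterizedMolecule.from_pairs(mol)


def pair_energy(
    molA,
    molB,
    scale_factor: float = 1.0,
    *,
    box: np.ndarray | None = None,
    dielectric: float = 1.0,
    debye_length: float | None = None,
    per_atom_sqrt_scaling: bool = False,
) -> float:
    """Intermolecular Coulomb + Lennard-Jones energy of two rigid molecules.

    ``scale_factor`` multiplies ``eps_ij`` for atom pairs whose members are
    both in the scaled subset (default convention), or contributes
    ``sqrt(scale_factor)`` per member atom when ``per_atom_sqrt_scaling``
    is set.  Raises ``ValueError`` on coincident atoms.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be > 0")
    a = _coerce(molA)
    b = _coerce(molB)
    diff = b.coords[None, :, :] - a.coords[:, None, :]
    if box is not None:
        box = np.asarray(box, dtype=float).reshape(3)
        diff = diff - box * np.round(diff / box)
    r = np.sqrt((diff * diff).sum(axis=-1))
    if np.any(r < 1e-12):
        raise ValueError("coincident atoms: zero interatomic distance")

    coulomb = COULOMB_CONSTANT * np.outer(a.charge, b.charge) / (dielectric * r)
    if debye_length is not None:
        coulomb = coulomb * np.exp(-r / debye_length)

    eps = np.sqrt(np.outer(a.epsilon, b.epsilon))
    if per_atom_sqrt_scaling:
        root = np.sqrt(scale_factor)
        factor = np.outer(
            np.where(a.scaled, root, 1.0), np.where(b.scaled, root, 1.0)
        )
    else:
        factor = np.where(np.outer(a.scaled, b.scaled), scale_factor, 1.0)
    x = (( (a.rmin_half[:, None] + b.rmin_half[None, :]) / r) ** 6)
    lj = factor * eps * (x * x - 2.0 * x)
    return float(coulomb.sum() + lj.sum())


@dataclass
class PesScan:
    """A rigid approach scan: distances, relative energies and well summary.

    ``delta_e`` is relative to the energy at ``reference_distance``;
    ``well_depth`` is the minimum of ``delta_e``, ``r_min_location`` its
    distance, and ``barrier_height`` the maximum of ``delta_e`` outward of
    the minimum (the Coulomb barrier two like-charged dyes must overcome
    before the van der Waals well captures them).
    """

    distances: np.ndarray
    delta_e: np.ndarray
    reference_distance: float
    well_depth: float = field(init=False)
    barrier_height: float = field(init=False)
    r_min_location: float = field(init=False)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.delta_e = np.asarray(self.delta_e, dtype=float)
        if self.distances.shape != self.delta_e.shape:
            raise ValueError("distances and delta_e must have equal length")
        imin = int(np.argmin(self.delta_e))
        self.well_depth = float(self.delta_e[imin])
        self.r_min_location = float(self.distances[imin])
        outward = self.delta_e[self.distances >= self.r_min_location]
        self.barrier_height = float(outward.max())

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"distance_A": self.distances, "delta_e_kcal": self.delta_e}
        ).to_csv(path, index=False)


def scan_pes(
    molA,
    molB,
    approach_axis: Sequence[float],
    distances: Sequence[float],
    scale_factor: float = 1.0,
    reference_distance: float = 40.0,
    **energy_kwargs,
) -> PesScan:
    """Rigid approach scan of molecule B along an axis from molecule A.

    Both monomer geometries are held fixed; B is rigidly translated so the
    (xanthene) center separation equals each requested distance.  Raises
    ``ValueError`` for unsorted/non-positive distances or steric overlap
    (any interatomic distance below 0.1 angstrom) at a scan point.
    """
    a = _coerce(molA)
    b = _coerce(molB)
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0 or np.any(distances <= 0):
        raise ValueError("distances must be positive")
    if np.any(np.diff(distances) <= 0):
        raise ValueError("distances must be strictly increasing")
    axis = np.asarray(approach_axis, dtype=float).reshape(3)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("approach_axis must be a nonzero vector")
    axis = axis / norm

    center_a = a.center()
    offset_b = b.center()

    def energy_at(d: float) -> float:
        target = center_a + axis * d
        shifted = b.translated(target - offset_b)
        dmin = np.sqrt(
            ((shifted.coords[None, :, :] - a.coords[:, None, :]) ** 2).sum(-1)
        ).min()
        if dmin < _OVERLAP_R:
            raise ValueError(
                f"steric overlap at scan distance {d:.3f} A (closest contact {dmin:.3f} A)"
            )
        return pair_energy(a, shifted, scale_factor, **energy_kwargs)

    e_ref = energy_at(float(reference_distance))
    delta = np.array([energy_at(float(d)) for d in distances]) - e_ref
    return PesScan(distances=distances, delta_e=delta, reference_distance=float(reference_distance))


def fit_scale_factor(
    reference_pes: PesScan,
    molA,
    molB,
    approach_axis: Sequence[float],
    bounds: tuple[float, float] = (0.5, 5.0),
    **energy_kwargs,
) -> float:
    """Epsilon scale factor that best reproduces a reference approach PES.

    Minimizes the squared ``delta_e`` deviation over the reference scan grid
    by bounded 1-D minimization.  The reference must have a well (a minimum
    below zero); a purely repulsive reference raises ``ValueError``.
    """
    if float(np.min(reference_pes.delta_e)) >= 0:
        raise ValueError("reference PES has no well: nothing to fit the scale factor to")

    def objective(s: float) -> float:
        scan = scan_pes(
            molA,
            molB,
            approach_axis,
            reference_pes.distances,
            scale_factor=s,
            reference_distance=reference_pes.reference_distance,
            **energy_kwargs,
        )
        return float(np.sum((scan.delta_e - reference_pes.delta_e) ** 2))

    res = minimize_scalar(
        objective, bounds=bounds, method="bounded", options={"xatol": 1e-4}
    )
    return float(res.x)
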