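"""Cosine-series dihedral refitting against a reference torsion scan.

Force-field dihedrals use the AMBER functional form

    V(phi) = offset + sum_n (V_n / 2) (1 + cos(n phi - gamma_n)),

with phases restricted to {0, 180} degrees so the fit stays linear (the
GAFF convention).  Given a reference potential profile (typically a
quantum-chemical constrained scan on a 10-degree grid) and the molecular-
mechanics profile computed *without* the torsion terms being fitted, the
residual is expanded in the cosine basis {1, cos(n phi)} for n = 1..max_n
by linear least squares; a negative coefficient maps to gamma = 180.

The convergence criterion follows standard refitting practice for these
dyes: the fitted MM profile must match the reference within 0.2 kcal/mol
in the region of the minima, where the thermally populated conformers
live.  A "minima region" is every grid interval within ``depth_window``
(default 1.0 kcal/mol) of a local minimum of the reference, detected on
the periodic continuation of the profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TorsionProfile",
    "CosineSeries",
    "FitReport",
    "find_minima_regions",
    "fit_torsion",
]


@dataclass
class TorsionProfile:
    """A dihedral scan: an increasing angle grid (deg) and energies (kcal/mol).

    Energies are min-shifted to zero on construction.  The grid must span
    at least 180 degrees.
    """

    angles: np.ndarray
    energies: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.angles.ndim != 1 or self.angles.shape != self.energies.shape:
            raise ValueError("angles and energies must be equal-length 1-D arrays")
        if self.angles.size < 2 or np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.angles[-1] - self.angles[0] < 180 - 1e-9:
            raise ValueError("angle grid must span at least 180 degrees")
        self.energies = self.energies - self.energies.min()

    @property
    def is_periodic(self) -> bool:
        """True when the grid covers a full period (next point would wrap)."""
        step = float(np.median(np.diff(self.angles)))
        return abs((self.angles[-1] - self.angles[0]) + step - 360.0) < 1e-6

    @classmethod
    def from_csv(cls, path) -> "TorsionProfile":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(angles=data[:, 0], energies=data[:, 1])

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("angle_deg,energy_kcal\n")
            for a, e in zip(self.angles, self.energies):
                fh.write(f"{a:.6f},{e:.8f}\n")


@dataclass
class CosineSeries:
    """Fitted dihedral terms ``(V_n, n, gamma_n)`` plus a constant offset."""

    terms: list[tuple[float, int, float]]
    offset: float = 0.0

    def __post_init__(self) -> None:
        ns = [n for _, n, _ in self.terms]
        if len(set(ns)) != len(ns):
            raise ValueError("multiplicities n must be distinct")
        for v, n, g in self.terms:
            if n < 1:
                raise ValueError("multiplicity n must be >= 1")
            if g not in (0.0, 180.0):
                raise ValueError("phases are restricted to 0 or 180 degrees")

    def evaluate(self, angles_deg: Sequence[float]) -> np.ndarray:
        phi = np.radians(np.asarray(angles_deg, dtype=float))
        out = np.full_like(phi, self.offset, dtype=float)
        for v, n, g in self.terms:
            out += (v / 2.0) * (1.0 + np.cos(n * phi - np.radians(g)))
        return out

    def to_frcmod_text(self, name: str = "X -X -X -X") -> str:
        """AMBER-flavored DIHE block (documented layout, not bit-exact AMBER)."""
        lines = ["DIHE"]
        for v, n, g in self.terms:
            lines.append(f"{name}    1  {v / 1.0:10.5f}  {g:8.2f}  {float(n):6.1f}")
        lines.append(f"# constant offset {self.offset:.5f} kcal/mol (not an AMBER term)")
        return "\n".join(lines)


@dataclass
class FitReport:
    """Outcome of a torsion refit: the series, deviations and convergence."""

    series: CosineSeries
    max_dev_minima: float
    max_dev_global: float
    minima_regions: list[tuple[float, float]]
    converged: bool
    tolerance: float

    def to_dict(self) -> dict:
        return {
            "terms": [
                {"V_n_kcal": v, "n": n, "gamma_deg": g} for v, n, g in self.series.terms
            ],
            "offset_kcal": self.series.offset,
            "max_dev_minima_kcal": self.max_dev_minima,
            "max_dev_global_kcal": self.max_dev_global,
            "minima_regions_deg": [list(r) for r in self.minima_regions],
            "converged": self.converged,
            "tolerance_kcal": self.tolerance,
        }


def _minima_mask(profile: TorsionProfile, depth_window: float) -> np.ndarray:
    e = profile.energies
    n = e.size
    if e.max() - e.min() < 1e-6:  # flat profile: one region covering everything
        return np.ones(n, dtype=bool)
    periodic = profile.is_periodic

    if periodic:
        left = np.roll(e, 1)
        right = np.roll(e, -1)
        minima = np.flatnonzero((e <= left) & (e <= right))
    else:
        interior = np.arange(1, n - 1)
        minima = interior[(e[interior] <= e[interior - 1]) & (e[interior] <= e[interior + 1])]
        if minima.size == 0:
            raise ValueError(
                "profile is monotone over a non-periodic span: no interior minimum"
            )

    mask = np.zeros(n, dtype=bool)
    for i in minima:
        limit = e[i] + depth_window
        mask[i] = True
        j = i
        while True:  # expand right
            nxt = (j + 1) % n if periodic else j + 1
            if (not periodic and nxt >= n) or nxt == i:
                break
            if e[nxt] <= limit:
                mask[nxt] = True
                j = nxt
            else:
                break
        j = i
        while True:  # expand left
            prv = (j - 1) % n if periodic else j - 1
            if (not periodic and prv < 0) or prv == i:
                break
            if e[prv] <= limit:
                mask[prv] = True
                j = prv
            else:
                break
    return mask


def _mask_to_intervals(profile: TorsionProfile, mask: np.ndarray) -> list[tuple[float, float]]:
    angles = profile.angles
    n = mask.size
    if mask.all():
        return [(float(angles[0]), float(angles[-1]))]
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    # merge a run touching both ends of a periodic grid into a wrapped pair
    return [(float(angles[i]), float(angles[j])) for i, j in runs]


def find_minima_regions(
    profile: TorsionProfile, depth_window: float = 1.0
) -> list[tuple[float, float]]:
    """Angle intervals within ``depth_window`` kcal/mol of each local minimum.

    Minima are detected on the periodic continuation when the grid covers a
    full period; a monotone non-periodic profile (no interior minimum)
    raises ``ValueError``.  A flat profile yields one region covering all
    angles.
    """
    return _mask_to_intervals(profile, _minima_mask(profile, depth_window))


def fit_torsion(
    reference: TorsionProfile,
    mm_without_torsion: TorsionProfile,
    max_n: int = 4,
    tolerance: float = 0.2,
    depth_window: float = 1.0,
) -> FitReport:
    """Least-squares cosine-series fit of the (reference - MM) residual.

    Both profiles must share the same angle grid.  The fitted series added
    to ``mm_without_torsion`` is compared against the reference; the
    maximum absolute deviation inside the reference's minima regions
    decides convergence at ``tolerance`` (kcal/mol).
    """
    if reference.angles.shape != mm_without_torsion.angles.shape or not np.allclose(
        reference.angles, mm_without_torsion.angles
    ):
        raise ValueError("reference and MM profiles must share the same angle grid")
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    phi = np.radians(reference.angles)
    if phi.size < max_n + 1:
        raise ValueError(
            f"{phi.size} grid points cannot determine {max_n + 1} basis coefficients"
        )

    y = reference.energies - mm_without_torsion.energies
    basis = np.column_stack([np.ones_like(phi)] + [np.cos(n * phi) for n in range(1, max_n + 1)])
    if np.linalg.matrix_rank(basis) < basis.shape[1]:
        raise ValueError("rank-deficient cosine basis on this angle grid")
    coeffs, *_ = np.linalg.lstsq(basis, y, rcond=None)

    terms: list[tuple[float, int, float]] = []
    half_sum = 0.0
    for n in range(1, max_n + 1):
        c = float(coeffs[n])
        if abs(c) < 1e-12:
            continue
        gamma = 0.0 if c >= 0 else 180.0
        v = 2.0 * abs(c)
        terms.append((v, n, gamma))
        half_sum += v / 2.0
    series = CosineSeries(terms=terms, offset=float(coeffs[0]) - half_sum)

    residual = y - basis @ coeffs
    mask = _minima_mask(reference, depth_window)
    max_dev_global = float(np.max(np.abs(residual)))
    max_dev_minima = float(np.max(np.abs(residual[mask])))
    return FitReport(
        series=series,
        max_dev_minima=max_dev_minima,
        max_dev_global=max_dev_global,
        minima_regions=_mask_to_intervals(reference, mask),
        converged=max_dev_minima <= tolerance,
        tolerance=tolerance,
    )
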