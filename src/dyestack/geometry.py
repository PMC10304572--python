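"""Per-molecule chromophore frames and pairwise dimer geometry.

The xanthene core of a rhodamine-type dye is planar, and the transition
dipole moment lies in that plane along its long axis.  Each dye therefore
gets a local orthonormal frame: ``x`` along the long axis (the dipole
proxy), ``z`` normal to the least-squares plane of the xanthene atoms, and
``y`` completing a right-handed triad.  Dimer geometry is expressed in
these frames: the center-center vector ``rCC`` between xanthene centroids
(minimum image when a box is present), its in-frame components
``(rx, ry, rz)``, the inter-axis angle ``theta``, the center-line angle
``alpha`` and the distances of each molecule's four stack-probe atoms from
the partner's plane.

``theta`` and ``alpha`` are folded into [0, 90] degrees because molecular
axes (and transition dipoles) are directionless.  ``alpha`` is measured
against the sign-aligned mean of the two long axes; it is only
interpreted for near-parallel pairs, where the two per-molecule choices
nearly coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .trajio import AtomRecord, SystemTopology

__all__ = ["MoleculeFrame", "DimerGeometry", "compute_frame", "dimer_geometry"]

_DEGENERACY_TOL = 1e-10


@dataclass
class MoleculeFrame:
    """Centroid and orthonormal axes of one xanthene plane.

    ``probe_coords`` holds the Cartesian positions of the four stack-probe
    atoms so dimer geometry can evaluate plane distances without going back
    to the raw frame.
    """

    center: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    probe_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("center", "x_axis", "y_axis", "z_axis"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        if self.probe_coords is not None:
            self.probe_coords = np.asarray(self.probe_coords, dtype=float).reshape(-1, 3)
        axes = np.stack([self.x_axis, self.y_axis, self.z_axis])
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-8):
            raise ValueError("frame axes are not orthonormal")
        if not np.allclose(np.cross(self.x_axis, self.y_axis), self.z_axis, atol=1e-8):
            raise ValueError("frame axes are not right-handed (z != x cross y)")


@dataclass
class DimerGeometry:
    """Pairwise geometry of two chromophore frames.

    ``components`` is a (2, 3) array: row 0 holds ``(|rCC.x|, |rCC.y|,
    |rCC.z|)`` evaluated in molecule A's frame, row 1 the same in molecule
    B's frame.  ``probe_plane_dists`` is (2, 4): row 0 the distances of A's
    probe atoms from B's plane, row 1 of B's probes from A's plane.  The
    scalar ``rx``/``ry``/``rz`` convenience properties report row 0.
    """

    rcc_vec: np.ndarray
    rcc: float
    theta: float
    alpha: float
    components: np.ndarray
    probe_plane_dists: np.ndarray | None = None

    @property
    def rx(self) -> float:
        return float(self.components[0, 0])

    @property
    def ry(self) -> float:
        return float(self.components[0, 1])

    @property
    def rz(self) -> float:
        return float(self.components[0, 2])


def _atom_lookup(atoms: Sequence[AtomRecord]) -> Mapping[str, np.ndarray]:
    table: dict[str, np.ndarray] = {}
    for a in atoms:
        table.setdefault(a.atom_name, a.coords)
    return table


def compute_frame(dye_atoms: Sequence[AtomRecord], topology: SystemTopology) -> MoleculeFrame:
    """Build the local chromophore frame of one dye molecule.

    The plane normal is the smallest-singular-value direction of the
    centered xanthene coordinates; the long axis is the vector between the
    two ``long_axis_atoms``, projected into the plane.  Raises
    ``ValueError`` on missing atoms or degenerate (collinear) geometry.
    """
    table = _atom_lookup(dye_atoms)
    missing = [n for n in topology.xanthene_atoms if n not in table]
    missing += [n for n in topology.long_axis_atoms if n not in table]
    if missing:
        raise ValueError(f"dye molecule is missing named atoms: {sorted(set(missing))}")

    coords = np.array([table[n] for n in topology.xanthene_atoms])
    center = coords.mean(axis=0)
    centered = coords - center
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] - s[2] < _DEGENERACY_TOL:
        raise ValueError("xanthene atoms are collinear or otherwise degenerate: no unique plane")
    z = vt[2]
    # deterministic sign: largest-magnitude component positive
    k = int(np.argmax(np.abs(z)))
    if z[k] < 0:
        z = -z

    a, b = topology.long_axis_atoms
    raw = table[b] - table[a]
    in_plane = raw - (raw @ z) * z
    norm = np.linalg.norm(in_plane)
    if norm < 1e-8:
        raise ValueError("long-axis vector is perpendicular to the plane or zero")
    x = in_plane / norm
    y = np.cross(z, x)

    probes = np.array([table[n] for n in topology.stack_probe_atoms])
    return MoleculeFrame(center=center, x_axis=x, y_axis=y, z_axis=z, probe_coords=probes)


def _minimum_image(vec: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return vec
    return vec - box * np.round(vec / box)


def _folded_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = abs(float(u @ v)) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dimer_geometry(
    frameA: MoleculeFrame,
    frameB: MoleculeFrame,
    box: np.ndarray | None = None,
) -> DimerGeometry:
    """Geometry of the (A, B) chromophore pair.

    ``rcc_vec`` is center(B) - center(A) under the minimum-image convention
    when ``box`` is given; probe coordinates are shifted consistently so a
    whole molecule is imaged, never split.  Raises ``ValueError`` for
    coincident centers (``alpha`` undefined).
    """
    if box is not None:
        box = np.asarray(box, dtype=float).reshape(3)
    d_raw = frameB.center - frameA.center
    d = _minimum_image(d_raw, box)
    shift = d - d_raw
    rcc = float(np.linalg.norm(d))
    if rcc < 1e-9:
        raise ValueError("coincident centers: alpha is undefined at rcc = 0")

    theta = _folded_angle_deg(frameA.x_axis, frameB.x_axis)
    sign = 1.0 if float(frameA.x_axis @ frameB.x_axis) >= 0 else -1.0
    mean_axis = frameA.x_axis + sign * frameB.x_axis
    if np.linalg.norm(mean_axis) < 1e-9:  # exactly perpendicular axes
        mean_axis = frameA.x_axis
    alpha = _folded_angle_deg(d, mean_axis)

    comp_a = np.abs(d @ np.stack([frameA.x_axis, frameA.y_axis, frameA.z_axis]).T)
    comp_b = np.abs(d @ np.stack([frameB.x_axis, frameB.y_axis, frameB.z_axis]).T)
    components = np.stack([comp_a, comp_b])

    dists = None
    if frameA.probe_coords is not None and frameB.probe_coords is not None:
        center_b = frameA.center + d  # B's center imaged next to A
        probes_b = frameB.probe_coords + shift
        dists_a = np.abs((frameA.probe_coords - center_b) @ frameB.z_axis)
        dists_b = np.abs((probes_b - frameA.center) @ frameA.z_axis)
        dists = np.stack([dists_a, dists_b])

    return DimerGeometry(
        rcc_vec=d,
        rcc=rcc,
        theta=theta,
        alpha=alpha,
        components=components,
        probe_plane_dists=dists,
    )
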