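"""Dimer classification: interacting / H / J / crossed-J and pi-stacking.

A dye pair is *interacting* when the center-center distance between the
two xanthene planes falls below a cutoff (default 6 angstrom, a distance
at which the stacked-dimer interaction is already attractive and which
excludes counterion-bridged pairs).  Interacting pairs are classified by
the folded angle ``theta`` between the long axes: parallel dimers
(theta below 12 degrees) are split into H (alpha above the magic angle,
54.7 degrees = arccos(1/sqrt(3))) and J (alpha below it); rotated pairs
are crossed-J.  H dimers quench fluorescence; J dimers are typically
emissive; the magic angle is where the excitonic coupling changes sign.

Pi-stacking is a separate flag: the lateral offsets of the center-center
vector must stay within the hexagon-scale cutoffs (rx < 4, ry < 2
angstrom by default) and all four stack-probe atoms of one molecule must
lie within 4.5 angstrom of the partner's plane.  Both molecule orderings
are tested and OR-combined.

Boundary values are resolved with the intervals closed on the lower
side: theta equal to the cutoff is crossed-J, alpha equal to the magic
angle is J, and rcc equal to the cutoff is non-interacting.  The
classification thresholds are all configurable in one record.

Note on the rx cutoff: one published statement of the lateral criterion
gives "within 5 and 2 angstrom" while the figure-level definition ties
rx < 4 angstrom to the hexagon dimensions of the xanthene plane.  The
default here is 4.0; pass ``stack_rx_cut=5.0`` to use the looser value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .geometry import DimerGeometry, compute_frame, dimer_geometry
from .trajio import Frame, SystemTopology, group_molecules

__all__ = [
    "GEOMETRY_CLASSES",
    "ClassificationThresholds",
    "DimerLabel",
    "classify_dimer",
    "is_stacked",
    "classify_frame",
]

GEOMETRY_CLASSES = ("H", "J", "crossed_J", "none")


@dataclass(frozen=True)
class ClassificationThresholds:
    """All geometric cutoffs of the dimer classifier, in one record.

    Units: distances in angstrom, angles in degrees.
    """

    rcc_cut: float = 6.0
    theta_cut: float = 12.0
    alpha_magic: float = 54.7
    stack_rx_cut: float = 4.0
    stack_ry_cut: float = 2.0
    stack_plane_cut: float = 4.5

    def __post_init__(self) -> None:
        for name in (
            "rcc_cut",
            "theta_cut",
            "alpha_magic",
            "stack_rx_cut",
            "stack_ry_cut",
            "stack_plane_cut",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.alpha_magic >= 90:
            raise ValueError("alpha_magic must be < 90 degrees")


@dataclass
class DimerLabel:
    """Classification outcome for one unordered dye pair."""

    pair: tuple[int, int]
    interacting: bool
    geometry_class: str
    stacked: bool

    def __post_init__(self) -> None:
        if self.geometry_class not in GEOMETRY_CLASSES:
            raise ValueError(f"unknown geometry class {self.geometry_class!r}")
        if self.geometry_class != "none" and not self.interacting:
            raise ValueError("a classified dimer must be interacting")
        if self.stacked and not self.interacting:
            raise ValueError("a stacked dimer must be interacting")


def is_stacked(g: DimerGeometry, t: ClassificationThresholds | None = None) -> bool:
    """Pi-stacking test, evaluated in both molecule orderings and OR-combined.

    Ordering ``m`` describes the partner relative to molecule m's plane:
    the lateral components of the center-center vector in m's frame must
    stay within the hexagon cutoffs AND all four probe atoms of the
    *partner* must lie within the plane cutoff of m's plane.  Pairing both
    sub-criteria to the same plane owner is what correctly rejects
    T-shaped (perpendicular-plane) contacts, whose flat partner would
    otherwise sit trivially close to the upright plane.
    """
    t = t or ClassificationThresholds()
    if g.probe_plane_dists is None:
        raise ValueError("geometry carries no probe-plane distances; stacking undefined")
    for m in (0, 1):
        rx, ry = g.components[m, 0], g.components[m, 1]
        partner_probe_dists = g.probe_plane_dists[1 - m]  # partner's probes onto m's plane
        if (
            rx < t.stack_rx_cut
            and ry < t.stack_ry_cut
            and bool((partner_probe_dists < t.stack_plane_cut).all())
        ):
            return True
    return False


def classify_dimer(
    g: DimerGeometry,
    t: ClassificationThresholds | None = None,
    pair: tuple[int, int] = (0, 1),
) -> DimerLabel:
    """Label one dimer geometry: interacting flag, H/J/crossed-J class, stacking."""
    t = t or ClassificationThresholds()
    interacting = g.rcc < t.rcc_cut
    if not interacting:
        return DimerLabel(pair=pair, interacting=False, geometry_class="none", stacked=False)
    if g.theta >= t.theta_cut:
        cls = "crossed_J"
    elif g.alpha > t.alpha_magic:
        cls = "H"
    else:
        cls = "J"
    stacked = g.probe_plane_dists is not None and is_stacked(g, t)
    return DimerLabel(pair=pair, interacting=True, geometry_class=cls, stacked=stacked)


def classify_frame(
    frame: Frame,
    topology: SystemTopology,
    t: ClassificationThresholds | None = None,
) -> list[DimerLabel]:
    """Classify every unordered dye pair of one frame.

    Returns one label per pair, sorted by molecule-id pair; an empty list
    when the frame holds fewer than two dyes.
    """
    t = t or ClassificationThresholds()
    dyes = [
        (mol_id, atoms)
        for mol_id, resname, atoms in group_molecules(frame)
        if topology.role_of(resname) == "dye"
    ]
    if len(dyes) < 2:
        return []
    frames = {mol_id: compute_frame(atoms, topology) for mol_id, atoms in dyes}
    labels = []
    for a, b in combinations(sorted(frames), 2):
        g = dimer_geometry(frames[a], frames[b], frame.box)
        labels.append(classify_dimer(g, t, pair=(a, b)))
    return labels
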