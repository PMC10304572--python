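import numpy as np
import pytest

from dyestack.classify import (
    ClassificationThresholds,
    classify_dimer,
    classify_frame,
    is_stacked,
)
from dyestack.geometry import DimerGeometry, compute_frame, dimer_geometry
from dyestack.synthetic import SyntheticConfig, make_dispersed_frame, make_planted_dimer
from dyestack.trajio import Frame, assign_molecule_ids

from oracles import oracle_classify_frame


def geometry(theta=0.0, alpha=90.0, rcc=4.0, probe=None):
    """Hand-built DimerGeometry with exact angle/distance values."""
    vec = np.array([rcc, 0.0, 0.0])
    comp = np.zeros((2, 3))
    comp[:, 0] = rcc
    return DimerGeometry(
        rcc_vec=vec,
        rcc=rcc,
        theta=theta,
        alpha=alpha,
        components=comp,
        probe_plane_dists=probe,
    )


class TestClassifyDimer:
    @pytest.mark.parametrize(
        "theta,alpha,rcc,expected",
        [
            (5.0, 75.0, 4.0, "H"),
            (5.0, 30.0, 4.0, "J"),
            (40.0, 50.0, 5.5, "crossed_J"),
        ],
    )
    def test_reference_assignments(self, theta, alpha, rcc, expected):
        label = classify_dimer(geometry(theta, alpha, rcc))
        assert label.interacting
        assert label.geometry_class == expected

    def test_beyond_cutoff_is_non_interacting(self):
        label = classify_dimer(geometry(5.0, 75.0, 6.5))
        assert not label.interacting
        assert label.geometry_class == "none"
        assert not label.stacked

    @pytest.mark.parametrize(
        "theta,alpha,rcc,expected_class,expected_interacting",
        [
            (12.0, 70.0, 4.0, "crossed_J", True),  # theta boundary closes into crossed-J
            (0.0, 54.7, 4.0, "J", True),  # magic-angle boundary closes into J
            (0.0, 90.0, 6.0, "none", False),  # rcc boundary is non-interacting
        ],
    )
    def test_boundary_tie_breaks(self, theta, alpha, rcc, expected_class, expected_interacting):
        label = classify_dimer(geometry(theta, alpha, rcc))
        assert label.interacting is expected_interacting
        assert label.geometry_class == expected_class


class TestIsStacked:
    def planted_geometry(self, topology, **kwargs):
        frame = make_planted_dimer(**kwargs)
        mols = {}
        for a in frame.atoms:
            mols.setdefault(a.molecule_id, []).append(a)
        fa, fb = (compute_frame(atoms, topology) for _, atoms in sorted(mols.items()))
        return dimer_geometry(fa, fb)

    def test_cofacial_contact_is_stacked(self, topology):
        g = self.planted_geometry(topology, theta=0.0, alpha=90.0, rcc=3.6, plane_sep=3.6)
        assert is_stacked(g)

    def test_lateral_offset_beyond_ry_cut_is_not_stacked(self, topology):
        # zero x offset, ry = 2.5, plane separation 3.6
        rcc = float(np.hypot(2.5, 3.6))
        g = self.planted_geometry(topology, theta=0.0, alpha=90.0, rcc=rcc, plane_sep=3.6)
        assert g.ry == pytest.approx(2.5, abs=1e-9)
        assert not is_stacked(g)

    def test_t_shaped_dimer_is_not_stacked(self, dye_template, topology):
        # planes perpendicular, centers 5 A apart: probes of the upright
        # molecule stand far off the partner plane
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("x", 90, degrees=True).as_matrix()
        atoms = dye_template.instantiate((0, 0, 0), residue_id=1)
        atoms += dye_template.instantiate((0, 0, 5.0), rot, residue_id=2)
        assign_molecule_ids(atoms)
        frame = Frame(time=0.0, atoms=atoms)
        labels = classify_frame(frame, topology)
        assert len(labels) == 1 and labels[0].interacting
        assert not labels[0].stacked

    def test_stacking_checks_both_orderings(self):
        # ordering 0 (A's frame) fails on rx; ordering 1 (B's frame) passes
        # both the components and A's probe distances to B's plane
        probe = np.array([[1.0, 1.0, 1.0, 1.0], [5.0, 5.0, 5.0, 5.0]])
        comp = np.array([[5.0, 3.0, 0.0], [0.5, 0.5, 5.7]])
        g = DimerGeometry(
            rcc_vec=np.array([5.74, 0, 0]),
            rcc=5.74,
            theta=80.0,
            alpha=10.0,
            components=comp,
            probe_plane_dists=probe,
        )
        # ordering 0 fails (rx too large), ordering 1 passes
        assert is_stacked(g)


class TestClassifyFrame:
    def test_dispersed_frame_has_45_noninteracting_pairs(self, topology):
        frame = make_dispersed_frame(SyntheticConfig(seed=7))
        labels = classify_frame(frame, topology)
        assert len(labels) == 45
        assert all(not l.interacting for l in labels)

    def test_planted_h_dimer_recovered(self, topology):
        frame = make_planted_dimer(theta=0.0, alpha=90.0, rcc=3.6, plane_sep=3.6)
        labels = classify_frame(frame, topology)
        assert [l.geometry_class for l in labels] == ["H"]
        assert labels[0].stacked

    def test_three_dye_stack_matches_brute_force(self, dye_template, topology):
        atoms = []
        for i, z in enumerate((0.0, 3.6, 7.2)):
            atoms += dye_template.instantiate((0, 0, z), residue_id=i + 1)
        assign_molecule_ids(atoms)
        frame = Frame(time=0.0, atoms=atoms)
        labels = classify_frame(frame, topology)
        assert len(labels) == 3
        t = ClassificationThresholds()
        expected = oracle_classify_frame(frame, topology, t)
        got = [(l.pair[0], l.pair[1], l.interacting, l.geometry_class, l.stacked) for l in labels]
        assert got == expected

    def test_single_dye_gives_empty_list(self, dye_template, topology):
        atoms = dye_template.instantiate((0, 0, 0), residue_id=1)
        assign_molecule_ids(atoms)
        assert classify_frame(Frame(time=0.0, atoms=atoms), topology) == []

    def test_interacting_count_monotone_in_rcc_cut(self, topology):
        from conftest import random_pose_frame

        rng = np.random.default_rng(11)
        frame = random_pose_frame(rng, 6, box_side=25.0)
        counts = []
        for cut in (2.0, 4.0, 6.0, 10.0, 20.0):
            t = ClassificationThresholds(rcc_cut=cut)
            counts.append(sum(l.interacting for l in classify_frame(frame, topology, t)))
        assert counts == sorted(counts)

    def test_each_interacting_pair_has_exactly_one_class(self, topology):
        from conftest import random_pose_frame

        rng = np.random.default_rng(5)
        for _ in range(10):
            frame = random_pose_frame(rng, 5, box_side=22.0)
            for l in classify_frame(frame, topology):
                if l.interacting:
                    assert l.geometry_class in ("H", "J", "crossed_J")
                else:
                    assert l.geometry_class == "none" and not l.stacked


PLANTED_GRID = [
    (theta, alpha)
    for theta in (1.0, 5.0, 11.0, 13.0, 30.0, 60.0, 89.0)
    for alpha in (5.0, 30.0, 53.7, 55.7, 75.0, 89.0)
]


@pytest.mark.parametrize("theta,alpha", PLANTED_GRID)
def test_planted_dimers_inside_class_regions_are_recovered(theta, alpha, topology):
    """Dimers planted >= 1 degree / 0.1 A away from every boundary classify exactly."""
    plane_sep = min(1.0, 0.9 * 4.5 * np.sin(np.radians(alpha)))
    frame = make_planted_dimer(theta=theta, alpha=alpha, rcc=4.5, plane_sep=plane_sep)
    labels = classify_frame(frame, topology)
    if theta >= 12.0:
        expected = "crossed_J"
    elif alpha > 54.7:
        expected = "H"
    else:
        expected = "J"
    assert [l.geometry_class for l in labels] == [expected]
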