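import numpy as np
import pytest

from dyestack.classify import classify_frame
from dyestack.energetics import NonbondedAtom, pair_energy
from dyestack.geometry import compute_frame, dimer_geometry
from dyestack.metrics import find_clusters, frame_stats
from dyestack.synthetic import (
    SyntheticConfig,
    _dispersed_state,
    _pair_tables,
    _site_energy,
    bulky_counterion_template,
    default_dye_template,
    make_dispersed_frame,
    make_planted_dimer,
    mc_site_parameters,
    run_aggregation,
    small_counterion_template,
)

from conftest import CONTRAST_SEEDS


def planted_geometry(frame, topology):
    mols = {}
    for a in frame.atoms:
        mols.setdefault(a.molecule_id, []).append(a)
    fa, fb = (compute_frame(atoms, topology) for _, atoms in sorted(mols.items()))
    return dimer_geometry(fa, fb)


class TestTemplates:
    def test_dye_template_is_planar_and_cationic(self, dye_template):
        idx = [dye_template.atom_names.index(n) for n in dye_template.xanthene_atoms]
        assert np.abs(dye_template.coords[idx][:, 2]).max() < 1e-6
        assert dye_template.net_charge == pytest.approx(1.0)
        assert set(dye_template.probe_atoms) <= set(dye_template.xanthene_atoms)

    def test_counterion_templates_are_anionic(self):
        assert bulky_counterion_template().net_charge == pytest.approx(-1.0)
        assert small_counterion_template().net_charge == pytest.approx(-1.0)


class TestMakePlantedDimer:
    @pytest.mark.parametrize(
        "theta,alpha,rcc,plane_sep",
        [
            (0.0, 90.0, 3.6, 3.6),
            (0.0, 30.0, 4.0, 1.0),
            (25.0, 60.0, 5.0, 3.0),
            (60.0, 5.0, 5.0, 0.0),
            (89.0, 89.0, 4.2, 2.0),
        ],
    )
    def test_requested_geometry_is_recovered(self, topology, theta, alpha, rcc, plane_sep):
        g = planted_geometry(make_planted_dimer(theta, alpha, rcc, plane_sep), topology)
        assert g.theta == pytest.approx(theta, abs=1e-6)
        assert g.alpha == pytest.approx(alpha, abs=1e-6)
        assert g.rcc == pytest.approx(rcc, abs=1e-6)

    def test_cofacial_contact_classifies_as_stacked_h(self, topology):
        frame = make_planted_dimer(theta=0.0, alpha=90.0, rcc=3.6, plane_sep=3.6)
        (label,) = classify_frame(frame, topology)
        assert label.geometry_class == "H" and label.stacked

    def test_rotated_pair_classifies_as_crossed_j(self, topology):
        frame = make_planted_dimer(theta=60.0, alpha=45.0, rcc=5.0, plane_sep=1.0)
        (label,) = classify_frame(frame, topology)
        assert label.geometry_class == "crossed_J"

    def test_plane_separation_beyond_rcc_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            make_planted_dimer(theta=0.0, alpha=90.0, rcc=3.0, plane_sep=4.0)

    def test_plane_separation_beyond_alpha_reach_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            make_planted_dimer(theta=0.0, alpha=30.0, rcc=4.0, plane_sep=3.0)


class TestMakeDispersedFrame:
    def test_default_composition_is_dispersed(self, topology):
        frame = make_dispersed_frame(SyntheticConfig(seed=1))
        residues = {(a.residue_name, a.residue_id) for a in frame.atoms}
        assert sum(1 for r in residues if r[0] == "RBD") == 10
        assert sum(1 for r in residues if r[0] == "FTB") == 10
        assert all(not l.interacting for l in classify_frame(frame, topology))

    def test_same_seed_is_bit_identical(self):
        f1 = make_dispersed_frame(SyntheticConfig(seed=5))
        f2 = make_dispersed_frame(SyntheticConfig(seed=5))
        assert np.array_equal(f1.coords(), f2.coords())

    def test_infeasible_density_rejected(self):
        with pytest.raises((ValueError, RuntimeError)):
            make_dispersed_frame(SyntheticConfig(seed=1, box_side=12.0))

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError, match="unknown configuration keys"):
            SyntheticConfig.from_dict({"n_dye": 4, "bogus_knob": 1})


class TestRunAggregation:
    def test_zero_steps_returns_initial_frame_only(self):
        frames = run_aggregation(SyntheticConfig(seed=3, n_steps=0))
        assert len(frames) == 1
        assert frames[0].time == 0.0

    def test_fixed_seed_reproduces_trajectory_exactly(self):
        cfg = SyntheticConfig(seed=11, n_steps=300, frame_stride=100)
        f1 = run_aggregation(cfg)
        f2 = run_aggregation(cfg)
        assert len(f1) == len(f2)
        for a, b in zip(f1, f2):
            assert a.time == b.time
            assert np.array_equal(a.coords(), b.coords())

    def test_times_are_monotone_stride_multiples(self):
        cfg = SyntheticConfig(seed=2, n_steps=250, frame_stride=100, timestep_label=0.001)
        times = [f.time for f in run_aggregation(cfg)]
        assert times == pytest.approx([0.0, 0.1, 0.2, 0.25])

    def test_mc_kernel_matches_pair_energy_sums(self):
        """The table-driven site energy equals explicit pair_energy calls."""
        cfg = SyntheticConfig(seed=6, n_dye=4, n_counterion=4)
        rng = np.random.default_rng(6)
        positions, _ = _dispersed_state(cfg, rng)
        qq, eps, rmin = _pair_tables(cfg)
        box = np.full(3, cfg.box_side)
        sites, _ = mc_site_parameters(cfg)
        rh = np.array([s.rmin_half for s in sites])
        q = np.array([s.charge for s in sites])
        for i in (0, 3, 5):
            fast = _site_energy(i, positions[i], positions, qq, eps, rmin, box, cfg.debye_length)
            slow = 0.0
            for j in range(len(sites)):
                if j == i:
                    continue
                slow += pair_energy(
                    [(positions[i], NonbondedAtom(q[i], eps[i, j], rh[i], True))],
                    [(positions[j], NonbondedAtom(q[j], eps[i, j], rh[j], True))],
                    box=box,
                    dielectric=cfg.dielectric,
                    debye_length=cfg.debye_length,
                )
            assert fast == pytest.approx(slow, rel=1e-10)


class TestCounterionContrast:
    """Qualitative two-regime behaviour at the study-default conditions."""

    def test_bulky_counterion_drives_full_aggregation(self, topology, contrast_runs):
        full = 0
        for frames in contrast_runs["bulky_hydrophobic"]:
            clusters = find_clusters(frames[-1], topology)
            dyes = set(range(10))
            if any(dyes <= c for c in clusters):
                full += 1
        assert full >= 4

    def test_small_ion_never_reaches_full_aggregate(self, topology, contrast_runs):
        for frames in contrast_runs["small_ionic"]:
            clusters = find_clusters(frames[-1], topology)
            dyes = set(range(10))
            assert not any(dyes <= c for c in clusters)

    def test_median_final_cluster_size_orders_the_modes(self, topology, contrast_runs):
        largest = {}
        for mode, runs in contrast_runs.items():
            largest[mode] = np.median(
                [max(len(c) for c in find_clusters(f[-1], topology)) for f in runs]
            )
        assert largest["bulky_hydrophobic"] > largest["small_ionic"]

    def test_small_ion_final_sum_rcc_matches_dispersed_expectation(self, topology, contrast_runs):
        expectation = np.mean(
            [
                frame_stats([], make_dispersed_frame(SyntheticConfig(seed=100 + s)), topology).sum_rcc
                for s in range(10)
            ]
        )
        finals = [
            frame_stats([], frames[-1], topology).sum_rcc
            for frames in contrast_runs["small_ionic"]
        ]
        assert abs(np.mean(finals) - expectation) / expectation < 0.10
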