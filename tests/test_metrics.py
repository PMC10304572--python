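import numpy as np
import pytest

from dyestack.classify import classify_frame
from dyestack.metrics import (
    block_average,
    find_clusters,
    frame_stats,
    rdf,
    summarize_stats,
    trajectory_stats,
)
from dyestack.synthetic import (
    SyntheticConfig,
    default_dye_template,
    make_dispersed_frame,
    make_planted_dimer,
)
from dyestack.trajio import Frame, assign_molecule_ids


def frame_of_dyes(positions, rotations=None, box=None):
    template = default_dye_template()
    atoms = []
    for i, pos in enumerate(positions):
        rot = None if rotations is None else rotations[i]
        atoms += template.instantiate(pos, rot, residue_id=i + 1)
    assign_molecule_ids(atoms)
    return Frame(time=0.0, atoms=atoms, box=box)


class TestFrameStats:
    def test_sum_rcc_is_sum_of_pairwise_center_distances(self, topology):
        frame = frame_of_dyes([(0, 0, 0), (0, 0, 3.0), (0, 4.0, 0)])
        st = frame_stats(classify_frame(frame, topology), frame, topology)
        assert st.sum_rcc == pytest.approx(3.0 + 4.0 + 5.0)

    def test_dispersed_frame_has_no_interactions(self, topology):
        frame = make_dispersed_frame(SyntheticConfig(seed=2))
        st = frame_stats(classify_frame(frame, topology), frame, topology)
        assert st.n_interacting == 0
        assert st.n_stacked == 0
        assert not st.full_aggregate

    def test_planted_h_and_crossed_j_counted_by_class(self, topology):
        h = make_planted_dimer(theta=0.0, alpha=90.0, rcc=3.6, plane_sep=3.6)
        x = make_planted_dimer(theta=40.0, alpha=90.0, rcc=3.5, plane_sep=3.5)
        atoms = list(h.atoms)
        for a in x.atoms:
            a.coords = a.coords + np.array([40.0, 0.0, 0.0])
            a.residue_id += 2
            atoms.append(a)
        assign_molecule_ids(atoms)
        frame = Frame(time=0.0, atoms=atoms)
        st = frame_stats(classify_frame(frame, topology), frame, topology)
        assert (st.n_H, st.n_J, st.n_crossedJ) == (1, 0, 1)
        assert st.n_stacked == 2

    def test_sum_rcc_invariant_under_rigid_motion_and_relabeling(self, topology):
        from scipy.spatial.transform import Rotation

        positions = [(0, 0, 0), (8, 1, 2), (3, 12, 5), (14, 6, 9)]
        f1 = frame_of_dyes(positions)
        rot = Rotation.from_euler("xyz", [20, 40, 60], degrees=True).as_matrix()
        moved = [rot @ np.asarray(p) + np.array([5.0, -3.0, 7.0]) for p in positions]
        f2 = frame_of_dyes([moved[i] for i in (2, 0, 3, 1)], rotations=[rot] * 4)
        s1 = frame_stats(classify_frame(f1, topology), f1, topology).sum_rcc
        s2 = frame_stats(classify_frame(f2, topology), f2, topology).sum_rcc
        assert s1 == pytest.approx(s2, abs=1e-8)

    def test_compaction_strictly_lowers_sum_rcc(self, topology):
        positions = np.array([(0.0, 0, 0), (10, 2, 1), (4, 12, 3), (9, 8, 11)])
        centroid = positions.mean(axis=0)
        compacted = centroid + 0.5 * (positions - centroid)
        s1 = frame_stats([], frame_of_dyes(positions), topology).sum_rcc
        s2 = frame_stats([], frame_of_dyes(compacted), topology).sum_rcc
        assert s2 < s1


class TestBlockAverage:
    def test_constant_series_stays_constant(self):
        series = [(0.01 * i, 5.0) for i in range(40)]
        out = block_average(series, window=0.1)
        assert np.allclose(out["value"], 5.0)

    def test_two_full_windows_average_correctly(self):
        series = [(0.01 * i, float(i + 1)) for i in range(10)]
        out = block_average(series, window=0.05)
        assert list(out["value"]) == [3.0, 8.0]
        assert list(out["time"]) == pytest.approx([0.025, 0.075])

    def test_single_point_passes_through(self):
        out = block_average([(1.0, 2.5)], window=0.1)
        assert len(out) == 1
        assert out["value"].iloc[0] == 2.5

    def test_trailing_partial_window_is_flagged_not_dropped(self):
        series = [(0.01 * i, 1.0) for i in range(13)]
        out = block_average(series, window=0.05)
        assert len(out) == 3
        assert list(out["partial"]) == [False, False, True]

    def test_empty_series_gives_empty_output(self):
        assert block_average([], window=0.1).empty


class TestFindClusters:
    def test_dispersed_molecules_are_singletons(self, topology):
        frame = make_dispersed_frame(SyntheticConfig(seed=4, n_dye=5, n_counterion=5))
        clusters = find_clusters(frame, topology)
        assert sorted(len(c) for c in clusters) == [1] * 10

    def test_contact_chain_is_transitive(self, topology):
        frame = frame_of_dyes([(0, 0, 0), (0, 0, 4.0), (0, 0, 8.0)])
        clusters = find_clusters(frame, topology, contact_cut=4.5)
        assert [len(c) for c in clusters] == [3]

    def test_two_planted_aggregates_match_brute_force_sizes(self, topology):
        stack1 = [(0, 0, 4.0 * i) for i in range(5)]
        stack2 = [(30.0, 0, 4.0 * i) for i in range(5)]
        frame = frame_of_dyes(stack1 + stack2)
        clusters = find_clusters(frame, topology, contact_cut=4.5)
        assert sorted(len(c) for c in clusters) == [5, 5]

    def test_clusters_partition_the_molecule_set(self, topology):
        frame = make_dispersed_frame(SyntheticConfig(seed=9, n_dye=6, n_counterion=6))
        clusters = find_clusters(frame, topology)
        everything = sorted(m for c in clusters for m in c)
        assert everything == list(range(12))


class TestRdf:
    def test_uniform_centers_give_unit_g(self, topology):
        rng = np.random.default_rng(12)
        box = np.full(3, 60.0)
        frames = []
        for k in range(150):
            frames.append(
                Frame(
                    time=float(k),
                    atoms=frame_of_dyes(rng.random((8, 3)) * 60.0).atoms,
                    box=box,
                )
            )
        out = rdf(frames, topology, "dye_dye", r_max=30.0, bin_width=1.0, tail=1e9)
        sel = out.bin_centers > 12.0
        assert abs(out.g[sel].mean() - 1.0) < 0.05

    def test_fixed_pair_occupies_single_bin(self, topology):
        frame = frame_of_dyes([(10, 10, 10), (15, 10, 10)], box=np.full(3, 40.0))
        frame.box = np.full(3, 40.0)
        out = rdf([frame], topology, "dye_dye", r_max=20.0, bin_width=0.5, tail=1.0)
        occupied = np.flatnonzero(out.g > 0)
        assert len(occupied) == 1
        assert out.bin_centers[occupied[0]] == pytest.approx(5.25)

    def test_missing_box_rejected(self, topology):
        frame = frame_of_dyes([(0, 0, 0), (5, 0, 0)])
        with pytest.raises(ValueError, match="periodic box"):
            rdf([frame], topology, "dye_dye")

    def test_r_max_limited_to_half_box(self, topology):
        frame = frame_of_dyes([(0, 0, 0), (5, 0, 0)], box=np.full(3, 30.0))
        frame.box = np.full(3, 30.0)
        with pytest.raises(ValueError, match="half the smallest"):
            rdf([frame], topology, "dye_dye", r_max=20.0)


class TestTrajectorySummary:
    def test_stats_table_and_summary_schema(self, topology):
        frames = [make_dispersed_frame(SyntheticConfig(seed=s, n_dye=4, n_counterion=4)) for s in (1, 2)]
        frames[1].time = 0.1
        stats = trajectory_stats(frames, topology)
        assert list(stats["time"]) == [0.0, 0.1]
        summary = summarize_stats(stats)
        assert summary["full_aggregate_reached"] is False
        assert summary["first_full_aggregate_time_ns"] is None
        assert summary["n_frames"] == 2

    def test_empty_stats_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            summarize_stats(pd.DataFrame())
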