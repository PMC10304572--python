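"""Time-series and ensemble statistics of dye aggregation.

Per-frame observables follow the standard trajectory-analysis readouts
for counterion-driven dye assembly: the number of interacting dimers,
the numbers of pi-stacked dimers by geometric class (H / J / crossed-J),
the sum of all dye-dye center-center distances (a scalar proxy that
drops when large aggregates form), and cluster sizes from a contact
graph over dyes and counterions.  Time series are condensed by
non-overlapping block averages (0.1 ns windows by default) and ensemble
structure by radial pair distribution functions g(r) for dye-dye and
dye-counterion center pairs, averaged over the trailing nanosecond of a
run by default.

The cluster criterion is a package choice (no algorithmic definition
exists in the emulated protocol, where aggregates are read off
snapshots): two molecules are in contact when their minimum heavy-atom
distance falls below ``contact_cut`` (default 4.5 angstrom), counterions
included, so counterion-bridged aggregates count as one cluster.  A
"full aggregate" is a cluster containing every dye.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .classify import ClassificationThresholds, DimerLabel, classify_frame
from .geometry import compute_frame
from .trajio import Frame, SystemTopology, group_molecules

__all__ = [
    "FrameStats",
    "RdfResult",
    "frame_stats",
    "block_average",
    "find_clusters",
    "rdf",
    "trajectory_stats",
    "summarize_stats",
]

STATS_COLUMNS = [
    "time",
    "n_interacting",
    "n_H",
    "n_J",
    "n_crossedJ",
    "n_stacked",
    "sum_rcc",
    "n_clusters",
    "largest_cluster",
    "full_aggregate",
]


@dataclass
class FrameStats:
    """Aggregation observables of one frame.

    ``n_H``/``n_J``/``n_crossedJ`` count *stacked* dimers by geometric
    class, so they sum to ``n_stacked``; ``n_interacting`` counts every
    pair below the interacting cutoff.  ``cluster_sizes`` is sorted
    descending and partitions the dye + counterion molecules.
    """

    time: float
    n_interacting: int
    n_H: int
    n_J: int
    n_crossedJ: int
    n_stacked: int
    sum_rcc: float
    cluster_sizes: list[int]
    full_aggregate: bool


@dataclass
class RdfResult:
    """A radial pair distribution function g(r) on a uniform grid."""

    bin_centers: np.ndarray
    g: np.ndarray
    pair_kind: str
    n_frames_averaged: int

    def to_csv(self, path) -> None:
        pd.DataFrame({"r_A": self.bin_centers, "g": self.g}).to_csv(path, index=False)


def _minimum_image_dist(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    d = b - a
    if box is not None:
        d = d - box * np.round(d / box)
    return np.sqrt((d * d).sum(axis=-1))


def _dye_centers(frame: Frame, topology: SystemTopology) -> dict[int, np.ndarray]:
    centers = {}
    for mol_id, resname, atoms in group_molecules(frame):
        if topology.role_of(resname) == "dye":
            centers[mol_id] = compute_frame(atoms, topology).center
    return centers


def frame_stats(
    labels: Sequence[DimerLabel],
    frame: Frame,
    topology: SystemTopology,
    contact_cut: float = 4.5,
) -> FrameStats:
    """Condense one frame's labels and coordinates into :class:`FrameStats`."""
    n_int = sum(1 for l in labels if l.interacting)
    n_h = sum(1 for l in labels if l.stacked and l.geometry_class == "H")
    n_j = sum(1 for l in labels if l.stacked and l.geometry_class == "J")
    n_x = sum(1 for l in labels if l.stacked and l.geometry_class == "crossed_J")

    centers = _dye_centers(frame, topology)
    ids = sorted(centers)
    sum_rcc = 0.0
    for a, b in combinations(ids, 2):
        sum_rcc += float(_minimum_image_dist(centers[a], centers[b], frame.box))

    clusters = find_clusters(frame, topology, contact_cut)
    sizes = sorted((len(c) for c in clusters), reverse=True)
    dye_ids = set(ids)
    full = any(dye_ids <= c for c in clusters) if dye_ids else False
    return FrameStats(
        time=frame.time,
        n_interacting=n_int,
        n_H=n_h,
        n_J=n_j,
        n_crossedJ=n_x,
        n_stacked=n_h + n_j + n_x,
        sum_rcc=sum_rcc,
        cluster_sizes=sizes,
        full_aggregate=full,
    )


def block_average(
    series: Sequence[tuple[float, float]], window: float = 0.1
) -> pd.DataFrame:
    """Non-overlapping block means of a (time, value) series.

    Windows of width ``window`` (ns) start at the first time; each output
    row is (window midpoint, mean inside).  A trailing partial window is
    averaged and flagged in the ``partial`` column rather than dropped.
    Returns an empty frame for an empty series.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if len(series) == 0:
        return pd.DataFrame(columns=["time", "value", "partial"])
    times = np.asarray([t for t, _ in series], dtype=float)
    values = np.asarray([v for _, v in series], dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted")
    t0 = times[0]
    idx = np.floor((times - t0) / window + 1e-12).astype(int)
    blocks = np.unique(idx)
    counts = {k: int(np.sum(idx == k)) for k in blocks}
    max_count = max(counts.values())
    rows = []
    for k in blocks:
        sel = idx == k
        # the trailing block is flagged partial when it holds fewer samples
        # than a full window would
        partial = bool(k == blocks[-1] and counts[k] < max_count)
        rows.append(
            {
                "time": t0 + (k + 0.5) * window,
                "value": float(values[sel].mean()),
                "partial": partial,
            }
        )
    return pd.DataFrame(rows)


def find_clusters(
    frame: Frame, topology: SystemTopology, contact_cut: float = 4.5
) -> list[set[int]]:
    """Connected components of the molecular contact graph.

    Nodes are dye and counterion molecules; an edge joins two molecules
    whose minimum heavy-atom (non-hydrogen) distance is below
    ``contact_cut`` under the minimum image.  Solvent and unknown residues
    are excluded.
    """
    if contact_cut <= 0:
        raise ValueError("contact_cut must be > 0")
    mols = [
        (mol_id, [a for a in atoms if a.element.upper() != "H"])
        for mol_id, resname, atoms in group_molecules(frame)
        if topology.role_of(resname) in ("dye", "counterion")
    ]
    graph = nx.Graph()
    graph.add_nodes_from(mid for mid, _ in mols)
    coords = {mid: np.array([a.coords for a in atoms]) for mid, atoms in mols}
    ids = [mid for mid, _ in mols]
    for a, b in combinations(ids, 2):
        diff = coords[b][None, :, :] - coords[a][:, None, :]
        if frame.box is not None:
            diff = diff - frame.box * np.round(diff / frame.box)
        dmin = np.sqrt((diff * diff).sum(axis=-1)).min()
        if dmin < contact_cut:
            graph.add_edge(a, b)
    return [set(c) for c in nx.connected_components(graph)]


def _pair_sites(
    frame: Frame, topology: SystemTopology
) -> tuple[np.ndarray, np.ndarray]:
    """Dye xanthene centroids and counterion centroids of one frame."""
    dyes, ions = [], []
    for mol_id, resname, atoms in group_molecules(frame):
        role = topology.role_of(resname)
        if role == "dye":
            dyes.append(compute_frame(atoms, topology).center)
        elif role == "counterion":
            ions.append(np.mean([a.coords for a in atoms], axis=0))
    return np.asarray(dyes), np.asarray(ions)


def rdf(
    frames: Sequence[Frame],
    topology: SystemTopology,
    pair_kind: str = "dye_dye",
    r_max: float = 40.0,
    bin_width: float = 0.1,
    tail: float = 1.0,
) -> RdfResult:
    """Center-to-center radial distribution function over the trailing window.

    Only frames within the last ``tail`` ns are averaged (the regime in
    which aggregates, if any, are fully formed).  The histogram is
    normalized per frame by the ideal-gas shell count
    ``n_pairs * V_shell / V_box``, so a uniform system gives g = 1.
    Requires a periodic box and ``r_max`` at most half the smallest side.
    """
    if pair_kind not in ("dye_dye", "dye_counterion"):
        raise ValueError("pair_kind must be 'dye_dye' or 'dye_counterion'")
    if not frames:
        raise ValueError("no frames given")
    if frames[0].box is None:
        raise ValueError("rdf requires a periodic box")
    box = frames[0].box
    if r_max > box.min() / 2 + 1e-9:
        raise ValueError("r_max must not exceed half the smallest box side")

    t_end = frames[-1].time
    use = [f for f in frames if f.time >= t_end - tail - 1e-12]
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    n_pairs = None
    for f in use:
        dyes, ions = _pair_sites(f, topology)
        if pair_kind == "dye_dye":
            if len(dyes) < 2:
                raise ValueError("dye_dye rdf needs at least two dyes")
            pairs = np.array(list(combinations(range(len(dyes)), 2)))
            dist = _minimum_image_dist(dyes[pairs[:, 0]], dyes[pairs[:, 1]], f.box)
        else:
            if len(dyes) == 0 or len(ions) == 0:
                raise ValueError("dye_counterion rdf needs both species")
            diff = ions[None, :, :] - dyes[:, None, :]
            diff = diff - f.box * np.round(diff / f.box)
            dist = np.sqrt((diff * diff).sum(axis=-1)).ravel()
        n_pairs = dist.size
        hist += np.histogram(dist, bins=edges)[0]

    volume = float(np.prod(box))
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n_pairs * shell / volume * len(use)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ideal > 0, hist / ideal, 0.0)
    return RdfResult(
        bin_centers=0.5 * (edges[1:] + edges[:-1]),
        g=g,
        pair_kind=pair_kind,
        n_frames_averaged=len(use),
    )


def trajectory_stats(
    frames: Sequence[Frame],
    topology: SystemTopology,
    thresholds: ClassificationThresholds | None = None,
    contact_cut: float = 4.5,
) -> pd.DataFrame:
    """Classify every frame and tabulate :data:`STATS_COLUMNS` per frame."""
    thresholds = thresholds or ClassificationThresholds()
    rows = []
    for f in frames:
        labels = classify_frame(f, topology, thresholds)
        st = frame_stats(labels, f, topology, contact_cut)
        rows.append(
            {
                "time": st.time,
                "n_interacting": st.n_interacting,
                "n_H": st.n_H,
                "n_J": st.n_J,
                "n_crossedJ": st.n_crossedJ,
                "n_stacked": st.n_stacked,
                "sum_rcc": st.sum_rcc,
                "n_clusters": len(st.cluster_sizes),
                "largest_cluster": max(st.cluster_sizes) if st.cluster_sizes else 0,
                "full_aggregate": st.full_aggregate,
            }
        )
    return pd.DataFrame(rows, columns=STATS_COLUMNS)


def summarize_stats(stats: pd.DataFrame) -> dict:
    """Run-level summary: full-aggregate first passage and dimer occupancies."""
    if stats.empty:
        raise ValueError("empty stats table")
    full = stats[stats["full_aggregate"].astype(bool)]
    reached = not full.empty
    n = len(stats)
    return {
        "n_frames": int(n),
        "full_aggregate_reached": bool(reached),
        "first_full_aggregate_time_ns": float(full["time"].iloc[0]) if reached else None,
        "mean_interacting_dimers": float(stats["n_interacting"].mean()),
        "mean_stacked_dimers": float(stats["n_stacked"].mean()),
        "occupancy_fraction": {
            "H": float((stats["n_H"] > 0).mean()),
            "J": float((stats["n_J"] > 0).mean()),
            "crossed_J": float((stats["n_crossedJ"] > 0).mean()),
            "any_interacting": float((stats["n_interacting"] > 0).mean()),
        },
        "final_sum_rcc_A": float(stats["sum_rcc"].iloc[-1]),
        "final_largest_cluster": int(stats["largest_cluster"].iloc[-1]),
    }
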