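"""Independent brute-force oracles used to cross-check the implementation.

Everything here is recomputed from raw coordinates with plain Python
loops and a different linear-algebra route (eigendecomposition instead
of SVD, explicit 27-image search instead of the round trick), so
agreement with the package is a genuine dual-route check.
"""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np


def oracle_plane_frame(atoms_by_name: dict, topology):
    """Centroid + axes from covariance eigenvectors and the projected long axis."""
    coords = np.array([atoms_by_name[n] for n in topology.xanthene_atoms])
    center = coords.mean(axis=0)
    cov = (coords - center).T @ (coords - center)
    evals, evecs = np.linalg.eigh(cov)
    z = evecs[:, 0]  # smallest eigenvalue: plane normal
    a, b = topology.long_axis_atoms
    raw = np.asarray(atoms_by_name[b]) - np.asarray(atoms_by_name[a])
    x = raw - (raw @ z) * z
    x = x / np.linalg.norm(x)
    probes = np.array([atoms_by_name[n] for n in topology.stack_probe_atoms])
    return center, x, z, probes


def _min_image_by_search(vec, box):
    """Minimum-image displacement via explicit 27-neighbour enumeration."""
    if box is None:
        return np.asarray(vec, dtype=float)
    best, best_n = None, math.inf
    for sx, sy, sz in product((-1, 0, 1), repeat=3):
        cand = np.asarray(vec, dtype=float) + box * np.array([sx, sy, sz])
        n = float(np.linalg.norm(cand))
        if n < best_n:
            best, best_n = cand, n
    return best


def _fold(deg):
    return deg if deg <= 90 else 180 - deg


def oracle_classify_frame(frame, topology, thresholds):
    """Re-derive every DimerLabel from raw coordinates, independently."""
    # independent molecule grouping by (resname, resid) runs
    mols = []
    prev = None
    for a in frame.atoms:
        key = (a.residue_name, a.residue_id)
        if key != prev:
            mols.append((a.residue_name, []))
            prev = key
        mols[-1][1].append(a)
    dyes = []
    mol_id = -1
    for resname, atoms in mols:
        mol_id += 1
        if topology.role_map.get(resname) == "dye":
            dyes.append((mol_id, {a.atom_name: a.coords for a in atoms}))

    labels = []
    for (ia, ta), (ib, tb) in combinations(dyes, 2):
        ca, xa, za, pa = oracle_plane_frame(ta, topology)
        cb, xb, zb, pb = oracle_plane_frame(tb, topology)
        d = _min_image_by_search(cb - ca, frame.box)
        shift = d - (cb - ca)
        rcc = float(np.linalg.norm(d))
        interacting = rcc < thresholds.rcc_cut
        if not interacting:
            labels.append((ia, ib, False, "none", False))
            continue
        theta = _fold(math.degrees(math.acos(min(1.0, abs(float(xa @ xb))))))
        m = xa + (1 if float(xa @ xb) >= 0 else -1) * xb
        if np.linalg.norm(m) < 1e-9:
            m = xa
        cosa = abs(float(d @ m)) / (np.linalg.norm(d) * np.linalg.norm(m))
        alpha = math.degrees(math.acos(min(1.0, cosa)))
        if theta >= thresholds.theta_cut:
            cls = "crossed_J"
        elif alpha > thresholds.alpha_magic:
            cls = "H"
        else:
            cls = "J"
        ya = np.cross(za, xa)
        yb = np.cross(zb, xb)
        stacked = False
        # ordering m: components in m's frame, partner probes onto m's plane
        for axes, probes_partner, center_self, z_self in (
            ((xa, ya), pb + shift, ca, za),
            ((xb, yb), pa, ca + d, zb),
        ):
            rx = abs(float(d @ axes[0]))
            ry = abs(float(d @ axes[1]))
            dists = [abs(float((p - center_self) @ z_self)) for p in probes_partner]
            if (
                rx < thresholds.stack_rx_cut
                and ry < thresholds.stack_ry_cut
                and all(dd < thresholds.stack_plane_cut for dd in dists)
            ):
                stacked = True
        labels.append((ia, ib, True, cls, stacked))
    return labels


def oracle_pair_energy(molA, molB, scale_factor=1.0):
    """Plain double-loop Coulomb + LJ sum over (coords, NonbondedAtom) pairs."""
    total = 0.0
    for ca, pa in molA:
        for cb, pb in molB:
            r = math.dist(tuple(ca), tuple(cb))
            total += 332.0636 * pa.charge * pb.charge / r
            eps = math.sqrt(pa.epsilon * pb.epsilon)
            if pa.scaled_subset and pb.scaled_subset:
                eps *= scale_factor
            rmin = pa.rmin_half + pb.rmin_half
            x = (rmin / r) ** 6
            total += eps * (x * x - 2 * x)
    return total
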