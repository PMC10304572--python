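"""Trajectory and topology I/O.

Two plain-text trajectory formats are supported:

* multi-frame PDB (``MODEL``/``ENDMDL`` records, box from ``CRYST1``),
  read and written through :mod:`MDAnalysis`;
* extended XYZ, where the comment line may carry ``Lattice="lx ly lz"``
  (a 9-number row-major cell is also accepted, its diagonal is used) and
  ``time=<ns>``, and each atom line is either the minimal
  ``element x y z`` or the extended
  ``element x y z atom_name residue_name residue_id``.

Coordinates are Cartesian angstrom throughout; times are nanoseconds.
Molecule identity is assigned from contiguous runs of identical
``(residue_name, residue_id)`` pairs, so chain identifiers are ignored --
packing-tool outputs frequently omit them.  Solvent atoms are kept on
read but excluded from every dye/counterion analysis downstream.

The topology/role configuration is a small YAML document::

    roles:
      RBD: dye
      FTB: counterion
      HOH: solvent
    xanthene_atoms: [C1, C2, ...]
    long_axis_atoms: [N1, N2]
    stack_probe_atoms: [C3, C4, C9, C10]

``xanthene_atoms`` define the chromophore plane, ``long_axis_atoms`` the
long-axis (transition-dipole) direction and ``stack_probe_atoms`` the
four atoms whose distances from the partner plane probe pi-stacking.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "AtomRecord",
    "Frame",
    "SystemTopology",
    "assign_molecule_ids",
    "group_molecules",
    "load_topology",
    "save_topology",
    "read_trajectory",
    "write_trajectory",
]

ROLES = ("dye", "counterion", "solvent", "other")


@dataclass
class AtomRecord:
    """A single atom: name, element, coordinates and residue identity."""

    atom_name: str
    element: str
    coords: np.ndarray
    residue_name: str
    residue_id: int
    molecule_id: int = -1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name!r}")
        if self.residue_id < 0:
            raise ValueError("residue_id must be >= 0")


@dataclass
class Frame:
    """One trajectory frame: a time label, an ordered atom list, an optional box.

    ``box`` holds the three side lengths of an orthorhombic periodic cell in
    angstrom; ``None`` means non-periodic analysis.
    """

    time: float
    atoms: list[AtomRecord]
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if not np.all(self.box > 0):
                raise ValueError("box side lengths must be > 0")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """All coordinates stacked into an ``(n_atoms, 3)`` array."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def atom_key(self) -> list[tuple[str, str, int]]:
        """Ordering signature used to check frame-to-frame consistency."""
        return [(a.atom_name, a.residue_name, a.residue_id) for a in self.atoms]


def assign_molecule_ids(atoms: Sequence[AtomRecord]) -> None:
    """Assign ``molecule_id`` by contiguous ``(residue_name, residue_id)`` runs."""
    mol = -1
    prev = None
    for a in atoms:
        key = (a.residue_name, a.residue_id)
        if key != prev:
            mol += 1
            prev = key
        a.molecule_id = mol


def group_molecules(frame: Frame) -> list[tuple[int, str, list[AtomRecord]]]:
    """Group a frame's atoms into ``(molecule_id, residue_name, atoms)`` triples."""
    out: list[tuple[int, str, list[AtomRecord]]] = []
    for a in frame.atoms:
        if out and out[-1][0] == a.molecule_id:
            out[-1][2].append(a)
        else:
            out.append((a.molecule_id, a.residue_name, [a]))
    return out


@dataclass
class SystemTopology:
    """Residue roles plus the named atoms that define the chromophore frame.

    ``stack_probe_atoms`` must name exactly four atoms of the xanthene plane;
    their distances from the partner molecule's plane enter the pi-stacking
    test.  The identity of these four atoms is a user choice -- see
    :func:`dyestack.synthetic.default_topology` for a documented example that
    picks the four central ring-junction carbons of the scaffold.
    """

    role_map: dict[str, str]
    xanthene_atoms: list[str]
    long_axis_atoms: tuple[str, str]
    stack_probe_atoms: list[str]
    _warned: set = field(default_factory=set, repr=False, compare=False)

    def __post_init__(self) -> None:
        for res, role in self.role_map.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for residue {res!r}")
        if len(self.xanthene_atoms) < 3:
            raise ValueError("need at least 3 xanthene atoms to define a plane")
        self.long_axis_atoms = tuple(self.long_axis_atoms)  # type: ignore[assignment]
        if len(self.long_axis_atoms) != 2 or self.long_axis_atoms[0] == self.long_axis_atoms[1]:
            raise ValueError("long_axis_atoms must be two distinct atom names")
        if len(self.stack_probe_atoms) != 4:
            raise ValueError(
                f"stack_probe_atoms must name exactly 4 atoms, got {len(self.stack_probe_atoms)}"
            )
        missing = set(self.stack_probe_atoms) - set(self.xanthene_atoms)
        if missing:
            raise ValueError(f"stack probe atoms not in xanthene set: {sorted(missing)}")

    def role_of(self, residue_name: str) -> str:
        """Role for a residue name; unknown residues get ``other`` with a warning."""
        role = self.role_map.get(residue_name)
        if role is None:
            if residue_name not in self._warned:
                warnings.warn(
                    f"residue {residue_name!r} has no declared role; treating as 'other'",
                    stacklevel=2,
                )
                self._warned.add(residue_name)
            return "other"
        return role


def load_topology(path: str | Path) -> SystemTopology:
    """Read and validate a YAML topology/role configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"topology config {path} is not a mapping")
    try:
        return SystemTopology(
            role_map=dict(data["roles"]),
            xanthene_atoms=list(data["xanthene_atoms"]),
            long_axis_atoms=tuple(data["long_axis_atoms"]),
            stack_probe_atoms=list(data["stack_probe_atoms"]),
        )
    except KeyError as exc:
        raise ValueError(f"topology config {path} is missing key {exc}") from exc


def save_topology(topology: SystemTopology, path: str | Path) -> None:
    data = {
        "roles": dict(topology.role_map),
        "xanthene_atoms": list(topology.xanthene_atoms),
        "long_axis_atoms": list(topology.long_axis_atoms),
        "stack_probe_atoms": list(topology.stack_probe_atoms),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# format detection and shared validation


def _infer_format(path: str | Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        fmt = Path(path).suffix.lstrip(".").lower()
    if fmt not in ("pdb", "xyz"):
        raise ValueError(f"unsupported trajectory format {fmt!r} (expected 'pdb' or 'xyz')")
    return fmt


def _warn_unknown_residues(frames: Sequence[Frame], topology: SystemTopology | None) -> None:
    if topology is None:
        return
    seen = {a.residue_name for a in frames[0].atoms}
    for res in sorted(seen):
        topology.role_of(res)


def read_trajectory(
    path: str | Path,
    topology: SystemTopology | None = None,
    format: str | None = None,
) -> list[Frame]:
    """Read a multi-frame trajectory into a list of :class:`Frame`.

    The atom count must be constant across frames (hard error otherwise).
    Residues with no role in ``topology`` trigger a warning and are treated
    as ``other`` downstream.  An absent box triggers a warning: analyses then
    run non-periodically.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    frames = _read_pdb(path) if fmt == "pdb" else _read_xyz(path)
    if not frames:
        raise ValueError(f"no frames found in {path}")
    key0 = frames[0].atom_key()
    for i, f in enumerate(frames[1:], start=2):
        if f.n_atoms != len(key0):
            raise ValueError(
                f"inconsistent atom count in {path}: frame 1 has {len(key0)} atoms, "
                f"frame {i} has {f.n_atoms}"
            )
        if f.atom_key() != key0:
            raise ValueError(f"atom ordering changes between frame 1 and frame {i} of {path}")
    if frames[0].box is None:
        warnings.warn(
            f"{path} carries no box information; analyses will be non-periodic",
            stacklevel=2,
        )
    _warn_unknown_residues(frames, topology)
    return frames


def write_trajectory(
    frames: Sequence[Frame],
    path: str | Path,
    format: str | None = None,
) -> None:
    """Write frames to a multi-frame PDB or extended XYZ file.

    Reading the file back reproduces coordinates within format precision
    (1e-3 angstrom for PDB, 1e-6 for XYZ).
    """
    if not frames:
        raise ValueError("cannot write an empty frame list")
    key0 = frames[0].atom_key()
    for i, f in enumerate(frames[1:], start=2):
        if f.atom_key() != key0:
            raise ValueError(f"frame {i} has a different atom ordering than frame 1")
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        _write_pdb(frames, Path(path))
    else:
        _write_xyz(frames, Path(path))


# ---------------------------------------------------------------------------
# PDB backend (MDAnalysis)


def _pdb_model_atom_counts(path: Path) -> list[int]:
    """Cheap pre-scan of ATOM/HETATM counts per MODEL block."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                current += 1
    if not saw_model:
        return [current] if current else []
    if in_model:  # unterminated final model
        counts.append(current)
    return counts


def _guess_element(name: str) -> str:
    stripped = name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _pdb_cryst1_box(path: Path) -> np.ndarray | None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                sides = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
                if np.all(sides > 0):
                    return sides
                return None
    return None


def _read_pdb(path: Path) -> list[Frame]:
    counts = _pdb_model_atom_counts(path)
    if len(set(counts)) > 1:
        raise ValueError(
            f"inconsistent atom count across MODEL blocks of {path}: {sorted(set(counts))}"
        )
    header_box = _pdb_cryst1_box(path)
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format="PDB")
        names = [str(n) for n in u.atoms.names]
        resnames = [str(r) for r in u.atoms.resnames]
        resids = [int(r) for r in u.atoms.resids]
        try:
            elements = [str(e) if str(e).strip() else _guess_element(n)
                        for e, n in zip(u.atoms.elements, names)]
        except Exception:
            elements = [_guess_element(n) for n in names]
        frames: list[Frame] = []
        for i, ts in enumerate(u.trajectory):
            dims = ts.dimensions
            box = None
            if dims is not None and np.all(np.asarray(dims[:3]) > 0):
                box = np.asarray(dims[:3], dtype=float)
            elif header_box is not None:
                # multi-model PDBs: the reader drops the header CRYST1
                box = header_box.copy()
            atoms = [
                AtomRecord(names[j], elements[j], ts.positions[j].astype(float),
                           resnames[j], resids[j])
                for j in range(len(names))
            ]
            assign_molecule_ids(atoms)
            # PDB has no time metadata: label frames by index (nominal ns).
            frames.append(Frame(time=float(i), atoms=atoms, box=box))
    return frames


def _write_pdb(frames: Sequence[Frame], path: Path) -> None:
    import MDAnalysis as mda

    atoms0 = frames[0].atoms
    n_atoms = len(atoms0)
    resindex = []
    n_res = -1
    prev = None
    for a in atoms0:
        key = (a.residue_name, a.residue_id)
        if key != prev:
            n_res += 1
            prev = key
        resindex.append(n_res)
    n_res += 1
    res_first = [i for i, idx in enumerate(resindex) if idx > resindex[i - 1] or i == 0]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms,
            n_residues=n_res,
            atom_resindex=np.asarray(resindex),
            residue_segindex=np.zeros(n_res, dtype=int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.atom_name for a in atoms0])
        u.add_TopologyAttr("elements", [a.element for a in atoms0])
        u.add_TopologyAttr("resnames", [atoms0[i].residue_name for i in res_first])
        u.add_TopologyAttr("resids", [atoms0[i].residue_id for i in res_first])
        with mda.Writer(str(path), n_atoms, multiframe=True) as writer:
            for f in frames:
                u.atoms.positions = f.coords()
                if f.box is not None:
                    u.dimensions = [*f.box, 90.0, 90.0, 90.0]
                writer.write(u.atoms)


# ---------------------------------------------------------------------------
# extended XYZ backend

_LATTICE_QUOTED = re.compile(r'Lattice="([^"]+)"')
_LATTICE_BARE = re.compile(
    r"Lattice=([-\d.eE+]+)\s+([-\d.eE+]+)\s+([-\d.eE+]+)"
)
_TIME = re.compile(r"time=([-\d.eE+]+)")


def _parse_xyz_comment(comment: str) -> tuple[np.ndarray | None, float | None]:
    box = None
    m = _LATTICE_QUOTED.search(comment)
    if m:
        vals = np.array([float(x) for x in m.group(1).split()])
        if vals.size == 9:
            box = vals.reshape(3, 3).diagonal().copy()
        elif vals.size == 3:
            box = vals
    else:
        m = _LATTICE_BARE.search(comment)
        if m:
            box = np.array([float(m.group(i)) for i in (1, 2, 3)])
    t = None
    m = _TIME.search(comment)
    if m:
        t = float(m.group(1))
    return box, t


def _read_xyz(path: Path) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path}: expected an atom count at line {i + 1}") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        box, t = _parse_xyz_comment(comment)
        atoms: list[AtomRecord] = []
        body = lines[i + 2 : i + 2 + natoms]
        if len(body) < natoms:
            raise ValueError(f"{path}: truncated frame at line {i + 1}")
        for ln in body:
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed atom line {ln!r}")
            element = parts[0]
            xyz = [float(v) for v in parts[1:4]]
            if len(parts) >= 7:
                name, resname, resid = parts[4], parts[5], int(parts[6])
            else:
                name, resname, resid = element, "UNK", 1
            atoms.append(AtomRecord(name, element, np.array(xyz), resname, resid))
        assign_molecule_ids(atoms)
        frames.append(Frame(time=t if t is not None else float(len(frames)), atoms=atoms, box=box))
        i += 2 + natoms
    return frames


def _write_xyz(frames: Sequence[Frame], path: Path) -> None:
    with open(path, "w") as fh:
        for f in frames:
            fh.write(f"{f.n_atoms}\n")
            parts = [f"time={f.time:.6f}"]
            if f.box is not None:
                parts.append('Lattice="{:.6f} {:.6f} {:.6f}"'.format(*f.box))
            fh.write(" ".join(parts) + "\n")
            for a in f.atoms:
                fh.write(
                    f"{a.element} {a.coords[0]:.6f} {a.coords[1]:.6f} {a.coords[2]:.6f} "
                    f"{a.atom_name} {a.residue_name} {a.residue_id}\n"
                )
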