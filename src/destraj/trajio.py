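"""Trajectory, topology and periodic-geometry primitives.

Coordinates are in Å and times in ps throughout the package.  Only
orthorhombic periodic cells are supported: every pairwise quantity in the
analysis modules goes through the minimum-image convention implemented
here.

File formats
------------
* extended XYZ — the comment line carries ``time=<ps>`` and
  ``box=<Lx>,<Ly>,<Lz>`` key/value items; optional columns 5–7 hold
  velocities in Å/ps.
* PDB — ATOM/HETATM records, MODEL/ENDMDL for multi-frame files (parsed
  with MDAnalysis).  PDB has no standard field for charges or
  Lennard-Jones parameters, so those come from a separate CSV parameter
  table keyed by site label (columns ``site_label,charge,D0,R0``).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MOLECULE_TYPES",
    "SimulationBox",
    "Topology",
    "Frame",
    "Trajectory",
    "SiteGroup",
    "TrajioError",
    "ParseError",
    "ValidationError",
    "load_topology",
    "load_trajectory",
    "write_xyz",
    "minimum_image",
    "minimum_image_displacement",
    "distance_matrix",
    "unwrap_positions",
]

#: recognised molecule types; anything else is mapped to "OTHER".
#: CH = choline cation, CL = chloride anion, CAP = caprylic acid,
#: LUA = lauric acid, WAT = water.
MOLECULE_TYPES = ("CAP", "LUA", "CH", "CL", "WAT", "OTHER")

# approximate atomic masses for centre-of-mass grouping; unlisted
# elements fall back to 12.0 (the analyses are insensitive to this --
# only COM grouping uses masses at all).
_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "CL": 35.453, "S": 32.06, "P": 30.974,
}


class TrajioError(Exception):
    """Base error for I/O and validation failures."""


class ParseError(TrajioError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(TrajioError):
    """Input parsed but violates a structural invariant."""


# --------------------------------------------------------------------------
# periodic cell
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationBox:
    """Orthorhombic periodic cell with edge lengths in Å."""

    lengths: np.ndarray
    orthorhombic: bool = True

    def __post_init__(self):
        lengths = np.asarray(self.lengths, dtype=float).reshape(3)
        if not np.all(lengths > 0):
            raise ValidationError(f"box lengths must be positive, got {lengths}")
        if not self.orthorhombic:
            raise ValidationError("only orthorhombic boxes are supported")
        object.__setattr__(self, "lengths", lengths)

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Wrap positions into [0, L) per axis."""
        return np.mod(positions, self.lengths)


def minimum_image(dvec: np.ndarray, box: SimulationBox) -> np.ndarray:
    """Apply the minimum-image convention to displacement vector(s).

    Each component of the result lies in (−L/2, L/2].
    """
    L = box.lengths
    # round-half-away from L/2: subtract floor(d/L + 1/2) images, then fix
    # the open/closed boundary so exactly −L/2 maps to +L/2.
    d = np.asarray(dvec, dtype=float)
    d = d - L * np.round(d / L)
    # np.round takes −L/2 to −L/2 (round-half-even); shift to +L/2
    d = np.where(d <= -L / 2, d + L, d)
    return d


# --------------------------------------------------------------------------
# topology
# --------------------------------------------------------------------------

@dataclass
class Topology:
    """Per-atom static information: site labels, molecule membership,
    partial charges (e) and Lennard-Jones well depth D0 (kcal/mol) /
    position of the minimum R0 (Å)."""

    site_labels: np.ndarray      # str
    elements: np.ndarray         # str
    molecule_ids: np.ndarray     # int
    molecule_types: np.ndarray   # str, one of MOLECULE_TYPES
    charges: np.ndarray          # e
    lj_depth: np.ndarray         # D0, kcal/mol
    lj_rmin: np.ndarray          # R0, Å

    def __post_init__(self):
        self.site_labels = np.asarray(self.site_labels, dtype=object)
        n = len(self.site_labels)
        self.elements = np.asarray(self.elements, dtype=object)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        self.molecule_types = np.asarray(self.molecule_types, dtype=object)
        self.charges = np.asarray(self.charges, dtype=float)
        self.lj_depth = np.asarray(self.lj_depth, dtype=float)
        self.lj_rmin = np.asarray(self.lj_rmin, dtype=float)
        for name in ("elements", "molecule_ids", "molecule_types",
                     "charges", "lj_depth", "lj_rmin"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"topology field {name!r} has length "
                                      f"{len(getattr(self, name))}, expected {n}")
        if not np.all(np.isfinite(self.charges)):
            raise ValidationError("charges must be finite")
        bad = set(self.molecule_types) - set(MOLECULE_TYPES)
        if bad:
            raise ValidationError(f"unknown molecule types {sorted(bad)}")

    @property
    def n_atoms(self) -> int:
        return len(self.site_labels)

    @property
    def masses(self) -> np.ndarray:
        return np.array([_MASSES.get(str(e).upper(), 12.0) for e in self.elements])

    def molecule_type_counts(self) -> dict:
        """Number of molecules of each type."""
        counts: dict = {}
        seen = {}
        for mid, mtype in zip(self.molecule_ids, self.molecule_types):
            if mid not in seen:
                seen[mid] = mtype
                counts[mtype] = counts.get(mtype, 0) + 1
        return counts

    def select(self, site_label: str | None = None,
               molecule_type: str | None = None) -> np.ndarray:
        """Atom indices matching a site label and/or molecule type."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if site_label is not None:
            mask &= self.site_labels == site_label
        if molecule_type is not None:
            mask &= self.molecule_types == molecule_type
        return np.nonzero(mask)[0]


@dataclass
class SiteGroup:
    """A named selection of atoms, analysed per atom or per molecule COM."""

    name: str
    indices: np.ndarray
    mode: str = "by_atom"          # or "by_molecule_com"

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValidationError(f"group {self.name!r}: duplicate indices")
        if self.mode not in ("by_atom", "by_molecule_com"):
            raise ValidationError(f"group {self.name!r}: unknown mode {self.mode!r}")


def as_indices(group) -> np.ndarray:
    """Accept a SiteGroup, an index array or a list of indices."""
    if isinstance(group, SiteGroup):
        return group.indices
    return np.asarray(group, dtype=int)


# --------------------------------------------------------------------------
# frames / trajectories
# --------------------------------------------------------------------------

@dataclass
class Frame:
    """One time point: positions (Å), optional velocities (Å/ps), box."""

    time: float
    positions: np.ndarray
    box: SimulationBox
    velocities: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError("positions must be (n_atoms, 3)")
        if self.time < 0:
            raise ValidationError("frame time must be non-negative")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValidationError("velocities shape mismatch")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """Time-ordered frames with uniform spacing and an associated topology."""

    frames: list
    topology: Topology
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.frames:
            raise ValidationError("trajectory must contain at least one frame")
        n = self.topology.n_atoms
        for k, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise ValidationError(
                    f"frame {k}: {fr.n_atoms} atoms, topology has {n}")
        times = np.array([fr.time for fr in self.frames])
        if len(times) > 1:
            dts = np.diff(times)
            if np.any(dts <= 0):
                raise ValidationError("frame times must be strictly increasing")
            if np.max(np.abs(dts - dts[0])) > 1e-9 * max(abs(times[-1]), 1.0):
                raise ValidationError("frame times must be uniformly spaced")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, k) -> Frame:
        return self.frames[k]

    @property
    def dt(self) -> float:
        """Timestep in ps (0 for a single frame)."""
        if len(self.frames) < 2:
            return 0.0
        return float(self.frames[1].time - self.frames[0].time)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    def positions_array(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked positions."""
        return np.stack([fr.positions for fr in self.frames])

    def velocities_array(self) -> np.ndarray:
        if any(fr.velocities is None for fr in self.frames):
            raise ValidationError("trajectory has no velocities")
        return np.stack([fr.velocities for fr in self.frames])


# --------------------------------------------------------------------------
# pairwise geometry
# --------------------------------------------------------------------------

def minimum_image_displacement(frame: Frame, i: int, j: int) -> np.ndarray:
    """Minimum-image displacement from atom ``i`` to atom ``j`` (Å)."""
    return minimum_image(frame.positions[j] - frame.positions[i], frame.box)


def distance_matrix(frame: Frame, idx_a: Sequence[int],
                    idx_b: Sequence[int]) -> np.ndarray:
    """Minimum-image distances between two index sets, shape (|A|, |B|)."""
    pa = frame.positions[np.asarray(idx_a, dtype=int)]
    pb = frame.positions[np.asarray(idx_b, dtype=int)]
    d = pb[None, :, :] - pa[:, None, :]
    d = minimum_image(d, frame.box)
    return np.sqrt(np.sum(d * d, axis=-1))


def unwrap_positions(traj: Trajectory,
                     indices: Sequence[int] | None = None) -> np.ndarray:
    """Unwrap periodic coordinates by accumulating minimum-image
    frame-to-frame displacements.

    Valid when no particle moves further than L/2 between consecutive
    frames.  Returns (n_frames, n_sel, 3).
    """
    pos = traj.positions_array()
    if indices is not None:
        pos = pos[:, np.asarray(indices, dtype=int), :]
    out = np.empty_like(pos)
    out[0] = pos[0]
    for k in range(1, pos.shape[0]):
        step = minimum_image(pos[k] - pos[k - 1], traj.frames[k].box)
        out[k] = out[k - 1] + step
    return out


def group_com_positions(traj: Trajectory, group: SiteGroup) -> np.ndarray:
    """Per-entity coordinate series for a group: raw atomic positions for
    ``by_atom`` groups, per-molecule mass-weighted centres (on unwrapped
    coordinates) for ``by_molecule_com``.  Returns (n_frames, n_entities, 3).
    """
    idx = as_indices(group)
    unwrapped = unwrap_positions(traj, idx)
    if getattr(group, "mode", "by_atom") == "by_atom":
        return unwrapped
    mids = traj.topology.molecule_ids[idx]
    masses = traj.topology.masses[idx]
    out = []
    for mid in np.unique(mids):
        sel = mids == mid
        w = masses[sel] / masses[sel].sum()
        out.append(np.einsum("fkx,k->fx", unwrapped[:, sel, :], w))
    return np.stack(out, axis=1)


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

_TABLE_COLUMNS = ["site_label", "element", "molecule_id", "molecule_type",
                  "charge", "D0", "R0"]


def _read_param_table(path_or_df) -> pd.DataFrame:
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(path_or_df, sep=None, engine="python",
                         skipinitialspace=True)
    required = {"site_label", "charge", "D0", "R0"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"parameter table missing column(s): {sorted(missing)}")
    return df


def load_topology(path, format: str = "table", params=None) -> Topology:
    """Read a topology from a per-atom CSV table or a PDB file.

    ``format='table'``: CSV with columns ``index`` (optional),
    ``site_label, element, molecule_id, molecule_type, charge, D0, R0``.

    ``format='PDB'``: atom names become site labels, residue ids molecule
    ids, residue names molecule types (unknown names map to OTHER);
    charges and LJ parameters are merged in from ``params`` (CSV path or
    DataFrame keyed by site_label), defaulting to zero when absent.
    """
    fmt = format.upper()
    if fmt == "TABLE":
        try:
            df = pd.read_csv(path, sep=None, engine="python",
                             skipinitialspace=True)
        except Exception as exc:                         # pragma: no cover
            raise ParseError(f"cannot parse topology table {path}: {exc}")
        missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(
                f"topology table missing column(s): {missing}")
        if "index" in df.columns and df["index"].duplicated().any():
            dup = df.loc[df["index"].duplicated(), "index"].iloc[0]
            raise ValidationError(f"duplicate atom index {dup} in topology table")
        if df["charge"].isna().any():
            row = int(df.index[df["charge"].isna()][0]) + 2
            raise ParseError(f"missing charge value at line {row} of {path}")
        mtypes = [m if m in MOLECULE_TYPES else "OTHER"
                  for m in df["molecule_type"].astype(str)]
        return Topology(
            site_labels=df["site_label"].astype(str).to_numpy(),
            elements=df["element"].astype(str).to_numpy(),
            molecule_ids=df["molecule_id"].to_numpy(),
            molecule_types=np.array(mtypes, dtype=object),
            charges=df["charge"].to_numpy(float),
            lj_depth=df["D0"].to_numpy(float),
            lj_rmin=df["R0"].to_numpy(float),
        )
    elif fmt == "PDB":
        import MDAnalysis as mda
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
        names = u.atoms.names.astype(object)
        try:
            elements = u.atoms.elements.astype(object)
        except Exception:
            elements = np.array([str(n)[0] for n in names], dtype=object)
        resids = u.atoms.resids
        resnames = [r if r in MOLECULE_TYPES else "OTHER"
                    for r in u.atoms.resnames]
        charges = np.zeros(len(names))
        d0 = np.zeros(len(names))
        r0 = np.zeros(len(names))
        if params is not None:
            table = _read_param_table(params).set_index("site_label")
            for k, name in enumerate(names):
                if name in table.index:
                    row = table.loc[name]
                    charges[k] = row["charge"]
                    d0[k] = row["D0"]
                    r0[k] = row["R0"]
        return Topology(names, elements, resids, np.array(resnames, dtype=object),
                        charges, d0, r0)
    raise ValueError(f"unknown topology format {format!r}")


def _parse_xyz_comment(line: str, lineno: int) -> dict:
    out = {}
    for tok in line.split():
        if "=" in tok:
            key, _, val = tok.partition("=")
            out[key] = val
    return out


def load_trajectory(path, format: str = "XYZ", topology: Topology | None = None,
                    box: SimulationBox | None = None) -> Trajectory:
    """Read a trajectory from extended XYZ or multi-model PDB.

    XYZ comment lines must carry ``box=Lx,Ly,Lz`` (unless a global ``box``
    is supplied) and may carry ``time=<ps>``; frames without times are
    numbered 0, 1, 2, … ps.
    """
    fmt = format.upper()
    if topology is None:
        raise ValidationError("a topology is required to load a trajectory")
    if fmt == "XYZ":
        frames = []
        with open(path) as fh:
            lines = fh.read().splitlines()
        k = 0
        frame_no = 0
        while k < len(lines):
            if not lines[k].strip():
                k += 1
                continue
            try:
                n = int(lines[k].split()[0])
            except ValueError:
                raise ParseError(f"{path}:{k+1}: expected atom count, got "
                                 f"{lines[k]!r}")
            if n != topology.n_atoms:
                raise ValidationError(
                    f"frame {frame_no}: {n} atoms, topology has "
                    f"{topology.n_atoms}")
            meta = _parse_xyz_comment(lines[k + 1], k + 2)
            if "box" in meta:
                try:
                    fbox = SimulationBox(
                        [float(x) for x in meta["box"].split(",")])
                except Exception:
                    raise ParseError(f"{path}:{k+2}: malformed box "
                                     f"{meta['box']!r}")
            elif box is not None:
                fbox = box
            else:
                raise ValidationError(
                    f"frame {frame_no}: no box in comment line and no "
                    "global box supplied")
            t = float(meta.get("time", frame_no))
            pos = np.empty((n, 3))
            vel = None
            for a in range(n):
                parts = lines[k + 2 + a].split()
                if len(parts) < 4:
                    raise ParseError(f"{path}:{k+3+a}: short atom record")
                pos[a] = [float(x) for x in parts[1:4]]
                if len(parts) >= 7:
                    if vel is None:
                        vel = np.zeros((n, 3))
                    vel[a] = [float(x) for x in parts[4:7]]
            frames.append(Frame(t, pos, fbox, vel))
            k += 2 + n
            frame_no += 1
        return Trajectory(frames, topology)
    elif fmt in ("PDB", "PDB_MULTIMODEL"):
        import MDAnalysis as mda
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
        frames = []
        for k, ts in enumerate(u.trajectory):
            if len(u.atoms) != topology.n_atoms:
                raise ValidationError(
                    f"frame {k}: {len(u.atoms)} atoms, topology has "
                    f"{topology.n_atoms}")
            dims = ts.dimensions
            if dims is not None and np.all(dims[:3] > 0):
                fbox = SimulationBox(dims[:3])
            elif box is not None:
                fbox = box
            else:
                raise ValidationError(f"frame {k}: no box in PDB CRYST1 "
                                      "and no global box supplied")
            frames.append(Frame(float(k), u.atoms.positions.copy(), fbox))
        return Trajectory(frames, topology)
    raise ValueError(f"unknown trajectory format {format!r}")


def write_xyz(traj: Trajectory, path, precision: int = 8) -> None:
    """Write a trajectory in the package's extended-XYZ dialect."""
    fmt = f"%.{precision}f"
    with open(path, "w") as fh:
        for fr in traj.frames:
            fh.write(f"{fr.n_atoms}\n")
            bx = ",".join(fmt % v for v in fr.box.lengths)
            fh.write(f"time={fmt % fr.time} box={bx}\n")
            for a in range(fr.n_atoms):
                label = traj.topology.site_labels[a]
                row = " ".join(fmt % v for v in fr.positions[a])
                if fr.velocities is not None:
                    row += " " + " ".join(fmt % v for v in fr.velocities[a])
                fh.write(f"{label} {row}\n")


def write_topology_csv(top: Topology, path) -> None:
    df = pd.DataFrame({
        "index": np.arange(top.n_atoms),
        "site_label": top.site_labels,
        "element": top.elements,
        "molecule_id": top.molecule_ids,
        "molecule_type": top.molecule_types,
        "charge": top.charges,
        "D0": top.lj_depth,
        "R0": top.lj_rmin,
    })
    df.to_csv(path, index=False)
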