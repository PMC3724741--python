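"""Core domain types, periodic geometry and file I/O for coarse-grained
membrane trajectories.

The in-memory model is deliberately small: a :class:`Topology` holding static
per-bead metadata (molecule id/type, residue index, bead role, bead radius),
a :class:`TrajectoryFrame` holding timestamped positions with an orthorhombic
periodic box, and a :class:`Trajectory` as an ordered, constant-spacing frame
sequence.  All distance computations in the package go through the
minimum-image convention implemented here.

Units: lengths in nm, times in ns throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "MoleculeType",
    "BeadRole",
    "Topology",
    "TrajectoryFrame",
    "Trajectory",
    "AnalysisWindow",
    "GeometryError",
    "GroParseError",
    "TopologyError",
    "minimum_image",
    "wrap_positions",
    "periodic_pairs",
    "read_gro",
    "write_gro",
    "read_topology_table",
    "write_topology_table",
    "DEFAULT_BEAD_RADIUS",
    "D_UNIT_NM2_PER_NS",
]

#: one unit of the conventional lateral-diffusion scale, 1e-8 cm^2/s, in nm^2/ns
D_UNIT_NM2_PER_NS = 1.0e-3

#: default coarse-grained bead radius (nm), half the standard 0.52 nm bead
#: interaction diameter
DEFAULT_BEAD_RADIUS = 0.26

#: GRO integer fields (residue and atom serial) wrap at this value
GRO_FIELD_WRAP = 100_000


class GeometryError(ValueError):
    """Invalid periodic geometry (non-positive or triclinic box, bad cutoff)."""


class GroParseError(ValueError):
    """Malformed GRO file; message names the offending line number."""


class TopologyError(ValueError):
    """Topology table violates a structural invariant."""


class MoleculeType(str, Enum):
    PROTEIN = "PROTEIN"
    DPPC = "DPPC"
    DLIPC = "DLIPC"
    CHOL = "CHOL"
    OTHER = "OTHER"


class BeadRole(str, Enum):
    BACKBONE = "BACKBONE"
    SIDECHAIN = "SIDECHAIN"
    LIPID_TAIL = "LIPID_TAIL"
    HEADGROUP = "HEADGROUP"
    OTHER = "OTHER"


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------

def _check_box(box: np.ndarray) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    if box.shape != (3,):
        raise GeometryError(f"box must be three edge lengths, got shape {box.shape}")
    if not np.all(box > 0):
        raise GeometryError(f"box edges must be strictly positive, got {box}")
    return box


def minimum_image(p1, p2, box) -> np.ndarray:
    """Displacement ``p2 - p1`` with every component wrapped into (-L/2, +L/2].

    Accepts single 3-vectors or ``(n, 3)`` arrays (broadcast elementwise).
    """
    box = _check_box(box)
    d = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    # ceil(d/L - 1/2) maps the component into the half-open interval (-L/2, L/2]
    return d - box * np.ceil(d / box - 0.5)


def wrap_positions(pos: np.ndarray, box) -> np.ndarray:
    """Wrap coordinates into [0, L) per axis."""
    box = _check_box(box)
    wrapped = np.mod(np.asarray(pos, dtype=float), box)
    # mod of a tiny negative value can round up to exactly L; fold it back
    wrapped[wrapped >= box] = 0.0
    return wrapped


def periodic_pairs(positions: np.ndarray, box, cutoff: float,
                   subset: np.ndarray | None = None) -> np.ndarray:
    """All unordered index pairs within `cutoff` under periodic minimum image.

    Uses a periodic k-d tree (near-linear neighbor search).  Returns an
    ``(n_pairs, 2)`` int array of indices into `positions` (or into `subset`
    positions mapped back to original indices when `subset` is given).
    The contact interval is closed: a pair exactly at `cutoff` is included.
    """
    box = _check_box(box)
    if cutoff <= 0:
        raise GeometryError("cutoff must be positive")
    if cutoff > box.min() / 2:
        raise GeometryError(
            f"cutoff {cutoff} nm exceeds half the smallest box edge "
            f"({box.min() / 2} nm); minimum image is ambiguous"
        )
    pos = np.asarray(positions, dtype=float)
    idx = np.arange(len(pos)) if subset is None else np.asarray(subset)
    if subset is not None:
        pos = pos[idx]
    if len(pos) < 2:
        return np.empty((0, 2), dtype=int)
    tree = cKDTree(np.mod(pos, box), boxsize=box)
    # tiny epsilon makes the criterion effectively closed at the cutoff
    pairs = tree.query_pairs(cutoff * (1 + 1e-12), output_type="ndarray")
    return idx[pairs] if len(pairs) else np.empty((0, 2), dtype=int)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

_TOPOLOGY_COLUMNS = ["bead_id", "molecule_id", "molecule_type",
                     "residue_index", "bead_role", "bead_radius"]

#: protein sizes used throughout: 186 residues full-length, 166 G-domain only
CANONICAL_PROTEIN_SIZES = (186, 166)


@dataclass
class Topology:
    """Static per-bead metadata, index-aligned with frame positions.

    Residue indices are 1-based within each molecule (matching conventional
    protein residue numbering); bead indices are 0-based.
    """

    molecule_id: np.ndarray
    molecule_type: np.ndarray  # array of str, values of MoleculeType
    residue_index: np.ndarray
    bead_role: np.ndarray      # array of str, values of BeadRole
    bead_radius: np.ndarray

    def __post_init__(self) -> None:
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        self.molecule_type = np.asarray(self.molecule_type, dtype="U16")
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.bead_role = np.asarray(self.bead_role, dtype="U16")
        self.bead_radius = np.asarray(self.bead_radius, dtype=float)
        n = len(self.molecule_id)
        for name in ("molecule_type", "residue_index", "bead_role", "bead_radius"):
            if len(getattr(self, name)) != n:
                raise TopologyError(f"column {name} has length "
                                    f"{len(getattr(self, name))}, expected {n}")

    def __len__(self) -> int:
        return len(self.molecule_id)

    @property
    def n_beads(self) -> int:
        return len(self)

    # -- masks -------------------------------------------------------------
    @property
    def is_protein(self) -> np.ndarray:
        return self.molecule_type == MoleculeType.PROTEIN.value

    @property
    def is_backbone(self) -> np.ndarray:
        return self.bead_role == BeadRole.BACKBONE.value

    @property
    def protein_backbone(self) -> np.ndarray:
        return self.is_protein & self.is_backbone

    def lipid_mask(self, kinds: Iterable[MoleculeType | str] | None = None) -> np.ndarray:
        """Beads belonging to lipid species (DPPC, DLiPC, CHOL by default)."""
        if kinds is None:
            kinds = (MoleculeType.DPPC, MoleculeType.DLIPC, MoleculeType.CHOL)
        names = {MoleculeType(k).value for k in kinds}
        return np.isin(self.molecule_type, sorted(names))

    @property
    def protein_ids(self) -> np.ndarray:
        """Sorted unique molecule ids of proteins."""
        return np.unique(self.molecule_id[self.is_protein])

    def protein_sizes(self) -> dict[int, int]:
        """Residues per protein, keyed by molecule id."""
        out: dict[int, int] = {}
        for mol in self.protein_ids:
            sel = (self.molecule_id == mol) & self.is_protein
            out[int(mol)] = int(np.unique(self.residue_index[sel]).size)
        return out

    # -- validation --------------------------------------------------------
    def validate(self, strict_sizes: bool = False) -> "Topology":
        """Check structural invariants; returns self for chaining.

        Each protein must carry exactly one backbone bead per residue and a
        contiguous 1..N_r residue range.  With ``strict_sizes=True``, N_r must
        additionally be one of the canonical protein sizes (186 or 166).
        """
        bad_type = ~np.isin(self.molecule_type, [m.value for m in MoleculeType])
        if np.any(bad_type):
            raise TopologyError(
                f"unknown molecule_type token(s): "
                f"{sorted(set(self.molecule_type[bad_type]))}")
        bad_role = ~np.isin(self.bead_role, [r.value for r in BeadRole])
        if np.any(bad_role):
            raise TopologyError(
                f"unknown bead_role token(s): {sorted(set(self.bead_role[bad_role]))}")
        if np.any(self.bead_radius <= 0):
            raise TopologyError("bead_radius must be > 0 for every bead")
        for mol in self.protein_ids:
            sel = (self.molecule_id == mol) & self.is_protein
            bb = self.residue_index[sel & self.is_backbone]
            residues = np.unique(self.residue_index[sel])
            n_r = residues.size
            if residues[0] != 1 or residues[-1] != n_r:
                raise TopologyError(
                    f"protein {mol}: residue indices must span 1..N_r "
                    f"contiguously, got range {residues[0]}..{residues[-1]} "
                    f"with {n_r} distinct values")
            counts = np.bincount(bb, minlength=n_r + 1)[1:n_r + 1]
            if np.any(counts > 1):
                dup = int(np.argwhere(counts > 1)[0, 0] + 1)
                raise TopologyError(
                    f"protein {mol}: duplicate BACKBONE bead for residue {dup}")
            if np.any(counts < 1):
                missing = int(np.argwhere(counts < 1)[0, 0] + 1)
                raise TopologyError(
                    f"protein {mol}: no BACKBONE bead for residue {missing}")
            if strict_sizes and n_r not in CANONICAL_PROTEIN_SIZES:
                raise TopologyError(
                    f"protein {mol} has {n_r} residues; expected one of "
                    f"{CANONICAL_PROTEIN_SIZES}")
        return self

    # -- pandas bridge -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bead_id": np.arange(len(self)),
            "molecule_id": self.molecule_id,
            "molecule_type": self.molecule_type,
            "residue_index": self.residue_index,
            "bead_role": self.bead_role,
            "bead_radius": self.bead_radius,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Topology":
        missing = [c for c in _TOPOLOGY_COLUMNS if c not in df.columns]
        if missing:
            raise TopologyError(f"topology table missing column(s): {missing}")
        order = np.argsort(df["bead_id"].to_numpy())
        df = df.iloc[order]
        ids = df["bead_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(ids))):
            raise TopologyError("bead_id must be 0..n-1 without gaps")
        return cls(
            molecule_id=df["molecule_id"].to_numpy(),
            molecule_type=df["molecule_type"].to_numpy(dtype="U16"),
            residue_index=df["residue_index"].to_numpy(),
            bead_role=df["bead_role"].to_numpy(dtype="U16"),
            bead_radius=df["bead_radius"].to_numpy(dtype=float),
        )

    @staticmethod
    def concatenate(parts: Sequence["Topology"]) -> "Topology":
        return Topology(
            molecule_id=np.concatenate([p.molecule_id for p in parts]),
            molecule_type=np.concatenate([p.molecule_type for p in parts]),
            residue_index=np.concatenate([p.residue_index for p in parts]),
            bead_role=np.concatenate([p.bead_role for p in parts]),
            bead_radius=np.concatenate([p.bead_radius for p in parts]),
        )


def read_topology_table(path_or_buf) -> Topology:
    """Read a TSV/CSV topology table and validate it.

    Expected columns: bead_id, molecule_id, molecule_type, residue_index,
    bead_role, bead_radius.  Separator is sniffed (tab or comma).
    """
    df = pd.read_csv(path_or_buf, sep=None, engine="python")
    return Topology.from_frame(df).validate()


def write_topology_table(topo: Topology, path_or_buf, sep: str = "\t") -> None:
    topo.to_frame().to_csv(path_or_buf, sep=sep, index=False)


# ---------------------------------------------------------------------------
# frames and trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryFrame:
    """One timestamped frame: positions (nm) plus orthorhombic box (nm)."""

    time: float
    box: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.box = _check_box(self.box)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise GeometryError(
                f"positions must be (n, 3), got {self.positions.shape}")

    @property
    def n_beads(self) -> int:
        return len(self.positions)


TIME_TOLERANCE_NS = 1e-6


@dataclass
class Trajectory:
    """Ordered frame sequence with strictly increasing, constant-spaced times."""

    frames: list[TrajectoryFrame]
    topology: Topology | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        t = self.times
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("frame times must be strictly increasing")
            if np.any(np.abs(dt - dt[0]) > TIME_TOLERANCE_NS):
                raise ValueError(
                    f"frame spacing is not constant: spacings range "
                    f"{dt.min()}..{dt.max()} ns")
        if self.topology is not None:
            n = self.topology.n_beads
            for i, fr in enumerate(self.frames):
                if fr.n_beads != n:
                    raise ValueError(
                        f"frame {i} has {fr.n_beads} beads, topology has {n}")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def spacing(self) -> float:
        t = self.times
        if len(t) < 2:
            raise ValueError("spacing undefined for a single-frame trajectory")
        return float(t[1] - t[0])

    def window(self, win: "AnalysisWindow") -> "Trajectory":
        sel = [f for f in self.frames if win.t_start - TIME_TOLERANCE_NS
               <= f.time <= win.t_end + TIME_TOLERANCE_NS]
        if not sel:
            raise ValueError(f"no frames inside window {win}")
        return Trajectory(sel, self.topology)


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-closed-feeling time window [t_start, t_end] in ns."""

    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(
                f"t_start ({self.t_start}) must be < t_end ({self.t_end})")

    @property
    def length(self) -> float:
        return self.t_end - self.t_start


# ---------------------------------------------------------------------------
# GRO I/O
# ---------------------------------------------------------------------------

@dataclass
class GroAtoms:
    """Raw per-atom GRO metadata: the topology skeleton of a parsed file.

    ``residue_serial`` is a wrap-corrected 0-based running residue counter
    (the stored residue field wraps at 100000; the counter advances on every
    change of the raw field, so large systems reindex correctly).
    """

    resid_raw: np.ndarray
    resname: np.ndarray
    atomname: np.ndarray
    residue_serial: np.ndarray


def _open_maybe(path_or_buf, mode: str):
    if hasattr(path_or_buf, "read") or hasattr(path_or_buf, "write"):
        return path_or_buf, False
    return open(path_or_buf, mode), True


def read_gro(path_or_buf) -> tuple[GroAtoms, list[TrajectoryFrame]]:
    """Parse a (possibly multi-frame, concatenated) GRO coordinate file.

    Returns the atom metadata of the first frame plus one
    :class:`TrajectoryFrame` per frame.  Times are taken from ``t=`` markers
    in title lines when present, else frame index.  Only orthorhombic boxes
    are accepted.
    """
    fh, close = _open_maybe(path_or_buf, "r")
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()

    frames: list[TrajectoryFrame] = []
    atoms: GroAtoms | None = None
    ln = 0
    n_total = len(lines)
    frame_idx = 0
    while ln < n_total:
        if not lines[ln].strip() and ln == n_total - 1:
            break
        title = lines[ln]
        ln += 1
        if ln >= n_total:
            raise GroParseError(f"line {ln + 1}: missing atom-count line")
        try:
            n_atoms = int(lines[ln].strip())
        except ValueError as exc:
            raise GroParseError(
                f"line {ln + 1}: malformed atom-count line "
                f"{lines[ln]!r}") from exc
        ln += 1
        if ln + n_atoms > n_total:
            raise GroParseError(
                f"line {ln + 1}: expected {n_atoms} atom lines, file ends early")

        block = lines[ln:ln + n_atoms]
        try:
            pos = np.array(
                [[float(l[20:28]), float(l[28:36]), float(l[36:44])]
                 for l in block])
        except (ValueError, IndexError) as exc:
            raise GroParseError(
                f"atom line near line {ln + 1}: malformed coordinates") from exc
        if atoms is None:
            resid_raw = np.array([int(l[0:5]) for l in block])
            resname = np.array([l[5:10].strip() for l in block], dtype="U8")
            atomname = np.array([l[10:15].strip() for l in block], dtype="U8")
            serial = np.zeros(n_atoms, dtype=int)
            if n_atoms:
                changed = np.empty(n_atoms, dtype=bool)
                changed[0] = False
                changed[1:] = resid_raw[1:] != resid_raw[:-1]
                serial = np.cumsum(changed)
            atoms = GroAtoms(resid_raw, resname, atomname, serial)
        ln += n_atoms

        if ln >= n_total:
            raise GroParseError(f"line {ln + 1}: missing box line")
        box_fields = lines[ln].split()
        ln += 1
        try:
            vals = [float(v) for v in box_fields]
        except ValueError as exc:
            raise GroParseError(f"line {ln}: malformed box line") from exc
        if len(vals) == 3:
            box = np.array(vals)
        elif len(vals) == 9:
            if any(abs(v) > 1e-12 for v in vals[3:]):
                raise GeometryError(
                    f"line {ln}: triclinic box (nonzero off-diagonal terms) "
                    "is not supported")
            box = np.array(vals[:3])
        else:
            raise GroParseError(
                f"line {ln}: box line must have 3 or 9 fields, got {len(vals)}")

        time = float(frame_idx)
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        frames.append(TrajectoryFrame(time=time, box=box, positions=pos))
        frame_idx += 1

    if atoms is None:
        raise GroParseError("line 1: empty GRO file")
    return atoms, frames


def write_gro(path_or_buf, frames: TrajectoryFrame | Sequence[TrajectoryFrame],
              resid: np.ndarray | None = None,
              resname: np.ndarray | None = None,
              atomname: np.ndarray | None = None,
              title: str = "cgagg frame") -> None:
    """Write one or more frames as concatenated fixed-column GRO.

    Residue and atom serial fields wrap at 100000 per the format's fixed
    field width.  Missing name arrays default to generic bead labels.
    """
    if isinstance(frames, TrajectoryFrame):
        frames = [frames]
    n = frames[0].n_beads
    if resid is None:
        resid = np.arange(1, n + 1)
    if resname is None:
        resname = np.full(n, "BEAD", dtype="U8")
    if atomname is None:
        atomname = np.full(n, "CG", dtype="U8")

    fh, close = _open_maybe(path_or_buf, "w")
    try:
        for fr in frames:
            fh.write(f"{title} t= {fr.time:.4f}\n")
            fh.write(f"{fr.n_beads:5d}\n")
            for i in range(fr.n_beads):
                x, y, z = fr.positions[i]
                fh.write(
                    f"{int(resid[i]) % GRO_FIELD_WRAP:5d}"
                    f"{resname[i]:<5s}{atomname[i]:>5s}"
                    f"{(i + 1) % GRO_FIELD_WRAP:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
            bx, by, bz = fr.box
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")
    finally:
        if close:
            fh.close()


def gro_string(frames, **kwargs) -> str:
    """Render frames as a GRO-format string (convenience for tests/fixtures)."""
    buf = io.StringIO()
    write_gro(buf, frames, **kwargs)
    return buf.getvalue()
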