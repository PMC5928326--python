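"""Readers/writers for the plain-text formats the toolkit consumes and the
shared molecular data model.

Supported formats: fixed-column (multi-frame) GRO, XYZ, a GROMOS-style ITP
subset ([atoms] with charge-group column, [bonds], [dihedrals]), XVG-like
whitespace tables with ``#``/``@`` comments, and CSV site reports.

Unit conventions (GROMOS/GROMACS): lengths nm, time ps, energies kJ/mol,
charges e, temperature K, pressure bar.  XYZ files are read as Angstrom and
converted to nm.  Atom indices are 1-based in files and in every public API;
internal arrays are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "MoleculeTopology",
    "TrajectoryFrame",
    "ObservableTable",
    "FormatError",
    "StructureError",
    "ChargeSumWarning",
    "REPORT_COLUMNS",
    "read_coordinates",
    "write_coordinates",
    "read_topology_subset",
    "write_topology_subset",
    "read_observable_table",
    "write_observable_table",
    "write_report",
    "read_report",
    "attach_coordinates",
]

ANGSTROM_TO_NM = 0.1

#: Column order of the per-site water-interaction report.
REPORT_COLUMNS = [
    "Molecule", "Atom", "Aver_HB", "tau_HB", "lifetime_HB", "dG_HB",
    "Percent", "CN", "OBD_HB", "Orientation",
]


class FormatError(ValueError):
    """A file does not parse under the declared dialect."""


class StructureError(ValueError):
    """A file parses but is internally inconsistent (e.g. ragged frames)."""


class ChargeSumWarning(UserWarning):
    """Charge-group or net-charge sums are non-integral (tolerated mid-fit)."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """One atom: 1-based index, name, element, position (nm), partial charge
    (e), charge-group id and mass (u)."""

    index: int
    name: str
    element: str
    position: np.ndarray | None = None
    partial_charge: float = 0.0
    charge_group_id: int = 1
    mass: float = 0.0

    def __post_init__(self) -> None:
        if self.position is not None:
            self.position = np.asarray(self.position, dtype=float)
            if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
                raise ValueError(f"atom {self.index}: position must be a finite 3-vector")


@dataclass
class MoleculeTopology:
    """A molecule: ordered atoms, bonds and dihedrals (1-based index tuples),
    and the declared integer net charge (e)."""

    name: str
    atoms: list[AtomRecord]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int, str]] = field(default_factory=list)
    net_charge: int = 0

    def __post_init__(self) -> None:
        idx = [a.index for a in self.atoms]
        if len(set(idx)) != len(idx):
            raise ValueError("atom indices must be unique within a molecule")
        known = set(idx)
        for b in self.bonds:
            if b[0] not in known or b[1] not in known:
                raise ValueError(f"bond {b} references unknown atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def positions(self) -> np.ndarray:
        if any(a.position is None for a in self.atoms):
            raise ValueError(f"molecule {self.name!r} has atoms without coordinates")
        return np.array([a.position for a in self.atoms], dtype=float)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def charge_groups(self) -> dict[int, list[int]]:
        """Map charge_group_id -> 1-based atom indices, in file order."""
        groups: dict[int, list[int]] = {}
        for a in self.atoms:
            groups.setdefault(a.charge_group_id, []).append(a.index)
        return groups

    def validate_charge_sums(self, tol: float = 1e-6, strict: bool = False) -> bool:
        """Check net-charge and per-group integer charge sums.

        Returns True when consistent; otherwise warns (or raises when
        ``strict``).  Tolerant by default because mid-fit inputs may carry
        non-integral group sums.
        """
        q = self.charges()
        ok = True
        msgs = []
        if abs(q.sum() - self.net_charge) > tol:
            ok = False
            msgs.append(f"net charge {q.sum():.6f} != declared {self.net_charge}")
        for gid, members in self.charge_groups().items():
            s = sum(self.atoms[i - 1].partial_charge for i in members)
            if abs(s - round(s)) > tol:
                ok = False
                msgs.append(f"charge group {gid} sums to {s:.6f} (non-integer)")
        if not ok:
            msg = f"molecule {self.name!r}: " + "; ".join(msgs)
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, ChargeSumWarning, stacklevel=2)
        return ok


@dataclass
class TrajectoryFrame:
    """One frame: time (ps), N x 3 coordinates (nm), orthorhombic box (nm)."""

    time: float
    coordinates: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be N x 3")
        if self.box.shape != (3,):
            raise NotImplementedError(
                "only orthorhombic boxes (3 edge lengths) are supported; "
                "triclinic input must be converted externally"
            )
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


class ObservableTable:
    """Time-stamped numeric observables (XVG-like carrier).

    Thin wrapper over a DataFrame whose first column is time (ps); remaining
    columns carry one observable each with units declared per column.
    """

    def __init__(self, data: pd.DataFrame, units: dict[str, str] | None = None):
        if data.shape[1] < 1:
            raise ValueError("observable table needs at least a time column")
        if len(data) == 0:
            raise ValueError("observable table is empty")
        t = data.iloc[:, 0].to_numpy()
        if np.any(np.diff(t) < 0):
            raise StructureError("time column must be non-decreasing")
        self.data = data.reset_index(drop=True)
        self.units = dict(units or {})

    @property
    def time(self) -> np.ndarray:
        return self.data.iloc[:, 0].to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# coordinate files
# ---------------------------------------------------------------------------

def read_coordinates(path, fmt: str = "gro") -> list[TrajectoryFrame]:
    """Read a (possibly multi-frame) GRO or XYZ file into frames, file order.

    GRO positions are nm; XYZ positions are Angstrom, converted to nm.
    Malformed lines raise :class:`FormatError` naming the line number;
    an inconsistent atom count across frames raises :class:`StructureError`.
    """
    fmt = fmt.lower()
    if fmt == "gro":
        frames = _read_gro(path)
    elif fmt == "xyz":
        frames = _read_xyz(path)
    else:
        raise ValueError(f"unknown coordinate format {fmt!r} (expected 'gro' or 'xyz')")
    counts = {f.n_atoms for f in frames}
    if len(counts) > 1:
        raise StructureError(f"{path}: inconsistent atom counts across frames: {sorted(counts)}")
    return frames


def _read_gro(path) -> list[TrajectoryFrame]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: list[TrajectoryFrame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():  # trailing blank lines
            i += 1
            continue
        title = lines[i]
        time = 0.0
        if "t=" in title:
            try:
                time = float(title.rsplit("t=", 1)[1].split()[0])
            except (ValueError, IndexError):
                pass
        try:
            natoms = int(lines[i + 1].strip())
        except (ValueError, IndexError):
            raise FormatError(f"{path}: line {i + 2}: expected atom count") from None
        atom_lines = lines[i + 2 : i + 2 + natoms]
        if len(atom_lines) < natoms:
            raise FormatError(f"{path}: truncated frame starting at line {i + 1}")
        coords = np.empty((natoms, 3))
        for j, ln in enumerate(atom_lines):
            lineno = i + 3 + j
            try:
                coords[j] = (float(ln[20:28]), float(ln[28:36]), float(ln[36:44]))
            except (ValueError, IndexError):
                raise FormatError(f"{path}: line {lineno}: malformed GRO atom line") from None
        box_lineno = i + 2 + natoms
        if box_lineno >= len(lines):
            raise FormatError(f"{path}: missing box line after line {box_lineno}")
        box_fields = lines[box_lineno].split()
        if len(box_fields) < 3:
            raise FormatError(f"{path}: line {box_lineno + 1}: malformed box line")
        if len(box_fields) > 3 and any(float(v) != 0.0 for v in box_fields[3:]):
            raise NotImplementedError(f"{path}: triclinic box unsupported (line {box_lineno + 1})")
        box = np.array([float(v) for v in box_fields[:3]])
        frames.append(TrajectoryFrame(time=time, coordinates=coords, box=box))
        i = box_lineno + 1
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return frames


def write_coordinates(path, frames, fmt: str = "gro", names=None, resname: str = "MOL") -> None:
    """Write frames as multi-frame GRO (nm) or XYZ (Angstrom)."""
    fmt = fmt.lower()
    frames = list(frames)
    n = frames[0].n_atoms
    if names is None:
        names = [f"A{i + 1}" for i in range(n)]
    with open(path, "w") as fh:
        for fr in frames:
            if fmt == "gro":
                fh.write(f"{resname} t= {fr.time:.4f}\n{fr.n_atoms:5d}\n")
                for i, xyz in enumerate(fr.coordinates):
                    fh.write(
                        f"{1:5d}{resname:<5s}{names[i]:>5s}{i + 1:5d}"
                        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}\n"
                    )
                fh.write(f"{fr.box[0]:10.5f}{fr.box[1]:10.5f}{fr.box[2]:10.5f}\n")
            elif fmt == "xyz":
                fh.write(f"{fr.n_atoms}\nt= {fr.time:.4f}\n")
                for i, xyz in enumerate(fr.coordinates):
                    a = xyz / ANGSTROM_TO_NM
                    fh.write(f"{names[i]:<4s} {a[0]:12.6f} {a[1]:12.6f} {a[2]:12.6f}\n")
            else:
                raise ValueError(f"unknown coordinate format {fmt!r}")


def _read_xyz(path) -> list[TrajectoryFrame]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: list[TrajectoryFrame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"{path}: line {i + 1}: expected atom count") from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        time = 0.0
        if "t=" in comment:
            try:
                time = float(comment.rsplit("t=", 1)[1].split()[0])
            except (ValueError, IndexError):
                pass
        atom_lines = lines[i + 2 : i + 2 + natoms]
        if len(atom_lines) < natoms:
            raise FormatError(f"{path}: truncated frame starting at line {i + 1}")
        coords = np.empty((natoms, 3))
        for j, ln in enumerate(atom_lines):
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(f"{path}: line {i + 3 + j}: malformed XYZ atom line")
            try:
                coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise FormatError(f"{path}: line {i + 3 + j}: malformed XYZ atom line") from None
        coords *= ANGSTROM_TO_NM
        # XYZ has no box; use a generous bounding box so downstream PBC math
        # degenerates to no wrapping.
        span = coords.max(axis=0) - coords.min(axis=0) + 100.0
        frames.append(TrajectoryFrame(time=time, coordinates=coords, box=span))
        i += 2 + natoms
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return frames


# ---------------------------------------------------------------------------
# ITP subset
# ---------------------------------------------------------------------------

def read_topology_subset(path) -> MoleculeTopology:
    """Parse the ITP subset: [moleculetype] (optional), [atoms] with the
    charge-group column, [bonds], [dihedrals].

    Charge-sum invariant violations are reported as :class:`ChargeSumWarning`,
    not errors, because inputs mid-fit may carry non-integral sums.
    """
    name = "molecule"
    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int]] = []
    dihedrals: list[tuple[int, int, int, int, str]] = []
    section = None
    saw_atoms = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split(";", 1)[0].strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[] \t").lower()
                if section == "atoms":
                    saw_atoms = True
                continue
            parts = line.split()
            try:
                if section == "moleculetype":
                    name = parts[0]
                elif section == "atoms":
                    # nr type resnr residue atom cgnr charge [mass]
                    if len(parts) < 7:
                        raise FormatError(
                            f"{path}: line {lineno}: [atoms] needs nr/type/resnr/"
                            "residue/atom/cgnr/charge columns"
                        )
                    atoms.append(AtomRecord(
                        index=int(parts[0]),
                        name=parts[4],
                        element=_element_from_type(parts[1]),
                        partial_charge=float(parts[6]),
                        charge_group_id=int(parts[5]),
                        mass=float(parts[7]) if len(parts) > 7 else 0.0,
                    ))
                elif section == "bonds":
                    bonds.append((int(parts[0]), int(parts[1])))
                elif section == "dihedrals":
                    param_id = parts[4] if len(parts) > 4 else ""
                    dihedrals.append((int(parts[0]), int(parts[1]),
                                      int(parts[2]), int(parts[3]), param_id))
            except (ValueError, IndexError):
                raise FormatError(f"{path}: line {lineno}: malformed [{section}] line") from None
    if not saw_atoms:
        raise FormatError(f"{path}: missing [atoms] section")
    net = int(round(sum(a.partial_charge for a in atoms)))
    mol = MoleculeTopology(name=name, atoms=atoms, bonds=bonds,
                           dihedrals=dihedrals, net_charge=net)
    mol.validate_charge_sums()
    return mol


def _element_from_type(atom_type: str) -> str:
    head = "".join(c for c in atom_type if c.isalpha())[:2].capitalize()
    if len(head) == 2 and head not in ("Cl", "Br", "Na", "Si", "Se"):
        head = head[0]
    return head


def write_topology_subset(path, mol: MoleculeTopology) -> None:
    with open(path, "w") as fh:
        fh.write(f"[ moleculetype ]\n{mol.name} 3\n\n[ atoms ]\n")
        fh.write("; nr  type  resnr  residue  atom  cgnr  charge  mass\n")
        for a in mol.atoms:
            fh.write(
                f"{a.index:5d}  {a.element:<4s} 1  {mol.name[:5]:<5s} "
                f"{a.name:<5s} {a.charge_group_id:4d}  {a.partial_charge:12.6f}  {a.mass:10.5f}\n"
            )
        if mol.bonds:
            fh.write("\n[ bonds ]\n")
            for i, j in mol.bonds:
                fh.write(f"{i:5d} {j:5d}\n")
        if mol.dihedrals:
            fh.write("\n[ dihedrals ]\n")
            for d in mol.dihedrals:
                fh.write(f"{d[0]:5d} {d[1]:5d} {d[2]:5d} {d[3]:5d} {d[4]}\n")


def attach_coordinates(mol: MoleculeTopology, frame: TrajectoryFrame) -> MoleculeTopology:
    """Copy a frame's coordinates onto the topology's atoms (in order)."""
    if frame.n_atoms != mol.n_atoms:
        raise StructureError(
            f"frame has {frame.n_atoms} atoms but topology {mol.name!r} has {mol.n_atoms}"
        )
    for a, xyz in zip(mol.atoms, frame.coordinates):
        a.position = np.array(xyz, dtype=float)
    return mol


# ---------------------------------------------------------------------------
# observable tables and reports
# ---------------------------------------------------------------------------

def read_observable_table(path, columns=None, units=None) -> ObservableTable:
    """Read an XVG-like table: ``#``/``@`` comment lines skipped, rows are
    whitespace-separated numbers.  Ragged rows raise :class:`FormatError`."""
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line[0] in "#@&":
                continue
            parts = line.split()
            try:
                vals = [float(v) for v in parts]
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-numeric value") from None
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise FormatError(
                    f"{path}: line {lineno}: ragged row ({len(vals)} fields, expected {width})"
                )
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: empty data section")
    if columns is None:
        columns = ["time"] + [f"col{i}" for i in range(1, width)]
    if len(columns) != width:
        raise ValueError(f"{len(columns)} column labels for {width} columns")
    return ObservableTable(pd.DataFrame(rows, columns=columns), units=units)


def write_observable_table(path, table: ObservableTable, comments=()) -> None:
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("@ " + "  ".join(table.columns) + "\n")
        for _, row in table.data.iterrows():
            fh.write("  ".join(f"{v:.8g}" for v in row.to_numpy()) + "\n")


def write_report(path, rows) -> None:
    """Write per-site report rows (dicts or a DataFrame) as CSV in the
    canonical column order."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"report rows missing columns: {missing}")
    df[REPORT_COLUMNS].to_csv(path, index=False)


def read_report(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: report missing columns: {missing}")
    return df
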