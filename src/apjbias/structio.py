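"""Structure and trajectory I/O.

The data model is deliberately small: an :class:`Atom` keeps the identity
fields needed for residue-level analyses (author residue numbering is
preserved verbatim, because residue labels such as Tyr221/Tyr309/Arg127
follow the source numbering), a :class:`Structure` is an ordered atom list,
and a :class:`Trajectory` is a stack of coordinate frames sharing one
topology.

Supported on-disk formats:

* multi-model PDB (``ATOM``/``HETATM``, optional ``MODEL``/``ENDMDL``);
  frame times are carried in ``REMARK 250 TIME_NS=`` records so trajectories
  round-trip losslessly;
* a plain delimited per-frame coordinate table
  (``frame,time_ns,atom_index,x,y,z``) as a lightweight trajectory dialect.

Parsing is self-contained so error contracts (line-numbered parse errors,
topology-mismatch checks) are exact; a test cross-checks the reader against
an independent PDB library.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import PDBParseError, SelectionError, TopologyMismatchError

# Bondi van der Waals radii (A).  Unknown elements fall back to 1.70 A
# (carbon), a conservative default for clash and SASA work.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "ZN": 1.39, "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70

_TWO_LETTER_ELEMENTS = {k for k in BONDI_RADII if len(k) == 2}


def infer_element(atom_name: str) -> str:
    """Infer an element symbol from a PDB atom name.

    Leading digits are ignored (e.g. ``1HB``); two-letter elements are
    recognised only when the full stripped name matches one (``CL``, ``BR``,
    ``NA`` ...), otherwise the first letter wins (``CA`` is carbon).
    """
    letters = re.sub(r"[^A-Za-z]", "", atom_name).upper()
    if not letters:
        return ""
    if letters in _TWO_LETTER_ELEMENTS:
        return letters
    return letters[0]


def vdw_radius(element: str) -> float:
    return BONDI_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


@dataclass
class Atom:
    """A named atom with coordinates in Angstrom."""

    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    element: str
    coords: np.ndarray
    vdw_radius: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be a finite 3-vector")
        if not self.element:
            self.element = infer_element(self.atom_name)
        if self.vdw_radius <= 0.0:
            self.vdw_radius = vdw_radius(self.element)

    @property
    def residue_label(self) -> str:
        return f"{self.residue_name}{self.residue_number}"

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Structure:
    """An ordered list of atoms for one conformation."""

    atoms: list[Atom]
    label: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in file order."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, label: Optional[str] = None) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape does not match topology")
        atoms = [replace(a, coords=c.copy()) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, label if label is not None else self.label)

    def subset(self, indices: Sequence[int], label: str = "") -> "Structure":
        atoms = [replace(self.atoms[i], coords=self.atoms[i].coords.copy())
                 for i in indices]
        return Structure(atoms, label or self.label)

    def select(
        self,
        chain: Optional[str] = None,
        residue_number: Optional[int] = None,
        residue_name: Optional[str] = None,
        atom_names: Optional[Union[str, Iterable[str]]] = None,
    ) -> list[int]:
        """Indices of atoms matching every provided criterion, in order.

        An empty result is valid; selection is order-preserving and a
        pure filter (hence idempotent).
        """
        if isinstance(atom_names, str):
            atom_names = [atom_names]
        names = {n.upper() for n in atom_names} if atom_names is not None else None
        out = []
        for i, a in enumerate(self.atoms):
            if chain is not None and a.chain_id != chain:
                continue
            if residue_number is not None and a.residue_number != residue_number:
                continue
            if residue_name is not None and a.residue_name.upper() != residue_name.upper():
                continue
            if names is not None and a.atom_name.upper() not in names:
                continue
            out.append(i)
        return out


def select(structure: Structure, **criteria) -> list[int]:
    """Module-level alias for :meth:`Structure.select`."""
    return structure.select(**criteria)


@dataclass
class Trajectory:
    """Frames sharing one topology, with frame times in ns."""

    topology: Structure
    frames: np.ndarray          # (F, N, 3)
    times_ns: np.ndarray        # (F,)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, N, 3)")
        if self.frames.shape[1] != len(self.topology):
            raise TopologyMismatchError(
                f"frames carry {self.frames.shape[1]} atoms, "
                f"topology has {len(self.topology)}"
            )
        if self.times_ns.shape != (self.frames.shape[0],):
            raise ValueError("one time per frame required")
        if self.n_frames > 1 and not np.all(np.diff(self.times_ns) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int, label: str = "") -> Structure:
        return self.topology.with_coords(self.frames[i], label or f"frame {i}")

    def subsample(self, stride: int) -> "Trajectory":
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return Trajectory(self.topology, self.frames[::stride], self.times_ns[::stride])


# ---------------------------------------------------------------------------
# PDB reading / writing

_TIME_RE = re.compile(r"^REMARK\s+250\s+TIME_NS=\s*([-+0-9.eE]+)")


def _parse_atom_line(line: str, lineno: int) -> Atom:
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(
            f"malformed coordinate field at line {lineno}: {line.rstrip()!r}"
        ) from exc
    try:
        resnum = int(line[22:26])
    except ValueError as exc:
        raise PDBParseError(
            f"malformed residue number at line {lineno}: {line.rstrip()!r}"
        ) from exc
    element = line[76:78].strip() if len(line) >= 77 else ""
    return Atom(
        atom_name=line[12:16].strip(),
        residue_name=line[17:20].strip(),
        residue_number=resnum,
        chain_id=line[21:22].strip(),
        element=element,
        coords=np.array([x, y, z]),
    )


def read_pdb(path, model_policy: str = "first") -> Union[Structure, Trajectory]:
    """Read a (multi-model) PDB file.

    ``model_policy="first"`` returns a :class:`Structure` built from the
    first model; ``"all"`` returns a :class:`Trajectory` whose topology is
    model 1 (a single-model file yields a one-frame trajectory).  Alternate
    locations other than '' or 'A' are dropped.
    """
    if model_policy not in ("first", "all"):
        raise ValueError("model_policy must be 'first' or 'all'")
    models: list[list[Atom]] = []
    times: list[float] = []
    current: list[Atom] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if in_model and current:
                    models.append(current)
                current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                altloc = line[16:17].strip()
                if altloc not in ("", "A"):
                    continue
                current.append(_parse_atom_line(line, lineno))
            elif rec == "REMARK":
                m = _TIME_RE.match(line)
                if m:
                    times.append(float(m.group(1)))
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PDBParseError(f"no ATOM/HETATM records found in {path}")

    if model_policy == "first":
        return Structure(models[0], label=str(path))

    n0 = len(models[0])
    for k, m in enumerate(models[1:], start=2):
        if len(m) != n0:
            raise TopologyMismatchError(
                f"model {k} has {len(m)} atoms, model 1 has {n0}"
            )
    frames = np.array([[a.coords for a in m] for m in models], dtype=float)
    if len(times) == len(models):
        t = np.asarray(times, dtype=float)
    else:
        t = np.arange(len(models), dtype=float)
    return Trajectory(Structure(models[0], label=str(path)), frames, t)


def _format_atom_name(name: str) -> str:
    # Names shorter than four characters start in column 14, per convention.
    return name[:4].ljust(4) if len(name) >= 4 else f" {name:<3s}"


def _atom_record(i: int, a: Atom, coords: np.ndarray) -> str:
    return (
        f"ATOM  {min(i, 99999):5d} {_format_atom_name(a.atom_name)} "
        f"{a.residue_name[:3]:>3s} {a.chain_id[:1] or 'A':1s}"
        f"{a.residue_number:4d}    "
        f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {a.element[:2]:>2s}"
    )


def write_pdb(obj: Union[Structure, Trajectory], path) -> None:
    """Write a Structure (single model) or Trajectory (MODEL blocks).

    Coordinates are serialised at the fixed PDB precision of three
    decimals, so a read/write round trip reproduces names, numbering and
    coordinates to 3 decimals.
    """
    lines: list[str] = []
    if isinstance(obj, Structure):
        for i, a in enumerate(obj.atoms, start=1):
            lines.append(_atom_record(i, a, a.coords))
    elif isinstance(obj, Trajectory):
        for f in range(obj.n_frames):
            lines.append(f"REMARK 250 TIME_NS= {obj.times_ns[f]:.6f}")
            lines.append(f"MODEL {f + 1:8d}")
            for i, a in enumerate(obj.topology.atoms, start=1):
                lines.append(_atom_record(i, a, obj.frames[f, i - 1]))
            lines.append("ENDMDL")
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Plain delimited coordinate-table trajectory dialect

def write_coord_table(traj: Trajectory, path) -> None:
    """Write a trajectory as a tidy table (frame, time_ns, atom_index, x, y, z)."""
    f_idx = np.repeat(np.arange(traj.n_frames), len(traj.topology))
    a_idx = np.tile(np.arange(len(traj.topology)), traj.n_frames)
    flat = traj.frames.reshape(-1, 3)
    df = pd.DataFrame(
        {
            "frame": f_idx,
            "time_ns": traj.times_ns[f_idx],
            "atom_index": a_idx,
            "x": flat[:, 0],
            "y": flat[:, 1],
            "z": flat[:, 2],
        }
    )
    df.to_csv(path, index=False)


def read_coord_table(path, topology: Structure) -> Trajectory:
    """Read the tidy coordinate-table dialect against a given topology."""
    df = pd.read_csv(path)
    required = {"frame", "time_ns", "atom_index", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise PDBParseError(f"coordinate table missing columns: {sorted(missing)}")
    n_atoms = len(topology)
    frames = []
    times = []
    for frame_id, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("atom_index")
        if len(grp) != n_atoms or not np.array_equal(
            grp["atom_index"].to_numpy(), np.arange(n_atoms)
        ):
            raise TopologyMismatchError(
                f"frame {frame_id} does not cover atoms 0..{n_atoms - 1} exactly"
            )
        frames.append(grp[["x", "y", "z"]].to_numpy(dtype=float))
        times.append(float(grp["time_ns"].iloc[0]))
    return Trajectory(topology, np.array(frames), np.array(times))


# ---------------------------------------------------------------------------
# Residue-label helpers shared by geometry / bias

_LABEL_RE = re.compile(r"^([A-Za-z]{1,3})?\s*(\d+)$")


def parse_residue_label(label: str) -> tuple[Optional[str], int]:
    """Parse 'ARG127' / 'Tyr221' / '127' into (name or None, number)."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise SelectionError(f"cannot parse residue label {label!r}")
    name = m.group(1).upper() if m.group(1) else None
    return name, int(m.group(2))


def residue_atom_indices(structure: Structure, label: str,
                         chain: Optional[str] = None) -> list[int]:
    """All atom indices belonging to a residue label such as 'ARG127'."""
    name, number = parse_residue_label(label)
    return structure.select(chain=chain, residue_number=number, residue_name=name)
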