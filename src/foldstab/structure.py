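"""PDB structure/trajectory parsing and atom selection.

PDB v3.3 reading and writing is delegated to biotite; this module adapts it
to the package's coordinate model: a :class:`Structure` (one atom table +
one coordinate matrix, angstrom) and a :class:`Trajectory` (ordered frames
sharing the topology of model 1).  Waters and hetero records are skipped by
default and only altloc 'A'/blank atoms are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from biotite.structure.info import mass as element_mass

from .errors import FormatError, SelectionError, ValidationError

__all__ = [
    "Structure",
    "Trajectory",
    "DomainDefinition",
    "AtomAddress",
    "read_pdb",
    "write_pdb",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "select",
    "resolve_atom",
    "parse_selection",
]

_DEFAULT_MASS = 12.011  # fall back to carbon for unknown elements


@dataclass
class Structure:
    """Atom table plus one coordinate set in angstrom."""

    serial: np.ndarray          # int
    atom_name: np.ndarray      # str
    residue_name: np.ndarray   # str
    chain_id: np.ndarray       # str
    residue_number: np.ndarray  # int
    element: np.ndarray        # str
    coords: np.ndarray         # (n_atoms, 3) float, angstrom
    masses: np.ndarray         # Da

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = self.coords.shape[0]
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must have shape (n_atoms, 3)")
        for name in ("serial", "atom_name", "residue_name", "chain_id",
                     "residue_number", "element", "masses"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length != n_atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")
        if np.any(self.masses <= 0):
            raise ValidationError("masses must be positive")
        keys = list(zip(self.chain_id, self.residue_number, self.atom_name))
        if len(set(keys)) != n:
            raise ValidationError("(chain, residue_number, atom_name) not unique")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """Ordered coordinate frames sharing one atom table."""

    topology: Structure
    frames: np.ndarray                      # (n_frames, n_atoms, 3)
    frame_times: Optional[np.ndarray] = None  # ps

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValidationError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValidationError("a trajectory needs at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValidationError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"{self.topology.n_atoms}"
            )
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.frames.shape[0],):
                raise ValidationError("frame_times length != n_frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class DomainDefinition:
    """A named set of inclusive residue-number ranges."""

    name: str
    residue_ranges: List[Tuple[int, int]]

    def __post_init__(self):
        ranges = sorted((int(a), int(b)) for a, b in self.residue_ranges)
        for (a, b) in ranges:
            if b < a:
                raise ValidationError(f"range ({a}, {b}) reversed in domain {self.name}")
        for (a1, b1), (a2, b2) in zip(ranges, ranges[1:]):
            if a2 <= b1:
                raise ValidationError(f"overlapping ranges in domain {self.name}")
        self.residue_ranges = ranges

    def mask(self, structure: Structure) -> np.ndarray:
        resno = structure.residue_number
        m = np.zeros(structure.n_atoms, dtype=bool)
        for a, b in self.residue_ranges:
            m |= (resno >= a) & (resno <= b)
        return m


@dataclass(frozen=True)
class AtomAddress:
    """Unique atom coordinate: (chain?, residue number, atom name)."""

    residue_number: int
    atom_name: str
    chain_id: Optional[str] = None

    def __str__(self):
        chain = f"{self.chain_id}/" if self.chain_id else ""
        return f"{chain}{self.residue_number}:{self.atom_name}"


# ---------------------------------------------------------------------------
# biotite adapters
# ---------------------------------------------------------------------------


def _mass_for(element: str, atom_name: str) -> float:
    el = element.strip()
    if not el:
        el = atom_name.strip()[:1]
    try:
        m = element_mass(el.capitalize())
        if m is not None and m > 0:
            return float(m)
    except Exception:
        pass
    warnings.warn(f"unknown element {element!r}; assigning default mass")
    return _DEFAULT_MASS


def _from_atom_array(atoms: "struc.AtomArray") -> Structure:
    n = atoms.array_length()
    masses = np.array(
        [_mass_for(e, a) for e, a in zip(atoms.element, atoms.atom_name)]
    )
    return Structure(
        serial=np.arange(1, n + 1),
        atom_name=np.asarray(atoms.atom_name, dtype=object),
        residue_name=np.asarray(atoms.res_name, dtype=object),
        chain_id=np.asarray(atoms.chain_id, dtype=object),
        residue_number=np.asarray(atoms.res_id, dtype=int),
        element=np.asarray(atoms.element, dtype=object),
        coords=np.asarray(atoms.coord, dtype=float),
        masses=masses,
    )


def _filter(atoms, keep_hetero: bool):
    mask = np.ones(atoms.array_length(), dtype=bool)
    if not keep_hetero:
        mask &= ~atoms.hetero
    return atoms[..., mask] if isinstance(atoms, struc.AtomArrayStack) else atoms[mask]


def read_pdb(path, keep_hetero: bool = False) -> Structure:
    """Read the first model of a PDB file.

    Altloc 'A'/blank atoms are kept; waters and hetero records skipped
    unless ``keep_hetero``.
    """
    pdb_file = pdbio.PDBFile.read(path)
    if pdb_file.get_model_count() == 0:
        raise FormatError(f"{path}: no ATOM records / coordinate models found")
    atoms = pdb_file.get_structure(model=1, altloc="first")
    atoms = _filter(atoms, keep_hetero)
    if atoms.array_length() == 0:
        raise FormatError(f"{path}: no atoms left after filtering")
    return _from_atom_array(atoms)


def _to_atom_array(structure: Structure) -> "struc.AtomArray":
    atoms = struc.AtomArray(structure.n_atoms)
    atoms.coord = np.asarray(structure.coords, dtype=np.float32)
    atoms.chain_id = np.asarray(structure.chain_id, dtype="U4")
    atoms.res_id = np.asarray(structure.residue_number, dtype=int)
    atoms.res_name = np.asarray(structure.residue_name, dtype="U5")
    atoms.atom_name = np.asarray(structure.atom_name, dtype="U6")
    atoms.element = np.asarray(structure.element, dtype="U2")
    atoms.hetero = np.zeros(structure.n_atoms, dtype=bool)
    return atoms


def write_pdb(structure: Structure, path) -> None:
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(_to_atom_array(structure))
    pdb_file.write(path)


def read_multimodel_pdb(path, keep_hetero: bool = False) -> Trajectory:
    """Read a multi-model PDB as a trajectory (topology from model 1)."""
    pdb_file = pdbio.PDBFile.read(path)
    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise FormatError(f"{path}: no coordinate models found")
    try:
        stack = pdb_file.get_structure(altloc="first")
    except Exception as exc:
        model = _find_inconsistent_model(path)
        raise FormatError(
            f"{path}: inconsistent atom table across models"
            + (f" (first mismatch at model {model})" if model else "")
        ) from exc
    stack = _filter(stack, keep_hetero)
    if stack.array_length() == 0:
        raise FormatError(f"{path}: no atoms left after filtering")
    topo = _from_atom_array(stack[0])
    frames = np.asarray(stack.coord, dtype=float)
    return Trajectory(topology=topo, frames=frames)


def _find_inconsistent_model(path) -> Optional[int]:
    counts = []
    current = 0
    in_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec.startswith("MODEL"):
                in_model = True
                current = 0
            elif rec.startswith("ENDMDL"):
                counts.append(current)
                in_model = False
            elif rec.startswith(("ATOM  ", "HETATM")) and in_model:
                current += 1
    for i, c in enumerate(counts[1:], start=2):
        if c != counts[0]:
            return i
    return None


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as MODEL/ENDMDL blocks (PDB precision: 1e-3 A)."""
    arrays = []
    for frame in traj.frames:
        a = _to_atom_array(traj.topology)
        a.coord = np.asarray(frame, dtype=np.float32)
        arrays.append(a)
    stack = struc.stack(arrays)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(path)


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


def select(
    structure_or_traj,
    chain: Optional[str] = None,
    residue_ranges: Optional[Sequence[Tuple[int, int]]] = None,
    atom_names: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Deterministic, topology-ordered atom index set.

    Empty selections are allowed but emit a warning (callers that require a
    non-empty selection raise :class:`SelectionError` themselves).
    """
    structure = (
        structure_or_traj.topology
        if isinstance(structure_or_traj, Trajectory)
        else structure_or_traj
    )
    mask = np.ones(structure.n_atoms, dtype=bool)
    if chain is not None:
        mask &= structure.chain_id == chain
    if residue_ranges is not None:
        rmask = np.zeros(structure.n_atoms, dtype=bool)
        for a, b in residue_ranges:
            rmask |= (structure.residue_number >= int(a)) & (
                structure.residue_number <= int(b)
            )
        mask &= rmask
    if atom_names is not None:
        mask &= np.isin(structure.atom_name, list(atom_names))
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn("selection matched no atoms")
    return idx


def resolve_atom(structure_or_traj, address: AtomAddress) -> int:
    """Resolve an :class:`AtomAddress` to exactly one atom index."""
    ranges = [(address.residue_number, address.residue_number)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idx = select(
            structure_or_traj,
            chain=address.chain_id,
            residue_ranges=ranges,
            atom_names=[address.atom_name],
        )
    if idx.size == 0:
        raise SelectionError(f"atom {address} not found")
    if idx.size > 1:
        raise SelectionError(f"atom {address} is ambiguous ({idx.size} matches)")
    return int(idx[0])


def parse_selection(text: str) -> dict:
    """Parse a CLI selection string like ``chain:A,res:50-163,atom:CA``."""
    out: dict = {}
    if not text:
        return out
    for token in text.split(","):
        key, _, value = token.partition(":")
        key = key.strip().lower()
        value = value.strip()
        if key == "chain":
            out["chain"] = value
        elif key == "res":
            ranges = out.setdefault("residue_ranges", [])
            if "-" in value:
                a, _, b = value.partition("-")
                ranges.append((int(a), int(b)))
            else:
                ranges.append((int(value), int(value)))
        elif key == "atom":
            out.setdefault("atom_names", []).append(value)
        else:
            raise SelectionError(f"unknown selection key {key!r} in {text!r}")
    return out
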