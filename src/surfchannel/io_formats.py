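"""Fixed-width PDB and CSV I/O for trajectories, centroid clouds and score maps.

The on-disk trajectory format is multi-model PDB: one ``MODEL``/``ENDMDL``
block per frame, atom labelling identical across models, coordinates in
Angstrom in columns 31-54. Substrate instances have no native PDB concept,
so every atom whose residue name is registered as a substrate gets a
``molecule_tag`` synthesised from (residue_name, chain, residue_number);
all downstream stages key on that tag.

Writers emit LF line endings and are byte-deterministic: identical inputs
produce identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    PdbFormatError,
    PdbParseError,
    SchemaError,
    StructureError,
    SurfChannelError,
    TableParseError,
)

__all__ = [
    "SubstrateType",
    "AtomRecord",
    "Structure",
    "Trajectory",
    "DEFAULT_SUBSTRATE_RESNAMES",
    "read_multimodel_pdb",
    "read_structure_pdb",
    "write_trajectory",
    "write_structure_pdb",
    "write_points_pdb",
    "write_bfactor_pdb",
    "read_centroid_table",
    "write_centroid_table",
]


class SubstrateType(str, Enum):
    """Ligand class of a substrate molecule.

    Two competing small-molecule types diffuse around the protein in the
    study design this package serves: an omega-amino-acid-like ligand
    (type A, "aha") and a diamine-like ligand (type B, "hmd"). Protein,
    cofactor and solvent atoms carry ``NONE``.
    """

    AHA_LIKE = "aha"
    HMD_LIKE = "hmd"
    NONE = "none"


#: residue-name -> substrate class used when reading PDB files
DEFAULT_SUBSTRATE_RESNAMES: dict[str, SubstrateType] = {
    "AHA": SubstrateType.AHA_LIKE,
    "HMD": SubstrateType.HMD_LIKE,
}

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the frame-invariant topology.

    Coordinates are Angstrom and belong to the *first* frame; per-frame
    positions live in :class:`Trajectory.frames`.
    """

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    x: float
    y: float
    z: float
    bfactor: float = 0.0
    element: str = ""
    molecule_tag: str | None = None
    substrate_type: SubstrateType = SubstrateType.NONE

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)

    @property
    def is_protein(self) -> bool:
        return self.residue_name in _STANDARD_AA

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


def synthesise_molecule_tag(residue_name: str, chain_id: str, residue_number: int) -> str:
    """Stable substrate-instance identifier, e.g. ``AHA_S007``."""
    return f"{residue_name}_{chain_id}{residue_number:03d}"


@dataclass
class Structure:
    """Ordered atom collection with a derived residue index."""

    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        self._residues: dict[tuple[str, int], list[int]] | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def residues(self) -> dict[tuple[str, int], list[int]]:
        """residue_key -> atom indices; partitions the atom list."""
        if self._residues is None:
            idx: dict[tuple[str, int], list[int]] = {}
            for i, a in enumerate(self.atoms):
                idx.setdefault(a.residue_key, []).append(i)
            self._residues = idx
        return self._residues

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array of first-frame coordinates."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def with_coords(self, xyz: np.ndarray) -> "Structure":
        """Copy of this structure with coordinates replaced."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise StructureError(
                f"coordinate array shape {xyz.shape} does not match {len(self.atoms)} atoms"
            )
        atoms = [
            replace(a, x=float(p[0]), y=float(p[1]), z=float(p[2]))
            for a, p in zip(self.atoms, xyz)
        ]
        return Structure(atoms)

    def subset(self, indices: Sequence[int]) -> "Structure":
        return Structure([self.atoms[i] for i in indices])

    def protein_residue_keys(self) -> list[tuple[str, int]]:
        keys: list[tuple[str, int]] = []
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            if a.is_protein and a.residue_key not in seen:
                seen.add(a.residue_key)
                keys.append(a.residue_key)
        return keys


@dataclass
class Trajectory:
    """Frame-invariant topology plus per-frame coordinates.

    ``frames`` has shape (n_frames, n_atoms, 3), Angstrom.
    """

    topology: Structure
    frames: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError(f"frames must be (n_frames, n_atoms, 3), got {self.frames.shape}")
        if self.frames.shape[1] != len(self.topology):
            raise StructureError(
                f"frames carry {self.frames.shape[1]} atoms but topology has {len(self.topology)}"
            )
        if self.n_frames < 1:
            raise StructureError("a trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return len(self.topology)


# ---------------------------------------------------------------------------
# PDB reading

def _parse_atom_line(
    line: str,
    lineno: int,
    substrate_resnames: Mapping[str, SubstrateType],
) -> AtomRecord:
    def _float(colspec: tuple[int, int], what: str) -> float:
        raw = line[colspec[0]:colspec[1]]
        try:
            v = float(raw)
        except ValueError:
            raise PdbParseError(
                f"line {lineno}: cannot parse {what} field {raw!r}"
            ) from None
        if not math.isfinite(v):
            raise PdbParseError(f"line {lineno}: non-finite {what} {raw!r}")
        return v

    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0  # overflowing serials (>99999) are not significant
    atom_name = line[12:16].strip()
    residue_name = line[17:20].strip()
    chain_id = line[21:22].strip() or " "
    try:
        residue_number = int(line[22:26])
    except ValueError:
        raise PdbParseError(
            f"line {lineno}: cannot parse residue number {line[22:26]!r}"
        ) from None
    x = _float((30, 38), "x")
    y = _float((38, 46), "y")
    z = _float((46, 54), "z")
    braw = line[60:66].strip()
    bfactor = float(braw) if braw else 0.0
    element = line[76:78].strip() if len(line) >= 78 else ""

    stype = substrate_resnames.get(residue_name, SubstrateType.NONE)
    tag = (
        synthesise_molecule_tag(residue_name, chain_id, residue_number)
        if stype is not SubstrateType.NONE
        else None
    )
    return AtomRecord(
        serial=serial,
        atom_name=atom_name,
        residue_name=residue_name,
        chain_id=chain_id,
        residue_number=residue_number,
        x=x, y=y, z=z,
        bfactor=bfactor,
        element=element,
        molecule_tag=tag,
        substrate_type=stype,
    )


def read_multimodel_pdb(
    path: str | Path,
    substrate_resnames: Mapping[str, SubstrateType] | None = None,
) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    ``MODEL``/``ENDMDL`` records delimit frames; a file without them is a
    single-frame trajectory. The first model defines the topology; every
    later model must carry the same number of atoms.

    Raises
    ------
    StructureError
        if a model's atom count differs from the first model's.
    PdbParseError
        if a coordinate or residue-number field is unparseable
        (message names the line number).
    """
    if substrate_resnames is None:
        substrate_resnames = DEFAULT_SUBSTRATE_RESNAMES
    path = Path(path)
    atoms: list[AtomRecord] = []
    frames: list[np.ndarray] = []
    current: list[list[float]] = []
    model_no = 0
    in_model = False
    seen_model_record = False

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                seen_model_record = True
                in_model = True
                model_no += 1
                current = []
            elif rec == "ENDMDL":
                in_model = False
                _close_model(current, atoms, frames, model_no)
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                a = _parse_atom_line(line, lineno, substrate_resnames)
                if not frames:
                    atoms.append(a)
                current.append([a.x, a.y, a.z])

    if not seen_model_record:
        if not current:
            raise StructureError(f"{path}: no atoms found")
        _close_model(current, atoms, frames, 1)
    elif in_model and current:
        # trailing model without ENDMDL
        _close_model(current, atoms, frames, model_no)

    if not frames:
        raise StructureError(f"{path}: no atoms found")
    return Trajectory(Structure(atoms), np.array(frames, dtype=float))


def _close_model(
    current: list[list[float]],
    atoms: list[AtomRecord],
    frames: list[np.ndarray],
    model_no: int,
) -> None:
    if frames and len(current) != len(atoms):
        raise StructureError(
            f"model {model_no} has {len(current)} atoms, expected {len(atoms)}"
        )
    if not current:
        raise StructureError(f"model {model_no} contains no atoms")
    frames.append(np.array(current, dtype=float))


def read_structure_pdb(
    path: str | Path,
    substrate_resnames: Mapping[str, SubstrateType] | None = None,
) -> Structure:
    """Read the first model of a PDB file as a static structure."""
    return read_multimodel_pdb(path, substrate_resnames).topology


# ---------------------------------------------------------------------------
# PDB writing

def _fmt_coord(v: float) -> str:
    s = f"{v:8.3f}"
    if len(s) != 8:
        raise PdbFormatError(f"coordinate {v!r} overflows the 8-column PDB field")
    return s


def _fmt_atom_name(name: str) -> str:
    # short names start in column 14 by convention
    return f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"


def _atom_line(
    record: str,
    serial: int,
    atom_name: str,
    residue_name: str,
    chain_id: str,
    residue_number: int,
    xyz: Sequence[float],
    occupancy: float = 1.00,
    bfactor: float = 0.00,
    element: str = "",
) -> str:
    b = f"{bfactor:6.2f}"
    if len(b) > 6:
        raise PdbFormatError(f"B-factor {bfactor!r} overflows the 6-column field")
    return (
        f"{record:<6s}{min(serial, 99999):>5d} {_fmt_atom_name(atom_name)} "
        f"{residue_name:<3s} {chain_id:1s}{residue_number % 10000:>4d}    "
        f"{_fmt_coord(xyz[0])}{_fmt_coord(xyz[1])}{_fmt_coord(xyz[2])}"
        f"{occupancy:6.2f}{b}          {element:>2s}"
    )


def _structure_lines(structure: Structure, coords: np.ndarray | None = None,
                     bfactors: Sequence[float] | None = None) -> list[str]:
    xyz = structure.coords() if coords is None else np.asarray(coords, dtype=float)
    lines = []
    for i, a in enumerate(structure.atoms):
        record = "ATOM" if a.is_protein else "HETATM"
        b = a.bfactor if bfactors is None else bfactors[i]
        lines.append(
            _atom_line(record, i + 1, a.atom_name, a.residue_name, a.chain_id,
                       a.residue_number, xyz[i], bfactor=b, element=a.element)
        )
    return lines


def write_structure_pdb(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB file."""
    with open(path, "w", newline="\n") as fh:
        for line in _structure_lines(structure):
            fh.write(line + "\n")
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB trajectory (one MODEL block per frame)."""
    with open(path, "w", newline="\n") as fh:
        for k in range(traj.n_frames):
            fh.write(f"MODEL {k + 1:>8d}\n")
            for line in _structure_lines(traj.topology, coords=traj.frames[k]):
                fh.write(line + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_points_pdb(
    points: Iterable[Sequence[float]],
    path: str | Path,
    labels: Sequence[str] | None = None,
) -> None:
    """Write a bare point cloud as HETATM records, one per point, in input order.

    Used for the per-iteration centroid snapshots so any molecular viewer
    can overlay the clustered substrate positions onto the protein.
    """
    pts = [np.asarray(p, dtype=float) for p in points]
    for p in pts:
        if not np.all(np.isfinite(p)):
            raise PdbFormatError("point coordinates must be finite")
    with open(path, "w", newline="\n") as fh:
        for i, p in enumerate(pts):
            resname = (labels[i][:3].upper() if labels is not None else "CEN")
            fh.write(
                _atom_line("HETATM", i + 1, "C", resname, "X", i + 1, p, element="C")
                + "\n"
            )
        fh.write("END\n")


def write_bfactor_pdb(
    structure: Structure,
    scores: Mapping[tuple[str, int], float],
    path: str | Path,
    scale: str = "linear_0_99",
    default: float = 0.0,
) -> None:
    """Write ``structure`` with per-residue scores in the B-factor column.

    Every atom inherits its residue's score, optionally min-max rescaled to
    [0, 99.99] (``scale="linear_0_99"``, the default) so viewers colour the
    full range; ``scale="raw"`` writes scores verbatim. Residues missing
    from ``scores`` get ``default``. Coordinates and all other columns are
    identical to :func:`write_structure_pdb` output.
    """
    if scale not in ("linear_0_99", "raw"):
        raise ValueError(f"unknown scale {scale!r}")
    bad = [k for k, v in scores.items() if not math.isfinite(v)]
    if bad:
        raise SurfChannelError(f"non-finite scores for residues: {sorted(bad)}")

    if scale == "linear_0_99" and scores:
        vals = np.array(list(scores.values()), dtype=float)
        lo, hi = float(vals.min()), float(vals.max())
        if hi - lo <= 0.0:
            rescale = {k: 0.0 for k in scores}  # degenerate range
        else:
            rescale = {k: (v - lo) / (hi - lo) * 99.99 for k, v in scores.items()}
    else:
        rescale = dict(scores)

    bfactors = [rescale.get(a.residue_key, default) for a in structure.atoms]
    with open(path, "w", newline="\n") as fh:
        for line in _structure_lines(structure, bfactors=bfactors):
            fh.write(line + "\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# centroid-table CSV dialect

CENTROID_TABLE_COLUMNS = ["frame", "molecule_tag", "substrate_type", "x", "y", "z"]


def write_centroid_table(series, path: str | Path) -> None:
    """Write a :class:`~surfchannel.centroids.CentroidSeries` as CSV.

    Header is exactly ``frame,molecule_tag,substrate_type,x,y,z``;
    coordinates carry 6 decimals, so round-trips are lossless at that
    precision.
    """
    df = series.frame_table[CENTROID_TABLE_COLUMNS]
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def read_centroid_table(path: str | Path):
    """Read the CSV centroid dialect back into a CentroidSeries."""
    import pandas as pd

    from .centroids import CentroidSeries

    df = pd.read_csv(path, dtype={"molecule_tag": str, "substrate_type": str})
    missing = [c for c in CENTROID_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"centroid table missing column(s): {missing}")
    df = df[CENTROID_TABLE_COLUMNS]
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad) or (df[col].isna().any()):
            row = int((vals.isna()).idxmax()) + 2  # +2: header + 1-based
            raise TableParseError(f"non-numeric {col} coordinate at row {row}")
        df[col] = vals.astype(float)
    df["frame"] = df["frame"].astype(int)
    return CentroidSeries(df)
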