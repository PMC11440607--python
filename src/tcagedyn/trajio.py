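"""Structure, trajectory and table I/O.

Multi-model PDB (MODEL/ENDMDL blocks sharing one topology) is the portable
on-disk trajectory format; tabular inputs (chemical shifts, NOESY peak
volumes, melting series) are TSV/CSV.  Residue numbering is kept in the
author (Ex4) scheme everywhere — the truncated 25-mer constructs retain
residues 15-39 — with :func:`renumber_offset` available to translate to the
1-based sequential numbering of a truncated chain.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from .nmrfold import MeltingSeries, ShiftTable
from .noecalib import Peak, PeakList

if TYPE_CHECKING:
    from .rbs import SegmentationResult

logger = logging.getLogger(__name__)

#: B-factor sentinel marking residues not assigned to any rigid segment.
UNASSIGNED_BFACTOR = -1.0


@dataclass(frozen=True)
class AtomRecord:
    """Identity of one atom in the shared topology (coords live on frames)."""

    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str


@dataclass
class Trajectory:
    """An ordered ensemble of frames over one fixed topology.

    atoms: per-atom metadata, identical order in every frame.
    coords: (n_frames, n_atoms, 3) array, Å.
    frame_interval: time between consecutive frames, ps.
    """

    atoms: list[AtomRecord]
    coords: np.ndarray
    frame_interval: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords atom count does not match topology")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0 ps")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def residues(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, residue_number) pairs, first-atom order."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_number), None)
        return list(seen)

    def atom_index(self, chain_id: str, residue_number: int, atom_name: str) -> int:
        """Index of one uniquely identified atom; KeyError if absent."""
        for i, a in enumerate(self.atoms):
            if (a.chain_id == chain_id and a.residue_number == residue_number
                    and a.atom_name == atom_name):
                return i
        raise KeyError(f"atom {atom_name} of {chain_id}:{residue_number} not in topology")

    def ca_indices(self) -> tuple[list[tuple[str, int]], np.ndarray]:
        """One Cα per residue, in residue order.

        Returns (residue ids, atom-index array); raises if any residue lacks
        a Cα or carries more than one.
        """
        by_res: dict[tuple[str, int], list[int]] = {}
        for key in self.residues():
            by_res[key] = []
        for i, a in enumerate(self.atoms):
            if a.atom_name == "CA":
                by_res[(a.chain_id, a.residue_number)].append(i)
        ids, idx = [], []
        for key, hits in by_res.items():
            if len(hits) != 1:
                raise ValueError(
                    f"residue {key[0]}:{key[1]} has {len(hits)} Cα atoms, expected 1")
            ids.append(key)
            idx.append(hits[0])
        return ids, np.array(idx, dtype=int)


def renumber_offset(residue_number: int, offset: int = -14) -> int:
    """Translate author (Ex4) numbering to sequential numbering of a truncated
    construct (Ex4 residue 16 ↔ truncated residue 2 under the default offset).
    """
    return residue_number + offset


def read_multimodel_pdb(path: str | Path, frame_interval: float = 1.0,
                        label: str | None = None) -> Trajectory:
    """Read a multi-model PDB file as a Trajectory, one frame per MODEL.

    All models must share one topology (same atoms in the same order); a
    mismatch is rejected naming the offending MODEL.  Atom order and author
    residue numbering are preserved as found.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no MODEL/ATOM records found")

    def topology_of(model):
        idents, xyz = [], []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    idents.append(AtomRecord(atom.get_name(), residue.resname,
                                             residue.id[1], chain.id))
                    xyz.append(atom.coord)
        return idents, np.asarray(xyz, dtype=float)

    atoms0, xyz0 = topology_of(models[0])
    if not atoms0:
        raise ValueError(f"{path}: first model contains no atoms")
    frames = [xyz0]
    for model in models[1:]:
        atoms_k, xyz_k = topology_of(model)
        if atoms_k != atoms0:
            raise ValueError(
                f"{path}: MODEL {model.serial_num} topology differs from first model "
                f"({len(atoms_k)} vs {len(atoms0)} atoms or mismatched identities)")
        frames.append(xyz_k)
    traj = Trajectory(atoms=atoms0, coords=np.stack(frames),
                      frame_interval=frame_interval,
                      label=label if label is not None else path.stem)
    logger.info("read %s: %d frames, %d atoms (sha256 %s)",
                path, traj.n_frames, traj.n_atoms, file_sha256(path)[:12])
    return traj


def _pdb_atom_name(name: str) -> str:
    # atom names < 4 chars start in column 14 by PDB convention
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def _write_frame(handle, atoms: list[AtomRecord], xyz: np.ndarray,
                 bfactors: np.ndarray | None) -> None:
    serial = 0
    last_chain = None
    for a, (x, y, z) in zip(atoms, xyz):
        if last_chain is not None and a.chain_id != last_chain:
            handle.write("TER\n")
        last_chain = a.chain_id
        serial += 1
        bfac = 0.0 if bfactors is None else float(bfactors[serial - 1])
        element = a.atom_name.lstrip("0123456789")[:1]
        handle.write(
            f"ATOM  {serial:>5d} {_pdb_atom_name(a.atom_name)} "
            f"{a.residue_name:>3s} {a.chain_id}{a.residue_number:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{bfac:6.2f}          "
            f"{element:>2s}\n")
    handle.write("TER\n")


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> Path:
    """Write every frame of a trajectory as a MODEL/ENDMDL block."""
    path = Path(path)
    with path.open("w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"MODEL     {k + 1:>4d}\n")
            _write_frame(fh, traj.atoms, traj.coords[k], None)
            fh.write("ENDMDL\n")
        fh.write("END\n")
    return path


def write_labeled_pdb(traj: Trajectory, labels: "SegmentationResult",
                      path: str | Path) -> Path:
    """Write the first frame with rigid-segment ids encoded in the B-factor
    column (segment 0, 1, ... as 0.00, 1.00, ...; unassigned as -1.00, stated
    in a REMARK header), for coloring in any molecular viewer.
    """
    label_of = dict(zip(labels.residue_index, labels.labels))
    missing = [key for key in traj.residues() if key not in label_of]
    if missing:
        raise ValueError(f"segmentation labels missing for residues {missing}")
    bfac = np.empty(traj.n_atoms)
    for i, a in enumerate(traj.atoms):
        seg = label_of[(a.chain_id, a.residue_number)]
        bfac[i] = UNASSIGNED_BFACTOR if seg < 0 else float(seg)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("REMARK   3 RIGID-BODY SEGMENT ID IN B-FACTOR COLUMN\n")
        fh.write(f"REMARK   3 UNASSIGNED RESIDUES CARRY SENTINEL "
                 f"{UNASSIGNED_BFACTOR:.2f}\n")
        _write_frame(fh, traj.atoms, traj.coords[0], bfac)
        fh.write("END\n")
    return path


@dataclass
class TableDialect:
    """How a tabular input is laid out: delimiter, header flag, and a map
    from canonical column roles to the file's actual column names."""

    delimiter: str = "\t"
    header: bool = True
    columns: dict[str, str] = field(default_factory=dict)

    def resolve(self, role: str) -> str:
        return self.columns.get(role, role)


_REQUIRED_COLUMNS = {
    "shifts": ["residue_number", "atom_name", "shift_ppm"],
    "peaks": ["res_i", "atom_i", "res_j", "atom_j", "volume"],
    "melting": ["temperature_C", "value"],
}
_NUMERIC_ROLES = {"residue_number", "shift_ppm", "res_i", "res_j", "volume",
                  "temperature_C", "value"}


def read_table(path: str | Path, kind: str,
               dialect: TableDialect | None = None,
               label: str | None = None,
               temperature: float | None = None):
    """Read a typed tabular input.

    kind="shifts" → ShiftTable (ppm), kind="peaks" → PeakList,
    kind="melting" → MeltingSeries (°C, sorted ascending on load).
    Missing required columns and non-numeric cells are rejected with the
    column name / 1-based data row number.
    """
    if kind not in _REQUIRED_COLUMNS:
        raise ValueError(f"unknown table kind {kind!r}")
    dialect = dialect or TableDialect()
    path = Path(path)
    frame = pd.read_csv(path, sep=dialect.delimiter,
                        header=0 if dialect.header else None, dtype=str)
    if not dialect.header:
        frame.columns = [dialect.resolve(r) for r in _REQUIRED_COLUMNS[kind]]

    columns: dict[str, pd.Series] = {}
    for role in _REQUIRED_COLUMNS[kind]:
        name = dialect.resolve(role)
        if name not in frame.columns:
            raise ValueError(f"{path}: required column {name!r} ({role}) missing")
        col = frame[name]
        if role in _NUMERIC_ROLES:
            converted = pd.to_numeric(col, errors="coerce")
            bad = converted.isna() & col.notna()
            if bad.any():
                row = int(bad.idxmax()) + 1
                raise ValueError(
                    f"{path}: non-numeric value {col[bad.idxmax()]!r} in column "
                    f"{name!r}, data row {row}")
            col = converted
        columns[role] = col

    if label is None:
        label = path.stem
    if kind == "shifts":
        entries: dict[tuple[int, str], float] = {}
        for row, (res, atom, ppm) in enumerate(
                zip(columns["residue_number"], columns["atom_name"],
                    columns["shift_ppm"]), start=1):
            key = (int(res), str(atom))
            if key in entries:
                raise ValueError(f"{path}: duplicate shift for {key}, data row {row}")
            entries[key] = float(ppm)
        return ShiftTable(entries=entries, temperature=temperature, label=label)
    if kind == "peaks":
        peaks = []
        for row, (ri, ai, rj, aj, vol) in enumerate(
                zip(columns["res_i"], columns["atom_i"], columns["res_j"],
                    columns["atom_j"], columns["volume"]), start=1):
            try:
                peaks.append(Peak(int(ri), str(ai), int(rj), str(aj), float(vol)))
            except ValueError as exc:
                raise ValueError(f"{path}: data row {row}: {exc}") from exc
        return PeakList(peaks=peaks, temperature=temperature, label=label)
    # melting
    order = np.argsort(columns["temperature_C"].to_numpy())
    if not np.array_equal(order, np.arange(order.size)):
        logger.info("%s: melting series temperatures sorted ascending on load", path)
    return MeltingSeries(kind="melting",
                         temperatures=columns["temperature_C"].to_numpy()[order],
                         values=columns["value"].to_numpy()[order],
                         label=label)


def file_sha256(path: str | Path) -> str:
    """Checksum used when logging run inputs."""
    digest = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()
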