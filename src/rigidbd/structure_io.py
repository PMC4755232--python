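"""Structure and trajectory I/O: fixed-column PDB, whitespace PQR, PDB export.

Only ATOM/HETATM records are read; multiple MODEL blocks are split.  PQR
rows additionally carry a partial charge (e) and radius (A) as the last two
fields.  Writers are deterministic: identical inputs give byte-identical
files.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import geometry
from .model import RigidBodyState, Solute

__all__ = ["StructureRecord", "StructureParseError", "read_structure", "write_structure", "export_trajectory_pdb"]


class StructureParseError(ValueError):
    """Malformed structure file; message carries the line number."""


@dataclass
class StructureRecord:
    serial: int
    name: str
    residue_name: str
    residue_number: int
    chain: str
    position: np.ndarray
    charge: Optional[float] = None  # e (PQR)
    radius: Optional[float] = None  # A (PQR)

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")


def read_structure(path: str, format: Optional[str] = None) -> list[StructureRecord]:
    """Read a PDB or PQR file; returns records of the first model only.

    ``format`` defaults to the file extension.  Use :func:`read_models` for
    multi-model files.
    """
    models = read_models(path, format)
    return models[0] if models else []


def read_models(path: str, format: Optional[str] = None) -> list[list[StructureRecord]]:
    if format is None:
        format = "pqr" if str(path).lower().endswith(".pqr") else "pdb"
    if format not in ("pdb", "pqr"):
        raise StructureParseError(f"unknown structure format {format!r}")
    models: list[list[StructureRecord]] = []
    current: list[StructureRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            rec = line.rstrip("\n")
            if not rec.strip():
                continue
            # PQR is whitespace-delimited; PDB record names live in columns 1-6
            tag = rec.split(None, 1)[0] if format == "pqr" else rec[:6].strip()
            if tag == "ENDMDL":
                models.append(current)
                current = []
                continue
            if tag not in ("ATOM", "HETATM"):
                continue
            try:
                if format == "pdb":
                    current.append(_parse_pdb_atom(rec))
                else:
                    current.append(_parse_pqr_atom(rec))
            except (ValueError, IndexError) as exc:
                raise StructureParseError(f"{path}:{ln}: malformed {format.upper()} ATOM record: {exc}") from exc
    if current:
        models.append(current)
    return models


def _parse_pdb_atom(rec: str) -> StructureRecord:
    return StructureRecord(
        serial=int(rec[6:11]),
        name=rec[12:16].strip(),
        residue_name=rec[17:20].strip(),
        chain=rec[21:22].strip(),
        residue_number=int(rec[22:26]),
        position=np.array([float(rec[30:38]), float(rec[38:46]), float(rec[46:54])]),
    )


def _parse_pqr_atom(rec: str) -> StructureRecord:
    tok = rec.split()
    # ATOM serial name resname [chain] resnum x y z charge radius
    if len(tok) == 11:
        chain = tok[4]
        resnum_idx = 5
    elif len(tok) == 10:
        chain = ""
        resnum_idx = 4
    else:
        raise ValueError(f"expected 10 or 11 whitespace fields, got {len(tok)}")
    return StructureRecord(
        serial=int(tok[1]),
        name=tok[2],
        residue_name=tok[3],
        chain=chain,
        residue_number=int(tok[resnum_idx]),
        position=np.array([float(t) for t in tok[resnum_idx + 1 : resnum_idx + 4]]),
        charge=float(tok[resnum_idx + 4]),
        radius=float(tok[resnum_idx + 5]),
    )


def _pdb_atom_line(r: StructureRecord, pos: np.ndarray) -> str:
    name = r.name if len(r.name) == 4 else f" {r.name:<3s}"
    return (
        f"ATOM  {r.serial:5d} {name:<4.4s}{'':1s}{r.residue_name:<3.3s} {r.chain:1.1s}"
        f"{r.residue_number:4d}    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{0.0:6.2f}\n"
    )


def write_structure(records: Sequence[StructureRecord], path: str, format: str = "pdb") -> None:
    with open(path, "w") as fh:
        if format == "pdb":
            for r in records:
                fh.write(_pdb_atom_line(r, r.position))
        elif format == "pqr":
            for r in records:
                q = 0.0 if r.charge is None else r.charge
                a = 0.0 if r.radius is None else r.radius
                chain = f"{r.chain} " if r.chain else ""
                fh.write(
                    f"ATOM {r.serial:6d} {r.name:<4s} {r.residue_name:<4s} {chain}"
                    f"{r.residue_number:5d} {r.position[0]:11.4f} {r.position[1]:11.4f} "
                    f"{r.position[2]:11.4f} {q:9.4f} {a:8.4f}\n"
                )
        else:
            raise StructureParseError(f"unknown structure format {format!r}")
        fh.write("END\n")


def export_trajectory_pdb(
    trajectory,
    solutes: Sequence[Solute],
    path: str,
    stride: int = 1,
    atom_records: Optional[Sequence[Sequence[StructureRecord]]] = None,
) -> None:
    """Write a many-molecule trajectory as a multi-model PDB.

    One MODEL block per stored frame (honouring ``stride``); coordinates are
    the body-frame atoms of each solute's active conformation mapped through
    the frame's pose.  ``atom_records`` optionally supplies per-solute
    template records for names/residues; otherwise generic CA pseudo-atoms
    are written.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    with open(path, "w") as fh:
        for fi in range(0, trajectory.n_frames, stride):
            fh.write(f"MODEL     {fi // stride + 1:4d}\n")
            serial = 1
            for si, sol in enumerate(solutes):
                conf = sol.conformations[int(trajectory.conformation_indices[fi, si])]
                state = RigidBodyState(
                    trajectory.positions[fi, si], trajectory.orientations[fi, si],
                )
                lab = geometry.apply_pose(conf.atom_positions, state)
                for ai, pos in enumerate(lab):
                    if atom_records is not None:
                        r = atom_records[si][ai]
                        rec = StructureRecord(serial, r.name, r.residue_name, r.residue_number, r.chain, pos)
                    else:
                        rec = StructureRecord(serial, "CA", "GLY", si + 1, "A", pos)
                    fh.write(_pdb_atom_line(rec, pos))
                    serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")
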