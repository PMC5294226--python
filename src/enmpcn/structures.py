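"""Coarse-grained protein structures at the Cα level.

Both network frameworks implemented in this package (elastic network
models and protein contact networks) operate on one residue-level
representation: the Cα position of every amino acid plus the list of
heavy atoms needed for atom-contact counting. This module parses PDB
files into that representation, superposes pairs of conformations to
obtain an observed deformation vector, and writes annotated per-residue
tables and B-factor-painted PDB files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

#: Backbone heavy-atom names; everything else heavy is counted as side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class StructureError(ValueError):
    """Raised for empty, malformed, or incompatible structures."""


class CorrespondenceError(StructureError):
    """Raised when two structures share too few residues to compare."""


class ResidueKey(NamedTuple):
    """Identity of one residue: chain id, sequence number, insertion code, name."""

    chain: str
    seqnum: int
    icode: str
    name: str

    def label(self) -> str:
        return f"{self.name}{self.seqnum}{self.icode.strip()}:{self.chain}"


@dataclass
class CoarseStructure:
    """One Cα node per residue, with per-residue heavy-atom lists.

    Residues are ordered by chain (order of appearance) then by position
    in the file; the concatenated residue index is contiguous ``1..N``
    across chains, which is the convention used for all user-facing
    profiles and tables.
    """

    residues: list[ResidueKey]
    coords: np.ndarray  # (N, 3) Cα coordinates, Å
    atom_names: list[list[str]]  # heavy atoms per residue
    atom_coords: list[np.ndarray]  # (k_i, 3) per residue, Å
    name: str = ""
    sidechain_counts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.residues), 3):
            raise StructureError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.residues)} residues"
            )
        if len(self.atom_names) != len(self.residues) or len(self.atom_coords) != len(
            self.residues
        ):
            raise StructureError("per-residue atom lists must have length N")
        self.atom_coords = [np.asarray(a, dtype=float).reshape(-1, 3) for a in self.atom_coords]
        self.sidechain_counts = np.array(
            [sum(1 for nm in names if nm not in BACKBONE_ATOMS) for names in self.atom_names],
            dtype=int,
        )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def index(self) -> np.ndarray:
        """1-based concatenated residue index across chains."""
        return np.arange(1, len(self.residues) + 1)

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen

    def chain_slices(self) -> dict[str, slice]:
        """Contiguous 0-based slice of residue positions for each chain."""
        out: dict[str, slice] = {}
        start = 0
        for i, r in enumerate(self.residues):
            if r.chain != self.residues[start].chain:
                out[self.residues[start].chain] = slice(start, i)
                start = i
        out[self.residues[start].chain] = slice(start, len(self.residues))
        return out

    def subset(self, positions: Sequence[int], name: str | None = None) -> "CoarseStructure":
        """New structure restricted to the given 0-based residue positions (order kept)."""
        positions = list(positions)
        return CoarseStructure(
            residues=[self.residues[i] for i in positions],
            coords=self.coords[positions],
            atom_names=[self.atom_names[i] for i in positions],
            atom_coords=[self.atom_coords[i] for i in positions],
            name=name if name is not None else self.name,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CoarseStructure":
        """Apply ``x -> R x + t`` to all coordinates (Cα and heavy atoms)."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        return CoarseStructure(
            residues=list(self.residues),
            coords=self.coords @ rotation.T + translation,
            atom_names=[list(a) for a in self.atom_names],
            atom_coords=[a @ rotation.T + translation for a in self.atom_coords],
            name=self.name,
        )

    def to_pdb(self, path: str | Path, bfactors: np.ndarray | None = None) -> None:
        write_pdb(self, path, bfactors=bfactors)


@dataclass
class DeformationVector:
    """Observed conformational change between two superposed structures.

    ``delta_r`` holds, for each matched residue, the reference-minus-mobile
    Cα displacement after rigid-body superposition, flattened (x, y, z).
    """

    delta_r: np.ndarray  # (3 M,)
    matched: list[tuple[int, int]]  # (mobile position, reference position), 0-based
    residues: list[ResidueKey]

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.delta_r))

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    def per_residue(self) -> np.ndarray:
        """Displacement magnitude per matched residue (Å)."""
        return np.linalg.norm(self.delta_r.reshape(-1, 3), axis=1)


def read_pdb(
    path: str | Path,
    chains: set[str] | None = None,
    name: str | None = None,
) -> CoarseStructure:
    """Parse a PDB file into a :class:`CoarseStructure`.

    Only the first model is read; HETATM records (heme, waters, ligands)
    are excluded; hydrogens are dropped; for alternate locations the
    parser keeps the highest-occupancy variant. Residues lacking a Cα
    are dropped with a warning.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:  # pragma: no cover - empty file
        raise StructureError(f"{path}: no models found")

    residues: list[ResidueKey] = []
    coords: list[np.ndarray] = []
    atom_names: list[list[str]] = []
    atom_coords: list[np.ndarray] = []
    for chain in model:
        if chains is not None and chain.id not in chains:
            continue
        for res in chain:
            hetflag, seqnum, icode = res.id
            if hetflag.strip():
                continue  # HETATM
            if "CA" not in res:
                logger.warning(
                    "%s: residue %s%s:%s has no CA, dropped", path.name, res.resname, seqnum, chain.id
                )
                continue
            names: list[str] = []
            xyz: list[np.ndarray] = []
            for atom in res:  # packed list: one atom per altloc group, highest occupancy
                if (atom.element or "").upper() in {"H", "D"}:
                    continue
                names.append(atom.get_name())
                xyz.append(np.asarray(atom.get_coord(), float))
            residues.append(ResidueKey(chain.id, int(seqnum), icode, res.resname.strip()))
            coords.append(np.asarray(res["CA"].get_coord(), float))
            atom_names.append(names)
            atom_coords.append(np.array(xyz).reshape(-1, 3))

    if not residues:
        raise StructureError(f"{path}: no amino-acid residues with Cα found")
    return CoarseStructure(
        residues=residues,
        coords=np.array(coords),
        atom_names=atom_names,
        atom_coords=atom_coords,
        name=name if name is not None else path.stem,
    )


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition: returns (R, t) with ref ≈ R·mob + t."""
    cm_m = mobile.mean(axis=0)
    cm_r = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - cm_r, mobile - cm_m)
    r_mat = rot.as_matrix()
    return r_mat, cm_r - r_mat @ cm_m


def match_residues(
    mobile: CoarseStructure, reference: CoarseStructure
) -> list[tuple[int, int]]:
    """Residue correspondence by (chain, seqnum, icode); unmatched residues excluded."""
    ref_lookup = {
        (r.chain, r.seqnum, r.icode): i for i, r in enumerate(reference.residues)
    }
    matched = []
    for i, r in enumerate(mobile.residues):
        j = ref_lookup.get((r.chain, r.seqnum, r.icode))
        if j is not None:
            matched.append((i, j))
    return matched


def superpose(mobile: CoarseStructure, reference: CoarseStructure) -> DeformationVector:
    """Kabsch-superpose ``mobile`` onto ``reference`` and return Δr.

    Residues are matched by (chain, residue number, insertion code);
    at least three matches are required. ``delta_r`` is the
    reference-minus-transformed-mobile Cα displacement field, the
    observed conformational change used for mode-overlap analysis.
    """
    matched = match_residues(mobile, reference)
    if len(matched) < 3:
        raise CorrespondenceError(
            f"only {len(matched)} residues match between the two structures (need ≥ 3)"
        )
    mi = [i for i, _ in matched]
    ri = [j for _, j in matched]
    mob = mobile.coords[mi]
    ref = reference.coords[ri]
    r_mat, t_vec = _kabsch(mob, ref)
    delta = ref - (mob @ r_mat.T + t_vec)
    return DeformationVector(
        delta_r=delta.ravel(),
        matched=matched,
        residues=[reference.residues[j] for j in ri],
    )


def write_residue_table(
    structure: CoarseStructure,
    columns: dict[str, np.ndarray],
    path: str | Path,
) -> pd.DataFrame:
    """Write a per-residue TSV with identity columns plus the given value columns."""
    n = len(structure)
    data: dict[str, object] = {
        "chain": [r.chain for r in structure.residues],
        "resnum": [r.seqnum for r in structure.residues],
        "resname": [r.name for r in structure.residues],
        "index": structure.index,
    }
    for key, values in columns.items():
        values = np.asarray(values)
        if values.shape[0] != n:
            raise StructureError(
                f"column {key!r} has length {values.shape[0]}, expected {n}"
            )
        data[key] = values
    frame = pd.DataFrame(data)
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return frame


# PDB B-factor column is fixed-width %6.2f
_BFACTOR_MIN, _BFACTOR_MAX = -99.99, 999.99


def write_pdb(
    structure: CoarseStructure,
    path: str | Path,
    bfactors: np.ndarray | None = None,
) -> None:
    """Write the coarse structure as PDB text, optionally painting a
    per-residue scalar into the B-factor column (clamped to the field width)."""
    if bfactors is not None:
        bfactors = np.asarray(bfactors, dtype=float)
        if bfactors.shape[0] != len(structure):
            raise StructureError(
                f"bfactors length {bfactors.shape[0]} != N = {len(structure)}"
            )
        if np.any(bfactors < _BFACTOR_MIN) or np.any(bfactors > _BFACTOR_MAX):
            warnings.warn("B-factor values clamped to the PDB fixed-width field")
        bfactors = np.clip(bfactors, _BFACTOR_MIN, _BFACTOR_MAX)

    lines: list[str] = []
    serial = 1
    for i, res in enumerate(structure.residues):
        b = 0.0 if bfactors is None else float(bfactors[i])
        for nm, xyz in zip(structure.atom_names[i], structure.atom_coords[i]):
            atom_field = f" {nm:<3s}" if len(nm) < 4 else nm
            element = nm[0] if nm[0].isalpha() else nm[1]
            lines.append(
                f"ATOM  {serial:>5d} {atom_field:<4s} {res.name:<3s} {res.chain}"
                f"{res.seqnum:>4d}{res.icode:1s}   "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{b:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
        # chain break
        nxt = structure.residues[i + 1] if i + 1 < len(structure) else None
        if nxt is None or nxt.chain != res.chain:
            lines.append(f"TER   {serial:>5d}      {res.name:<3s} {res.chain}{res.seqnum:>4d}")
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_bfactor_pdb(
    structure: CoarseStructure, values: np.ndarray, path: str | Path
) -> None:
    """Write a PDB copy with the B-factor column replaced by a per-residue value."""
    write_pdb(structure, path, bfactors=np.asarray(values, dtype=float))
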