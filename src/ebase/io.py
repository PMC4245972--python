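"""Nucleotide-level structure model and PDB/mmCIF input/output.

The in-memory model is deliberately minimal: an :class:`RnaStructure` is an
ordered list of :class:`Nucleotide` records, each carrying its heavy atoms and
the three ring atoms (C2, C4, C6) from which the local nucleobase frame is
built.  Residues lacking any of the three frame atoms are skipped with a
logged warning; everything downstream may therefore assume complete frames.

Multi-model PDB files map onto :class:`Trajectory`, a list of structures
sharing one topology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.PDB import MMCIFParser, PDBIO, PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder

from .errors import (
    CorrespondenceError,
    EmptyStructureError,
    GeometryError,
    InputError,
    ParseError,
    TopologyError,
)

logger = logging.getLogger(__name__)

RING_ATOMS = ("C2", "C4", "C6")

#: residue-name -> one-letter parent base for recognized nucleotides
RESIDUE_NAMES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "DA": "A", "DC": "C", "DG": "G", "DT": "T",
    # occasional legacy one/two-letter DNA names
    "T": "T", "RA": "A", "RC": "C", "RG": "G", "RU": "U",
}

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CUT")


def base_class_of(base_identity: str) -> str:
    if base_identity in PURINES:
        return "purine"
    if base_identity in PYRIMIDINES:
        return "pyrimidine"
    raise InputError(f"unknown base identity {base_identity!r}")


@dataclass
class Nucleotide:
    """One nucleotide: identity, author bookkeeping and heavy-atom coordinates.

    Coordinates are in Å.  ``heavy_atoms`` maps atom name to a (3,) array and
    must contain the three ring atoms C2, C4 and C6.
    """

    base_identity: str
    chain_id: str
    resnum: int
    icode: str = ""
    resname: str = ""
    seq_index: int = 0
    heavy_atoms: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.base_class = base_class_of(self.base_identity)
        if not self.resname:
            self.resname = self.base_identity
        missing = [a for a in RING_ATOMS if a not in self.heavy_atoms]
        if missing:
            raise InputError(
                f"nucleotide {self.chain_id}{self.resnum} missing ring atoms {missing}"
            )
        # ring atoms must span a plane
        c2, c4, c6 = (np.asarray(self.heavy_atoms[a], float) for a in RING_ATOMS)
        area = 0.5 * np.linalg.norm(np.cross(c4 - c2, c6 - c2))
        if area <= 1e-3:
            raise GeometryError(
                f"ring atoms of {self.chain_id}{self.resnum} are (near-)collinear"
            )

    @property
    def ring_atoms(self) -> dict[str, np.ndarray]:
        return {a: self.heavy_atoms[a] for a in RING_ATOMS}

    @property
    def ring_coords(self) -> np.ndarray:
        """(3, 3) array of C2, C4, C6 coordinates in that order."""
        return np.array([self.heavy_atoms[a] for a in RING_ATOMS], float)

    @property
    def ring_center(self) -> np.ndarray:
        return self.ring_coords.mean(axis=0)

    def copy(self) -> "Nucleotide":
        return Nucleotide(
            base_identity=self.base_identity,
            chain_id=self.chain_id,
            resnum=self.resnum,
            icode=self.icode,
            resname=self.resname,
            seq_index=self.seq_index,
            heavy_atoms={k: np.array(v, float) for k, v in self.heavy_atoms.items()},
        )


class RnaStructure:
    """Ordered collection of nucleotides from one model of one file."""

    def __init__(self, nucleotides: Sequence[Nucleotide], model_index: int = 0,
                 source: str = ""):
        self.nucleotides: list[Nucleotide] = list(nucleotides)
        self.model_index = model_index
        self.source = source
        for i, nt in enumerate(self.nucleotides):
            nt.seq_index = i

    def __len__(self) -> int:
        return len(self.nucleotides)

    def __iter__(self):
        return iter(self.nucleotides)

    def __getitem__(self, i: int) -> Nucleotide:
        return self.nucleotides[i]

    @property
    def chain_ids(self) -> list[str]:
        return [nt.chain_id for nt in self.nucleotides]

    @property
    def author_numbering(self) -> list[tuple[int, str]]:
        return [(nt.resnum, nt.icode) for nt in self.nucleotides]

    @property
    def sequence(self) -> str:
        return "".join(nt.base_identity for nt in self.nucleotides)

    def ring_centers(self) -> np.ndarray:
        """(N, 3) array of six-membered-ring centroids."""
        return np.array([nt.ring_center for nt in self.nucleotides])

    def heavy_coords(self) -> np.ndarray:
        """All heavy-atom coordinates concatenated in nucleotide order."""
        return np.concatenate([
            np.array(list(nt.heavy_atoms.values()), float) for nt in self.nucleotides
        ])

    def chain_breaks(self) -> list[int]:
        """Indices i such that a chain boundary falls between i and i+1."""
        return [
            i for i in range(len(self) - 1)
            if self.nucleotides[i].chain_id != self.nucleotides[i + 1].chain_id
        ]

    def subset(self, indices: Iterable[int]) -> "RnaStructure":
        """New structure from the given nucleotide indices, in the given order."""
        nts = [self.nucleotides[i].copy() for i in indices]
        return RnaStructure(nts, model_index=self.model_index, source=self.source)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "RnaStructure":
        """Copy with every atom mapped to ``R x + t`` (rigid motion helper)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        out = []
        for nt in self.nucleotides:
            c = nt.copy()
            c.heavy_atoms = {k: R @ v + t for k, v in c.heavy_atoms.items()}
            out.append(c)
        return RnaStructure(out, model_index=self.model_index, source=self.source)


class Trajectory:
    """Ordered frames sharing one topology (same nucleotides, same order)."""

    def __init__(self, frames: Sequence[RnaStructure], time_step: float = 1.0):
        frames = list(frames)
        if not frames:
            raise InputError("trajectory needs at least one frame")
        n0 = len(frames[0])
        seq0 = frames[0].sequence
        for i, f in enumerate(frames):
            if len(f) != n0 or f.sequence != seq0:
                raise TopologyError(
                    f"frame {i} has {len(f)} nt ({f.sequence!r}); "
                    f"frame 0 has {n0} ({seq0!r})"
                )
        self.frames = frames
        self.time_step = time_step

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> RnaStructure:
        return self.frames[i]


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _pick_atom(atom):
    """Resolve a possibly disordered atom: keep altloc 'A' or blank."""
    if not atom.is_disordered():
        return atom
    for alt in ("A", " ", ""):
        if atom.disordered_has_id(alt):
            return atom.disordered_get(alt)
    return atom.disordered_get_list()[0]


def _residue_to_nucleotide(residue, chain_id: str,
                           name_map: Mapping[str, str] | None) -> Nucleotide | None:
    resname = residue.get_resname().strip()
    identity = RESIDUE_NAMES.get(resname)
    if identity is None and name_map:
        identity = name_map.get(resname)
    if identity is None:
        logger.warning("skipping unrecognized residue %s %s%s", resname,
                       chain_id, residue.id[1])
        return None
    heavy: dict[str, np.ndarray] = {}
    for atom in residue.get_list():
        atom = _pick_atom(atom)
        name = atom.get_name().strip()
        if atom.element == "H" or name.startswith("H"):
            continue
        if name in heavy:  # duplicate names cannot occur after altloc pick
            continue
        heavy[name] = np.array(atom.get_coord(), float)
    missing = [a for a in RING_ATOMS if a not in heavy]
    if missing:
        logger.warning("skipping residue %s %s%s: missing frame atom(s) %s",
                       resname, chain_id, residue.id[1], ",".join(missing))
        return None
    # N9 presence is a purine consistency check only
    if base_class_of(identity) == "purine" and "N9" not in heavy:
        logger.warning("purine %s %s%s lacks N9 (kept; frame uses C2/C4/C6 only)",
                       resname, chain_id, residue.id[1])
    _, resnum, icode = residue.id
    return Nucleotide(
        base_identity=identity, chain_id=chain_id, resnum=resnum,
        icode=icode.strip(), resname=resname, heavy_atoms=heavy,
    )


def _parse_file(path):
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    suffix = path.suffix.lower()
    parser = MMCIFParser(QUIET=True) if suffix in (".cif", ".mmcif") \
        else PDBParser(QUIET=True)
    try:
        return parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise ParseError(f"could not parse {path}: {exc}") from exc


def _model_to_structure(model, model_index: int, source: str,
                        name_map: Mapping[str, str] | None) -> RnaStructure:
    nts = []
    for chain in model:
        for residue in chain:
            nt = _residue_to_nucleotide(residue, chain.id, name_map)
            if nt is not None:
                nts.append(nt)
    if not nts:
        raise EmptyStructureError(f"{source}: no usable nucleotide found")
    return RnaStructure(nts, model_index=model_index, source=source)


def read_structure(path, model: int | None = None,
                   name_map: Mapping[str, str] | None = None) -> RnaStructure:
    """Read one model of a PDB or mmCIF file into an :class:`RnaStructure`.

    Parameters
    ----------
    path:
        PDB (``.pdb``) or mmCIF (``.cif``) file.
    model:
        Model index (0-based) for multi-model files; default first model.
    name_map:
        Optional extra residue-name -> parent-base mapping for modified
        nucleotides, e.g. ``{"PSU": "U"}``.  Unmapped modified residues are
        skipped with a warning.
    """
    bio = _parse_file(path)
    models = list(bio)
    if not models:
        raise EmptyStructureError(f"{path}: file contains no model")
    idx = 0 if model is None else model
    if idx >= len(models):
        raise InputError(f"{path}: model {idx} requested, file has {len(models)}")
    return _model_to_structure(models[idx], idx, str(path), name_map)


def read_trajectory(path, name_map: Mapping[str, str] | None = None) -> Trajectory:
    """Read a multi-model PDB as a trajectory (one frame per MODEL record)."""
    bio = _parse_file(path)
    frames = [
        _model_to_structure(m, i, str(path), name_map) for i, m in enumerate(bio)
    ]
    if not frames:
        raise EmptyStructureError(f"{path}: file contains no model")
    return Trajectory(frames)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _build_bio_structure(frames: Sequence[RnaStructure]):
    builder = StructureBuilder()
    builder.init_structure("ebase")
    for mi, structure in enumerate(frames):
        builder.init_model(mi)
        current_chain = None
        serial = 1
        for nt in structure:
            if nt.chain_id != current_chain:
                builder.init_chain(nt.chain_id)
                current_chain = nt.chain_id
            builder.init_seg(" ")
            builder.init_residue(nt.resname.rjust(3)[:3].strip() or nt.base_identity,
                                 " ", nt.resnum, nt.icode or " ")
            for name, coord in nt.heavy_atoms.items():
                builder.init_atom(name, np.asarray(coord, float), 0.0, 1.0, " ",
                                  name.center(4)[:4], serial, element=name[0])
                serial += 1
    return builder.get_structure()


def write_structure(structure: RnaStructure, path) -> None:
    """Write a structure as a single-model PDB file."""
    if len(structure) == 0:
        raise InputError("refusing to write an empty structure")
    _write_frames([structure], path)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    _write_frames(traj.frames, path)


def _write_frames(frames: Sequence[RnaStructure], path) -> None:
    bio = _build_bio_structure(frames)
    io = PDBIO()
    io.set_structure(bio)
    try:
        io.save(str(path))
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


def check_correspondence(a: RnaStructure, b: RnaStructure) -> int:
    """Assert positional 1:1 correspondence; return the common length."""
    if len(a) != len(b):
        raise CorrespondenceError(
            f"structures have {len(a)} and {len(b)} nucleotides"
        )
    return len(a)
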