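"""PDB structure I/O and backbone bookkeeping.

The pipeline's common currency is :class:`ChainStructure`: an ordered list of
amino-acid residues with explicit atoms.  Reading and writing go through
gemmi; on top of its parser we apply the pipeline's preparation rules
(alternate-location resolution by occupancy, HETATM/water exclusion,
nonstandard residues rendered ``X``, unstructured-tail trimming).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import EmptyStructureError, MissingBackboneError, ValidationError

BACKBONE_ATOMS = ("N", "CA", "C", "O")

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}
AA_1TO3["X"] = "UNK"


@dataclass
class Atom:
    """A single atom: name, element symbol, position (Å), occupancy, B-factor (Å²)."""

    name: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValidationError(f"atom {self.name!r}: xyz must be a finite 3-vector")


@dataclass
class Residue:
    """An amino-acid residue: one-letter code (``X`` if nonstandard), author
    numbering, insertion code, and its atoms."""

    code: str
    seq_index: int
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def backbone_complete(self) -> bool:
        names = [a.name for a in self.atoms]
        return all(names.count(n) == 1 for n in BACKBONE_ATOMS)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def bfactor(self) -> float:
        if not self.atoms:
            return 0.0
        return float(np.mean([a.bfactor for a in self.atoms]))


@dataclass
class ChainStructure:
    """An ordered single chain of residues, the unit every stage operates on."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.code for r in self.residues)

    def coords(self) -> np.ndarray:
        """All atom coordinates, concatenated in residue/atom order, shape (n, 3)."""
        if not self.residues:
            return np.zeros((0, 3))
        return np.array([a.xyz for r in self.residues for a in r.atoms], dtype=float)


@dataclass
class Transform:
    """A proper rigid-body motion: ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValidationError("Transform needs a 3x3 rotation and a 3-vector")
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-8 or abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValidationError("rotation must be proper orthonormal (det +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def compose(self, other: "Transform") -> "Transform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)


def _residue_code(name: str) -> str:
    if name in AA_3TO1:
        return AA_3TO1[name]
    return "X"


def _is_water(name: str) -> bool:
    return name in ("HOH", "WAT", "DOD")


def read_pdb(path) -> list[ChainStructure]:
    """Read a PDB file into one :class:`ChainStructure` per chain.

    Alternate locations are resolved per atom name by highest occupancy
    (ties: first occurrence in the file); HETATM records and waters are
    dropped; nonstandard amino acids keep their atoms but render as ``X``.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no coordinate records")
    model = st[0]
    chains: list[ChainStructure] = []
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.het_flag != "A" or _is_water(res.name):
                continue
            atoms: list[Atom] = []
            # altloc resolution: per atom name keep the highest-occupancy
            # conformer; ties broken by file order (stable max).
            by_name: dict[str, gemmi.Atom] = {}
            for ga in res:
                prev = by_name.get(ga.name)
                if prev is None or ga.occ > prev.occ:
                    by_name[ga.name] = ga
            for ga in res:  # preserve file order of first occurrences
                if by_name.get(ga.name) is ga:
                    atoms.append(Atom(
                        name=ga.name,
                        element=ga.element.name,
                        xyz=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=float(min(max(ga.occ, 0.0), 1.0)),
                        bfactor=float(ga.b_iso),
                    ))
            if atoms:
                residues.append(Residue(
                    code=_residue_code(res.name),
                    seq_index=res.seqid.num,
                    atoms=atoms,
                    icode=(res.seqid.icode or "").strip(),
                ))
        if residues:
            residues.sort(key=lambda r: (r.seq_index, r.icode))
            chains.append(ChainStructure(chain_id=chain.name, residues=residues,
                                         source_id=path.stem))
    if not chains:
        raise EmptyStructureError(f"{path}: no standard ATOM records")
    return chains


def write_pdb(structures: Sequence[ChainStructure], path) -> None:
    """Write chains as standard PDB ATOM records (1-based serials, 3-decimal coords)."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = "motifdock"
    model = gemmi.Model("1")
    for cs in structures:
        chain = gemmi.Chain(cs.chain_id or "A")
        for res in cs.residues:
            if not res.atoms:
                raise ValidationError(
                    f"residue {res.seq_index} in chain {cs.chain_id}: no atoms to write")
            gres = gemmi.Residue()
            gres.name = AA_1TO3.get(res.code, "UNK")
            gres.seqid = gemmi.SeqId(int(res.seq_index), res.icode or " ")
            gres.het_flag = "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element or "C")
                ga.pos = gemmi.Position(*np.round(atom.xyz, 3))
                ga.occ = float(atom.occupancy)
                ga.b_iso = float(atom.bfactor)
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write PDB file {path}: {exc}") from exc


def write_models_pdb(models: Sequence[Sequence[ChainStructure]], path) -> None:
    """Write a multi-model PDB (MODEL/ENDMDL blocks), one model per entry."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = "motifdock"
    for mi, chains in enumerate(models, start=1):
        model = gemmi.Model(str(mi))
        for cs in chains:
            chain = gemmi.Chain(cs.chain_id or "A")
            for res in cs.residues:
                gres = gemmi.Residue()
                gres.name = AA_1TO3.get(res.code, "UNK")
                gres.seqid = gemmi.SeqId(int(res.seq_index), res.icode or " ")
                gres.het_flag = "A"
                for atom in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element or "C")
                    ga.pos = gemmi.Position(*np.round(atom.xyz, 3))
                    ga.occ = float(atom.occupancy)
                    ga.b_iso = float(atom.bfactor)
                    gres.add_atom(ga)
                chain.add_residue(gres)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write PDB file {path}: {exc}") from exc


def extract_backbone(chain: ChainStructure, start: int, length: int) -> np.ndarray:
    """Backbone coordinates of ``chain[start:start+length]`` as an (L, 4, 3) array.

    Atom order per residue is N, CA, C, O.  Raises
    :class:`MissingBackboneError` if any residue in the window is incomplete,
    so callers can skip that motif match.
    """
    if start < 0 or length < 1 or start + length > len(chain):
        raise ValidationError(
            f"window [{start}, {start + length}) outside chain of length {len(chain)}")
    out = np.empty((length, 4, 3), dtype=float)
    for i, res in enumerate(chain.residues[start:start + length]):
        if not res.backbone_complete:
            raise MissingBackboneError(
                f"{chain.source_id}:{chain.chain_id} residue {res.seq_index} "
                f"lacks a complete N/CA/C/O backbone")
        for j, name in enumerate(BACKBONE_ATOMS):
            out[i, j] = res.atom(name).xyz
    return out


def _disorder_flags(chain: ChainStructure) -> list[bool]:
    """A residue counts as unstructured if its backbone is incomplete or its
    B-factor exceeds the chain's 90th percentile."""
    if not chain.residues:
        return []
    bfacs = np.array([r.bfactor for r in chain.residues])
    cutoff = float(np.percentile(bfacs, 90))
    return [(not r.backbone_complete) or (r.bfactor > cutoff)
            for r in chain.residues]


def trim_unstructured_tails(chain: ChainStructure, max_tail: int = 10) -> ChainStructure:
    """Remove unstructured terminal runs of length at most ``max_tail``.

    A disordered run longer than ``max_tail`` is left in place (it is treated
    as structure, not tail).  The B-factor percentile is recomputed and
    trimming repeated until a fixed point, so the operation is idempotent.
    Interior residues are never touched; ``max_tail=0`` disables trimming.
    """
    if max_tail < 0:
        raise ValidationError("max_tail must be >= 0")
    if max_tail == 0:
        return chain
    residues = list(chain.residues)
    while residues:
        flags = _disorder_flags(ChainStructure(chain.chain_id, residues))
        lo = 0
        while lo < len(flags) and flags[lo]:
            lo += 1
        hi = len(flags)
        while hi > 0 and flags[hi - 1]:
            hi -= 1
        if lo > max_tail:
            lo = 0
        n_c = len(flags) - max(hi, lo)
        if n_c > max_tail:
            n_c = 0
        if lo == 0 and n_c == 0:
            break
        residues = residues[lo:len(residues) - n_c]
    return ChainStructure(chain.chain_id, residues, chain.source_id)
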