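"""Synthetic structures for building and testing the pipeline end to end.

Everything the protocol consumes — a receptor with a geometrically
complementary pocket, a native peptide pose planted in it, and a fragment
database with a controlled number of motif matches — is generated
deterministically from a :class:`FixtureSpec` seed.  Geometry is idealized
(planar extended strands with fixed intra-residue offsets), which trades
physical realism for exact, verifiable ground truth: the planted pose can be
confirmed to be the global optimum of the scoring function by direct
enumeration, with no reference to the FFT path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .fftdock import (EnergyGrids, GridSpec, WeightSet, auto_grid_spec,
                      fragment_charges, make_receptor_grids)
from .motiflib import (AA_ALPHABET, FragmentRecord, compile_motif,
                       find_matches)
from .structio import (Atom, ChainStructure, Residue, Transform, write_pdb)

RISE = 4.0  # Å per residue along the strand axis (lattice-aligned)
# intra-residue atom offsets (N, CA, C, O) for the idealized extended strand;
# integer offsets keep every atom on the 1 Å voxel lattice, so grid
# discretization is exact and planted optima are free of rounding slop
_TEMPLATE = np.array([
    [0.0, 0.0, 0.0],    # N
    [1.0, 1.0, 0.0],    # CA
    [2.0, 0.0, 0.0],    # C
    [3.0, -1.0, 0.0],   # O
])
_ELEMENTS = ("N", "C", "C", "O")
_ATOM_NAMES = ("N", "CA", "C", "O")

STRAND_LEN = 12        # receptor strand length (residues)
GAP = (3, 9)           # stub strands keep residues [0, GAP[0]) and [GAP[1], STRAND_LEN)
Y_SPACING = 5.0
DEFAULT_LAYER_Z = 4.0
PENDANT_HEIGHT = 2.0   # Å, charge site above the ligand's charged CA
_POSITIVE = "KR"
_NEGATIVE = "DE"


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for every synthetic input.

    ``planted_variants`` plants extra windows matching a different (e.g.
    generalized or flank-extended) motif; variants whose windows also match
    the primary motif count toward ``planted_matches``.
    """

    seed: int = 0
    n_db_chains: int = 30
    planted_matches: int = 150
    motif: str = "KGRRL"
    noise_sigma: float = 0.1
    pocket_depth: float = DEFAULT_LAYER_Z
    n_conformers: int = 2
    planted_variants: tuple = ()
    duplicate_of: Optional[str] = None


def _strand_residues(n: int, origin, codes: str, start_index: int,
                     bfactor: float = 10.0) -> list[Residue]:
    origin = np.asarray(origin, dtype=float)
    residues = []
    for i in range(n):
        base = origin + np.array([i * RISE, 0.0, 0.0])
        atoms = [Atom(name=nm, element=el, xyz=base + off, bfactor=bfactor)
                 for nm, el, off in zip(_ATOM_NAMES, _ELEMENTS, _TEMPLATE)]
        residues.append(Residue(code=codes[i], seq_index=start_index + i, atoms=atoms))
    return residues


def strand_backbone(n: int, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Idealized extended backbone, shape (n, 4, 3)."""
    origin = np.asarray(origin, dtype=float)
    bases = origin[None, :] + np.arange(n)[:, None] * np.array([RISE, 0.0, 0.0])
    return bases[:, None, :] + _TEMPLATE[None, :, :]


def _charged_positions(motif: str) -> list[tuple[int, float]]:
    """(position, charge) of every charged *fixed* motif residue."""
    out = []
    for i, ch in enumerate(motif.upper()):
        if ch in _POSITIVE:
            out.append((i, +1.0))
        elif ch in _NEGATIVE:
            out.append((i, -1.0))
    return out


def make_toy_receptor(spec: FixtureSpec) -> ChainStructure:
    """A ~66-residue slab of extended strands with a peptide-sized groove.

    Two layers of strands run along x; the top layer's middle strand is
    interrupted, leaving a groove closed at both ends that exactly fits the
    motif-length peptide.  A charge site complementary to the peptide's first
    charged residue hangs over the groove: the charge-bearing atom sits
    ``PENDANT_HEIGHT`` above the planted CA, recessed behind a collar of
    neutral atoms so the optimal charge contact is reachable only from the
    planted placement.  ``pocket_depth <= 0`` closes the groove (convex
    slab, no charge apparatus).
    """
    layer_z = spec.pocket_depth if spec.pocket_depth > 0 else DEFAULT_LAYER_Z
    residues: list[Residue] = []
    idx = 1

    def add(n, origin, codes):
        nonlocal idx
        residues.extend(_strand_residues(n, origin, codes, idx))
        idx += n

    plain = "A" * STRAND_LEN
    for y in (0.0, Y_SPACING, 2 * Y_SPACING):        # bottom layer
        add(STRAND_LEN, (0.0, y, 0.0), plain)
    add(STRAND_LEN, (0.0, 0.0, layer_z), plain)       # top layer, side walls
    add(STRAND_LEN, (0.0, 2 * Y_SPACING, layer_z), plain)
    if spec.pocket_depth > 0:                         # interrupted middle strand
        g0, g1 = GAP
        add(g0, (0.0, Y_SPACING, layer_z), "A" * g0)
        add(STRAND_LEN - g1, (g1 * RISE, Y_SPACING, layer_z),
            "A" * (STRAND_LEN - g1))
        origin = _pocket_origin(len(spec.motif), layer_z)
        for pos, q in _charged_positions(spec.motif):
            ca = origin + np.array([pos * RISE, 0.0, 0.0]) + _TEMPLATE[1]
            pendant = ca + np.array([0.0, 0.0, PENDANT_HEIGHT])
            code, charge_atom = ("D", "CG") if q > 0 else ("K", "NZ")
            base = pendant + np.array([-1.0, 0.0, 3.0])  # backbone out of the way
            atoms = [Atom(name=nm, element=el, xyz=base + off, bfactor=10.0)
                     for nm, el, off in zip(_ATOM_NAMES, _ELEMENTS, _TEMPLATE)]
            atoms.append(Atom(name=charge_atom, element="O" if q > 0 else "N",
                              xyz=pendant, bfactor=10.0))
            # neutral collar blocking every distance-2 lattice approach to the
            # pendant except the one from the planted CA below
            for ci, off in enumerate(([2, 0, 0], [-2, 0, 0], [0, 2, 0],
                                      [0, -2, 0], [0, 0, 2])):
                atoms.append(Atom(name=f"CB{ci + 1}", element="C",
                                  xyz=pendant + np.array(off, dtype=float),
                                  bfactor=10.0))
            residues.append(Residue(code=code, seq_index=idx, atoms=atoms))
            idx += 1
    else:
        add(STRAND_LEN, (0.0, Y_SPACING, layer_z), plain)
    return ChainStructure(chain_id="R", residues=residues, source_id="toy_receptor")


def _peptide_codes(motif: str, rng: np.random.Generator,
                   background: str) -> str:
    return "".join(ch if ch != "X" else background[int(rng.integers(len(background)))]
                   for ch in motif.upper())


def _pocket_origin(motif_len: int, layer_z: float) -> np.ndarray:
    g0, g1 = GAP
    free_lo = (g0 - 1) * RISE + _TEMPLATE[:, 0].max()   # last stub-N atom x
    free_hi = g1 * RISE                                  # first stub-C atom x
    span = (motif_len - 1) * RISE + _TEMPLATE[:, 0].max()
    px = free_lo + (free_hi - free_lo - span) / 2.0
    return np.array([px, Y_SPACING, layer_z])


def make_planted_complex(spec: FixtureSpec) -> tuple[ChainStructure, ChainStructure, Transform]:
    """Receptor, native peptide planted in its pocket, and the ground-truth
    transform (identity: database fragments carry native-frame coordinates).

    The planted placement is constructed to be the unique optimum of the
    standard score over the fixture rotation set; tests confirm this by
    exhaustive direct scoring rather than assuming it.
    """
    if spec.pocket_depth <= 0:
        raise ValidationError("a planted complex needs pocket_depth > 0")
    receptor = make_toy_receptor(spec)
    L = len(spec.motif)
    rng = np.random.default_rng(spec.seed)
    background = _background_alphabet(spec)
    codes = _peptide_codes(spec.motif, rng, background)
    origin = _pocket_origin(L, spec.pocket_depth)
    peptide = ChainStructure(
        chain_id="P",
        residues=_strand_residues(L, origin, codes, start_index=1),
        source_id="native_peptide")
    return receptor, peptide, Transform.identity()


def _background_alphabet(spec: FixtureSpec) -> str:
    forbidden = set(_POSITIVE + _NEGATIVE + "H")  # keep background neutral
    for m in (spec.motif, *[v[0] for v in spec.planted_variants]):
        forbidden.update(ch for ch in m.upper() if ch != "X")
    background = "".join(ch for ch in AA_ALPHABET if ch not in forbidden)
    if not background:
        raise ValidationError("motif fixes every amino-acid type; no background left")
    return background


def make_fragment_database(spec: FixtureSpec) -> list[ChainStructure]:
    """Chains of random background sequence with exactly ``planted_matches``
    windows matching ``spec.motif``.

    Every planted window carries the native peptide backbone jittered by
    ``noise_sigma`` Å Gaussian noise, so downstream clustering sees real
    conformational structure.  Background letters exclude all fixed motif
    letters, which is what makes the match count exact by construction; it is
    still re-verified with :func:`find_matches` before returning.
    """
    if spec.planted_matches < 1:
        raise ValidationError("need at least one planted match")
    primary = compile_motif(spec.motif)
    L = len(primary)
    rng = np.random.default_rng(spec.seed + 1)
    background = _background_alphabet(spec)

    variants = [(compile_motif(m), int(c)) for m, c in spec.planted_variants]
    # a variant contributes to the primary count iff its fixed skeleton
    # already satisfies every fixed position of the primary motif
    n_from_variants = 0
    for pat, c in variants:
        probe = "".join(p if p is not None else background[0] for p in pat.positions)
        if find_matches(primary, probe):
            n_from_variants += c
    n_pure = spec.planted_matches - n_from_variants
    if n_pure < 0:
        raise ValidationError("planted variants alone exceed planted_matches")

    _, native_peptide, _ = make_planted_complex(
        FixtureSpec(seed=spec.seed, motif=spec.motif,
                    pocket_depth=spec.pocket_depth if spec.pocket_depth > 0
                    else DEFAULT_LAYER_Z))
    native_bb = np.stack([
        np.array([a.xyz for a in r.atoms]) for r in native_peptide.residues])
    conformers = _conformer_set(native_bb, max(spec.n_conformers, 1))

    slots: list[str] = []
    for _ in range(n_pure):
        slots.append(_peptide_codes(spec.motif, rng, background))
    for pat, c in variants:
        for _ in range(c):
            slots.append(_peptide_codes(pat.render(), rng, background))

    n_chains = max(spec.n_db_chains, 1)
    chains: list[ChainStructure] = []
    per_chain: list[list[str]] = [[] for _ in range(n_chains)]
    for i, s in enumerate(slots):
        per_chain[i % n_chains].append(s)

    for ci, windows in enumerate(per_chain):
        seq_parts = []
        window_starts = []
        pos = 0
        spacer = lambda n: "".join(background[int(rng.integers(len(background)))]
                                   for _ in range(n))
        lead = spacer(2)
        seq_parts.append(lead)
        pos += len(lead)
        for w in windows:
            window_starts.append(pos)
            seq_parts.append(w)
            pos += len(w)
            gap = spacer(2)
            seq_parts.append(gap)
            pos += len(gap)
        if not windows:
            seq_parts.append(spacer(28))
            pos += 28
        seq = "".join(seq_parts)
        bb = strand_backbone(len(seq))
        for wi, start in enumerate(window_starts):
            jitter = rng.normal(0.0, spec.noise_sigma, size=(L, 4, 3)) \
                if spec.noise_sigma > 0 else 0.0
            conformer = conformers[(ci + wi) % len(conformers)]
            bb[start:start + L] = conformer + jitter
        residues = []
        for i, code in enumerate(seq):
            atoms = [Atom(name=nm, element=el, xyz=bb[i, j], bfactor=10.0)
                     for j, (nm, el) in enumerate(zip(_ATOM_NAMES, _ELEMENTS))]
            residues.append(Residue(code=code, seq_index=i + 1, atoms=atoms))
        chains.append(ChainStructure(chain_id="A", residues=residues,
                                     source_id=f"db{ci:04d}"))

    if spec.duplicate_of:
        seq = spec.duplicate_of.upper()
        bb = strand_backbone(len(seq))
        residues = []
        for i, code in enumerate(seq):
            atoms = [Atom(name=nm, element=el, xyz=bb[i, j], bfactor=10.0)
                     for j, (nm, el) in enumerate(zip(_ATOM_NAMES, _ELEMENTS))]
            residues.append(Residue(code=code if code in AA_ALPHABET else "X",
                                    seq_index=i + 1, atoms=atoms))
        chains.append(ChainStructure(chain_id="A", residues=residues,
                                     source_id="db_dup"))

    found = sum(len(find_matches(primary, c.sequence)) for c in chains
                if c.source_id != "db_dup")
    if found != spec.planted_matches:
        raise ValidationError(
            f"fixture self-check failed: planted {spec.planted_matches} primary "
            f"matches but find_matches sees {found}")
    return chains


def _conformer_set(native_bb: np.ndarray, n: int) -> list[np.ndarray]:
    """Distinct, groove-compatible conformational variants of the native
    backbone: conformer k shifts residues {k, k+1} by one lattice step along
    the strand axis (pairwise superposed RMSD ~0.6 Å, beyond the 0.5 Å
    fragment clustering radius, while all atoms stay clash-free in the
    pocket)."""
    L = native_bb.shape[0]
    out = [native_bb.copy()]
    for k in range(1, min(n, L - 1)):
        variant = native_bb.copy()
        variant[k:k + 2, :, 0] += 1.0
        out.append(variant)
    return out


def native_fragment(spec: FixtureSpec) -> FragmentRecord:
    """The native peptide backbone as a FragmentRecord (the ideal docking
    candidate; ground truth for planted-pose recovery)."""
    _, peptide, _ = make_planted_complex(spec)
    bb = np.stack([np.array([a.xyz for a in r.atoms]) for r in peptide.residues])
    return FragmentRecord(source_id="native", chain_id="P", start=0,
                          sequence=peptide.sequence, backbone=bb)


def add_floppy_tail(chain: ChainStructure, n: int, terminus: str = "N",
                    bfactor: float = 50.0) -> ChainStructure:
    """Append an n-residue high-B-factor tail (for tail-trimming tests)."""
    if terminus not in ("N", "C"):
        raise ValidationError("terminus must be 'N' or 'C'")
    coords = chain.coords()
    if terminus == "N":
        origin = coords.min(axis=0) - np.array([n * RISE + RISE, 0.0, 0.0])
        tail = _strand_residues(n, origin, "G" * n,
                                start_index=chain.residues[0].seq_index - n,
                                bfactor=bfactor)
        residues = tail + list(chain.residues)
    else:
        origin = coords.max(axis=0) + np.array([RISE, 0.0, 0.0])
        tail = _strand_residues(n, origin, "G" * n,
                                start_index=chain.residues[-1].seq_index + 1,
                                bfactor=bfactor)
        residues = list(chain.residues) + tail
    return ChainStructure(chain.chain_id, residues, chain.source_id)


# ---------------------------------------------------------------------------
# direct (non-FFT) scoring, used to verify planted optimality by enumeration

def direct_best_pose(grids: EnergyGrids, fragment: FragmentRecord,
                     rotations, weights: WeightSet):
    """Exhaustively score every (rotation, valid translation) by direct
    summation over ligand atoms — no FFT anywhere — and return
    ``(rotation_index, translation_voxel, score)`` of the optimum.

    Ties resolve to the lower rotation index, then the lexicographically
    first translation, matching the docking convention.
    """
    dims = np.array(grids.spec.dims)
    charges = fragment_charges(fragment)
    coords = fragment.backbone_flat()
    centered = coords - coords.mean(axis=0)
    best = None
    for ri, rot in enumerate(rotations):
        offsets = np.rint(centered @ np.asarray(rot).T / grids.spec.spacing).astype(int)
        lo = np.maximum(0, -offsets.min(axis=0))
        hi = dims - 1 - offsets.max(axis=0)
        if np.any(hi < lo):
            continue
        shape = tuple(hi - lo + 1)
        S = np.zeros(shape)
        for o, q in zip(offsets, charges):
            sl = tuple(slice(lo[k] + o[k], hi[k] + o[k] + 1) for k in range(3))
            S += weights.w_rep * grids.rep[sl] + weights.w_att * grids.att[sl]
            if q:
                S += weights.w_elec * q * grids.elec[sl]
        flat = int(np.argmin(S))
        t = np.array(np.unravel_index(flat, shape)) + lo
        score = float(S.flat[flat])
        if best is None or score < best[2]:
            best = (ri, tuple(int(x) for x in t), score)
    return best


def write_fixture_set(out_dir, spec: FixtureSpec) -> dict:
    """Write receptor, native peptide, database PDBs, manifest and spec to
    ``out_dir``; returns a paths dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    receptor, peptide, truth = make_planted_complex(spec)
    db = make_fragment_database(spec)
    write_pdb([receptor], out_dir / "receptor.pdb")
    write_pdb([peptide], out_dir / "native_peptide.pdb")
    db_dir = out_dir / "db"
    db_dir.mkdir(exist_ok=True)
    paths = []
    for chain in db:
        p = db_dir / f"{chain.source_id}.pdb"
        write_pdb([chain], p)
        paths.append(p)
    manifest = out_dir / "manifest.txt"
    manifest.write_text("".join(f"{p}\n" for p in paths))
    meta = {
        "seed": spec.seed, "motif": spec.motif,
        "n_db_chains": spec.n_db_chains, "planted_matches": spec.planted_matches,
        "noise_sigma": spec.noise_sigma, "pocket_depth": spec.pocket_depth,
    }
    (out_dir / "fixture.json").write_text(json.dumps(meta, indent=2) + "\n")
    return {"receptor": out_dir / "receptor.pdb",
            "native_peptide": out_dir / "native_peptide.pdb",
            "manifest": manifest, "db_dir": db_dir}
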