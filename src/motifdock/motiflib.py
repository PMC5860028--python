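"""Motif-guided fragment libraries.

A short linear motif (e.g. ``RXL``, ``X`` = any residue) is compiled into a
positional pattern, scanned over a structure database, and the matching
backbone windows are harvested as rigid docking candidates.  The library size
is steered into a target window (default 100-1000 members) by iteratively
generalizing the pattern (introducing wildcards) or restricting it (appending
fixed flanking residues from the peptide context).  Finally the fragments are
clustered at a stringent radius (default 0.5 Å backbone RMSD under optimal
superposition) and up to 25 cluster centers are retained for docking.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import EmptyLibraryError, MissingBackboneError, ValidationError
from .structio import ChainStructure, extract_backbone

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
WILDCARD = "X"


# ---------------------------------------------------------------------------
# motif patterns

@dataclass(frozen=True)
class MotifPattern:
    """A sequence pattern of fixed one-letter codes and wildcards.

    ``positions[i]`` is a one-letter amino-acid code or ``None`` for a
    wildcard; ``original`` flags which positions belong to the user's initial
    motif (generalization spares those longest).
    """

    positions: tuple
    origin: str = "user"
    original: tuple = ()

    def __post_init__(self):
        if len(self.positions) < 1:
            raise ValidationError("motif must have at least one position")
        if not self.original:
            object.__setattr__(self, "original", tuple(True for _ in self.positions))
        if len(self.original) != len(self.positions):
            raise ValidationError("original mask length mismatch")

    def __len__(self) -> int:
        return len(self.positions)

    def render(self) -> str:
        return "".join(c if c is not None else WILDCARD for c in self.positions)

    @property
    def n_fixed(self) -> int:
        return sum(c is not None for c in self.positions)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.render()


def compile_motif(text: str) -> MotifPattern:
    """Compile a motif string (20 amino-acid codes plus ``X`` wildcard)."""
    if not text:
        raise ValidationError("motif string is empty")
    positions = []
    for ch in text.upper():
        if ch == WILDCARD:
            positions.append(None)
        elif ch in AA_ALPHABET:
            positions.append(ch)
        else:
            raise ValidationError(f"illegal motif character {ch!r} "
                                  f"(use the 20 amino-acid codes or 'X')")
    return MotifPattern(tuple(positions), origin="user")


def find_matches(pattern: MotifPattern, sequence: str) -> list[int]:
    """All 0-based start positions where the pattern matches; overlaps included."""
    L = len(pattern)
    n = len(sequence)
    out = []
    fixed = [(k, c) for k, c in enumerate(pattern.positions) if c is not None]
    for p in range(n - L + 1):
        if all(sequence[p + k] == c for k, c in fixed):
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# sequence identity and the exclusion filter

def _nw_identity(a: str, b: str, gap: int = -1) -> int:
    """Identity count of the global alignment maximizing (score, identities)
    lexicographically, with match +1, mismatch 0, linear gap ``gap``.

    The secondary criterion makes the value well defined: co-optimal
    alignments under this scoring can differ in identity count.
    """
    n, m = len(a), len(b)
    NEG = -(10 ** 9)
    # score rows and identity rows; python loops kept lean on purpose
    prev_s = [j * gap for j in range(m + 1)]
    prev_i = [0] * (m + 1)
    for i in range(1, n + 1):
        cur_s = [i * gap] + [NEG] * m
        cur_i = [0] * (m + 1)
        ai = a[i - 1]
        ps, pi = prev_s, prev_i
        for j in range(1, m + 1):
            match = 1 if ai == b[j - 1] else 0
            s_d = ps[j - 1] + match
            i_d = pi[j - 1] + match
            s_u = ps[j] + gap
            i_u = pi[j]
            s_l = cur_s[j - 1] + gap
            i_l = cur_i[j - 1]
            s, ident = s_d, i_d
            if s_u > s or (s_u == s and i_u > ident):
                s, ident = s_u, i_u
            if s_l > s or (s_l == s and i_l > ident):
                s, ident = s_l, i_l
            cur_s[j] = s
            cur_i[j] = ident
        prev_s, prev_i = cur_s, cur_i
    return prev_i[m]


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity, normalized by the shorter length."""
    if not a or not b:
        raise ValidationError("sequence_identity requires nonempty sequences")
    return _nw_identity(a, b) / min(len(a), len(b))


def filter_by_identity(chains: Sequence[ChainStructure],
                       target_sequences: Sequence[str],
                       threshold: float = 0.30) -> list[ChainStructure]:
    """Drop database chains with more than ``threshold`` identity to any target.

    This prevents the fragment search from simply rediscovering the target's
    own (or a close homolog's) structure.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError("threshold must be in (0, 1]")
    targets = [t for t in target_sequences if t]
    kept = []
    for chain in chains:
        seq = chain.sequence
        if seq and any(sequence_identity(seq, t) > threshold for t in targets):
            continue
        kept.append(chain)
    return kept


# ---------------------------------------------------------------------------
# fragment harvesting

@dataclass
class FragmentRecord:
    """An L-residue backbone conformation extracted at a motif match."""

    source_id: str
    chain_id: str
    start: int
    sequence: str
    backbone: np.ndarray  # (L, 4, 3): N, CA, C, O per residue

    def __post_init__(self):
        self.backbone = np.asarray(self.backbone, dtype=float)
        if self.backbone.shape != (len(self.sequence), 4, 3):
            raise ValidationError("backbone shape must be (len(sequence), 4, 3)")
        if not np.all(np.isfinite(self.backbone)):
            raise ValidationError("backbone coordinates must be finite")

    def backbone_flat(self) -> np.ndarray:
        return self.backbone.reshape(-1, 3)


def harvest_fragments(pattern: MotifPattern,
                      chains: Sequence[ChainStructure]) -> tuple[list[FragmentRecord], int]:
    """Extract one FragmentRecord per (chain, match) with a complete backbone.

    Returns ``(records, n_skipped)`` where ``n_skipped`` counts matches whose
    window overlapped a backbone-incomplete residue.
    """
    records: list[FragmentRecord] = []
    skipped = 0
    L = len(pattern)
    for chain in chains:
        seq = chain.sequence
        for p in find_matches(pattern, seq):
            try:
                bb = extract_backbone(chain, p, L)
            except MissingBackboneError:
                skipped += 1
                continue
            records.append(FragmentRecord(
                source_id=chain.source_id, chain_id=chain.chain_id,
                start=p, sequence=seq[p:p + L], backbone=bb))
    return records, skipped


# ---------------------------------------------------------------------------
# library-size control

@dataclass
class FragmentLibrary:
    pattern_final: MotifPattern
    records: list[FragmentRecord]
    history: list[tuple[str, int]]
    n_skipped: int = 0


def _pad_to_min_length(pattern: MotifPattern, min_len: int,
                       pad_side: str = "c") -> MotifPattern:
    """Pad a short motif with wildcards (default: all at the C-terminus)."""
    positions = list(pattern.positions)
    original = list(pattern.original)
    n_side = 0
    while len(positions) < min_len:
        if pad_side == "n" or (pad_side == "alternate" and n_side % 2 == 1):
            positions.insert(0, None)
            original.insert(0, False)
        else:
            positions.append(None)
            original.append(False)
        n_side += 1
    if len(positions) == len(pattern.positions):
        return pattern
    return MotifPattern(tuple(positions), origin="expanded", original=tuple(original))


def generalize_pattern(pattern: MotifPattern,
                       aa_freq: Optional[dict] = None) -> Optional[MotifPattern]:
    """One generalization move: convert a fixed position to a wildcard.

    Priority: the outermost fixed position not in the user's original motif;
    if none remain, the original fixed position whose residue type is rarest
    in the database (``aa_freq``), never dropping below two fixed positions.
    Returns None when no move is available.
    """
    L = len(pattern)
    non_orig = [i for i, (c, o) in enumerate(zip(pattern.positions, pattern.original))
                if c is not None and not o]
    if non_orig:
        i = min(non_orig, key=lambda k: (min(k, L - 1 - k), k))
    else:
        if pattern.n_fixed <= 2:
            return None
        orig = [i for i, c in enumerate(pattern.positions) if c is not None]
        freq = aa_freq or {}
        i = min(orig, key=lambda k: (freq.get(pattern.positions[k], 0), k))
    positions = list(pattern.positions)
    positions[i] = None
    return MotifPattern(tuple(positions), origin="generalized",
                        original=pattern.original)


def restrict_pattern(pattern: MotifPattern, context: str, ctx_start: int,
                     n_restricted: int) -> Optional[tuple[MotifPattern, int]]:
    """One restriction move: append a fixed residue from the peptide's actual
    flanking sequence, alternating C-terminal then N-terminal.

    ``ctx_start`` is the pattern's current offset inside ``context``;
    ``n_restricted`` counts prior restriction moves (drives the alternation).
    Returns ``(new_pattern, new_ctx_start)`` or None when the context is
    exhausted on both sides.
    """
    L = len(pattern)
    ctx_end = ctx_start + L
    want_c_first = n_restricted % 2 == 0
    for side in (("c", "n") if want_c_first else ("n", "c")):
        if side == "c" and ctx_end < len(context):
            ch = context[ctx_end].upper()
            if ch in AA_ALPHABET:
                positions = pattern.positions + (ch,)
                original = pattern.original + (False,)
                return (MotifPattern(positions, origin="restricted",
                                     original=original), ctx_start)
        if side == "n" and ctx_start > 0:
            ch = context[ctx_start - 1].upper()
            if ch in AA_ALPHABET:
                positions = (ch,) + pattern.positions
                original = (False,) + pattern.original
                return (MotifPattern(positions, origin="restricted",
                                     original=original), ctx_start - 1)
    return None


def _database_aa_frequency(chains: Iterable[ChainStructure]) -> dict:
    counts: Counter = Counter()
    for chain in chains:
        counts.update(chain.sequence)
    return dict(counts)


def build_library(motif: str,
                  chains: Sequence[ChainStructure],
                  target_sequences: Sequence[str] = (),
                  low: int = 100,
                  high: int = 1000,
                  min_len: int = 5,
                  max_iter: int = 20,
                  identity_threshold: float = 0.30,
                  peptide_context: Optional[str] = None,
                  pad_side: str = "c") -> FragmentLibrary:
    """Build a fragment library of ``low``-``high`` members by iterative
    generalization/restriction of the motif.

    The identity-exclusion filter is applied to the database first.  A motif
    shorter than ``min_len`` is padded with wildcards before any counting.
    Restriction requires ``peptide_context`` (the peptide sequence the motif
    sits in); without it, only generalization moves are available.
    """
    if not low < high:
        raise ValidationError("need low < high")
    pattern = compile_motif(motif)
    db = filter_by_identity(chains, target_sequences, identity_threshold) \
        if target_sequences else list(chains)
    pattern = _pad_to_min_length(pattern, min_len, pad_side)
    aa_freq = _database_aa_frequency(db)

    ctx_start = 0
    if peptide_context is not None:
        hits = find_matches(compile_motif(motif), peptide_context.upper())
        if not hits:
            raise ValidationError("peptide_context does not contain the motif")
        ctx_start = hits[0]
    n_restricted = 0

    history: list[tuple[str, int]] = []
    seen = set()

    def count_matches(pat: MotifPattern) -> int:
        return sum(len(find_matches(pat, c.sequence)) for c in db)

    for _ in range(max_iter):
        rendering = pattern.render()
        count = count_matches(pattern)
        history.append((rendering, count))
        seen.add(rendering)
        if low <= count <= high:
            break
        if count > high:
            move = restrict_pattern(pattern, peptide_context.upper(), ctx_start,
                                    n_restricted) if peptide_context else None
            if move is None:
                break
            new_pattern, new_ctx = move
            if new_pattern.render() in seen:  # oscillation: stop where we are
                break
            pattern, ctx_start = new_pattern, new_ctx
            n_restricted += 1
        else:
            new_pattern = generalize_pattern(pattern, aa_freq)
            if new_pattern is None or new_pattern.render() in seen:
                break
            pattern = new_pattern

    if history and history[-1][0] != pattern.render():
        history.append((pattern.render(), count_matches(pattern)))

    records, skipped = harvest_fragments(pattern, db)
    if not records:
        raise EmptyLibraryError(
            f"motif search for {motif!r} yielded no usable fragments", history)
    return FragmentLibrary(pattern_final=pattern, records=records,
                           history=history, n_skipped=skipped)


# ---------------------------------------------------------------------------
# superposition RMSD and greedy clustering

def kabsch_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Minimal RMSD between two point sets over proper rigid motions.

    Standard SVD superposition with the determinant sign correction that
    excludes reflections.
    """
    A = np.asarray(A, dtype=float).reshape(-1, 3)
    B = np.asarray(B, dtype=float).reshape(-1, 3)
    if A.shape != B.shape or A.shape[0] < 3:
        raise ValidationError("kabsch_rmsd needs two equal sets of >= 3 points")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    H = Ac.T @ Bc
    U, S, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T)) or 1.0])
    R = Vt.T @ D @ U.T
    # applying the rotation explicitly avoids the cancellation error of the
    # closed-form residual near zero
    diff = Ac @ R.T - Bc
    return float(np.sqrt(np.einsum("ij,ij->", diff, diff) / A.shape[0]))


def superposition_transform(mobile: np.ndarray, target: np.ndarray):
    """Optimal proper rotation R and translation t with R@mobile + t ≈ target."""
    from .structio import Transform
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise ValidationError("superposition needs two equal sets of >= 3 points")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, S, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T)) or 1.0])
    R = Vt.T @ D @ U.T
    return Transform(R, tc - R @ mc)


def pairwise_kabsch_matrix(backbones: np.ndarray) -> np.ndarray:
    """All-pairs superposed RMSD for n stacked (m, 3) point sets, batched."""
    X = np.asarray(backbones, dtype=float)
    n, m = X.shape[0], X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.einsum("nij,nij->n", Xc, Xc)
    # cross-covariances for every ordered pair, then batched 3x3 SVD
    H = np.einsum("aij,bik->abjk", Xc, Xc)
    Hf = H.reshape(n * n, 3, 3)
    S = np.linalg.svd(Hf, compute_uv=False)
    det = np.linalg.det(Hf)
    sign = np.where(det < 0, -1.0, 1.0)
    d = S[:, 0] + S[:, 1] + sign * S[:, 2]
    msd = (norms[:, None] + norms[None, :] - 2.0 * d.reshape(n, n)) / m
    np.fill_diagonal(msd, 0.0)
    return np.sqrt(np.clip(msd, 0.0, None))


def greedy_cluster(dist: np.ndarray, radius: float) -> list[tuple[int, list[int]]]:
    """Greedy radius clustering on a symmetric distance matrix.

    Repeatedly pick the element with the most neighbors within ``radius``
    (ties: lowest index), emit (center, members incl. center), remove them.
    Returned in formation order.
    """
    n = dist.shape[0]
    within = dist <= radius
    alive = np.ones(n, dtype=bool)
    clusters: list[tuple[int, list[int]]] = []
    while alive.any():
        counts = np.where(alive, (within & alive[None, :]).sum(axis=1), -1)
        center = int(np.argmax(counts))  # argmax takes the first max: lowest index
        members = np.flatnonzero(within[center] & alive)
        clusters.append((center, members.tolist()))
        alive[members] = False
    return clusters


@dataclass
class FragmentClusterSet:
    """Size-ranked fragment clusters; ``clusters[i] = (center, member_count)``."""

    clusters: list[tuple[FragmentRecord, int]]
    member_indices: list[list[int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def centers(self) -> list[FragmentRecord]:
        return [c for c, _ in self.clusters]


def cluster_fragments(records: Sequence[FragmentRecord],
                      radius: float = 0.5,
                      max_clusters: int = 25) -> FragmentClusterSet:
    """Greedy-cluster fragments at ``radius`` Å superposed backbone RMSD and
    keep the ``max_clusters`` largest clusters, size-descending
    (ties: earlier-formed first)."""
    if not records:
        raise ValidationError("cluster_fragments requires at least one record")
    bb = np.stack([r.backbone_flat() for r in records])
    dist = pairwise_kabsch_matrix(bb)
    formed = greedy_cluster(dist, radius)
    order = sorted(range(len(formed)),
                   key=lambda i: (-len(formed[i][1]), i))[:max_clusters]
    clusters = [(records[formed[i][0]], len(formed[i][1])) for i in order]
    members = [formed[i][1] for i in order]
    return FragmentClusterSet(clusters=clusters, member_indices=members)
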