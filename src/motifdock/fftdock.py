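"""FFT rigid-body docking of backbone fragments to a receptor.

The receptor is discretized onto three scalar fields — a repulsive core
(voxel value 1 within ``core_radius`` of any heavy atom), an attractive
surface shell (value -1 in a band of ``shell_width`` outside the core), and a
Coulombic potential with a distance-dependent dielectric eps(r) = 4r,
truncated at 12 Å.  A rotated fragment is deposited onto matching occupancy
and charge grids; the score of every integer translation is then the
cross-correlation of the weighted receptor fields with the ligand fields,
evaluated for all translations at once with the FFT:

    S(t) = w_rep * (rep ⋆ occ)(t) + w_att * (att ⋆ occ)(t) + w_elec * (elec ⋆ q)(t)

One best translation is kept per rotation, and the pooled per-fragment poses
are truncated to the ``keep`` lowest energies (default 250).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.fft

from .errors import GridFitError, ValidationError
from .motiflib import FragmentClusterSet, FragmentRecord
from .structio import ChainStructure, Transform

logger = logging.getLogger(__name__)

ELEC_CUTOFF = 12.0  # Å, Coulomb truncation

# Residue-level unit charges.  The named atom carries the charge; when it is
# absent (backbone-only models) the charge falls back to CA.
RESIDUE_CHARGES: dict[str, tuple[str, float]] = {
    "D": ("CG", -1.0),
    "E": ("CD", -1.0),
    "K": ("NZ", +1.0),
    "R": ("NH1", +1.0),
    "H": ("ND1", +0.1),
}


# ---------------------------------------------------------------------------
# grids

@dataclass(frozen=True)
class GridSpec:
    """Regular cubic-voxel grid: spacing (Å), dims (voxels), origin = center
    of voxel (0,0,0) in Å."""

    spacing: float
    dims: tuple
    origin: tuple

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValidationError("grid spacing must be positive")
        if len(self.dims) != 3 or any(d < 8 for d in self.dims):
            raise ValidationError("grid needs 3 dims, each >= 8")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))

    def voxel_center(self, ijk: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(ijk, dtype=float) * self.spacing

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = self.origin
        return tuple(o[k] + self.spacing * np.arange(self.dims[k]) for k in range(3))


def auto_grid_spec(receptor: ChainStructure, ligand_diameter: float,
                   spacing: float = 1.0, pad: int = 2) -> GridSpec:
    """Smallest FFT-friendly grid holding the receptor plus a fully rotated
    ligand on every side without wrap-around of valid translations."""
    coords = receptor.coords()
    if coords.size == 0:
        raise ValidationError("receptor has no atoms")
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    margin = ligand_diameter + pad * spacing
    # snap the origin onto the spacing lattice so that inputs built on that
    # lattice land exactly on voxel centers (removes rounding slop)
    origin = np.floor((lo - margin) / spacing) * spacing
    dims = []
    for k in range(3):
        need = (hi[k] + margin - origin[k]) / spacing + 1
        dims.append(scipy.fft.next_fast_len(max(int(np.ceil(need)), 8), real=True))
    return GridSpec(spacing=spacing, dims=tuple(dims), origin=tuple(origin))


@dataclass
class EnergyGrids:
    """Receptor-side fields: repulsive core (>=0), attractive shell (<=0),
    electrostatic potential."""

    spec: GridSpec
    rep: np.ndarray
    att: np.ndarray
    elec: np.ndarray
    _ffts: dict = field(default_factory=dict, repr=False)

    def fft(self, name: str) -> np.ndarray:
        if name not in self._ffts:
            self._ffts[name] = scipy.fft.rfftn(getattr(self, name))
        return self._ffts[name]

    def shifted(self, voxels) -> "EnergyGrids":
        """Receptor fields circularly shifted by an integer voxel vector
        (diagnostic helper for translational-equivariance checks)."""
        v = tuple(int(x) for x in voxels)
        return EnergyGrids(self.spec,
                           np.roll(self.rep, v, axis=(0, 1, 2)),
                           np.roll(self.att, v, axis=(0, 1, 2)),
                           np.roll(self.elec, v, axis=(0, 1, 2)))


@dataclass
class LigandGrids:
    """Ligand-side fields: heavy-atom occupancy and per-voxel charge, with the
    fragment centroid at the origin voxel.  ``offsets`` are the signed voxel
    offsets of each atom (kept for wrap-validity masks and exact rescoring)."""

    spec: GridSpec
    occ: np.ndarray
    q: np.ndarray
    offsets: np.ndarray
    charges: np.ndarray


@dataclass(frozen=True)
class WeightSet:
    """Coefficients combining the three correlation terms into one score."""

    name: str
    w_rep: float
    w_att: float
    w_elec: float

    def __post_init__(self):
        if self.w_rep <= 0:
            raise ValidationError("w_rep must be positive: clashes are always penalized")

    def total(self, e_rep: float, e_att: float, e_elec: float) -> float:
        return self.w_rep * e_rep + self.w_att * e_att + self.w_elec * e_elec


# The repulsive coefficient is tied to the deepest electrostatic well
# (0.25 * w_elec at the 1 Å distance cap) so a clash can never be bought
# with a single favorable charge contact.
STANDARD_WEIGHTS = WeightSet("standard", w_rep=150.0, w_att=1.0, w_elec=300.0)
ELECTROSTATICS_FAVORED_WEIGHTS = WeightSet("electrostatics-favored",
                                           w_rep=750.0, w_att=1.0, w_elec=1500.0)
WEIGHT_SETS = {w.name: w for w in (STANDARD_WEIGHTS, ELECTROSTATICS_FAVORED_WEIGHTS)}


def residue_charge_site(code: str, atom_names: Sequence[str]) -> Optional[tuple[str, float]]:
    """(atom name, charge) for a residue, or None if neutral."""
    entry = RESIDUE_CHARGES.get(code)
    if entry is None:
        return None
    name, q = entry
    if name not in atom_names:
        name = "CA" if "CA" in atom_names else (atom_names[0] if atom_names else None)
    if name is None:
        return None
    return name, q


def _receptor_charges(receptor: ChainStructure) -> tuple[np.ndarray, np.ndarray]:
    """Positions and charges of the receptor's charged sites."""
    pos, q = [], []
    for res in receptor.residues:
        names = [a.name for a in res.atoms]
        site = residue_charge_site(res.code, names)
        if site is None:
            continue
        pos.append(res.atom(site[0]).xyz)
        q.append(site[1])
    if not pos:
        return np.zeros((0, 3)), np.zeros(0)
    return np.array(pos), np.array(q)


def make_receptor_grids(receptor: ChainStructure, spec: GridSpec,
                        core_radius: float = 1.8,
                        shell_width: float = 3.0) -> EnergyGrids:
    """Discretize the receptor into repulsive/attractive/electrostatic fields."""
    coords = receptor.coords()
    if coords.size == 0:
        raise ValidationError("receptor has no atoms")
    axes = spec.axes()
    lo = np.array([ax[0] for ax in axes])
    hi = np.array([ax[-1] for ax in axes])
    if np.any(coords.min(axis=0) < lo - 0.5 * spec.spacing) or \
       np.any(coords.max(axis=0) > hi + 0.5 * spec.spacing):
        raise GridFitError("receptor atoms fall outside the grid")

    dims = spec.dims
    core = np.zeros(dims, dtype=bool)
    near = np.zeros(dims, dtype=bool)
    reach = core_radius + shell_width
    r_vox = int(np.ceil(reach / spec.spacing))
    for atom in coords:
        ijk0 = np.floor((atom - spec.origin) / spec.spacing - r_vox).astype(int)
        ijk1 = np.ceil((atom - spec.origin) / spec.spacing + r_vox).astype(int)
        sl = tuple(slice(max(a, 0), min(b + 1, d))
                   for a, b, d in zip(ijk0, ijk1, dims))
        if any(s.start >= s.stop for s in sl):
            continue
        gx, gy, gz = np.ix_(axes[0][sl[0]], axes[1][sl[1]], axes[2][sl[2]])
        d2 = (gx - atom[0]) ** 2 + (gy - atom[1]) ** 2 + (gz - atom[2]) ** 2
        core[sl] |= d2 <= core_radius ** 2
        near[sl] |= d2 <= reach ** 2
    rep = core.astype(float)
    att = np.where(near & ~core, -1.0, 0.0)

    elec = np.zeros(dims, dtype=float)
    qpos, qval = _receptor_charges(receptor)
    r_vox_e = int(np.ceil(ELEC_CUTOFF / spec.spacing))
    for p, q in zip(qpos, qval):
        ijk0 = np.floor((p - spec.origin) / spec.spacing - r_vox_e).astype(int)
        ijk1 = np.ceil((p - spec.origin) / spec.spacing + r_vox_e).astype(int)
        sl = tuple(slice(max(a, 0), min(b + 1, d))
                   for a, b, d in zip(ijk0, ijk1, dims))
        if any(s.start >= s.stop for s in sl):
            continue
        gx, gy, gz = np.ix_(axes[0][sl[0]], axes[1][sl[1]], axes[2][sl[2]])
        r = np.sqrt((gx - p[0]) ** 2 + (gy - p[1]) ** 2 + (gz - p[2]) ** 2)
        rc = np.maximum(r, spec.spacing)  # cap below at one voxel
        contrib = np.where(r <= ELEC_CUTOFF, q / (4.0 * rc * rc), 0.0)
        elec[sl] += contrib
    return EnergyGrids(spec=spec, rep=rep, att=att, elec=elec)


def fragment_charges(fragment: FragmentRecord) -> np.ndarray:
    """Per-backbone-atom charges for a fragment: residue charges sit on CA
    (index 1 of each residue's N, CA, C, O quartet)."""
    L = len(fragment.sequence)
    q = np.zeros(L * 4)
    for i, code in enumerate(fragment.sequence):
        entry = RESIDUE_CHARGES.get(code)
        if entry is not None:
            q[i * 4 + 1] = entry[1]
    return q


def make_ligand_grids(fragment: FragmentRecord, rotation: np.ndarray,
                      spec: GridSpec) -> LigandGrids:
    """Deposit the centroid-centered, rotated fragment onto occupancy/charge
    grids (nearest-voxel), centroid at the origin voxel."""
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3) or \
       np.abs(rotation.T @ rotation - np.eye(3)).max() > 1e-6 or \
       np.linalg.det(rotation) < 0:
        raise ValidationError("rotation must be a proper orthonormal 3x3 matrix")
    coords = fragment.backbone_flat()
    centered = coords - coords.mean(axis=0)
    rotated = centered @ rotation.T
    offsets = np.rint(rotated / spec.spacing).astype(int)
    dims = np.array(spec.dims)
    if np.any(offsets.max(axis=0) - offsets.min(axis=0) >= dims - 1):
        raise GridFitError("rotated ligand does not fit inside the grid")
    occ = np.zeros(spec.dims, dtype=float)
    qgrid = np.zeros(spec.dims, dtype=float)
    charges = fragment_charges(fragment)
    idx = tuple((offsets % dims).T)
    np.add.at(occ, idx, 1.0)
    np.add.at(qgrid, idx, charges)
    return LigandGrids(spec=spec, occ=occ, q=qgrid, offsets=offsets, charges=charges)


# ---------------------------------------------------------------------------
# correlation

def _corr(R_fft: np.ndarray, Lg: np.ndarray, shape) -> np.ndarray:
    """Circular cross-correlation S(t) = sum_x R(x) * L(x - t) via FFT."""
    return scipy.fft.irfftn(R_fft * np.conj(scipy.fft.rfftn(Lg)), s=shape)


def correlate_terms(receptor: EnergyGrids, ligand: LigandGrids) -> dict[str, np.ndarray]:
    """The three raw correlation fields over all integer translations."""
    if receptor.spec.dims != ligand.spec.dims or \
       receptor.spec.spacing != ligand.spec.spacing:
        raise ValidationError("receptor and ligand grids must share spacing and dims")
    shape = receptor.spec.dims
    return {
        "rep": _corr(receptor.fft("rep"), ligand.occ, shape),
        "att": _corr(receptor.fft("att"), ligand.occ, shape),
        "elec": _corr(receptor.fft("elec"), ligand.q, shape),
    }


def correlate(receptor: EnergyGrids, ligand: LigandGrids,
              weights: WeightSet) -> np.ndarray:
    """Weighted total score field S(t) over all integer translations t."""
    if receptor.spec.dims != ligand.spec.dims or \
       receptor.spec.spacing != ligand.spec.spacing:
        raise ValidationError("receptor and ligand grids must share spacing and dims")
    shape = receptor.spec.dims
    shape_spec = weights.w_rep * receptor.fft("rep") + weights.w_att * receptor.fft("att")
    S = _corr(shape_spec, ligand.occ, shape)
    if np.any(ligand.q):
        S += weights.w_elec * _corr(receptor.fft("elec"), ligand.q, shape)
    return S


# ---------------------------------------------------------------------------
# rotations

@dataclass
class RotationSet:
    """An ordered set of proper rotation matrices; the first is the identity."""

    rotations: np.ndarray
    description: str = ""

    def __post_init__(self):
        self.rotations = np.asarray(self.rotations, dtype=float)
        if self.rotations.ndim != 3 or self.rotations.shape[1:] != (3, 3):
            raise ValidationError("rotations must be an (n, 3, 3) array")
        if np.abs(self.rotations[0] - np.eye(3)).max() > 1e-9:
            raise ValidationError("first rotation must be the identity")

    def __len__(self) -> int:
        return self.rotations.shape[0]

    def __iter__(self):
        return iter(self.rotations)


def _super_fibonacci(n: int) -> np.ndarray:
    """Super-Fibonacci spiral: a deterministic low-discrepancy set of n unit
    quaternions covering SO(3) quasi-uniformly."""
    PHI = np.sqrt(2.0)
    PSI = 1.533751168755204288118041  # real root of x^4 = x + 4
    i = np.arange(n, dtype=float)
    s = i + 0.5
    t = s / n
    r = np.sqrt(t)
    R = np.sqrt(1.0 - t)
    alpha = 2.0 * np.pi * s / PHI
    beta = 2.0 * np.pi * s / PSI
    quat = np.stack([r * np.sin(alpha), r * np.cos(alpha),
                     R * np.sin(beta), R * np.cos(beta)], axis=1)
    return quat


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.from_quat(q).as_matrix()


def generate_rotations(n: int, seed: int = 0) -> RotationSet:
    """Identity plus a seeded super-Fibonacci cover of rotation space.

    The seed composes a fixed global rotation onto the spiral, which shuffles
    its placement without touching its uniformity; same (n, seed) gives an
    identical set.
    """
    if n < 1:
        raise ValidationError("need at least one rotation")
    mats = [np.eye(3)]
    if n > 1:
        quat = _super_fibonacci(n - 1)
        base = _quat_to_matrix(quat) if n > 1 else np.zeros((0, 3, 3))
        rng = np.random.default_rng(seed)
        from scipy.spatial.transform import Rotation
        g = Rotation.random(random_state=rng).as_matrix()
        mats.extend(g @ m for m in base)
    return RotationSet(np.stack(mats), description=f"super-fibonacci n={n} seed={seed}")


# ---------------------------------------------------------------------------
# poses

@dataclass
class DockPose:
    """A rigid placement of a fragment plus its per-term and total scores."""

    fragment_id: int
    rotation_index: int
    transform: Transform
    tvoxel: tuple
    e_rep: float
    e_att: float
    e_elec: float
    e_total: float

    def transformed_backbone(self, fragment: FragmentRecord) -> np.ndarray:
        return self.transform.apply(fragment.backbone_flat())


def _valid_translation_mask(offsets: np.ndarray, dims) -> np.ndarray:
    """Boolean field over translations t where no ligand atom wraps around."""
    masks = []
    for k in range(3):
        o_min, o_max = offsets[:, k].min(), offsets[:, k].max()
        t = np.arange(dims[k])
        masks.append((t + o_min >= 0) & (t + o_max <= dims[k] - 1))
    return masks[0][:, None, None] & masks[1][None, :, None] & masks[2][None, None, :]


def _rescore(receptor: EnergyGrids, ligand: LigandGrids,
             t: np.ndarray) -> tuple[float, float, float]:
    """Exact per-term energies of a single translation, by direct summation
    over ligand atoms (independent of the FFT path)."""
    idx = tuple((ligand.offsets + t).T)
    e_rep = float(receptor.rep[idx].sum())
    e_att = float(receptor.att[idx].sum())
    e_elec = float((receptor.elec[idx] * ligand.charges).sum())
    return e_rep, e_att, e_elec


def dock_fragment(receptor: EnergyGrids, fragment: FragmentRecord,
                  rotations: RotationSet, weights: WeightSet,
                  keep: int = 250, fragment_id: int = 0) -> list[DockPose]:
    """Dock one fragment: best valid translation per rotation, pooled and
    truncated to the ``keep`` lowest total energies (ties: lower rotation
    index)."""
    if keep < 1:
        raise ValidationError("keep must be >= 1")
    spec = receptor.spec
    dims = np.array(spec.dims)
    poses: list[DockPose] = []
    for ri, rot in enumerate(rotations):
        try:
            ligand = make_ligand_grids(fragment, rot, spec)
        except GridFitError:
            continue
        S = correlate(receptor, ligand, weights)
        valid = _valid_translation_mask(ligand.offsets, spec.dims)
        if not valid.any():
            continue
        S_masked = np.where(valid, S, np.inf)
        flat = int(np.argmin(S_masked))
        t = np.array(np.unravel_index(flat, spec.dims))
        e_rep, e_att, e_elec = _rescore(receptor, ligand, t)
        e_total = weights.total(e_rep, e_att, e_elec)
        centroid = fragment.backbone_flat().mean(axis=0)
        translation = np.asarray(spec.origin) + spec.spacing * t - rot @ centroid
        poses.append(DockPose(
            fragment_id=fragment_id, rotation_index=ri,
            transform=Transform(rot, translation), tvoxel=tuple(int(x) for x in t),
            e_rep=e_rep, e_att=e_att, e_elec=e_elec, e_total=e_total))
    if not poses:
        warnings.warn("no valid translation for any rotation; empty docking result")
        return []
    poses.sort(key=lambda p: (p.e_total, p.rotation_index))
    return poses[:keep]


def dock_library(receptor: EnergyGrids, library: FragmentClusterSet,
                 rotations: RotationSet, weights: WeightSet,
                 keep: int = 250) -> list[DockPose]:
    """Dock every retained cluster center and pool the results."""
    if len(library) == 0:
        raise ValidationError("empty fragment library")
    pooled: list[DockPose] = []
    for fid, center in enumerate(library.centers):
        result = dock_fragment(receptor, center, rotations, weights,
                               keep=keep, fragment_id=fid)
        logger.info("fragment %d: %d poses pooled", fid, len(result))
        pooled.extend(result)
    return pooled
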