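"""Model selection: pose clustering, ranking, interface filtering, and
evaluation against a native complex.

Docked poses are compared by ligand-backbone RMSD in the fixed receptor frame
(no re-superposition — superposing would erase the binding-site location that
pose clustering must distinguish).  Clusters are ranked by size, a proxy for
the breadth of the underlying energy basin.  Predictions count as acceptable
when the peptide lies within 4.0 Å backbone RMSD of the native peptide after
the receptors are superposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .errors import ValidationError
from .fftdock import DockPose
from .motiflib import (FragmentClusterSet, FragmentRecord, greedy_cluster,
                       superposition_transform)
from .structio import ChainStructure, Transform, extract_backbone

logger = logging.getLogger(__name__)

FragmentLookup = Union[FragmentClusterSet, Mapping[int, FragmentRecord], Sequence[FragmentRecord]]


def _fragment(fragments: FragmentLookup, fid: int) -> FragmentRecord:
    if isinstance(fragments, FragmentClusterSet):
        return fragments.centers[fid]
    if isinstance(fragments, Mapping):
        return fragments[fid]
    return fragments[fid]


@dataclass
class PoseCluster:
    """A ranked basin of mutually similar poses; the representative is the
    lowest-energy member."""

    representative: DockPose
    member_count: int
    rank: int
    member_indices: tuple = ()


@dataclass
class EvaluationReport:
    """Per-prediction backbone RMSD to the native peptide and the best rank
    meeting the acceptance threshold."""

    rmsds: list[float]
    threshold: float
    best_rank_acceptable: Optional[int]

    @property
    def acceptable(self) -> list[bool]:
        return [r <= self.threshold for r in self.rmsds]


def pose_rmsd(a: DockPose, b: DockPose, fragments: FragmentLookup) -> float:
    """Backbone RMSD between two placements in the common receptor frame,
    without re-superposition."""
    xa = a.transformed_backbone(_fragment(fragments, a.fragment_id))
    xb = b.transformed_backbone(_fragment(fragments, b.fragment_id))
    if xa.shape != xb.shape:
        raise ValidationError("poses reference fragments of different backbone length")
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def _pose_coords(poses: Sequence[DockPose], fragments: FragmentLookup) -> np.ndarray:
    coords = [p.transformed_backbone(_fragment(fragments, p.fragment_id)) for p in poses]
    shapes = {c.shape for c in coords}
    if len(shapes) > 1:
        raise ValidationError("all poses must reference equal-length fragments")
    return np.stack(coords)


def pose_distance_matrix(poses: Sequence[DockPose],
                         fragments: FragmentLookup) -> np.ndarray:
    """All-pairs unsuperposed backbone RMSD, via the Gram trick (no n^2 x m
    coordinate broadcast)."""
    X = _pose_coords(poses, fragments)
    n, m, _ = X.shape
    F = X.reshape(n, -1)
    sq = np.einsum("ij,ij->i", F, F)
    d2 = (sq[:, None] + sq[None, :] - 2.0 * (F @ F.T)) / m
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.clip(d2, 0.0, None))


def cluster_poses(poses: Sequence[DockPose], fragments: FragmentLookup,
                  radius: float = 3.5, max_report: int = 20) -> list[PoseCluster]:
    """Greedy-cluster poses at ``radius`` Å and rank clusters by size.

    Representative: lowest-energy member (ties: lowest input index).  Size
    ties are broken by lower representative energy.  At most ``max_report``
    clusters are returned, re-ranked 1..k.
    """
    if not poses:
        raise ValidationError("cluster_poses requires at least one pose")
    dist = pose_distance_matrix(poses, fragments)
    formed = greedy_cluster(dist, radius)
    reps = []
    for center, members in formed:
        rep_idx = min(members, key=lambda i: (poses[i].e_total, i))
        reps.append(rep_idx)
    order = sorted(range(len(formed)),
                   key=lambda i: (-len(formed[i][1]), poses[reps[i]].e_total, i))
    clusters = []
    for rank, i in enumerate(order[:max_report], start=1):
        clusters.append(PoseCluster(representative=poses[reps[i]],
                                    member_count=len(formed[i][1]),
                                    rank=rank,
                                    member_indices=tuple(formed[i][1])))
    return clusters


def filter_interface_overlap(clusters: Sequence[PoseCluster],
                             receptor: ChainStructure,
                             excluded_residues: Sequence[int],
                             fragments: FragmentLookup,
                             contact_cutoff: float = 5.0) -> list[PoseCluster]:
    """Drop clusters whose representative contacts a declared other-domain
    interface residue (any backbone atom within ``contact_cutoff`` of any
    atom of an excluded residue); survivors are re-ranked consecutively."""
    if not excluded_residues:
        return list(clusters)
    by_index = {r.seq_index: r for r in receptor.residues}
    excl_atoms = []
    for idx in excluded_residues:
        if idx not in by_index:
            raise ValidationError(f"excluded residue {idx} not found in receptor")
        excl_atoms.extend(a.xyz for a in by_index[idx].atoms)
    excl = np.array(excl_atoms)
    out = []
    for cl in clusters:
        bb = cl.representative.transformed_backbone(
            _fragment(fragments, cl.representative.fragment_id))
        d2 = np.sum((bb[:, None, :] - excl[None, :, :]) ** 2, axis=-1)
        if d2.min() < contact_cutoff ** 2:
            logger.info("cluster rank %d removed: contacts excluded interface", cl.rank)
            continue
        out.append(cl)
    return [replace(cl, rank=i + 1) for i, cl in enumerate(out)]


def _common_ca(a: ChainStructure, b: ChainStructure) -> tuple[np.ndarray, np.ndarray]:
    bx = {(r.seq_index, r.icode): r for r in b.residues}
    pa, pb = [], []
    for r in a.residues:
        other = bx.get((r.seq_index, r.icode))
        if other is None:
            continue
        try:
            pa.append(r.atom("CA").xyz)
            pb.append(other.atom("CA").xyz)
        except KeyError:
            continue
    return np.array(pa), np.array(pb)


def _chain_backbone(chain: ChainStructure) -> np.ndarray:
    return extract_backbone(chain, 0, len(chain)).reshape(-1, 3)


def evaluate_capri(predictions: Sequence[PoseCluster],
                   native_receptor: ChainStructure,
                   native_peptide: ChainStructure,
                   model_receptor: ChainStructure,
                   fragments: FragmentLookup,
                   threshold: float = 4.0) -> EvaluationReport:
    """Score predictions against the native complex.

    The model receptor is superposed onto the native receptor on common CA
    atoms (matched by author residue number); that rigid motion is applied to
    every predicted peptide, whose backbone RMSD to the native peptide is then
    measured directly (no further superposition).  ``best_rank_acceptable`` is
    the lowest rank with RMSD <= ``threshold`` (default 4.0 Å).
    """
    ca_model, ca_native = _common_ca(model_receptor, native_receptor)
    if len(ca_model) < 3:
        raise ValidationError("model and native receptors share fewer than 3 CA atoms")
    fit = superposition_transform(ca_model, ca_native)
    native_bb = _chain_backbone(native_peptide)
    rmsds = []
    best: Optional[int] = None
    for cl in sorted(predictions, key=lambda c: c.rank):
        bb = cl.representative.transformed_backbone(
            _fragment(fragments, cl.representative.fragment_id))
        moved = fit.apply(bb)
        if moved.shape != native_bb.shape:
            raise ValidationError("prediction and native peptide backbone lengths differ")
        rmsd = float(np.sqrt(np.mean(np.sum((moved - native_bb) ** 2, axis=1))))
        rmsds.append(rmsd)
        if best is None and rmsd <= threshold:
            best = cl.rank
    return EvaluationReport(rmsds=rmsds, threshold=threshold, best_rank_acceptable=best)


def refine_representatives(clusters: Sequence[PoseCluster],
                           refiner=None) -> list[PoseCluster]:
    """Hook for local refinement of cluster representatives.

    By default a logged pass-through: no force-field minimizer is bundled.
    A ``refiner(DockPose) -> DockPose`` callable can be plugged in; counts and
    ranks are preserved either way.
    """
    if refiner is None:
        logger.info("representative refinement disabled (pass-through)")
        return list(clusters)
    return [replace(cl, representative=refiner(cl.representative)) for cl in clusters]
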