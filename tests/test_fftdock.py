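import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import motifdock as md
from motifdock import fftdock, fixtures
from motifdock.errors import GridFitError, ValidationError

from _oracles import direct_correlation
from conftest import random_fragment


def small_spec(dim=8, spacing=1.0):
    return fftdock.GridSpec(spacing=spacing, dims=(dim, dim, dim),
                            origin=(0.0, 0.0, 0.0))


def random_grids(rng, dim=8):
    spec = small_spec(dim)
    rep = rng.random((dim,) * 3)
    att = -rng.random((dim,) * 3)
    elec = rng.normal(size=(dim,) * 3)
    return fftdock.EnergyGrids(spec=spec, rep=rep, att=att, elec=elec)


class TestReceptorGrids:
    def test_single_atom_core_voxel_count(self):
        res = md.Residue(code="A", seq_index=1, atoms=[
            md.Atom(name="CA", element="C", xyz=[8.0, 8.0, 8.0])])
        chain = md.ChainStructure("A", [res])
        spec = fftdock.GridSpec(1.0, (16, 16, 16), (0.0, 0.0, 0.0))
        grids = fftdock.make_receptor_grids(chain, spec, core_radius=1.8)
        # brute-force enumeration of voxel centers within 1.8 A
        count = 0
        expected = np.zeros((16, 16, 16))
        for i in range(16):
            for j in range(16):
                for k in range(16):
                    if (i - 8) ** 2 + (j - 8) ** 2 + (k - 8) ** 2 <= 1.8 ** 2:
                        count += 1
                        expected[i, j, k] = 1.0
        assert count == 27  # shells at squared distance 0, 1, 2, 3
        assert np.array_equal(grids.rep, expected)

    def test_chargeless_receptor_zero_elec(self, receptor):
        neutral = md.ChainStructure(
            "R", [md.Residue(code="A", seq_index=r.seq_index, atoms=r.atoms)
                  for r in receptor.residues])
        spec = fftdock.auto_grid_spec(neutral, 20.0)
        grids = fftdock.make_receptor_grids(neutral, spec)
        assert np.all(grids.elec == 0.0)

    def test_core_and_shell_disjoint(self, receptor_grids):
        assert np.all(receptor_grids.rep * receptor_grids.att == 0.0)

    def test_field_signs(self, receptor_grids):
        assert np.all(receptor_grids.rep >= 0)
        assert np.all(receptor_grids.att <= 0)
        assert np.all(np.isfinite(receptor_grids.elec))

    def test_atom_outside_grid_rejected(self):
        res = md.Residue(code="A", seq_index=1, atoms=[
            md.Atom(name="CA", element="C", xyz=[99.0, 0.0, 0.0])])
        chain = md.ChainStructure("A", [res])
        with pytest.raises(GridFitError):
            fftdock.make_receptor_grids(chain, small_spec())


class TestLigandGrids:
    def test_single_atom_occupancy(self):
        frag = md.FragmentRecord("s", "A", 0, "A",
                                 np.zeros((1, 4, 3)) + [[0, 0, 0]])
        lig = fftdock.make_ligand_grids(frag, np.eye(3), small_spec(16))
        assert lig.occ.sum() == pytest.approx(4.0)  # 4 backbone atoms

    def test_occupancy_conserved_under_rotation(self, native_frag):
        spec = small_spec(32)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            rot = Rotation.random(random_state=rng).as_matrix()
            lig = fftdock.make_ligand_grids(native_frag, rot, spec)
            assert lig.occ.sum() == pytest.approx(native_frag.backbone.shape[0] * 4)

    def test_point_reflection_under_180_rotation(self):
        rng = np.random.default_rng(1)
        bb = np.round(rng.normal(0, 3, size=(5, 4, 3)))
        bb[:, :, 2] = 0.0  # planar fragment
        frag = md.FragmentRecord("s", "A", 0, "KGRRL", bb)
        spec = small_spec(32)
        rot = np.diag([-1.0, -1.0, 1.0])  # exact 180 degrees about z
        lig0 = fftdock.make_ligand_grids(frag, np.eye(3), spec)
        lig1 = fftdock.make_ligand_grids(frag, rot, spec)
        # reflect occupancy of the unrotated grid through the origin voxel
        reflected = np.zeros_like(lig0.occ)
        nz = np.argwhere(lig0.occ > 0)
        for idx in nz:
            target = tuple((-idx) % np.array(spec.dims))
            reflected[target] += lig0.occ[tuple(idx)]
        assert np.array_equal(reflected, lig1.occ)

    def test_oversized_ligand_rejected(self):
        bb = np.zeros((2, 4, 3))
        bb[1] = [[30.0, 0, 0]] * 4
        frag = md.FragmentRecord("s", "A", 0, "AA", bb)
        with pytest.raises(GridFitError):
            fftdock.make_ligand_grids(frag, np.eye(3), small_spec(8))

    def test_improper_rotation_rejected(self, native_frag):
        with pytest.raises(ValidationError):
            fftdock.make_ligand_grids(native_frag, np.diag([1.0, 1.0, -1.0]),
                                      small_spec(32))


class TestCorrelate:
    def test_zero_occupancy_zero_field(self):
        rng = np.random.default_rng(0)
        grids = random_grids(rng)
        lig = fftdock.LigandGrids(spec=grids.spec,
                                  occ=np.zeros(grids.spec.dims),
                                  q=np.zeros(grids.spec.dims),
                                  offsets=np.zeros((1, 3), int),
                                  charges=np.zeros(1))
        S = fftdock.correlate(grids, lig, fftdock.STANDARD_WEIGHTS)
        assert np.allclose(S, 0.0, atol=1e-9)

    def test_delta_function_recovers_receptor_field(self):
        rng = np.random.default_rng(1)
        grids = random_grids(rng)
        occ = np.zeros(grids.spec.dims)
        occ[0, 0, 0] = 1.0
        lig = fftdock.LigandGrids(spec=grids.spec, occ=occ,
                                  q=np.zeros(grids.spec.dims),
                                  offsets=np.zeros((1, 3), int),
                                  charges=np.zeros(1))
        w = fftdock.WeightSet("unit", 1.0, 1.0, 1.0)
        S = fftdock.correlate(grids, lig, w)
        assert np.allclose(S, grids.rep + grids.att, atol=1e-9)

    @pytest.mark.parametrize("dim", [8, 16])
    def test_fft_equals_direct_sum(self, dim):
        rng = np.random.default_rng(dim)
        grids = random_grids(rng, dim)
        occ = (rng.random((dim,) * 3) < 0.05).astype(float)
        q = occ * rng.normal(size=(dim,) * 3)
        lig = fftdock.LigandGrids(spec=grids.spec, occ=occ, q=q,
                                  offsets=np.zeros((1, 3), int),
                                  charges=np.zeros(1))
        w = fftdock.WeightSet("rand", *(rng.random(3) + 0.1))
        S = fftdock.correlate(grids, lig, w)
        direct = (w.w_rep * direct_correlation(grids.rep, occ)
                  + w.w_att * direct_correlation(grids.att, occ)
                  + w.w_elec * direct_correlation(grids.elec, q))
        assert np.abs(S - direct).max() <= 1e-6 * np.abs(direct).max()

    def test_mismatched_grids_rejected(self):
        rng = np.random.default_rng(2)
        grids = random_grids(rng, 8)
        lig = fftdock.LigandGrids(spec=small_spec(16),
                                  occ=np.zeros((16,) * 3), q=np.zeros((16,) * 3),
                                  offsets=np.zeros((1, 3), int),
                                  charges=np.zeros(1))
        with pytest.raises(ValidationError):
            fftdock.correlate(grids, lig, fftdock.STANDARD_WEIGHTS)


class TestRotations:
    def test_single_rotation_is_identity(self):
        rs = fftdock.generate_rotations(1, seed=5)
        assert np.allclose(rs.rotations[0], np.eye(3))

    def test_deterministic(self):
        a = fftdock.generate_rotations(100, seed=7)
        b = fftdock.generate_rotations(100, seed=7)
        assert np.array_equal(a.rotations, b.rotations)

    def test_all_proper_orthonormal(self):
        rs = fftdock.generate_rotations(50, seed=1)
        for R in rs:
            assert np.abs(R.T @ R - np.eye(3)).max() < 1e-9
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_quasi_uniform_cover(self):
        rs = fftdock.generate_rotations(500, seed=2)
        q = Rotation.from_matrix(rs.rotations).as_quat()
        dots = np.clip(np.abs(q @ q.T), -1.0, 1.0)
        ang = 2 * np.arccos(dots)
        np.fill_diagonal(ang, np.inf)
        nn = ang.min(axis=1)
        assert nn.std() / nn.mean() < 0.5


class TestDockFragment:
    def test_one_pose_per_rotation(self, receptor_grids, native_frag,
                                   coarse_rotations):
        poses = fftdock.dock_fragment(receptor_grids, native_frag,
                                      coarse_rotations,
                                      fftdock.STANDARD_WEIGHTS, keep=250)
        assert len(poses) == len(coarse_rotations)
        assert len({p.rotation_index for p in poses}) == len(poses)

    def test_energies_sorted_ascending(self, receptor_grids, native_frag,
                                       coarse_rotations):
        poses = fftdock.dock_fragment(receptor_grids, native_frag,
                                      coarse_rotations,
                                      fftdock.STANDARD_WEIGHTS)
        totals = [p.e_total for p in poses]
        assert totals == sorted(totals)

    def test_score_decomposition(self, receptor_grids, native_frag,
                                 coarse_rotations):
        w = fftdock.STANDARD_WEIGHTS
        poses = fftdock.dock_fragment(receptor_grids, native_frag,
                                      coarse_rotations, w)
        for p in poses:
            assert p.e_total == pytest.approx(
                w.w_rep * p.e_rep + w.w_att * p.e_att + w.w_elec * p.e_elec,
                abs=1e-9)

    def test_planted_pose_recovered_rank_one(self, receptor_grids, native_frag,
                                             coarse_rotations):
        poses = fftdock.dock_fragment(receptor_grids, native_frag,
                                      coarse_rotations,
                                      fftdock.STANDARD_WEIGHTS)
        top = poses[0]
        assert top.rotation_index == 0
        moved = top.transformed_backbone(native_frag)
        disp = np.sqrt(np.mean(np.sum(
            (moved - native_frag.backbone_flat()) ** 2, axis=1)))
        assert disp <= receptor_grids.spec.spacing * np.sqrt(3)

    def test_planted_pose_is_exhaustive_optimum(self, receptor_grids,
                                                native_frag, coarse_rotations):
        best = fixtures.direct_best_pose(receptor_grids, native_frag,
                                         coarse_rotations,
                                         fftdock.STANDARD_WEIGHTS)
        poses = fftdock.dock_fragment(receptor_grids, native_frag,
                                      coarse_rotations,
                                      fftdock.STANDARD_WEIGHTS)
        assert best[0] == poses[0].rotation_index == 0
        assert best[1] == poses[0].tvoxel
        assert best[2] == pytest.approx(poses[0].e_total, rel=1e-9)

    def test_translational_equivariance(self, receptor_grids, native_frag):
        rots = fftdock.RotationSet(np.eye(3)[None, :, :])
        w = fftdock.STANDARD_WEIGHTS
        base = fftdock.dock_fragment(receptor_grids, native_frag, rots, w)[0]
        shift = (2, 1, 3)
        shifted = fftdock.dock_fragment(receptor_grids.shifted(shift),
                                        native_frag, rots, w)[0]
        assert tuple(np.array(base.tvoxel) + shift) == shifted.tvoxel
        assert shifted.e_total == pytest.approx(base.e_total, abs=1e-6)


class TestDockLibrary:
    def test_pool_size_bound(self, receptor_grids, db150, coarse_rotations):
        from motifdock import motiflib
        records, _ = motiflib.harvest_fragments(
            motiflib.compile_motif("KGRRL"), db150)
        clusters = motiflib.cluster_fragments(records[:40], max_clusters=3)
        poses = fftdock.dock_library(receptor_grids, clusters,
                                     coarse_rotations,
                                     fftdock.STANDARD_WEIGHTS, keep=250)
        assert len(poses) <= 3 * len(coarse_rotations)
        assert {p.fragment_id for p in poses} <= set(range(len(clusters)))

    def test_single_fragment_equals_dock_fragment(self, receptor_grids,
                                                  native_frag, coarse_rotations):
        from motifdock.motiflib import FragmentClusterSet
        lib = FragmentClusterSet(clusters=[(native_frag, 1)])
        pooled = fftdock.dock_library(receptor_grids, lib, coarse_rotations,
                                      fftdock.STANDARD_WEIGHTS)
        single = fftdock.dock_fragment(receptor_grids, native_frag,
                                       coarse_rotations,
                                       fftdock.STANDARD_WEIGHTS)
        assert [(p.rotation_index, p.tvoxel, p.e_total) for p in pooled] == \
               [(p.rotation_index, p.tvoxel, p.e_total) for p in single]
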