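"""Lesion analytics tests: hand-counted oracles on toy volumes, the
sparse-CCA map contract, disconnection maps, and the predictive
validity comparison."""

import numpy as np
import pytest

from discourselsm import lesionmap as lm
from discourselsm.lesionmap import (CohortLesions, LesionVolume, SpaceError,
                                    StreamlineSet, TractAtlas,
                                    disconnection_map, label_weights,
                                    lesion_matrix, load_lesion_nifti, pvc,
                                    pvc_verdict, regress_out, sparse_cca_lsm,
                                    save_volume_nifti, tract_lesion_percentage,
                                    voxel_coverage_filter)

SHAPE = (6, 6, 6)


def vol_from_voxels(voxels, shape=SHAPE):
    data = np.zeros(shape, np.uint8)
    for v in voxels:
        data[v] = 1
    return LesionVolume(data=data, voxel_size_mm=(2.0, 2.0, 2.0))


class TestCoverageFilter:
    def test_single_subject_boundary_inclusive(self):
        vols = [vol_from_voxels([(0, 0, 0)])] + [vol_from_voxels([(1, 1, 1)])] * 9
        cohort = CohortLesions(tuple(f"s{i}" for i in range(10)), tuple(vols))
        kept = voxel_coverage_filter(cohort, 0.10)
        # voxel lesioned in exactly 1 of 10 subjects is retained (1/10 >= 0.10)
        assert np.ravel_multi_index((0, 0, 0), SHAPE) in kept
        assert np.ravel_multi_index((2, 2, 2), SHAPE) not in kept

    def test_n63_requires_seven_subjects(self):
        base = [(0, 0, 0)]
        vols = [vol_from_voxels(base + ([(1, 1, 1)] if i < 6 else []))
                for i in range(63)]
        cohort = CohortLesions(tuple(f"s{i}" for i in range(63)), tuple(vols))
        kept = set(voxel_coverage_filter(cohort, 0.10).tolist())
        assert np.ravel_multi_index((0, 0, 0), SHAPE) in kept       # 63/63
        assert np.ravel_multi_index((1, 1, 1), SHAPE) not in kept   # 6/63 < 0.10
        vols7 = [vol_from_voxels(base + ([(1, 1, 1)] if i < 7 else []))
                 for i in range(63)]
        cohort7 = CohortLesions(tuple(f"s{i}" for i in range(63)), tuple(vols7))
        assert np.ravel_multi_index((1, 1, 1), SHAPE) in set(
            voxel_coverage_filter(cohort7, 0.10).tolist())          # 7/63 >= 0.10

    def test_invalid_fraction(self):
        cohort = CohortLesions(("s0",), (vol_from_voxels([(0, 0, 0)]),))
        with pytest.raises(ValueError):
            voxel_coverage_filter(cohort, 0.0)


class TestRegressOut:
    def test_residuals_orthogonal_and_zero_mean(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(30)
        z = rng.standard_normal(30)
        res = regress_out(y, z)
        assert abs(res.mean()) < 1e-10
        assert abs(res @ z) < 1e-8

    def test_behavior_equals_covariate(self):
        z = np.arange(10.0)
        assert np.allclose(regress_out(z, z), 0.0, atol=1e-10)

    def test_constant_behavior_rejected(self):
        with pytest.raises(ValueError):
            regress_out(np.ones(10), np.arange(10.0))


class TestTractPercentage:
    def test_hand_counts(self):
        atlas = TractAtlas(tracts={
            "t8": np.array([[0, 0, i] for i in range(4)] + [[0, 1, i] for i in range(4)]),
            "far": np.array([[5, 5, 5]]),
        }, grid_shape=SHAPE)
        lesion = vol_from_voxels([(0, 0, 0), (0, 0, 1), (3, 3, 3)])
        pct = tract_lesion_percentage(lesion, atlas)
        assert pct["t8"] == pytest.approx(0.25)   # 2 of 8 voxels
        assert pct["far"] == 0.0                  # disjoint
        full = vol_from_voxels([(5, 5, 5)])
        assert tract_lesion_percentage(full, atlas)["far"] == 1.0  # superset

    def test_monotone_in_lesion(self):
        atlas = TractAtlas(tracts={"t": np.array([[0, 0, i] for i in range(4)])},
                           grid_shape=SHAPE)
        small = vol_from_voxels([(0, 0, 0)])
        big = vol_from_voxels([(0, 0, 0), (0, 0, 1), (2, 2, 2)])
        assert (tract_lesion_percentage(big, atlas)["t"]
                >= tract_lesion_percentage(small, atlas)["t"])

    def test_grid_mismatch(self):
        atlas = TractAtlas(tracts={"t": np.array([[0, 0, 0]])}, grid_shape=(3, 3, 3))
        with pytest.raises(SpaceError):
            tract_lesion_percentage(vol_from_voxels([(0, 0, 0)]), atlas)


class TestDisconnection:
    def make_streamlines(self):
        # three streamlines crossing voxel (2,2,2); one also passes (0,0,0)
        return StreamlineSet(streamlines=(
            np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]]),
            np.array([[2, 2, 0], [2, 2, 1], [2, 2, 2]]),
            np.array([[2, 0, 2], [2, 1, 2], [2, 2, 2]]),
        ), grid_shape=SHAPE)

    def test_untouched_lesion_all_zero(self):
        frac, binary = disconnection_map(vol_from_voxels([(5, 5, 5)]),
                                         self.make_streamlines())
        assert frac.sum() == 0.0
        assert binary.sum() == 0

    def test_one_of_three_disconnected(self):
        frac, binary = disconnection_map(vol_from_voxels([(0, 0, 0)]),
                                         self.make_streamlines())
        assert frac[2, 2, 2] == pytest.approx(1 / 3)
        assert binary[2, 2, 2] == 0            # 1/3 < 0.5
        assert frac[1, 1, 1] == pytest.approx(1.0)
        assert binary[1, 1, 1] == 1

    def test_everything_disconnected(self):
        frac, binary = disconnection_map(vol_from_voxels([(2, 2, 2)]),
                                         self.make_streamlines())
        traversed = frac > 0
        assert np.all(frac[traversed] == 1.0)
        assert np.array_equal(binary.astype(bool), traversed)

    def test_fraction_bounds_and_binary_subset(self, small_cohort):
        vol = small_cohort.lesions.volumes[0]
        frac, binary = disconnection_map(vol, small_cohort.streamlines)
        assert frac.min() >= 0.0 and frac.max() <= 1.0
        assert np.all(frac[binary.astype(bool)] >= 0.5)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            disconnection_map(vol_from_voxels([(0, 0, 0)]),
                              self.make_streamlines(), binarize_threshold=1.5)


def _recovery_world(n=40, shape=(16, 16, 16), seed=2):
    """Small lesion cohort with behaviour driven by one compact region."""
    from discourselsm.synthdata import SimulationConfig, generate_cohort

    cfg = SimulationConfig(n_participants=n, grid_shape=shape, seed=seed,
                           effect_beta=0.0)
    cohort = generate_cohort(cfg)
    region = np.array(cohort.critical_region)
    loads = np.array([v.data[region[:, 0], region[:, 1], region[:, 2]].mean()
                      for v in cohort.lesions.volumes])
    rng = np.random.default_rng(seed + 100)
    y = -loads + 0.2 * rng.standard_normal(n)
    vox = voxel_coverage_filter(cohort.lesions, 0.10)
    X = lesion_matrix(cohort.lesions, vox)
    return cohort, X, y, vox, region


class TestSparseCCA:
    def test_sparsity_contract(self):
        cohort, X, y, vox, _ = _recovery_world()
        res = sparse_cca_lsm(X, y, sparseness=-0.3, folds=4, seed=1,
                             voxels=vox, grid_shape=(16, 16, 16))
        frac_nonzero = np.mean(res.weights != 0)
        assert frac_nonzero <= 0.3 + 1e-9
        assert res.displayed_voxels <= set(vox[res.weights != 0].tolist())
        assert abs(np.linalg.norm(res.weights) - 1.0) < 1e-9

    def test_full_sparseness_keeps_everything(self):
        _, X, y, vox, _ = _recovery_world()
        res = sparse_cca_lsm(X, y, sparseness=-1.0, folds=4, seed=1, voxels=vox)
        # projection at magnitude 1.0 never removes voxels
        assert np.count_nonzero(res.weights) == X.shape[1]

    def test_deterministic(self):
        _, X, y, vox, _ = _recovery_world()
        r1 = sparse_cca_lsm(X, y, -0.3, 4, seed=9, voxels=vox)
        r2 = sparse_cca_lsm(X, y, -0.3, 4, seed=9, voxels=vox)
        assert np.array_equal(r1.weights, r2.weights)
        assert r1.cv_correlation == r2.cv_correlation

    def test_signal_detected(self):
        _, X, y, vox, _ = _recovery_world()
        res = sparse_cca_lsm(X, y, -0.3, 4, seed=1, voxels=vox)
        assert res.cv_correlation > 0.3
        assert res.p < 0.05

    def test_constant_behavior_rejected(self):
        _, X, _, vox, _ = _recovery_world()
        with pytest.raises(ValueError):
            sparse_cca_lsm(X, np.ones(X.shape[0]), voxels=vox)


class TestLabelWeights:
    def _result(self, weights, voxels, grid=SHAPE):
        return lm.LSMResult(weights=np.asarray(weights, float),
                            voxels=np.asarray(voxels, int), grid_shape=grid,
                            cv_correlation=0.0, p=1.0, sparseness=-0.3,
                            folds=4, seed=0)

    def test_all_in_one_region(self):
        atlas = TractAtlas(tracts={"A": np.array([[0, 0, 0], [0, 0, 1]])},
                           grid_shape=SHAPE)
        res = self._result([-1.0, 0.5], [0, 1])  # flat voxels 0,1 = region A
        table = label_weights(res, atlas)
        assert table["region"].tolist() == ["A"]
        assert table["share"].iloc[0] == pytest.approx(1.0)

    def test_split_60_40(self):
        atlas = TractAtlas(tracts={"A": np.array([[0, 0, 0]]),
                                   "B": np.array([[0, 0, 1]])}, grid_shape=SHAPE)
        res = self._result([-0.6, 0.4], [0, 1])
        table = label_weights(res, atlas)
        assert set(table["region"]) == {"A", "B"}
        shares = dict(zip(table["region"], table["share"]))
        assert shares["A"] == pytest.approx(0.6)
        assert shares["B"] == pytest.approx(0.4)

    def test_small_share_filtered(self):
        atlas = TractAtlas(tracts={"A": np.array([[0, 0, 0]]),
                                   "B": np.array([[0, 0, 1]])}, grid_shape=SHAPE)
        res = self._result([-0.95, 0.05], [0, 1])
        table = label_weights(res, atlas)
        assert table["region"].tolist() == ["A"]

    def test_empty_weights_empty_table(self):
        atlas = TractAtlas(tracts={"A": np.array([[0, 0, 0]])}, grid_shape=SHAPE)
        table = label_weights(self._result([0.0], [0]), atlas)
        assert len(table) == 0


class TestPVC:
    def test_identical_behaviors_single_map(self):
        _, X, y, vox, _ = _recovery_world()
        res = pvc(X, y, y.copy(), sparseness=-0.3, folds=4, seed=3)
        assert res.aic_difference <= 0.0
        assert res.verdict == "single_map"

    def test_disjoint_regions_larger_difference(self):
        cohort, X, y, vox, region = _recovery_world()
        shape = (16, 16, 16)
        # second region: far corner voxels present in the coverage mask
        far = [v for v in vox.tolist()
               if v not in set(np.ravel_multi_index(
                   (region[:, 0], region[:, 1], region[:, 2]), shape).tolist())]
        far = np.array(far[-30:])
        cols = np.isin(vox, far)
        load2 = X[:, cols].mean(axis=1)
        rng = np.random.default_rng(77)
        y2 = -load2 + 0.2 * rng.standard_normal(len(load2))
        res_disjoint = pvc(X, y, y2, -0.3, 4, seed=3)
        res_identical = pvc(X, y, y.copy(), -0.3, 4, seed=3)
        assert res_disjoint.aic_difference > res_identical.aic_difference

    def test_verdict_boundary_exact(self):
        assert pvc_verdict(100.0) == "single_map"
        assert pvc_verdict(100.0000001) == "two_maps"
        assert pvc_verdict(14.0) == "single_map"  # a small difference: one map

    def test_mismatched_subjects_rejected(self):
        _, X, y, vox, _ = _recovery_world()
        with pytest.raises(ValueError):
            pvc(X, y, y[:-1])


class TestNiftiIO:
    def test_roundtrip(self, tmp_path):
        vol = vol_from_voxels([(0, 0, 0), (1, 2, 3)])
        path = tmp_path / "mask.nii.gz"
        save_volume_nifti(vol.data, path, vol.voxel_size_mm)
        back = load_lesion_nifti(path)
        assert np.array_equal(back.data, vol.data)
        assert back.voxel_size_mm == (2.0, 2.0, 2.0)
        assert back.size_cc == pytest.approx(2 * 8 / 1000.0)

    def test_lesion_size_cc(self):
        vol = vol_from_voxels([(0, 0, 0)] )
        assert vol.size_cc == pytest.approx(0.008)
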