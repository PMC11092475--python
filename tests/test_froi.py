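"""Coactivation maps, adaptive thresholding, overlap removal, fROIs, QC."""

import numpy as np
import pytest

from thalamoloc.froi import (
    CoactivationMap,
    FroiResult,
    ThresholdConfig,
    adaptive_threshold,
    coactivation_map,
    extract_froi,
    qc_flags,
    remove_cross_modal_overlap,
)
from thalamoloc.imaging import MaskVolume, VolumeSeries

EYE = np.eye(4)


def _precision_partial_corr(x, y, Z):
    """Independent oracle: partial correlation from the precision matrix."""
    cols = [x, y] + ([] if Z is None else [Z[:, i] for i in range(Z.shape[1])])
    P = np.linalg.inv(np.cov(np.stack(cols)))
    return -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])


def _series_from(voxel_matrix):
    """Pack a (T, V) matrix into a (V,1,1,T) series with an all-true mask."""
    T, V = voxel_matrix.shape
    data = np.zeros((V, 1, 1, T))
    data[:, 0, 0, :] = voxel_matrix.T
    return VolumeSeries(data, EYE, 1.0), MaskVolume(np.ones((V, 1, 1), bool), EYE)


class TestCoactivationMap:
    def test_identity_without_nuisance(self, rng):
        x = rng.normal(size=60)
        series, tsr = _series_from(x[:, None])
        cmap = coactivation_map(series, tsr, x, None)
        assert cmap.values[tsr.data] == pytest.approx(1.0)

    def test_matches_precision_matrix_oracle(self, rng):
        """Residualize-then-correlate equals the inverse-covariance route."""
        T, V, K = 60, 7, 4
        voxels = rng.normal(size=(T, V))
        cortex = rng.normal(size=T)
        nuisance = rng.normal(size=(T, K))
        series, tsr = _series_from(voxels)
        cmap = coactivation_map(series, tsr, cortex, nuisance)
        got = cmap.values[:, 0, 0]
        for v in range(V):
            expected = _precision_partial_corr(voxels[:, v], cortex, nuisance)
            assert abs(got[v] - expected) < 1e-10

    def test_cortex_in_nuisance_degenerates_to_zero(self, rng):
        x = rng.normal(size=60)
        series, tsr = _series_from(rng.normal(size=(60, 3)))
        cmap = coactivation_map(series, tsr, x, x[:, None])
        np.testing.assert_allclose(cmap.values[tsr.data], 0.0, atol=1e-8)


def _cmap(values3d, tsr_data):
    return CoactivationMap(
        values=values3d, tsr=MaskVolume(tsr_data, EYE), cortex_target="AC"
    )


class TestAdaptiveThreshold:
    def test_mean_320_numerator_32_keeps_32(self, rng):
        tsr = np.zeros((20, 20, 1), bool)
        tsr.ravel()[:320] = True
        values = np.zeros(tsr.shape)
        values[tsr] = rng.normal(size=320)
        kept = adaptive_threshold(_cmap(values, tsr), (320, 320), 32)
        assert kept.size == 32
        # kept voxels are exactly the 32 largest values
        assert values[kept.data].min() >= np.sort(values[tsr])[-32]

    def test_asymmetric_hemispheres(self, rng):
        left = np.zeros((10, 10, 1), bool)
        left.ravel()[:100] = True
        right = np.zeros((10, 10, 1), bool)
        right.ravel()[:60] = True
        vals_l = np.zeros(left.shape)
        vals_l[left] = rng.normal(size=100)
        vals_r = np.zeros(right.shape)
        vals_r[right] = rng.normal(size=60)
        # fraction = 20 / mean(100, 60) = 0.25
        assert adaptive_threshold(_cmap(vals_l, left), (100, 60), 20).size == 25
        assert adaptive_threshold(_cmap(vals_r, right), (100, 60), 20).size == 15

    def test_numerator_at_least_mean_keeps_all(self, rng):
        tsr = np.zeros((5, 5, 1), bool)
        tsr.ravel()[:20] = True
        values = np.zeros(tsr.shape)
        values[tsr] = rng.normal(size=20)
        kept = adaptive_threshold(_cmap(values, tsr), (20, 20), 50)
        assert kept.size == 20

    def test_monotone_in_numerator(self, rng):
        tsr = np.zeros((10, 10, 1), bool)
        tsr.ravel()[:90] = True
        values = np.zeros(tsr.shape)
        values[tsr] = rng.normal(size=90)
        sizes = [
            adaptive_threshold(_cmap(values, tsr), (90, 90), num).size
            for num in (5, 10, 20, 40, 80, 160)
        ]
        assert sizes == sorted(sizes)


class TestOverlapRemoval:
    def test_disjoint_unchanged(self):
        a = MaskVolume(np.eye(4, dtype=bool)[..., None], EYE)
        b = MaskVolume(np.zeros((4, 4, 1), bool), EYE)
        b.data[0, 1, 0] = True
        a2, b2 = remove_cross_modal_overlap(a, b)
        np.testing.assert_array_equal(a2.data, a.data)
        np.testing.assert_array_equal(b2.data, b.data)

    def test_identical_inputs_both_empty(self):
        a = MaskVolume(np.ones((3, 3, 3), bool), EYE)
        a2, b2 = remove_cross_modal_overlap(a, a)
        assert a2.size == 0 and b2.size == 0

    def test_partial_overlap_removed_from_both(self):
        a = np.zeros((6, 6, 1), bool)
        b = np.zeros((6, 6, 1), bool)
        a[0:3, 0, 0] = True
        a[0:3, 1, 0] = True
        b[0:3, 1, 0] = True  # 3-voxel overlap
        b[0:3, 2, 0] = True
        a2, b2 = remove_cross_modal_overlap(
            MaskVolume(a, EYE), MaskVolume(b, EYE)
        )
        assert a2.size == a.sum() - 3
        assert b2.size == b.sum() - 3
        assert not (a2.data & b2.data).any()


class TestExtractFroi:
    def test_largest_component_wins(self):
        data = np.zeros((20, 8, 8), bool)
        data[1:3, 1:8, 1:2] = True  # 14 voxels
        data[10:16, 5, 5] = True  # 6 voxels
        froi, flags = extract_froi(MaskVolume(data, EYE))
        assert froi.size == 14
        assert flags == []

    def test_single_component_identity(self):
        data = np.zeros((6, 6, 6), bool)
        data[2:4, 2:4, 2:4] = True
        froi, flags = extract_froi(MaskVolume(data, EYE))
        np.testing.assert_array_equal(froi.data, data)

    def test_empty_input_flagged(self):
        froi, flags = extract_froi(MaskVolume(np.zeros((4, 4, 4), bool), EYE))
        assert froi.size == 0
        assert flags == ["empty_froi"]


def _result_from_centroids(mgn_l, lgn_l, sizes=(3, 3, 3, 3)):
    """Construct an FroiResult with small blocks at given left-hemisphere
    centers (right hemisphere mirrored)."""
    shape = (40, 40, 40)
    aff = np.diag([2.0, 2.0, 2.0, 1.0])
    aff[:3, 3] = -40.0

    def block(center, n):
        data = np.zeros(shape, bool)
        x, y, z = center
        data[x : x + 1, y : y + 1, z : z + n] = True
        return MaskVolume(data, aff)

    def mirror(center):
        return (39 - center[0], center[1], center[2])

    return FroiResult(
        mgn_left=block(mgn_l, sizes[0]),
        mgn_right=block(mirror(mgn_l), sizes[1]),
        lgn_left=block(lgn_l, sizes[2]),
        lgn_right=block(mirror(lgn_l), sizes[3]),
    )


class TestQcFlags:
    def test_plausible_configuration_unflagged(self):
        # LGN lateral (smaller x index = more negative world x) and superior
        result = _result_from_centroids(mgn_l=(14, 20, 20), lgn_l=(10, 20, 24))
        assert qc_flags(result) == []

    def test_medial_lgn_flagged(self):
        result = _result_from_centroids(mgn_l=(10, 20, 20), lgn_l=(16, 20, 24))
        assert "lgn_medial_to_mgn_left" in qc_flags(result)

    def test_inferior_lgn_flagged(self):
        result = _result_from_centroids(mgn_l=(14, 20, 24), lgn_l=(10, 20, 18))
        flags = qc_flags(result)
        assert "lgn_inferior_to_mgn_left" in flags

    def test_asymmetry_flagged(self):
        result = _result_from_centroids(
            mgn_l=(14, 20, 20), lgn_l=(10, 20, 32), sizes=(16, 4, 3, 3)
        )
        assert "asymmetric_mgn" in qc_flags(result)  # ratio 4 > 3

    def test_empty_froi_flagged(self):
        result = _result_from_centroids((14, 20, 20), (10, 20, 24))
        result.mgn_left = MaskVolume(
            np.zeros(result.mgn_left.shape, bool), result.mgn_left.affine
        )
        assert "empty_mgn_left" in qc_flags(result)

    def test_pipeline_result_clean(self, localizer_output):
        assert localizer_output.froi.qc == []


class TestThresholdConfig:
    def test_numerators(self):
        cfg = ThresholdConfig()
        assert cfg.numerator("MGN") == 32.0
        assert cfg.numerator("LGN") == 20.0
        with pytest.raises(ValueError):
            ThresholdConfig(mgn_numerator=0)
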