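"""Resting-state post-processing, censoring rules, connectivity, statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thalamoloc._stats import partial_correlation
from thalamoloc.imaging import MaskVolume, VolumeImage, VolumeSeries
from thalamoloc.rsfc import (
    CensorConfig,
    apply_retention_rules,
    bandpass_filter,
    bandpass_with_interpolation,
    build_rsfc_nuisance,
    detrend_center,
    dice,
    edge_discard_count,
    eye_closure_censor,
    mode1000_normalize,
    roi_pair_connectivity,
    seed_connectivity_map,
    selectivity_tests,
)

EYE = np.eye(4)


def _series(data, tr=0.8):
    return VolumeSeries(np.asarray(data, float), EYE, tr)


def _brain(shape):
    return MaskVolume(np.ones(shape, bool), EYE)


class TestMode1000:
    def test_constant_500_maps_to_1000(self):
        s = _series(np.full((3, 3, 3, 10), 500.0))
        out = mode1000_normalize(s, _brain((3, 3, 3)))
        # the histogram mode of a constant image is slightly offset by the
        # bin construction, but the dominant value lands on 1000
        np.testing.assert_allclose(out.data, 1000.0, rtol=0.01)

    def test_scale_invariance(self, rng):
        data = rng.uniform(500, 1500, size=(4, 4, 4, 20))
        a = mode1000_normalize(_series(data), _brain((4, 4, 4)))
        b = mode1000_normalize(_series(3.7 * data), _brain((4, 4, 4)))
        np.testing.assert_allclose(a.data, b.data, rtol=1e-12)

    def test_bimodal_uses_dominant_mode(self, rng):
        data = np.empty((10, 10, 1, 4))
        vals = np.concatenate(
            [np.full(70, 800.0), np.full(30, 200.0)]
        ) + rng.normal(0, 1, 100)
        data[..., :] = vals.reshape(10, 10, 1, 1)
        out = mode1000_normalize(_series(data), _brain((10, 10, 1)))
        # dominant cluster (800) is scaled to ~1000, not the minor one
        hi = out.data[..., 0][data[..., 0] > 500]
        assert np.abs(np.median(hi) - 1000.0) < 20.0


class TestDetrend:
    def test_ramp_and_constant_go_to_zero(self):
        t = np.arange(30, dtype=float)
        data = np.empty((2, 1, 1, 30))
        data[0, 0, 0] = 3.0 + 2.0 * t
        data[1, 0, 0] = 7.0
        out = detrend_center(_series(data))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-9)

    def test_residual_orthogonal_to_line(self, rng):
        data = rng.normal(size=(3, 3, 3, 40))
        out = detrend_center(_series(data))
        t = np.arange(40, dtype=float)
        flat = out.data.reshape(-1, 40)
        assert np.abs(flat.sum(axis=1)).max() < 1e-8
        assert np.abs(flat @ (t - t.mean())).max() < 1e-6


class TestEyeCensor:
    def test_short_closure_ignored(self):
        keep = eye_closure_censor([(10.0, 12.0)], tr=0.8, n_volumes=50)
        assert keep.all()

    def test_long_closure_censors_overlapping_volumes(self):
        # 4 s closure [10, 14): volumes overlapping it at TR 0.8 are 12..17
        keep = eye_closure_censor([(10.0, 14.0)], tr=0.8, n_volumes=50)
        censored = np.flatnonzero(~keep)
        expected = [
            t
            for t in range(50)
            if (t * 0.8 < 14.0) and ((t + 1) * 0.8 > 10.0)
        ]
        assert censored.tolist() == expected

    def test_gap_between_qualifying_closures_censored(self):
        # two 4 s closures 20 s apart: both and the gap between are censored
        keep = eye_closure_censor([(8.0, 12.0), (32.0, 36.0)], tr=1.0, n_volumes=60)
        assert not keep[8:36].any()
        assert keep[:8].all() and keep[36:].all()

    def test_distant_closures_leave_gap_alone(self):
        keep = eye_closure_censor([(0.0, 4.0), (40.0, 44.0)], tr=1.0, n_volumes=60)
        assert keep[10:39].all()

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            eye_closure_censor([(5.0, 3.0)], tr=1.0, n_volumes=10)


class TestRetention:
    def test_short_island_censored(self):
        # 7 s island at TR 1 s between censored spans is dropped (7 < 8)
        keep = np.ones(200, bool)
        keep[50:60] = False
        keep[67:80] = False  # leaves a 7-volume island at 60..66
        pruned, run_keep, _, _ = apply_retention_rules([keep], tr=1.0)
        assert not pruned[0][60:67].any()
        assert run_keep[0]

    def test_run_below_90s_dropped(self):
        keep = np.zeros(200, bool)
        keep[:80] = True  # 80 s at TR 1 s
        _, run_keep, participant, _ = apply_retention_rules([keep], tr=1.0)
        assert run_keep == [False]
        assert not participant

    def test_two_runs_of_140s_fail_total(self):
        keep = np.zeros(200, bool)
        keep[:140] = True
        _, run_keep, participant, report = apply_retention_rules(
            [keep.copy(), keep.copy()], tr=1.0
        )
        assert run_keep == [True, True]
        assert not participant  # 280 < 300 s total
        assert report["total_retained_seconds"] == 280.0

    def test_sufficient_data_kept(self):
        keep = np.ones(200, bool)
        _, run_keep, participant, _ = apply_retention_rules(
            [keep.copy(), keep.copy()], tr=1.0
        )
        assert participant


class TestBandpass:
    @pytest.mark.parametrize("tr,expected", [(0.85, 26), (0.80, 28)])
    def test_edge_discard_counts(self, tr, expected):
        assert edge_discard_count(tr) == expected

    def test_passband_and_stopband(self):
        tr = 0.8
        t = np.arange(2000) * tr
        passing = np.sin(2 * np.pi * 0.03 * t)
        stopped = np.sin(2 * np.pi * 0.2 * t)
        keep = np.ones(2000, bool)
        out_pass, idx = bandpass_with_interpolation(passing[None, :], keep, tr)
        out_stop, _ = bandpass_with_interpolation(stopped[None, :], keep, tr)
        # compare RMS amplitudes over the retained interior
        rms = lambda x: np.sqrt(np.mean(np.square(x)))
        assert rms(out_pass) > 0.95 * rms(passing[idx])
        assert rms(out_stop) < 0.10 * rms(stopped[idx])
        # and the zero-phase frequency response itself
        from scipy import signal as sig

        b, a = sig.butter(2, [0.009 / (0.5 / tr), 0.08 / (0.5 / tr)], "bandpass")
        _, h = sig.freqz(b, a, worN=[0.03, 0.2], fs=1 / tr)
        gain = np.abs(h) ** 2  # forward + backward application
        assert gain[0] > 0.95
        assert gain[1] < 0.10

    def test_censored_points_interpolated_then_dropped(self):
        tr = 1.0
        n = 300
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * 0.02 * t)
        keep = np.ones(n, bool)
        keep[100:110] = False
        out, idx = bandpass_with_interpolation(x[None, :], keep, tr)
        n_edge = edge_discard_count(tr)
        assert idx.min() >= n_edge
        assert idx.max() < n - n_edge
        assert not np.isin(np.arange(100, 110), idx).any()
        assert out.shape[-1] == idx.size

    def test_too_few_volumes_rejected(self):
        with pytest.raises(ValueError):
            bandpass_with_interpolation(np.zeros((1, 50)), np.ones(50, bool), 0.85)


class TestNuisance:
    def test_28_columns(self, rng):
        X = build_rsfc_nuisance(
            rng.normal(size=(120, 6)), rng.normal(size=120), rng.normal(size=120), 0.8
        )
        assert X.shape == (120, 28)

    def test_constant_motion_gives_zero_derivative(self):
        X = build_rsfc_nuisance(
            np.ones((120, 6)), np.zeros(120), np.zeros(120), 0.8
        )
        # filtered constant is ~0; its derivative columns are exactly the
        # backward differences (0 everywhere up to numerics)
        d = X[:, 12:18]
        assert np.abs(d[1:]).max() < 1e-10
        assert np.all(d[0] == 0)

    def test_squares_follow_filtering(self, rng):
        mp = rng.normal(size=(200, 6))
        X = build_rsfc_nuisance(mp, np.zeros(200), np.zeros(200), 0.8)
        mp_f = bandpass_filter(mp, 0.8, axis=0)
        np.testing.assert_allclose(X[:, 6:12], mp_f**2, atol=1e-12)
        # and not the filtered squares
        assert not np.allclose(X[:, 6:12], bandpass_filter(mp**2, 0.8, axis=0))

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            build_rsfc_nuisance(
                rng.normal(size=(120, 6)), rng.normal(size=100), np.zeros(120), 0.8
            )


def _precision_partial_corr(x, y, Z):
    cols = [x, y] + [Z[:, i] for i in range(Z.shape[1])]
    P = np.linalg.inv(np.cov(np.stack(cols)))
    return -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])


class TestRoiPairConnectivity:
    def test_equal_pairwise_correlations_average_exactly(self, rng):
        x = rng.normal(size=100)
        y = 0.5 * x + rng.normal(size=100)
        est = roi_pair_connectivity([(x, x)], [(y, y)], [None], pair="MGN-AC")
        expected = partial_correlation(x, y, None)
        assert est.participant_value == pytest.approx(expected, abs=1e-12)

    def test_oracle_agreement(self, rng):
        sl, sr = rng.normal(size=(2, 60))
        tl, tr_ = rng.normal(size=(2, 60))
        Z = rng.normal(size=(60, 5))
        est = roi_pair_connectivity([(sl, sr)], [(tl, tr_)], [Z], pair="LGN-VC")
        expected = np.mean(
            [
                _precision_partial_corr(s, t, Z)
                for s in (sl, sr)
                for t in (tl, tr_)
            ]
        )
        assert abs(est.participant_value - expected) < 1e-10

    def test_multi_run_mean(self, rng):
        runs = [rng.normal(size=(4, 80)) for _ in range(3)]
        est = roi_pair_connectivity(
            [(r[0], r[1]) for r in runs],
            [(r[2], r[3]) for r in runs],
            [None] * 3,
            pair="MGN-AC",
        )
        assert est.participant_value == pytest.approx(np.mean(est.run_values))
        assert len(est.run_values) == 3

    @given(a=st.floats(0.5, 3.0), b=st.floats(-2.0, -0.1))
    @settings(max_examples=20, deadline=None)
    def test_invariance_to_affine_rescaling(self, a, b):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=(2, 50))
        Z = rng.normal(size=(50, 3))
        r0 = partial_correlation(x, y, Z)
        r1 = partial_correlation(a * x + 5.0, b * y - 2.0, 2.5 * Z + 1.0)
        assert r1 == pytest.approx(np.sign(b) * np.sign(a) * r0, abs=1e-9)


class TestSelectivity:
    def test_identical_columns_give_null_result(self):
        vals = np.linspace(0.1, 0.5, 10)
        table = pd.DataFrame(
            {"MGN-AC": vals, "MGN-VC": vals, "LGN-AC": vals, "LGN-VC": vals}
        )
        out = selectivity_tests(table)
        np.testing.assert_allclose(out["t"], 0.0)
        np.testing.assert_allclose(out["p"], 0.5)

    def test_planted_effect_strongly_significant(self, rng):
        n = 20
        base = rng.normal(0, 0.1, size=n)
        table = pd.DataFrame(
            {
                "MGN-AC": base + 0.45,
                "MGN-VC": base + 0.15 + rng.normal(0, 0.1, n),
                "LGN-AC": base + 0.15 + rng.normal(0, 0.1, n),
                "LGN-VC": base + 0.45 + rng.normal(0, 0.05, n),
            }
        )
        out = selectivity_tests(table)
        assert (out["p"] < 1e-3).all()
        assert out["significant"].all()

    def test_bh_step_up_hand_computed(self):
        """p = (0.01, 0.02, 0.03, 0.04) at alpha 0.05: every hypothesis is
        rejected because p_(4) = 0.04 <= 0.05 * 4/4."""
        rng = np.random.default_rng(0)
        # construct paired columns whose four contrasts give those p-values
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests(
            [0.01, 0.02, 0.03, 0.04], alpha=0.05, method="fdr_bh"
        )
        assert reject.all()
        np.testing.assert_allclose(p_adj, [0.04, 0.04, 0.04, 0.04])

    def test_too_few_rows_rejected(self):
        table = pd.DataFrame(
            {"MGN-AC": [0.1], "MGN-VC": [0.1], "LGN-AC": [0.1], "LGN-VC": [0.1]}
        )
        with pytest.raises(ValueError):
            selectivity_tests(table)


class TestSeedMap:
    def test_copied_seed_gives_unit_correlation(self, rng):
        seed = rng.normal(size=50)
        data = rng.normal(size=(5, 1, 1, 50))
        data[2, 0, 0] = seed
        out = seed_connectivity_map(seed, seed, _series(data), None)
        assert out.data[2, 0, 0] == pytest.approx(1.0)

    def test_hemisphere_maps_averaged(self, rng):
        t = 200
        shared = rng.normal(size=t)
        left = shared + rng.normal(0, 1.0, t)
        right = shared + rng.normal(0, 1.0, t)
        data = np.zeros((1, 1, 1, t))
        data[0, 0, 0] = shared
        out = seed_connectivity_map(left, right, _series(data), None)
        rl = partial_correlation(left, shared, None)
        rr = partial_correlation(right, shared, None)
        assert out.data[0, 0, 0] == pytest.approx((rl + rr) / 2, abs=1e-12)

    def test_oracle_on_toy_volume(self, rng):
        data = rng.normal(size=(5, 1, 1, 60))
        seed_l, seed_r = rng.normal(size=(2, 60))
        Z = rng.normal(size=(60, 3))
        out = seed_connectivity_map(seed_l, seed_r, _series(data), Z)
        for v in range(5):
            expected = np.mean(
                [
                    _precision_partial_corr(s, data[v, 0, 0], Z)
                    for s in (seed_l, seed_r)
                ]
            )
            assert abs(out.data[v, 0, 0] - expected) < 1e-10


class TestDice:
    def test_basic_values(self):
        a = MaskVolume(np.zeros((5, 5, 5), bool), EYE)
        b = MaskVolume(np.zeros((5, 5, 5), bool), EYE)
        a.data[0, 0, :5] = True
        assert dice(a, a) == 1.0
        b.data[4, 4, :5] = True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = MaskVolume(np.zeros((5, 5, 5), bool), EYE)
        b = MaskVolume(np.zeros((5, 5, 5), bool), EYE)
        a.data.ravel()[:10] = True
        b.data.ravel()[5:15] = True
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_warns_zero(self):
        a = MaskVolume(np.zeros((3, 3, 3), bool), EYE)
        with pytest.warns(UserWarning):
            assert dice(a, a) == 0.0


class TestCensorConfig:
    def test_study_values_are_defaults(self):
        cfg = CensorConfig()
        assert cfg.lpf_fd_threshold == pytest.approx(0.07587)
        assert cfg.gev_dv_parameter == pytest.approx(3.105)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            CensorConfig(min_segment=0.0)
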