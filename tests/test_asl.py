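import numpy as np
import pytest
from scipy import stats

from neurovasc import asl
from neurovasc.core import BlockParadigm, PCASL_GEOMETRY
from neurovasc.synthetic import SubjectTruth, generate_pcasl_series


def _make_series(echo1, echo2=None, geometry=PCASL_GEOMETRY, paradigm=BlockParadigm()):
    n = echo1.shape[-1]
    is_label = np.zeros(n, dtype=bool)
    is_label[1::2] = True
    if echo2 is None:
        echo2 = echo1.copy()
    return asl.DualEchoASLSeries(
        echo1=echo1, echo2=echo2, is_label=is_label, geometry=geometry, paradigm=paradigm
    )


class TestComputeCbfSeries:
    def test_control_equal_label_gives_zero_series(self):
        e1 = np.full((4, 4, 2, 108), 50.0)
        cbf = asl.compute_cbf_series(_make_series(e1))
        assert np.all(cbf.volumes == 0.0)

    def test_108_volumes_give_54_timepoints_at_pair_midpoints(self):
        e1 = np.zeros((2, 2, 1, 108))
        cbf = asl.compute_cbf_series(_make_series(e1))
        assert cbf.volumes.shape[-1] == 54
        tr = PCASL_GEOMETRY.tr / 1000.0
        assert cbf.times[0] == pytest.approx(0.5 * tr)
        assert np.allclose(np.diff(cbf.times), 2 * tr)

    def test_configured_perfusion_signal_recovered_exactly(self):
        e1 = np.full((2, 2, 1, 8), 100.0)
        e1[..., 1::2] -= 1.25  # label volumes lose the perfusion signal
        geom = PCASL_GEOMETRY
        cbf = asl.compute_cbf_series(
            _make_series(e1, geometry=geom, paradigm=BlockParadigm(1.0, 1))
        )
        assert np.all(cbf.volumes == pytest.approx(1.25))

    def test_invalid_flag_patterns_rejected(self):
        e1 = np.zeros((2, 2, 1, 4))
        s = _make_series(e1)
        s.is_label = np.array([0, 0, 1, 1], dtype=bool)
        with pytest.raises(ValueError):
            asl.DualEchoASLSeries(e1, e1, s.is_label, PCASL_GEOMETRY, BlockParadigm())
        with pytest.raises(ValueError):
            asl.DualEchoASLSeries(
                np.zeros((2, 2, 1, 5)),
                np.zeros((2, 2, 1, 5)),
                np.array([0, 1, 0, 1, 0], dtype=bool),
                PCASL_GEOMETRY,
                BlockParadigm(),
            )


class TestPreprocess:
    times = np.arange(54) * 9.1

    def test_spatially_constant_volume_unchanged_by_smoothing(self):
        vol = np.full((8, 8, 4, 5), 7.0)
        out = asl.smooth_volumes(vol, (2.75, 2.75, 5.0), 5.0)
        assert np.allclose(out, 7.0, atol=1e-12)

    def test_linear_drift_removed(self):
        drift = 5.0 * self.times / self.times.max()
        out = asl.highpass_detrend(drift, self.times, 90.0)
        assert np.abs(out - out.mean()).max() < 0.01 * 5.0

    def test_20s_sinusoid_amplitude_preserved_within_2_percent(self):
        y = np.sin(2 * np.pi * self.times / 20.0)
        out = asl.highpass_detrend(y, self.times, 90.0)
        X = np.c_[
            np.sin(2 * np.pi * self.times / 20.0),
            np.cos(2 * np.pi * self.times / 20.0),
            np.ones_like(self.times),
        ]
        c = np.linalg.lstsq(X, out, rcond=None)[0]
        assert np.hypot(c[0], c[1]) == pytest.approx(1.0, abs=0.02)

    def test_paradigm_fundamental_attenuation_characterized(self):
        # the 90-s cutoff partially attenuates the 108-s paradigm period;
        # this is a property of the filter, compensated in the GLM by
        # filtering the design matrix with the same operator
        y = np.sin(2 * np.pi * self.times / 108.0)
        out = asl.highpass_detrend(y, self.times, 90.0)
        X = np.c_[
            np.sin(2 * np.pi * self.times / 108.0),
            np.cos(2 * np.pi * self.times / 108.0),
            np.ones_like(self.times),
        ]
        c = np.linalg.lstsq(X, out, rcond=None)[0]
        amp = np.hypot(c[0], c[1])
        assert 0.5 < amp < 1.0

    def test_mean_preserved_by_highpass(self, rng):
        y = rng.normal(10.0, 1.0, (6, 54))
        out = asl.highpass_detrend(y, self.times, 90.0)
        assert np.allclose(out.mean(axis=-1), y.mean(axis=-1), atol=1e-10)

    def test_cutoff_below_nyquist_period_rejected(self):
        with pytest.raises(ValueError):
            asl.highpass_detrend(np.zeros(54), self.times, 9.0)


class TestBuildBlockRegressor:
    def test_long_block_plateau_is_unit_height(self):
        p = BlockParadigm(segment_duration=120.0, n_stim_blocks=1)
        t = np.array([230.0])  # deep inside the stimulation block
        r = asl.build_block_regressor(p, t)
        assert r[0] == pytest.approx(1.0, abs=1e-6)

    def test_null_paradigm_gives_zero_regressor(self):
        p = BlockParadigm(segment_duration=54.0, n_stim_blocks=0)
        t = np.arange(0, 54, 9.1)
        assert np.all(asl.build_block_regressor(p, t) == 0.0)

    def test_step_response_equals_gamma_cdf(self):
        # convolving the block onset with the unit-area kernel must give the
        # gamma CDF with shape (mean/sd)^2 = 4 and scale sd^2/mean = 1.5 s
        p = BlockParadigm(segment_duration=200.0, n_stim_blocks=1)
        t = np.array([205.0, 210.0, 215.0, 230.0])
        r = asl.build_block_regressor(p, t)
        expect = stats.gamma.cdf(t - 200.0, a=4.0, scale=1.5)
        assert np.allclose(r, expect, atol=2e-4)

    def test_invalid_hrf_rejected(self):
        with pytest.raises(ValueError):
            asl.build_block_regressor(BlockParadigm(), np.arange(10.0), hrf_mean=0.0)


class TestFitVoxelwiseGlm:
    times = np.arange(54) * 9.1

    def _regressor(self):
        return asl.build_block_regressor(BlockParadigm(), self.times)

    def test_exact_response_gives_beta_and_capped_z(self):
        r = self._regressor()
        vol = 100.0 * (1.0 + 0.03 * (r - r.mean()))[None, None, None, :]
        beta, z = asl.fit_voxelwise_glm(vol, r)
        assert beta[0, 0, 0] == pytest.approx(3.0, abs=1e-9)
        assert z[0, 0, 0] == asl.Z_CAP

    def test_matches_hand_coded_least_squares_oracle(self, rng):
        n = 10
        y = rng.normal(100.0, 2.0, (1, 1, 1, n))
        x = rng.normal(0.0, 1.0, n)
        beta, z = asl.fit_voxelwise_glm(y, x)
        # independent two-column normal-equations oracle
        pct = 100.0 * (y[0, 0, 0] / y[0, 0, 0].mean() - 1.0)
        pct -= pct.mean()
        X = np.c_[np.ones(n), x - x.mean()]
        coef, res, *_ = np.linalg.lstsq(X, pct, rcond=None)
        resid = pct - X @ coef
        se = np.sqrt(resid @ resid / (n - 2) / ((x - x.mean()) @ (x - x.mean())))
        t = coef[1] / se
        z_oracle = np.sign(t) * stats.norm.isf(stats.t.sf(abs(t), n - 2))
        assert beta[0, 0, 0] == pytest.approx(coef[1], abs=1e-10)
        assert z[0, 0, 0] == pytest.approx(z_oracle, abs=1e-10)

    def test_null_tail_calibration(self, rng):
        vol = rng.normal(100.0, 1.0, (100, 100, 1, 54))
        _, z = asl.fit_voxelwise_glm(vol, self._regressor())
        p = stats.norm.sf(3.1)
        frac = (z > 3.1).mean()
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / z.size)

    def test_beta_invariant_to_global_intensity_scaling(self, rng):
        vol = rng.normal(100.0, 1.0, (4, 4, 2, 54))
        r = self._regressor()
        b1, _ = asl.fit_voxelwise_glm(vol, r)
        b2, _ = asl.fit_voxelwise_glm(vol * 7.3, r)
        assert np.allclose(b1, b2, atol=1e-10)

    def test_zero_variance_voxel_flagged_as_null(self):
        vol = np.full((1, 1, 1, 54), 5.0)
        beta, z = asl.fit_voxelwise_glm(vol, self._regressor())
        assert beta[0, 0, 0] == 0.0 and z[0, 0, 0] == 0.0


def _roi_oracle(z_map, thr=3.1, pct=90.0):
    """Brute-force flood fill + percentile selection."""
    supra = z_map > thr
    visited = np.zeros_like(supra)
    comps = []
    idx = np.argwhere(supra)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for start in map(tuple, idx):
        if visited[start]:
            continue
        stack, comp = [start], []
        visited[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for off in offsets:
                w = tuple(np.add(v, off))
                if all(0 <= w[i] < z_map.shape[i] for i in range(3)):
                    if supra[w] and not visited[w]:
                        visited[w] = True
                        stack.append(w)
        comps.append(comp)
    if not comps:
        return np.zeros_like(supra)
    best = max(len(c) for c in comps)
    winners = [c for c in comps if len(c) == best]
    if len(winners) > 1:
        winners.sort(key=lambda c: min(np.ravel_multi_index(v, z_map.shape) for v in c))
    comp = winners[0]
    vals = np.array([z_map[v] for v in comp])
    cut = np.percentile(vals, pct)
    mask = np.zeros_like(supra)
    for v in comp:
        if z_map[v] >= cut:
            mask[v] = True
    return mask


class TestSelectActivationRoi:
    def test_all_subthreshold_gives_empty_mask(self):
        assert not asl.select_activation_roi(np.full((4, 4, 4), 2.0)).any()

    def test_largest_component_wins_and_percentile_keeps_top_decile(self):
        z = np.zeros((10, 10, 4))
        z[0:2, 0:5, 0:4] = 4.0 + np.arange(40).reshape(2, 5, 4) * 0.01  # 40 voxels
        z[7:9, 7:9, 0:3] = 9.0  # 10-voxel decoy with higher z (smaller cluster)
        roi = asl.select_activation_roi(z)
        assert roi.sum() == 4
        assert roi[0:2, 0:5, 0:4].sum() == 4  # subset of the large component

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(2.5, 1.0, (8, 8, 4))
        assert np.array_equal(asl.select_activation_roi(z), _roi_oracle(z))

    def test_nonfinite_z_rejected(self):
        z = np.zeros((2, 2, 2))
        z[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            asl.select_activation_roi(z)


class TestEstimateResponses:
    def test_uniform_beta_gives_that_delta_bold(self):
        beta = np.full((4, 4, 2), 2.0)
        roi = np.zeros((4, 4, 2), dtype=bool)
        roi[1:3, 1:3, :] = True
        times = np.arange(54) * 9.1
        r = asl.build_block_regressor(BlockParadigm(), times)
        vols = np.full((4, 4, 2, 54), 1.0) * (1.0 + 0.1 * (r - r.mean()))
        cbf = asl.CBFSeries(volumes=vols, times=times)
        dbold, dcbf, p = asl.estimate_responses(beta, roi, cbf, r)
        assert dbold == pytest.approx(2.0)
        assert dcbf == pytest.approx(10.0, abs=1e-9)
        assert p < 1e-10

    def test_empty_roi_rejected(self):
        cbf = asl.CBFSeries(volumes=np.ones((2, 2, 1, 4)), times=np.arange(4.0))
        with pytest.raises(ValueError):
            asl.estimate_responses(
                np.ones((2, 2, 1)), np.zeros((2, 2, 1), bool), cbf, np.arange(4.0)
            )


class TestQcFilter:
    def _result(self, **kw):
        base = dict(
            roi_mask=np.ones((2, 2, 2), dtype=bool),
            delta_cbf=77.0,
            delta_bold=2.0,
            qc_status="ok",
        )
        base.update(kw)
        return asl.ActivationResult(**base)

    def test_anomalous_response_excluded(self):
        ok, reason = asl.qc_filter(self._result(delta_cbf=450.0))
        assert not ok and reason == "anomalous"

    def test_typical_response_included(self):
        ok, reason = asl.qc_filter(self._result())
        assert ok and reason == "ok"

    def test_empty_roi_excluded_as_no_activation(self):
        ok, reason = asl.qc_filter(self._result(roi_mask=np.zeros((2, 2, 2), bool)))
        assert not ok and reason == "no_activation"

    def test_insignificant_cbf_response_excluded(self):
        ok, reason = asl.qc_filter(self._result(qc_status="no_cbf_response"))
        assert not ok and reason == "no_cbf_response"


class TestFullChain:
    @pytest.mark.parametrize("dcbf", [25.0, 77.1, 399.0])
    def test_zero_noise_round_trip_any_response(self, example_truth, dcbf):
        truth = SubjectTruth(**{**example_truth.__dict__, "true_dcbf_visact": dcbf})
        s = generate_pcasl_series(PCASL_GEOMETRY, BlockParadigm(), truth, noise_sd=0.0)
        res = asl.analyze_subject(s, smoothing_fwhm=0.0)
        assert res.delta_cbf == pytest.approx(dcbf, abs=0.5)
        assert res.qc_status == "ok"

    def test_pure_noise_input_rarely_reports_a_response(self, example_truth):
        # no silent fabrication: a response requires both a z>3.1 cluster
        # and a significant CBF fit, so noise-only subjects are excluded
        truth = SubjectTruth(
            **{**example_truth.__dict__, "true_dcbf_visact": 1e-9, "true_dbold_visact": 0.0}
        )
        included = 0
        for seed in range(10):
            s = generate_pcasl_series(
                PCASL_GEOMETRY, BlockParadigm(), truth, noise_sd=1.0, seed=seed
            )
            res = asl.analyze_subject(s)
            ok, _ = asl.qc_filter(res)
            included += ok
        assert included <= 3

    def test_noisy_recovery_with_default_settings(self, example_truth):
        s = generate_pcasl_series(
            PCASL_GEOMETRY, BlockParadigm(), example_truth, noise_sd=1.0, seed=4
        )
        res = asl.analyze_subject(s)
        assert res.qc_status == "ok"
        assert res.delta_cbf == pytest.approx(77.1, abs=20.0)
        assert res.delta_bold == pytest.approx(2.0, abs=0.5)
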