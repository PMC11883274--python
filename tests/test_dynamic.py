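import numpy as np
import pytest

from chromopws.dynamic import (CvcTrace, DiffusionEstimator,
                               MovingMassEstimator, TemporalCube,
                               bleb_body_cvc_ratio, diffusion_from_tau,
                               effective_diffusion, ensemble_cvc,
                               fit_polynomial_trend, fractional_moving_mass,
                               medium_wavenumber, relative_cvc_trace)
from chromopws.optics import fmm_prefactor
from chromopws.synthetic import ScenarioSpec, make_scene, synth_temporal_cube


def make_cube(intensity, i0=None, dt=0.05):
    intensity = np.asarray(intensity, dtype=float)
    if i0 is None:
        i0 = np.ones(intensity.shape[:2])
    return TemporalCube(intensity=intensity, i0=i0, frame_interval=dt)


def ar1_traces(rng, n_traces, n_frames, rho, std):
    g = np.empty((n_traces, n_frames))
    g[:, 0] = rng.standard_normal(n_traces)
    for t in range(1, n_frames):
        g[:, t] = rho * g[:, t - 1] + np.sqrt(1 - rho**2) * \
            rng.standard_normal(n_traces)
    return g * std


class TestMovingMass:
    def test_constant_cube_exactly_zero(self, cfg):
        cube = make_cube(np.ones((3, 3, 50)))
        np.testing.assert_array_equal(
            fractional_moving_mass(cube, cfg), 0.0)

    def test_linearity_in_generator_variance(self, cfg):
        # doubling the mobile fraction doubles the variance, hence the FMM
        rng = np.random.default_rng(0)
        base = rng.standard_normal((4, 4, 200))
        f1 = np.nanmean(fractional_moving_mass(
            make_cube(1.0 + 0.05 * base), cfg))
        f2 = np.nanmean(fractional_moving_mass(
            make_cube(1.0 + 0.05 * np.sqrt(2) * base), cfg))
        assert f2 / f1 == pytest.approx(2.0, rel=1e-9)

    def test_closed_loop_recovery_in_observed_band(self, cfg, small_spec):
        # moving mass within the instrument's observed ~2e-19 g band
        import dataclasses
        spec = dataclasses.replace(small_spec, fmm_body=2.0e-19, n_frames=300)
        scene = make_scene(spec, 3)
        est = []
        for seed in range(5):
            cube, _ = synth_temporal_cube(scene, spec, rng_seed=seed)
            fmm = fractional_moving_mass(cube, cfg)
            est.append(np.nanmean(fmm[scene.body_mask]))
        assert np.mean(est) == pytest.approx(2.0e-19, rel=0.10)

    def test_bad_reference_pixels_masked(self, cfg):
        i0 = np.ones((2, 2))
        i0[0, 0] = 0.0
        fmm = fractional_moving_mass(
            make_cube(np.random.default_rng(1).random((2, 2, 30)), i0), cfg)
        assert np.isnan(fmm[0, 0]) and np.isfinite(fmm).sum() == 3

    def test_estimator_generator_share_prefactor(self, cfg):
        # the same A(cfg) constant appears on both sides of the closed loop
        assert fmm_prefactor(cfg) == fmm_prefactor(cfg.replace())


class TestDiffusion:
    def test_constant_trace_flagged_not_raised(self, cfg):
        cube = make_cube(np.ones((2, 2, 40)))
        maps = effective_diffusion(cube, cfg)
        assert np.isnan(maps.d_e).all()
        assert maps.below_floor.all()

    def test_too_few_frames_rejected(self, cfg):
        with pytest.raises(ValueError):
            effective_diffusion(
                make_cube(np.random.default_rng(0).random((2, 2, 12))), cfg)

    def test_tau_half_second_recovery(self, cfg):
        # exact exponential-ACF Gaussian process at tau_d = 0.5 s
        rng = np.random.default_rng(5)
        rho = np.exp(-0.05 / 0.5)
        traces = ar1_traces(rng, 256, 300, rho, 0.1)
        cube = make_cube(1.0 + traces.reshape(16, 16, 300))
        maps = effective_diffusion(cube, cfg,
                                   regions={"all": np.ones((16, 16), bool)})
        want = diffusion_from_tau(0.5, cfg)
        assert maps.region_summaries["all"]["d_e"] == pytest.approx(
            want, rel=0.05)

    def test_decay_ordering_preserved(self, cfg):
        rng = np.random.default_rng(9)
        des = []
        for tau in (0.2, 1.0):
            rho = np.exp(-0.05 / tau)
            traces = ar1_traces(rng, 64, 300, rho, 0.1)
            cube = make_cube(1.0 + traces.reshape(8, 8, 300))
            maps = effective_diffusion(
                cube, cfg, regions={"all": np.ones((8, 8), bool)})
            des.append(maps.region_summaries["all"]["d_e"])
        assert des[0] > des[1]  # faster decay => larger D_e

    def test_out_of_band_clipped_with_flag(self, cfg):
        # nearly white traces decay within one frame: D_e beyond the ceiling
        rng = np.random.default_rng(2)
        traces = ar1_traces(rng, 64, 300, 0.05, 0.1)
        cube = make_cube(1.0 + traces.reshape(8, 8, 300))
        maps = effective_diffusion(cube, cfg)
        finite = np.isfinite(maps.d_e)
        assert finite.any()
        assert np.nanmax(maps.d_e) <= 0.065 + 1e-12

    def test_wavenumber_convention(self, cfg):
        # k_med = 2 pi n_1 / lambda with lambda in µm
        assert medium_wavenumber(cfg) == pytest.approx(
            2 * np.pi * 1.37 / 0.55)


class TestCvcTrace:
    def test_flat_trace_tie_rule(self, cfg):
        cube = make_cube(np.ones((2, 2, 40)))
        tr = relative_cvc_trace(cube, np.ones((2, 2), bool))
        assert tr.flat_trace
        np.testing.assert_array_equal(tr.cvc_rel, 0.5)

    def test_monotone_intensity_inverts(self):
        ramp = np.linspace(1.0, 2.0, 50)
        cube = make_cube(np.tile(ramp, (2, 2, 1)))
        tr = relative_cvc_trace(cube, np.ones((2, 2), bool))
        assert np.all(np.diff(tr.cvc_rel) < 0)
        assert tr.cvc_rel[0] == 1.0 and tr.cvc_rel[-1] == 0.0

    def test_bounds_always_unit_interval(self):
        rng = np.random.default_rng(3)
        cube = make_cube(0.5 + rng.random((4, 4, 80)))
        tr = relative_cvc_trace(cube, np.ones((4, 4), bool))
        assert tr.cvc_rel.min() >= 0.0 and tr.cvc_rel.max() <= 1.0

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        base = 1.0 + 0.1 * rng.standard_normal((3, 3, 60))
        i0 = np.ones((3, 3))
        a = relative_cvc_trace(make_cube(base, i0), np.ones((3, 3), bool))
        b = relative_cvc_trace(make_cube(base * 50.0, i0 * 50.0),
                               np.ones((3, 3), bool))
        np.testing.assert_allclose(a.cvc_rel, b.cvc_rel, rtol=1e-9)

    def test_generator_ramp_recovered(self, cfg, small_spec):
        # quiet medium (negligible moving mass) isolates the slow CVC ramp
        import dataclasses
        spec = dataclasses.replace(small_spec, fmm_body=1e-22, fmm_bleb=1e-22)
        scene = make_scene(spec, 2)
        cube, _ = synth_temporal_cube(scene, spec, cfg, rng_seed=6)
        tr = relative_cvc_trace(cube, scene.body_mask)
        # generator drives a linearly increasing CVC depression
        truth = np.linspace(0, 1, spec.n_frames)
        r = np.corrcoef(tr.cvc_rel, truth)[0, 1]
        assert r >= 0.95

    def test_empty_region_rejected(self):
        cube = make_cube(np.ones((2, 2, 40)))
        with pytest.raises(ValueError):
            relative_cvc_trace(cube, np.zeros((2, 2), bool))


class TestPolynomialTrend:
    def test_exact_quartic_recovered(self):
        t = np.linspace(0, 15, 300)
        coeffs = np.array([2e-5, -6e-4, 4e-3, -0.02, 0.8])
        tr = CvcTrace(t=t, raw=np.zeros_like(t), cvc_rel=np.polyval(coeffs, t))
        fit_polynomial_trend(tr, order=4)
        np.testing.assert_allclose(tr.poly_coeffs, coeffs, rtol=1e-8)

    def test_order_zero_is_mean(self):
        t = np.arange(10.0)
        vals = np.tile([0.0, 1.0], 5)
        tr = CvcTrace(t=t, raw=vals, cvc_rel=vals)
        fit_polynomial_trend(tr, order=0)
        assert tr.poly_coeffs[0] == pytest.approx(0.5)

    def test_trend_tracks_low_frequency(self, cfg, small_spec):
        scene = make_scene(small_spec, 2)
        cube, _ = synth_temporal_cube(scene, small_spec, cfg, rng_seed=8)
        tr = fit_polynomial_trend(relative_cvc_trace(cube, scene.body_mask))
        rmse = np.sqrt(np.mean((tr.cvc_rel - tr.trend) ** 2))
        assert rmse < tr.cvc_rel.std(ddof=1)

    def test_underdetermined_rejected(self):
        tr = CvcTrace(t=np.arange(4.0), raw=np.zeros(4), cvc_rel=np.zeros(4))
        with pytest.raises(ValueError):
            fit_polynomial_trend(tr, order=4)


class TestEnsemble:
    def _trace(self, values):
        t = np.linspace(0, 1, len(values))
        return CvcTrace(t=t, raw=np.asarray(values, float),
                        cvc_rel=np.asarray(values, float))

    def test_identical_traces_zero_sem(self):
        tr = [self._trace(np.linspace(0, 1, 20)) for _ in range(2)]
        out = ensemble_cvc(tr)
        np.testing.assert_allclose(out["sem"], 0.0, atol=1e-12)

    def test_hand_computed_sem(self):
        out = ensemble_cvc([self._trace(np.full(10, 0.4)),
                            self._trace(np.full(10, 0.6))], order=0)
        np.testing.assert_allclose(out["mean"], 0.5)
        np.testing.assert_allclose(out["sem"], 0.1)

    def test_single_trace_flagged(self):
        out = ensemble_cvc([self._trace(np.linspace(0, 1, 20))])
        assert out["sem_undefined"] and out["sem"] is None

    def test_body_above_bleb_preserved(self):
        rng = np.random.default_rng(0)
        body = [self._trace(0.6 + 0.02 * rng.standard_normal(30))
                for _ in range(20)]
        bleb = [self._trace(0.4 + 0.02 * rng.standard_normal(30))
                for _ in range(20)]
        eb, el = ensemble_cvc(body), ensemble_cvc(bleb)
        assert np.all(eb["mean"] > el["mean"])


class TestBlebBodyRatio:
    def test_identical_traces_unit_ratio(self):
        rows = [{"cell_id": "a", "region": "body", "cvc_mean": 0.5},
                {"cell_id": "a", "region": "bleb", "cvc_mean": 0.5}]
        out = bleb_body_cvc_ratio(rows)
        np.testing.assert_array_equal(out["ratio"], [1.0])

    def test_hand_computed_ratio(self):
        rows = [{"cell_id": "a", "region": "body", "cvc_mean": 0.6},
                {"cell_id": "a", "region": "bleb", "cvc_mean": 0.3}]
        assert bleb_body_cvc_ratio(rows)["ratio"][0] == pytest.approx(0.5)

    def test_unpaired_and_zero_body_excluded(self):
        rows = [{"cell_id": "a", "region": "body", "cvc_mean": 0.5},
                {"cell_id": "b", "region": "bleb", "cvc_mean": 0.5},
                {"cell_id": "c", "region": "body", "cvc_mean": 0.0},
                {"cell_id": "c", "region": "bleb", "cvc_mean": 0.4}]
        out = bleb_body_cvc_ratio(rows)
        assert out["ratio"].size == 0
        assert {c for c, _ in out["excluded"]} == {"a", "b", "c"}
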