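"""Ensemble MSD, bootstrap bands, diffusion-coefficient fitting."""

import numpy as np
import pytest

from dxtrack import MSDCurve, SimulationParams, ensemble_msd, \
    fit_diffusion_coefficient, make_lag_grid, msd_confidence_band, \
    simulate_trajectories

from conftest import brownian_ensemble, linear_traj, make_traj

LAGS10 = make_lag_grid(0.1, 10)


def naive_msd(trajs, axis, lags):
    """Double-loop recomputation, independent of the vectorized path."""
    out_lags, out_msd, out_n = [], [], []
    for lag in lags:
        vals = []
        for tr in trajs:
            d = tr.displacement_from_start(axis, lag)
            if d is not None:
                vals.append(d**2)
        if vals:
            out_lags.append(lag)
            out_msd.append(sum(vals) / len(vals))
            out_n.append(len(vals))
    return np.array(out_lags), np.array(out_msd), np.array(out_n)


class TestEnsembleMSD:
    def test_deterministic_linear_motion(self):
        # chi = v t with v = 2 mrad/s: squared displacement is 4 t^2
        curve = ensemble_msd([linear_traj(2.0, n=11)], "chi", LAGS10)
        assert np.allclose(curve.msd, 4.0 * curve.lags**2)

    def test_constant_trajectories_zero_msd(self):
        trajs = [make_traj(np.full(11, c), tid=f"c{c}") for c in (0.0, 5.0)]
        curve = ensemble_msd(trajs, "chi", LAGS10)
        assert np.all(curve.msd == 0.0)

    def test_brownian_matches_expectation(self):
        # per-axis MSD of free diffusion is 2 d t; check the first 10 lags
        d = 1.0
        trajs = brownian_ensemble(2000, 101, d=d, seed=1234)
        curve = ensemble_msd(trajs, "chi", LAGS10)
        expected = 2 * d * curve.lags
        se = expected * np.sqrt(2.0 / curve.n_pairs)
        assert np.all(np.abs(curve.msd - expected) < 1.96 * se * 1.5)

    def test_censoring_shrinks_n_pairs(self):
        trajs = [make_traj(np.zeros(3), tid="short"),
                 make_traj(np.zeros(11), tid="long")]
        curve = ensemble_msd(trajs, "chi", LAGS10)
        assert list(curve.n_pairs[:2]) == [2, 2]
        assert np.all(curve.n_pairs[2:] == 1)
        assert np.all(np.diff(curve.n_pairs) <= 0)

    def test_lags_nobody_reaches_are_dropped(self):
        trajs = [make_traj(np.zeros(4))]
        curve = ensemble_msd(trajs, "chi", LAGS10)
        assert len(curve.lags) == 3

    def test_error_when_first_lag_unreachable(self):
        with pytest.raises(ValueError, match="first lag"):
            ensemble_msd([make_traj([0.0])], "chi", LAGS10)

    def test_equals_naive_double_loop(self):
        rng = np.random.default_rng(1234)
        trajs = [
            make_traj(np.cumsum(rng.normal(0, 1, size=n)), tid=f"t{i}")
            for i, n in enumerate([3, 4, 5, 6, 6])
        ]
        lags = make_lag_grid(0.1, 5)
        curve = ensemble_msd(trajs, "chi", lags)
        ref_lags, ref_msd, ref_n = naive_msd(trajs, "chi", lags)
        assert np.allclose(curve.lags, ref_lags, rtol=1e-12)
        assert np.allclose(curve.msd, ref_msd, rtol=1e-12)
        assert np.array_equal(curve.n_pairs, ref_n)

    def test_scaling_property(self):
        rng = np.random.default_rng(1234)
        chi = np.cumsum(rng.normal(0, 1, size=20))
        k = 3.7
        c1 = ensemble_msd([make_traj(chi)], "chi", LAGS10)
        c2 = ensemble_msd([make_traj(k * chi)], "chi", LAGS10)
        assert np.allclose(c2.msd, k**2 * c1.msd, rtol=1e-12)


class TestConfidenceBand:
    def test_identical_trajectories_zero_width(self):
        trajs = [make_traj(np.arange(11.0), tid=f"t{i}") for i in range(100)]
        lo, hi = msd_confidence_band(trajs, "chi", LAGS10, n_boot=200, seed=1)
        assert np.allclose(lo, hi)

    def test_seed_reproducibility(self):
        trajs = brownian_ensemble(50, 11, seed=1234)
        b1 = msd_confidence_band(trajs, "chi", LAGS10, n_boot=200, seed=7)
        b2 = msd_confidence_band(trajs, "chi", LAGS10, n_boot=200, seed=7)
        assert np.array_equal(b1[0], b2[0]) and np.array_equal(b1[1], b2[1])

    def test_needs_enough_trajectories_and_resamples(self):
        trajs = brownian_ensemble(5, 11, seed=0)
        with pytest.raises(ValueError):
            msd_confidence_band(trajs[:1], "chi", LAGS10)
        with pytest.raises(ValueError):
            msd_confidence_band(trajs, "chi", LAGS10, n_boot=50)

    def test_coverage_at_first_lag(self):
        # over replicates, the true value 2 d t should fall inside the 95%
        # band about 95% of the time (percentile bootstrap, n = 100)
        d, dt = 1.0, 0.1
        lags = np.array([dt])
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            trajs = brownian_ensemble(100, 2, d=d, dt=dt, seed=10_000 + rep)
            lo, hi = msd_confidence_band(trajs, "chi", lags, n_boot=500,
                                         seed=rep)
            hits += lo[0] <= 2 * d * dt <= hi[0]
        assert hits / n_rep == pytest.approx(0.95, abs=0.04)


class TestDiffusionFit:
    def test_exact_line(self):
        lags = make_lag_grid(0.1, 5)
        curve = MSDCurve(axis="chi", lags=lags, msd=4 * 0.5 * lags + 0.1,
                         n_pairs=np.full(5, 10))
        fit = fit_diffusion_coefficient(curve)
        assert fit.D == pytest.approx(0.5, rel=1e-12)
        assert fit.A == pytest.approx(0.1, rel=1e-12)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_flat_curve(self):
        lags = make_lag_grid(0.1, 5)
        curve = MSDCurve(axis="chi", lags=lags, msd=np.full(5, 2.5),
                         n_pairs=np.full(5, 10))
        fit = fit_diffusion_coefficient(curve)
        assert fit.D == pytest.approx(0.0, abs=1e-12)
        assert fit.A == pytest.approx(2.5, rel=1e-12)

    def test_normal_equations_reproduced(self):
        rng = np.random.default_rng(1234)
        lags = make_lag_grid(0.1, 8)
        msd = 2.0 * lags + rng.normal(0, 0.05, size=8)
        curve = MSDCurve(axis="chi", lags=lags, msd=msd,
                         n_pairs=np.full(8, 10))
        fit = fit_diffusion_coefficient(curve, fit_lags=lags)
        t, y = lags, msd
        slope = (np.mean(t * y) - t.mean() * y.mean()) / np.var(t)
        intercept = y.mean() - slope * t.mean()
        assert 4 * fit.D == pytest.approx(slope, rel=1e-10)
        assert fit.A == pytest.approx(intercept, rel=1e-10)

    def test_too_few_lags_rejected(self):
        curve = MSDCurve(axis="chi", lags=np.array([0.1]),
                         msd=np.array([0.2]), n_pairs=np.array([5]))
        with pytest.raises(ValueError, match="2 usable lags"):
            fit_diffusion_coefficient(curve, fit_lags=np.array([0.1]))

    @pytest.mark.parametrize("d", [0.1, 1.0, 10.0])
    def test_parameter_recovery_median_within_5pct(self, d):
        # the 4Dt convention on per-axis data implies slope = 2 d, D = d/2
        errs = []
        for rep in range(20):
            params = SimulationParams(
                n_traj=1000, max_frames=500, d_chi=d, d_theta=d,
                seed=50_000 + rep,
            )
            trajs, _ = simulate_trajectories(params)
            for axis in ("chi", "theta"):
                curve = ensemble_msd(trajs, axis, make_lag_grid(0.1, 5))
                fit = fit_diffusion_coefficient(curve)
                errs.append(abs(fit.D * 4 / 2 - d) / d)
        assert np.median(errs) <= 0.05
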