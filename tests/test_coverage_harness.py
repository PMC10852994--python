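import numpy as np
import pytest

from conjcr import (
    ConditionModel,
    GridSpec,
    NoiseSpec,
    ScalarField,
    SimulationConfig,
    binomial_ci,
    check_inclusion,
    conjunction_inference,
    naive_intersection_crs,
    ring_conjunction_signals,
    run_simulation,
    simulation_signals,
)
from conjcr.coverage_harness import _intercept_models
from conjcr.confidence_regions import construct_crs
from conjcr.excursion_geometry import extract_zero_boundary


class TestBinomialCi:
    def test_clipped_at_one(self):
        lo, hi = binomial_ci(100, 100)
        assert hi == 1.0
        lo99, hi99 = binomial_ci(99, 100)
        assert hi99 == 1.0  # clipped
        assert lo99 < 0.99

    def test_half_width_closed_form(self):
        lo, hi = binomial_ci(2375, 2500)  # p-hat = 0.95
        half = 1.959963984540054 * np.sqrt(0.95 * 0.05 / 2500)
        assert (hi - lo) / 2 == pytest.approx(half, rel=1e-6)
        assert half == pytest.approx(0.008544, abs=2e-5)

    def test_symmetry_about_half(self):
        lo1, hi1 = binomial_ci(30, 100)
        lo2, hi2 = binomial_ci(70, 100)
        assert lo1 == pytest.approx(1 - hi2)
        assert hi1 == pytest.approx(1 - lo2)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(0, 0)


class TestSimulationSignals:
    @pytest.mark.parametrize("sim", [1, 2, 3])
    @pytest.mark.parametrize("snr,c", [("high", 2.0), ("low", 0.5)])
    def test_nonempty_true_sets(self, sim, snr, c):
        signals, threshold, rho = simulation_signals(sim, snr, {1: 20.0, 2: 0.0, 3: 1.0}[sim])
        assert threshold == c
        margin = np.minimum(signals[0].values, signals[1].values) - threshold
        assert (margin >= 0).sum() > 0
        assert len(extract_zero_boundary(margin)) > 0

    def test_sim2_sweeps_correlation(self):
        _, _, rho = simulation_signals(2, "high", -0.4)
        assert rho == -0.4

    def test_sim3_gradient_divisor_moves_boundary(self):
        fast, _, _ = simulation_signals(3, "high", 0.5)
        slow, _, _ = simulation_signals(3, "high", 1.5)
        # boundary column is at 50 * k for the horizontal ramp
        row = fast[0].values[0]
        assert np.argmax(row >= 2.0) == pytest.approx(25, abs=1)
        assert np.argmax(slow[0].values[0] >= 2.0) == pytest.approx(75, abs=1)

    def test_low_snr_is_quarter_signal(self):
        hi, _, _ = simulation_signals(1, "high", 20.0)
        lo, _, _ = simulation_signals(1, "low", 20.0)
        np.testing.assert_allclose(lo[0].values, hi[0].values / 4.0, atol=1e-12)


class FakeFit:
    """Minimal stand-in exposing the estimate and SE maps used by the check."""

    def __init__(self, mu, se):
        self.mu_hat = ScalarField(mu)
        self.se = ScalarField(se)


class TestCheckInclusion:
    def test_zero_noise_true_for_positive_a(self, circle_signals):
        # mu-hat equals the true signal exactly: the interpolated statistic
        # vanishes on the true boundary and any a > 0 passes
        se = np.full(circle_signals[0].shape, 0.1)
        fits = [FakeFit(s.values, se) for s in circle_signals]
        stat = np.minimum.reduce([(s.values - 2.0) / se for s in circle_signals])
        crs = construct_crs(ScalarField(stat * 0.1), 0.1, a=1.0)
        assert check_inclusion(circle_signals, 2.0, crs, fits) is True

    def test_a_zero_with_noise_fails(self, circle_signals, rng):
        se = np.full(circle_signals[0].shape, 0.1)
        fits = [FakeFit(s.values + 0.1 * rng.standard_normal(s.shape), se) for s in circle_signals]
        stat = np.minimum.reduce([(f.mu_hat.values - 2.0) / se for f in fits])
        crs = construct_crs(ScalarField(stat * 0.1), 0.1, a=0.0)
        assert check_inclusion(circle_signals, 2.0, crs, fits, a=0.0) is False

    def test_empty_true_set_rejected(self, circle_signals):
        se = np.full(circle_signals[0].shape, 0.1)
        fits = [FakeFit(s.values, se) for s in circle_signals]
        crs = construct_crs(ScalarField(np.zeros(circle_signals[0].shape)), 0.1, a=1.0)
        with pytest.raises(ValueError):
            check_inclusion(circle_signals, 99.0, crs, fits)

    def test_agreement_with_supersampled_oracle(self):
        # oracle: bilinear-upsample every field to a 10x refined lattice and
        # rerun the same inclusion check there; the coarse edge crossings are
        # an exact subset of the refined ones, so the refined verdict is a
        # strictly denser evaluation of the same continuum event
        grid = GridSpec((50, 50))
        signals = ring_conjunction_signals(grid, threshold=1.0, r_inner=12.0, r_outer=20.0, slope=0.15)
        scale = 10
        from scipy.ndimage import map_coordinates

        shape_fine = (50 * scale - scale + 1,) * 2
        rr, cc = np.mgrid[0 : shape_fine[0], 0 : shape_fine[1]].astype(np.float64) / scale

        def upsample(values):
            return map_coordinates(values, [rr.ravel(), cc.ravel()], order=1).reshape(shape_fine)

        fine_signals = [ScalarField(upsample(s.values)) for s in signals]

        n = 50
        agreements = 0
        for i in range(50):
            rng = np.random.default_rng(800 + i)
            models = _intercept_models(signals, 1.0, n, NoiseSpec(fwhm=3.0), rng)
            res = conjunction_inference(models, 1.0, alpha=0.05, n_boot=300, seed=rng)
            got = check_inclusion(signals, 1.0, res.regions, res.fits)
            fine_fits = [FakeFit(upsample(f.mu_hat.values), upsample(f.se.values)) for f in res.fits]
            stat_fine = np.minimum.reduce(
                [(f.mu_hat.values - 1.0) / f.se.values for f in fine_fits]
            )
            fine_regions = construct_crs(
                ScalarField(stat_fine * res.fits[0].tau_n), res.fits[0].tau_n, a=res.regions.a
            )
            oracle = check_inclusion(fine_signals, 1.0, fine_regions, fine_fits)
            agreements += got == oracle
        assert agreements == 50


class TestRunSimulation:
    def test_single_instance_reproducible(self):
        cfg = SimulationConfig(simulation=1, snr="high", n=(60,), sweep=(20.0,), instances=2,
                               n_boot=100, seed=5, grid=GridSpec((60, 60)))
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert a.table.equals(b.table)

    def test_zero_noise_limit_full_coverage(self):
        cfg = SimulationConfig(simulation=1, snr="high", n=(20,), sweep=(20.0,), instances=5,
                               n_boot=100, seed=2, noise_scale=1e-6, grid=GridSpec((60, 60)))
        res = run_simulation(cfg)
        assert res.table["coverage"].iloc[0] == 1.0

    def test_outcome_categories_sum(self):
        cfg = SimulationConfig(simulation=1, snr="high", n=(40,), sweep=(20.0,), instances=4,
                               n_boot=100, seed=8, grid=GridSpec((60, 60)))
        tab = run_simulation(cfg).table
        row = tab.iloc[0]
        assert row["successes"] + row["violations"] + row["empty"] == row["instances"]
        assert row["ci_lo"] <= row["coverage"] <= row["ci_hi"]

    def test_parallel_matches_serial(self):
        cfg = SimulationConfig(simulation=1, snr="high", n=(40,), sweep=(20.0,), instances=4,
                               n_boot=80, seed=21, grid=GridSpec((60, 60)))
        serial = run_simulation(cfg, n_jobs=1)
        parallel = run_simulation(cfg, n_jobs=2)
        assert serial.table.equals(parallel.table)


class TestNaiveIntersection:
    def test_single_condition_identity(self, toy_models):
        res = conjunction_inference([toy_models[0]], 2.0, n_boot=100, seed=4)
        naive = naive_intersection_crs([res.regions])
        assert naive.upper == res.regions.upper
        assert naive.point_estimate == res.regions.point_estimate
        assert naive.lower == res.regions.lower

    def test_intersected_point_estimate_matches_joint(self, toy_models):
        joint = conjunction_inference(toy_models, 2.0, n_boot=100, seed=6)
        singles = [conjunction_inference([m], 2.0, n_boot=100, seed=6) for m in toy_models]
        naive = naive_intersection_crs([s.regions for s in singles])
        assert naive.point_estimate == joint.regions.point_estimate

    def test_naive_crs_differ_from_joint(self, toy_models):
        # the CR masks themselves must NOT agree with naive intersections
        joint = conjunction_inference(toy_models, 2.0, n_boot=400, seed=6)
        singles = [conjunction_inference([m], 2.0, n_boot=400, seed=6) for m in toy_models]
        naive = naive_intersection_crs([s.regions for s in singles])
        assert not (naive.upper == joint.regions.upper and naive.lower == joint.regions.lower)

    def test_grid_mismatch_rejected(self, toy_models, rng):
        res = conjunction_inference([toy_models[0]], 2.0, n_boot=50, seed=1)
        other = ConditionModel(rng.standard_normal((10, 20, 20)), np.ones((10, 1)), np.ones(1))
        res2 = conjunction_inference([other], 0.0, n_boot=50, seed=1)
        with pytest.raises(ValueError):
            naive_intersection_crs([res.regions, res2.regions])


class TestCoverageMonotonicity:
    def test_shrinking_a_never_helps(self, circle_signals):
        rng = np.random.default_rng(0)
        models = _intercept_models(circle_signals, 2.0, 60, NoiseSpec(fwhm=3.0), rng)
        res = conjunction_inference(models, 2.0, alpha=0.05, n_boot=200, seed=rng)
        tau = res.fits[0].tau_n
        outcomes = []
        for a in (res.regions.a, res.regions.a / 2, 0.0):
            crs = construct_crs(ScalarField(res.statistic.values * tau), tau, a=a)
            outcomes.append(check_inclusion(circle_signals, 2.0, crs, res.fits, a=a))
        # once it fails for some a, it fails for every smaller a
        for earlier, later in zip(outcomes, outcomes[1:]):
            assert later <= earlier
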