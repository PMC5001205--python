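"""Tests for the local-regression / subsample / nonlinear-least-squares cascade."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from gevm.fitting import (
    FitError,
    LocalFitCurve,
    SubsampledPoints,
    cv_difference,
    determine_support,
    estimate_models,
    fit_gevm,
    fit_noise_model,
    robust_local_fit,
    subsample_curve,
)
from gevm.model_core import GEVMParams, model_log10cv
from gevm.preprocessing import GeneStats


def stats_from_xy(x, y):
    """Build GeneStats whose (log10 mean, log10 CV) cloud is exactly (x, y)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    mean = 10.0**x
    cv = 10.0**y
    return GeneStats(
        gene_ids=np.array([f"g{i}" for i in range(len(x))], dtype=object),
        mean=mean,
        sd=cv * mean,
        cv=cv,
        n_expressed=np.full(len(x), 10),
    )


@pytest.fixture
def line_stats():
    x = np.linspace(-2.0, 1.0, 600)
    return stats_from_xy(x, -0.5 * x), x


class TestRobustLocalFit:
    def test_noiseless_line_recovery(self, line_stats):
        stats, x = line_stats
        curve = robust_local_fit(stats)
        assert np.max(np.abs(curve.fitted - (-0.5 * curve.grid))) < 1e-3

    def test_outlier_resistance_vs_plain_fit(self, line_stats):
        """5 % of points offset by +1: the robust curve barely moves, a
        non-robust fit (zero reweighting passes) moves visibly more."""
        stats, x = line_stats
        y = -0.5 * x
        rng = np.random.default_rng(0)
        bad = rng.choice(len(x), size=len(x) // 20, replace=False)
        y = y.copy()
        y[bad] += 1.0
        contaminated = stats_from_xy(x, y)
        robust = robust_local_fit(contaminated, robust_iters=4)
        plain = robust_local_fit(contaminated, robust_iters=0)
        core = slice(len(robust.grid) // 10, -len(robust.grid) // 10)
        err_robust = np.max(np.abs(robust.fitted[core] - (-0.5 * robust.grid[core])))
        err_plain = np.max(np.abs(plain.fitted[core] - (-0.5 * plain.grid[core])))
        assert err_robust < 0.02
        assert err_plain > err_robust

    def test_matches_statsmodels_lowess(self):
        """Independent cross-check against statsmodels' robust lowess."""
        from statsmodels.nonparametric.smoothers_lowess import lowess

        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(-2, 1, 2000))
        y = -0.5 * x + rng.normal(0, 0.05, len(x))
        curve = robust_local_fit(stats_from_xy(x, y), span=0.3, robust_iters=4)
        ref = lowess(y, x, frac=0.3, it=4, return_sorted=True)
        ref_on_grid = np.interp(curve.grid, ref[:, 0], ref[:, 1])
        core = slice(len(curve.grid) // 10, -len(curve.grid) // 10)
        assert np.max(np.abs(curve.fitted[core] - ref_on_grid[core])) < 0.03

    def test_degenerate_input_errors(self):
        stats = stats_from_xy(np.zeros(100), np.zeros(100))
        with pytest.raises(FitError):
            robust_local_fit(stats)

    def test_too_few_genes_errors(self):
        stats = stats_from_xy(np.linspace(0, 1, 10), np.zeros(10))
        with pytest.raises(FitError):
            robust_local_fit(stats)


class TestDetermineSupport:
    def test_uniform_cloud_starts_at_first_grid_point(self, line_stats):
        stats, _ = line_stats
        curve = robust_local_fit(stats)
        start, term = determine_support(stats, curve)
        assert start == curve.grid[0]
        assert term == curve.grid[-1]  # monotone decreasing curve

    def test_straggler_region_excluded_matches_oracle(self):
        rng = np.random.default_rng(2)
        dense = np.sort(rng.uniform(0.0, 1.0, 2000))
        stragglers = np.array([-2.0, -1.99, -1.98])
        x = np.concatenate([stragglers, dense])
        stats = stats_from_xy(x, -0.5 * x)
        curve = robust_local_fit(stats)
        start, _ = determine_support(stats, curve, density_fraction=0.005, window=0.05)
        assert start > -1.0  # straggler region skipped
        # brute-force neighbourhood-count oracle over the same grid
        n = len(x)
        for g in curve.grid:
            cnt = np.sum(np.abs(x - g) <= 0.05)
            if cnt > 0.005 * n:
                assert start == pytest.approx(g)
                break

    def test_no_dense_region_errors(self):
        x = np.linspace(-3, 3, 60)  # 60 genes spread over 6 decades
        stats = stats_from_xy(x, -0.5 * x)
        curve = robust_local_fit(stats)
        with pytest.raises(FitError):
            determine_support(stats, curve, density_fraction=0.5, window=0.01)


class TestSubsampleCurve:
    def _curve(self, lo, hi, fn):
        grid = np.linspace(lo, hi, 501)
        return LocalFitCurve(grid=grid, fitted=fn(grid), start_pos=lo, terminal_pos=hi)

    def test_point_counts_inclusive(self):
        assert len(subsample_curve(self._curve(0.0, 0.05, lambda g: -g / 2))) == 6
        assert len(subsample_curve(self._curve(-1.0, 1.0, lambda g: -g / 2))) == 201

    def test_linear_interpolation_exact(self):
        pts = subsample_curve(self._curve(-1.0, 1.0, lambda g: -0.5 * g + 0.3))
        assert np.max(np.abs(pts.y - (-0.5 * pts.x + 0.3))) < 1e-9
        assert np.allclose(np.diff(pts.x), 0.01, atol=1e-9)

    def test_short_support_errors(self):
        with pytest.raises(FitError):
            subsample_curve(self._curve(0.0, 0.005, lambda g: -g / 2))

    def test_missing_support_errors(self):
        curve = LocalFitCurve(grid=np.linspace(0, 1, 11), fitted=np.zeros(11))
        with pytest.raises(FitError):
            subsample_curve(curve)


def exact_points(alpha, beta, lo=-1.0, hi=1.0):
    x = lo + 0.01 * np.arange(int(round((hi - lo) / 0.01)) + 1)
    return SubsampledPoints(x=x, y=model_log10cv(10.0**x, GEVMParams(alpha, beta)))


class TestFitGEVM:
    @pytest.mark.parametrize("alpha, beta", [(0.15, 1.2), (0.5, 1.5), (0.02, 1.05)])
    def test_exact_recovery(self, alpha, beta):
        fit = fit_gevm(exact_points(alpha, beta))
        assert fit.params.alpha == pytest.approx(alpha, abs=1e-6)
        assert fit.params.beta == pytest.approx(beta, abs=1e-6)
        assert fit.converged

    def test_poisson_line(self):
        fit = fit_gevm(exact_points(0.0, 1.0))
        assert fit.params.alpha < 1e-4
        assert fit.params.beta == pytest.approx(1.0, abs=1e-3)

    def test_underdetermined_errors(self):
        with pytest.raises(FitError):
            fit_gevm(SubsampledPoints(x=np.array([0.0, 0.1]), y=np.array([0.0, -0.05])))

    def test_scale_equivariance(self):
        """Scaling expression by c shifts the cloud by log10 c: beta scales by c,
        alpha is unchanged."""
        base = exact_points(0.2, 1.3)
        c = 7.0
        shifted = SubsampledPoints(x=base.x + np.log10(c), y=base.y)
        fit = fit_gevm(shifted)
        assert fit.params.alpha == pytest.approx(0.2, abs=1e-5)
        assert fit.params.beta == pytest.approx(c * 1.3, rel=1e-5)


class TestFitNoiseModel:
    def test_poisson_line_recovery(self):
        nm = fit_noise_model(exact_points(0.0, 1.0))
        assert nm.gamma == pytest.approx(-0.5, abs=1e-4)
        assert nm.delta == pytest.approx(0.0, abs=1e-4)

    def test_mismatch_on_overdispersed_curve(self):
        """On a curved variation-model locus, the noise model fits worse."""
        pts = exact_points(0.5, 1.5)
        nm = fit_noise_model(pts)
        gevm = fit_gevm(pts)
        from gevm.model_core import noise_model_log10cv

        mu = 10.0**pts.x
        rmse_noise = np.sqrt(np.mean((pts.y - noise_model_log10cv(mu, nm)) ** 2))
        rmse_gevm = np.sqrt(np.mean((pts.y - model_log10cv(mu, gevm.params)) ** 2))
        assert rmse_noise > rmse_gevm
        assert rmse_gevm < 1e-8

    def test_underdetermined_errors(self):
        with pytest.raises(FitError):
            fit_noise_model(SubsampledPoints(x=np.array([0.0, 0.1]), y=np.array([0.0, -0.05])))


class TestCVDifference:
    def test_points_on_curve_get_zero(self):
        params = GEVMParams(0.15, 1.2)
        x = np.linspace(-1, 1, 40)
        stats = stats_from_xy(x, model_log10cv(10.0**x, params))
        D = cv_difference(stats, params, support=(-1.0, 1.0))
        assert np.max(np.abs(D)) < 1e-6

    def test_poisson_line_analytic_distance(self):
        """Vertical offset +0.3 from the slope -1/2 line: D = 0.3*cos(atan(1/2))."""
        params = GEVMParams(0.0, 1.0)
        x = np.array([0.0, 0.5, -0.5])
        stats = stats_from_xy(x, -0.5 * x + 0.3)
        D = cv_difference(stats, params)
        assert np.allclose(D, 0.3 * math.cos(math.atan(0.5)), atol=1e-10)

    def test_sign_convention(self):
        params = GEVMParams(0.15, 1.2)
        x = np.array([0.0, 0.0])
        y = model_log10cv(10.0**x, params) + np.array([0.2, -0.2])
        D = cv_difference(stats_from_xy(x, y), params, support=(-1.0, 1.0))
        assert D[0] > 0 > D[1]

    def test_matches_brute_force_oracle(self):
        """|D| equals an independent 1-D minimization over the curve to 1e-4."""
        params = GEVMParams(0.15, 1.2)
        rng = np.random.default_rng(3)
        x = rng.uniform(-1, 1, 100)
        y = model_log10cv(10.0**x, params) + rng.uniform(-0.5, 0.5, 100)
        stats = stats_from_xy(x, y)
        D = cv_difference(stats, params, support=(-1.0, 1.0))

        for xi, yi, di in zip(x, y, D):
            res = minimize_scalar(
                lambda t: (xi - t) ** 2
                + (yi - model_log10cv(10.0**t, params)) ** 2,
                bounds=(-2.0, 2.0),
                method="bounded",
                options={"xatol": 1e-10},
            )
            assert abs(abs(di) - math.sqrt(res.fun)) < 1e-4

    def test_vertical_variant(self):
        params = GEVMParams(0.15, 1.2)
        x = np.array([0.3])
        y = model_log10cv(10.0**x, params) + 0.25
        D = cv_difference(stats_from_xy(x, y), params, method="vertical")
        assert D[0] == pytest.approx(0.25, abs=1e-12)


class TestEndToEnd:
    def test_recovery_on_simulated_data(self, small_homogeneous_stats):
        est = estimate_models(small_homogeneous_stats)
        assert est.gevm.params.alpha == pytest.approx(0.15, abs=0.02)
        assert est.gevm.params.beta == pytest.approx(1.2, abs=0.05)

    def test_curve_tracks_model_on_simulation(self, small_homogeneous, small_homogeneous_stats):
        curve = robust_local_fit(small_homogeneous_stats)
        determine_support(small_homogeneous_stats, curve)
        sel = (curve.grid >= curve.start_pos) & (curve.grid <= curve.terminal_pos)
        gap = np.abs(
            curve.fitted[sel]
            - model_log10cv(10.0 ** curve.grid[sel], small_homogeneous.config.params)
        )
        lo = int(0.1 * gap.size)
        assert np.max(gap[lo : gap.size - lo]) < 0.05
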