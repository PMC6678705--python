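"""Modified ALSS baseline estimation: oracle equivalence and exact limits."""

import numpy as np
import pytest

from seiraquant import (
    BaselineConfig,
    ConfigurationError,
    Spectrum,
    WavenumberPanel,
    alss_baseline,
    baseline_sensitivity,
    correct_spectrum,
    divide_baseline,
)
from seiraquant.baseline import exclusion_mask
from seiraquant.synthetic import SimTruth, simulate_spectrum

GRID = 900.0 + np.arange(301.0)


def dense_alss_oracle(nu, y, config):
    """Independent dense-matrix implementation of the same weighted penalized
    least-squares iteration: builds D2 explicitly and solves with a dense
    factorization at every weight iteration."""
    n = y.size
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i], D[i, i + 1], D[i, i + 2] = 1.0, -2.0, 1.0
    P = config.lam * (D.T @ D)
    excl = np.zeros(n, dtype=bool)
    for lo, hi in config.exclusion_windows:
        excl |= (nu >= lo) & (nu <= hi)
    w = np.where(excl, 0.0, 1.0)
    z = np.linalg.solve(np.diag(w) + P, w * y)
    tau = 1e-8 * max(1.0, float(np.max(np.abs(y))))
    for _ in range(config.max_iter):
        w_new = np.where(excl, 0.0, np.where(y - z > tau, config.p, 1.0 - config.p))
        if np.array_equal(w_new, w):
            break
        w = w_new
        z = np.linalg.solve(np.diag(w) + P, w * y)
    return z


class TestAlssOracle:
    @pytest.mark.parametrize("seed,n,lam,p", [
        (0, 120, 500.0, 0.99),
        (1, 200, 50.0, 0.9),
        (2, 150, 5000.0, 0.5),
        (3, 80, 500.0, 0.01),
    ])
    def test_banded_solver_matches_dense_solve(self, seed, n, lam, p):
        rng = np.random.default_rng(seed)
        nu = 900.0 + np.arange(float(n)) * (300.0 / n)
        y = 0.5 + 0.4 * np.exp(-0.5 * ((nu - 1050) / 90) ** 2) + 0.01 * rng.standard_normal(n)
        cfg = BaselineConfig(lam=lam, p=p, exclusion_windows=((1000.0, 1100.0),))
        z = alss_baseline(Spectrum(nu, y), cfg).baseline.values
        z_oracle = dense_alss_oracle(nu, y, cfg)
        assert np.allclose(z, z_oracle, rtol=1e-8, atol=1e-12)

    def test_lorentzian_hump_with_excluded_bump_recovers_hump(self):
        """A narrow additive bump centred at 1050 cm-1 inside the exclusion
        window must not drag the baseline away from the broad hump."""
        hump = 0.8 * 120.0 ** 2 / ((GRID - 1060.0) ** 2 + 120.0 ** 2)
        bump = 0.05 * np.exp(-0.5 * ((GRID - 1050.0) / 3.0) ** 2)
        cfg = BaselineConfig()
        z = alss_baseline(Spectrum(GRID, hump + bump), cfg).baseline.values
        window = (GRID >= 1000) & (GRID <= 1100)
        assert np.max(np.abs(z - hump)[window]) < 0.05  # ~6% of the 0.8 hump peak
        assert np.allclose(z, dense_alss_oracle(GRID, hump + bump, cfg), rtol=1e-8)


class TestAlssExactLimits:
    def test_constant_spectrum_gives_constant_baseline(self):
        sp = Spectrum(GRID, np.ones_like(GRID))
        res = alss_baseline(sp, BaselineConfig())
        assert np.allclose(res.baseline.values, 1.0, atol=1e-10)
        assert res.converged

    def test_straight_line_is_reproduced(self):
        y = 0.2 + 1e-3 * GRID
        z = alss_baseline(Spectrum(GRID, y), BaselineConfig(exclusion_windows=())).baseline.values
        assert np.allclose(z, y, atol=1e-9)

    def test_huge_lambda_tends_to_straight_line(self):
        rng = np.random.default_rng(5)
        y = 0.5 + 1e-3 * (GRID - 900) + 0.01 * rng.standard_normal(GRID.size)
        z = alss_baseline(
            Spectrum(GRID, y), BaselineConfig(lam=1e12, exclusion_windows=())
        ).baseline.values
        A = np.column_stack([np.ones_like(GRID), GRID])
        coef, *_ = np.linalg.lstsq(A, z, rcond=None)
        assert np.max(np.abs(z - A @ coef)) < 1e-6

    def test_excluded_points_have_zero_influence(self):
        rng = np.random.default_rng(6)
        y = 0.5 + 0.3 * np.exp(-0.5 * ((GRID - 1050) / 100) ** 2)
        cfg = BaselineConfig()
        z0 = alss_baseline(Spectrum(GRID, y), cfg).baseline.values
        y_pert = y.copy()
        inside = (GRID >= 1000) & (GRID <= 1100)
        y_pert[inside] += 0.2 * rng.random(inside.sum())
        z1 = alss_baseline(Spectrum(GRID, y_pert), cfg).baseline.values
        assert np.array_equal(z0, z1) or np.max(np.abs(z0 - z1)) < 1e-14

    def test_all_points_excluded_is_configuration_error(self):
        cfg = BaselineConfig(exclusion_windows=((0.0, 5000.0),))
        with pytest.raises(ConfigurationError, match="excluded"):
            alss_baseline(Spectrum(GRID, np.ones_like(GRID)), cfg)

    def test_non_overlapping_window_is_ignored_with_warning(self, caplog):
        cfg = BaselineConfig(exclusion_windows=((2000.0, 2100.0),))
        with caplog.at_level("WARNING", logger="seiraquant.baseline"):
            mask = exclusion_mask(GRID, cfg)
        assert not mask.any()
        assert any("does not overlap" in r.message for r in caplog.records)


class TestDivision:
    def test_measured_equals_baseline_gives_unity(self):
        sp = Spectrum(GRID, 0.7 * np.ones_like(GRID))
        bl = Spectrum(GRID, 0.7 * np.ones_like(GRID), kind="baseline")
        corr = divide_baseline(sp, bl)
        assert np.allclose(corr.rbc, 1.0)

    def test_known_multiplicative_feature_is_recovered(self):
        g = 0.05 * np.exp(-0.5 * ((GRID - 1034) / 4) ** 2)
        bl_vals = 0.6 + 1e-4 * (GRID - 900)
        sp = Spectrum(GRID, bl_vals * (1 + g))
        corr = divide_baseline(sp, Spectrum(GRID, bl_vals, kind="baseline"))
        assert np.allclose(corr.rbc, 1 + g, rtol=0, atol=1e-14)

    def test_nonpositive_baseline_names_wavenumber(self):
        bl = np.ones_like(GRID)
        bl[GRID == 1034.0] = -1.0
        sp = Spectrum(GRID, np.ones_like(GRID))
        with pytest.raises(ValueError, match="1034"):
            divide_baseline(sp, Spectrum(GRID, bl))  # raw kind dodges the >0 invariant

    def test_simulated_glucose_spectrum_peaks_near_panel_lines(self):
        truth = SimTruth(noise_sigma=0.0)
        sp = simulate_spectrum((50.0, 0.0), truth, GRID)
        corr = correct_spectrum(sp, BaselineConfig())
        delta = corr.rbc - 1.0
        for nu_line in (1034.0, 1078.0):
            sel = np.abs(GRID - nu_line) <= 2.0
            # peak rises well above the local background beside the line
            bg = np.median(delta[(np.abs(GRID - nu_line) >= 8) &
                                 (np.abs(GRID - nu_line) <= 12)])
            assert delta[sel].max() - bg > 0.01
            # local maximum sits within +-2 grid steps of the nominal line
            near = np.abs(GRID - nu_line) <= 6.0
            local = GRID[near][np.argmax(delta[near])]
            assert abs(local - nu_line) <= 2.0


class TestSensitivity:
    def test_peak_positions_stable_amplitudes_vary_across_lambda(self):
        truth = SimTruth(noise_sigma=0.0)
        sp = simulate_spectrum((50.0, 0.0), truth, GRID)
        panel = WavenumberPanel()
        table = baseline_sensitivity(sp, [50.0, 500.0, 5000.0, 50000.0],
                                     BaselineConfig(), panel)
        assert len(table) == 4
        for nu in panel.nus:
            assert table[f"argmax_{nu:g}"].nunique() == 1
        amp_spread = table["delta_s_1034"].max() - table["delta_s_1034"].min()
        assert amp_spread > 0

    def test_single_lambda_row_matches_direct_pipeline(self):
        truth = SimTruth(noise_sigma=0.0)
        sp = simulate_spectrum((25.0, 0.0), truth, GRID)
        panel = WavenumberPanel()
        cfg = BaselineConfig()
        table = baseline_sensitivity(sp, [cfg.lam], cfg, panel)
        from seiraquant import extract_peaks

        direct = extract_peaks(correct_spectrum(sp, cfg), panel)
        assert np.allclose(table.iloc[0][[f"delta_s_{nu:g}" for nu in panel.nus]].to_numpy(float),
                           direct.delta_s)

    def test_empty_lambda_grid_is_error(self):
        sp = Spectrum(GRID, np.ones_like(GRID))
        with pytest.raises(ConfigurationError, match="empty"):
            baseline_sensitivity(sp, [], BaselineConfig(), WavenumberPanel())
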