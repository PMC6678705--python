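"""Clipped nonlinear least-squares inversion and error metrics."""

import numpy as np
import pytest

from seiraquant import (
    BasisModel,
    SolverConfig,
    WaterConstants,
    WavenumberPanel,
    estimate_concentrations,
    evaluate_cycle,
    order_sweep,
    summarize_errors,
)


def make_model(phi, psi, k=(0.01, 0.012, 0.009), c_max=50.0):
    panel = WavenumberPanel()
    return BasisModel(
        panel=panel,
        k=WaterConstants(np.array(k), "toy", 1),
        phi_coeffs=np.array(phi), psi_coeffs=np.array(psi), c_max=c_max,
    )


QUAD_MODEL = make_model(
    phi=[(6.0e-4, 2.0e-6), (0.8e-4, 0.3e-6), (4.5e-4, 1.2e-6)],
    psi=[(0.9e-4, 0.3e-6), (5.5e-4, 1.8e-6), (1.5e-4, 0.5e-6)],
)


def grid_search_oracle(model, delta_s, resolution=0.01, lo=0.0, hi=60.0):
    """Exhaustive objective minimisation on a regular (cg, cf) grid.

    Exploits separability: F_i(x, y) = P_i(x) + Q_i(y) - t_i, so the
    objective decomposes into per-axis terms plus outer-product cross terms,
    evaluated blockwise to bound memory.
    """
    target = np.asarray(delta_s) - model.k.k
    c = np.arange(lo, hi + resolution / 2, resolution)
    n = c.size
    P = np.vstack([np.vander(c, model.phi_coeffs.shape[1] + 1, increasing=True)[:, 1:]
                   @ model.phi_coeffs[i] for i in range(model.panel.n)])
    Q = np.vstack([np.vander(c, model.psi_coeffs.shape[1] + 1, increasing=True)[:, 1:]
                   @ model.psi_coeffs[i] for i in range(model.panel.n)])
    P = P - target[:, None]  # fold the target into the glucose axis
    best_val, best_xy = np.inf, (np.nan, np.nan)
    block = 512
    sumP2 = np.sum(P ** 2, axis=0)
    sumQ2 = np.sum(Q ** 2, axis=0)
    for s in range(0, n, block):
        Pb = P[:, s:s + block]
        obj = sumP2[s:s + block, None] + sumQ2[None, :] + 2.0 * (Pb.T @ Q)
        ij = np.unravel_index(np.argmin(obj), obj.shape)
        if obj[ij] < best_val:
            best_val = float(obj[ij])
            best_xy = (c[s + ij[0]], c[ij[1]])
    return best_val, best_xy


class TestEstimate:
    def test_water_only_signal_gives_origin(self):
        est = estimate_concentrations(QUAD_MODEL.k.k.copy(), QUAD_MODEL)
        assert est.c_glucose == pytest.approx(0.0, abs=1e-8)
        assert est.c_fructose == pytest.approx(0.0, abs=1e-8)
        assert est.objective < 1e-16

    def test_known_mixture_recovered_and_beats_grid_oracle(self):
        ds = QUAD_MODEL.predict_delta_s(25.0, 40.0)
        est = estimate_concentrations(ds, QUAD_MODEL)
        assert est.c_glucose == pytest.approx(25.0, abs=1e-6)
        assert est.c_fructose == pytest.approx(40.0, abs=1e-6)
        oracle_val, oracle_xy = grid_search_oracle(QUAD_MODEL, ds)
        assert est.objective <= oracle_val + 1e-15
        assert oracle_xy == pytest.approx((25.0, 40.0), abs=0.02)

    def test_negative_component_is_clipped_with_raw_retained(self):
        """A pure-glucose signature nudged down at the fructose line drives
        the unconstrained minimiser negative in c_fructose; the estimate is
        clipped to zero and the raw solution keeps the sign."""
        ds = QUAD_MODEL.predict_delta_s(20.0, 0.0)
        ds[1] -= 5e-4  # push the 1063 cm-1 (fructose) height below water level
        est = estimate_concentrations(ds, QUAD_MODEL)
        assert est.raw_solution[1] < 0
        assert est.c_fructose == 0.0
        assert est.c_glucose > 0
        assert np.all(np.array([est.c_glucose, est.c_fructose])
                      == np.maximum(est.raw_solution, 0.0))

    def test_panel_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            estimate_concentrations(np.zeros(4), QUAD_MODEL)

    def test_collinear_bases_flagged_ill_conditioned(self):
        phi = [(6.0e-4, 2.0e-6), (0.8e-4, 0.3e-6), (4.5e-4, 1.2e-6)]
        psi = [tuple(2 * a for a in row) for row in phi]  # psi = 2*phi exactly
        model = make_model(phi=phi, psi=psi)
        est = estimate_concentrations(model.predict_delta_s(10.0, 10.0), model)
        assert est.ill_conditioned

    def test_solver_never_worse_than_coarse_grid_oracle_on_random_instances(self):
        """Smaller-scale version of the solver/oracle comparison: 10 seeded
        random models and targets, 0.05 g/l oracle grid."""
        rng = np.random.default_rng(123)
        for _ in range(10):
            phi = np.column_stack([rng.uniform(1e-4, 8e-4, 3), rng.uniform(0, 5e-6, 3)])
            psi = np.column_stack([rng.uniform(1e-4, 8e-4, 3), rng.uniform(0, 5e-6, 3)])
            model = make_model(phi=phi, psi=psi, k=rng.uniform(0.005, 0.02, 3))
            cg, cf = rng.uniform(0, 60, 2)
            ds = model.predict_delta_s(cg, cf) + rng.normal(0, 2e-4, 3)
            est = estimate_concentrations(ds, model)
            oracle_val, _ = grid_search_oracle(model, ds, resolution=0.05)
            assert est.objective <= oracle_val + 1e-14


class TestErrorMetrics:
    def test_closed_form_arithmetic(self):
        s = summarize_errors(np.array([[1.0, 2.0], [3.0, 0.0]])[:, :])
        # pooled over {1, 2, 3, 0}
        assert s.e_mean == pytest.approx(1.5)
        assert s.e_max == 3.0

    def test_one_two_three_pooled(self):
        s = summarize_errors(np.array([[1.0], [2.0], [3.0]]))
        assert s.e_mean == pytest.approx(2.0)
        assert s.e_rms == pytest.approx(np.sqrt(14.0 / 3.0))
        assert s.e_max == pytest.approx(3.0)

    def test_perfect_estimates_give_zero_errors(self):
        s = summarize_errors(np.zeros((5, 2)))
        assert s.e_rms == s.e_mean == s.e_max == 0.0

    def test_metric_inequalities(self):
        rng = np.random.default_rng(8)
        s = summarize_errors(rng.exponential(1.0, size=(20, 2)))
        assert s.e_max >= s.e_rms >= s.e_mean >= 0


class TestEvaluation:
    def test_unknown_condition_is_evaluation_error(self, separated_truth):
        from seiraquant import Cycle, EvaluationError, MeasurementSet, calibrate
        from seiraquant.synthetic import simulate_experiment

        g, f, m = simulate_experiment(truth=separated_truth, seed=0)
        model = calibrate(g, f, orders=(2, 2))
        blind = Cycle(m.name, [
            MeasurementSet(s.label, None if i == 1 else s.condition, s.replicates)
            for i, s in enumerate(m.sets)
        ])
        with pytest.raises(EvaluationError, match="unknown"):
            evaluate_cycle(blind, model)

    def test_order_sweep_shape_and_row_inequalities(self, small_experiment):
        g, f, m = small_experiment
        table = order_sweep(g, f, [g, f, m])
        assert len(table) == 9
        assert set(zip(table.n_glucose, table.n_fructose)) == {
            (a, b) for a in (1, 2, 3) for b in (1, 2, 3)}
        assert (table.e_max >= table.e_rms).all()
        assert (table.e_rms >= table.e_mean).all()

    def test_zero_noise_sweep_quadratic_rows_beat_linear(self, separated_truth):
        """Truth is quadratic: order-2 glucose rows achieve near-zero error,
        order-1 rows carry model-mismatch error."""
        from seiraquant.synthetic import default_designs, simulate_experiment

        g, f, m = simulate_experiment(
            designs=default_designs(replicates_per_set=1), truth=separated_truth)
        table = order_sweep(g, f, [g, f, m]).set_index(["n_glucose", "n_fructose"])
        assert table.loc[(2, 2), "e_rms"] < 1e-6
        assert table.loc[(1, 1), "e_rms"] > 10 * table.loc[(2, 2), "e_rms"]
        assert table.loc[(1, 2), "e_rms"] > 10 * table.loc[(2, 2), "e_rms"]
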