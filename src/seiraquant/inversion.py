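"""Concentration inversion by clipped nonlinear least squares, and evaluation.

Given measured peak heights Δsm at the n ≥ 2 panel wavenumbers and a
calibrated :class:`~seiraquant.calibration.BasisModel`, the unknown
concentrations x = [c_glucose, c_fructose]ᵀ solve

    F_i(x) = φᵢ(x₁) + ψᵢ(x₂) − (Δsm(νᵢ) − kᵢ),   i = 1..n,

in the least-squares sense, followed by componentwise clipping at zero:
x* = max(argmin_x F(x)ᵀF(x), 0). Negative concentrations are physically
infeasible but the unconstrained minimiser is retained for diagnostics, so
the semantics are clip-after-argmin, not a bound-constrained argmin.

The minimisation is multi-start local descent over a box extending slightly
below zero (so negative unconstrained minima are reachable) and above the
calibration ceiling; starts are the box corners, the centre, and a
closed-form guess from the linear terms of the bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .baseline import BaselineConfig
from .calibration import BasisModel, calibrate, estimate_water_constants
from .errors import EvaluationError
from .features import PeakVector, WavenumberPanel, cycle_peaks
from .spectra import Cycle


@dataclass(frozen=True)
class SolverConfig:
    """Search-box and termination settings for the inversion solver.

    The box is ``[box_lo_factor*c_max, box_hi_factor*c_max]`` per component;
    ``cond_threshold`` flags near-singular Jacobians at the solution
    (ill-conditioned line panels cannot separate the two analytes).
    """

    box_lo_factor: float = -0.2
    box_hi_factor: float = 1.5
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12
    cond_threshold: float = 1e8


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Clipped estimate with the pre-clip solver solution retained."""

    c_glucose: float
    c_fructose: float
    raw_solution: np.ndarray
    objective: float
    converged: bool
    ill_conditioned: bool = False
    set_label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "raw_solution", np.asarray(self.raw_solution, dtype=float))


@dataclass(frozen=True)
class ErrorSummary:
    """Pooled absolute-error metrics over evaluated sets (both analytes)."""

    e_rms: float
    e_mean: float
    e_max: float
    n_sets: int
    per_set_errors: np.ndarray  # (n_sets, 2): |Δc_glucose|, |Δc_fructose|

    def __post_init__(self):
        object.__setattr__(self, "per_set_errors", np.asarray(self.per_set_errors, dtype=float))


def summarize_errors(per_set_errors: np.ndarray, n_sets: Optional[int] = None) -> ErrorSummary:
    """Pool per-analyte absolute errors into e_rms / e_mean / e_max.

    The pooling rule: every evaluated set contributes one absolute error per
    analyte (water sets contribute both analytes' errors versus 0 g/l), and
    the scalar metrics are taken over that pooled collection. Isolated here
    so alternative conventions are a one-line change.
    """
    errs = np.asarray(per_set_errors, dtype=float)
    pooled = errs.ravel()
    return ErrorSummary(
        e_rms=float(np.sqrt(np.mean(pooled ** 2))),
        e_mean=float(np.mean(pooled)),
        e_max=float(np.max(pooled)),
        n_sets=int(n_sets if n_sets is not None else errs.shape[0]),
        per_set_errors=errs,
    )


def _starts(model: BasisModel, target: np.ndarray, lo: float, hi: float) -> list[np.ndarray]:
    corners = [np.array([lo, lo]), np.array([lo, hi]), np.array([hi, lo]), np.array([hi, hi])]
    centre = [np.array([(lo + hi) / 2, (lo + hi) / 2])]
    # closed-form guess from the linear terms only: A x ~ target
    A = np.column_stack([model.phi_coeffs[:, 0], model.psi_coeffs[:, 0]])
    guess, *_ = np.linalg.lstsq(A, target, rcond=None)
    linear = [np.clip(guess, lo, hi)]
    return corners + centre + linear


def estimate_concentrations(delta_s_measured, model: BasisModel,
                            solver: SolverConfig = SolverConfig(),
                            set_label: str = "") -> ConcentrationEstimate:
    """Solve the superposition system for (c_glucose, c_fructose) and clip.

    ``delta_s_measured`` is a :class:`PeakVector` or array of raw peak
    heights Δsm (water *not* yet subtracted); the model's kᵢ are subtracted
    internally. Non-convergence from every start still returns an estimate,
    flagged ``converged=False``.
    """
    if isinstance(delta_s_measured, PeakVector):
        if not set_label:
            set_label = delta_s_measured.set_label
        ds = delta_s_measured.delta_s
    else:
        ds = np.asarray(delta_s_measured, dtype=float)
    if ds.size != model.panel.n:
        raise ValueError(
            f"peak vector length {ds.size} does not match model panel ({model.panel.n})"
        )
    if model.panel.n < 2:
        raise ValueError("inversion needs n >= 2 wavenumbers")
    target = ds - model.k.k

    def residual(x):
        return model.phi_values(x[0]) + model.psi_values(x[1]) - target

    def jac(x):
        pg = np.array([(j + 1) * x[0] ** j for j in range(model.phi_coeffs.shape[1])])
        pf = np.array([(j + 1) * x[1] ** j for j in range(model.psi_coeffs.shape[1])])
        return np.column_stack([model.phi_coeffs @ pg, model.psi_coeffs @ pf])

    lo = solver.box_lo_factor * model.c_max
    hi = solver.box_hi_factor * model.c_max
    best = None
    any_ok = False
    for x0 in _starts(model, target, lo, hi):
        res = least_squares(
            residual, x0, jac=jac, bounds=(lo, hi), method="trf",
            xtol=solver.xtol, ftol=solver.ftol, gtol=solver.gtol,
        )
        any_ok = any_ok or res.status > 0
        if best is None or res.cost < best.cost:
            best = res
    raw = best.x
    obj = float(2.0 * best.cost)  # least_squares cost is 0.5 * sum(r^2)
    J = jac(raw)
    sv = np.linalg.svd(J, compute_uv=False)
    ill = bool(sv[-1] == 0 or sv[0] / sv[-1] > solver.cond_threshold)
    clipped = np.maximum(raw, 0.0)
    return ConcentrationEstimate(
        c_glucose=float(clipped[0]), c_fructose=float(clipped[1]),
        raw_solution=raw, objective=obj, converged=bool(any_ok),
        ill_conditioned=ill, set_label=set_label,
    )


def evaluate_cycle(cycle: Cycle, model: BasisModel,
                   baseline_config: BaselineConfig = BaselineConfig(),
                   solver: SolverConfig = SolverConfig(),
                   peaks: Optional[Sequence[PeakVector]] = None,
                   cycle_local_k: bool = True
                   ) -> tuple[ErrorSummary, list[ConcentrationEstimate]]:
    """Estimate every set of a cycle and compare to the known conditions.

    With ``cycle_local_k`` (default) the water constants are re-estimated
    from the evaluated cycle's own pure-water sets, reflecting the per-cycle
    calibration of kᵢ; the polynomial bases stay as trained.
    """
    for s in cycle.sets:
        if s.condition is None:
            raise EvaluationError(
                f"set {s.label!r} in cycle {cycle.name!r} has unknown condition; "
                "evaluation requires ground truth"
            )
    if peaks is None:
        peaks = cycle_peaks(cycle, baseline_config, panel=model.panel)
    if cycle_local_k:
        k_local = estimate_water_constants(cycle, model.panel, baseline_config, peaks=peaks)
        model = model.with_water_constants(k_local)
    estimates = []
    errors = np.empty((len(cycle.sets), 2))
    for row, (s, pv) in enumerate(zip(cycle.sets, peaks)):
        est = estimate_concentrations(pv, model, solver, set_label=s.label)
        estimates.append(est)
        errors[row, 0] = abs(est.c_glucose - s.condition[0])
        errors[row, 1] = abs(est.c_fructose - s.condition[1])
    return summarize_errors(errors, n_sets=len(cycle.sets)), estimates


def evaluate_experiment(cycles: Sequence[Cycle], model: BasisModel,
                        baseline_config: BaselineConfig = BaselineConfig(),
                        solver: SolverConfig = SolverConfig(),
                        peaks_by_cycle: Optional[Sequence[Sequence[PeakVector]]] = None
                        ) -> tuple[ErrorSummary, dict[str, list[ConcentrationEstimate]]]:
    """Evaluate several cycles and pool their errors into one summary."""
    all_errors = []
    estimates = {}
    n_sets = 0
    for idx, cyc in enumerate(cycles):
        pk = peaks_by_cycle[idx] if peaks_by_cycle is not None else None
        summary, ests = evaluate_cycle(cyc, model, baseline_config, solver, peaks=pk)
        all_errors.append(summary.per_set_errors)
        estimates[cyc.name] = ests
        n_sets += summary.n_sets
    return summarize_errors(np.vstack(all_errors), n_sets=n_sets), estimates


def order_sweep(glucose_cycle: Cycle, fructose_cycle: Cycle,
                evaluation_cycles: Sequence[Cycle],
                panel: WavenumberPanel = WavenumberPanel(),
                baseline_config: BaselineConfig = BaselineConfig(),
                solver: SolverConfig = SolverConfig(),
                orders: Sequence[tuple[int, int]] = tuple(
                    (g, f) for g in (1, 2, 3) for f in (1, 2, 3))
                ) -> pd.DataFrame:
    """Calibrate and evaluate every polynomial-order pair; one row per pair.

    Peak extraction is order-independent, so the baseline stage runs once per
    cycle and is reused across all order pairs. Columns mirror the error
    comparison: n_glucose, n_fructose, e_rms, e_mean, e_max (g/l).
    """
    g_peaks = cycle_peaks(glucose_cycle, baseline_config, panel)
    f_peaks = cycle_peaks(fructose_cycle, baseline_config, panel)
    eval_peaks = []
    for cyc in evaluation_cycles:
        if cyc is glucose_cycle:
            eval_peaks.append(g_peaks)
        elif cyc is fructose_cycle:
            eval_peaks.append(f_peaks)
        else:
            eval_peaks.append(cycle_peaks(cyc, baseline_config, panel))
    rows = []
    for n_g, n_f in orders:
        model = calibrate(
            glucose_cycle, fructose_cycle, panel, (n_g, n_f), baseline_config,
            glucose_peaks=g_peaks, fructose_peaks=f_peaks,
        )
        summary, _ = evaluate_experiment(
            evaluation_cycles, model, baseline_config, solver, peaks_by_cycle=eval_peaks)
        rows.append(
            {"n_glucose": n_g, "n_fructose": n_f, "e_rms": summary.e_rms,
             "e_mean": summary.e_mean, "e_max": summary.e_max}
        )
    return pd.DataFrame(rows)
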