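"""Per-cycle water-constant calibration and polynomial basis fitting.

The superposition model assumes the peak height at each characteristic
wavenumber decomposes additively,

    Δs(νᵢ) = kᵢ + φᵢ(c_glucose) + ψᵢ(c_fructose),

with kᵢ the constant contribution of pure water and φᵢ, ψᵢ polynomial basis
functions with zero constant term (at zero concentration the analyte
contributes nothing — forced by the model, encoded structurally here).
kᵢ varies between measurement cycles (residue carry-over, drift), so it is
calibrated per cycle from that cycle's pure-water sets; φᵢ and ψᵢ are fitted
per wavenumber, independently, from the pure-glucose and pure-fructose
training cycles after subtracting the respective cycle's kᵢ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .baseline import BaselineConfig
from .errors import CalibrationError, FitError
from .features import PeakVector, WavenumberPanel, cycle_peaks, peaks_for_set
from .spectra import Cycle

VALID_ORDERS = (1, 2, 3)


@dataclass(frozen=True)
class WaterConstants:
    """Mean pure-water peak heights kᵢ for one cycle, with per-set values."""

    k: np.ndarray
    cycle_name: str
    n_water_sets: int
    per_set: np.ndarray = field(default=None)  # (n_water_sets, n) for dispersion diagnostics

    def __post_init__(self):
        object.__setattr__(self, "k", np.asarray(self.k, dtype=float))
        if self.per_set is not None:
            object.__setattr__(self, "per_set", np.asarray(self.per_set, dtype=float))
        if not np.all(np.isfinite(self.k)):
            raise ValueError("water constants must be finite")


def estimate_water_constants(cycle: Cycle, panel: WavenumberPanel,
                             baseline_config: BaselineConfig,
                             peaks: Optional[Sequence[PeakVector]] = None) -> WaterConstants:
    """kᵢ = arithmetic mean of Δs(νᵢ) over the pure-water sets of the cycle.

    ``peaks`` may carry precomputed per-set peak vectors (cycle order) to
    avoid re-running the baseline stage; otherwise they are computed here.
    """
    water_idx = [i for i, s in enumerate(cycle.sets) if s.is_water]
    if not water_idx:
        raise CalibrationError(
            f"cycle {cycle.name!r} has no pure-water set; cannot calibrate k"
        )
    if peaks is None:
        per_set = np.vstack(
            [peaks_for_set(cycle.sets[i], baseline_config, panel).delta_s for i in water_idx]
        )
    else:
        per_set = np.vstack([np.asarray(peaks[i].delta_s, float) for i in water_idx])
    return WaterConstants(
        k=per_set.mean(axis=0),
        cycle_name=cycle.name,
        n_water_sets=len(water_idx),
        per_set=per_set,
    )


def fit_basis(concentrations: Sequence[float], y: Sequence[float], order: int
              ) -> tuple[np.ndarray, float]:
    """Least-squares fit of y ≈ Σ_{j=1..order} a_j c^j (zero constant term).

    Returns ``(coefficients a_1..a_order, residual_norm)``. Requires at least
    ``order`` distinct positive concentration values; the zero-intercept
    constraint plays the role of the (0, 0) calibration point.
    """
    if order not in VALID_ORDERS:
        raise FitError(f"polynomial order must be in {VALID_ORDERS}, got {order}")
    c = np.asarray(concentrations, dtype=float)
    yv = np.asarray(y, dtype=float)
    if c.shape != yv.shape or c.ndim != 1:
        raise FitError("concentrations and y must be 1-d arrays of equal length")
    n_distinct = np.unique(c[c > 0]).size
    if n_distinct < order:
        raise FitError(
            f"{n_distinct} distinct positive concentration(s) cannot determine an "
            f"order-{order} basis; reduce the order"
        )
    # Vandermonde without the constant column enforces phi(0) = 0 structurally
    A = np.column_stack([c ** j for j in range(1, order + 1)])
    coeffs, _, _, _ = np.linalg.lstsq(A, yv, rcond=None)
    residual_norm = float(np.linalg.norm(A @ coeffs - yv))
    return coeffs, residual_norm


def _polyval_no_const(coeffs: np.ndarray, c: float) -> float:
    return float(sum(a * c ** (j + 1) for j, a in enumerate(coeffs)))


@dataclass(frozen=True)
class BasisModel:
    """Calibrated superposition model: panel, water constants, and bases.

    ``phi_coeffs``/``psi_coeffs`` are (n_wavenumbers, order) arrays of
    ascending-power coefficients a_1..a_order (no constant term), for glucose
    and fructose respectively. ``c_max`` is the largest concentration seen in
    calibration and bounds the inversion search box.
    """

    panel: WavenumberPanel
    k: WaterConstants
    phi_coeffs: np.ndarray
    psi_coeffs: np.ndarray
    c_max: float
    phi_residuals: Optional[np.ndarray] = None
    psi_residuals: Optional[np.ndarray] = None

    def __post_init__(self):
        phi = np.atleast_2d(np.asarray(self.phi_coeffs, dtype=float))
        psi = np.atleast_2d(np.asarray(self.psi_coeffs, dtype=float))
        object.__setattr__(self, "phi_coeffs", phi)
        object.__setattr__(self, "psi_coeffs", psi)
        n = self.panel.n
        if phi.shape[0] != n or psi.shape[0] != n:
            raise ValueError("coefficient arrays must have one row per panel wavenumber")
        for name, arr in (("phi", phi), ("psi", psi)):
            if arr.shape[1] not in VALID_ORDERS:
                raise ValueError(f"{name} order must be in {VALID_ORDERS}")
        if self.k.k.size != n:
            raise ValueError("water constants length must match panel")

    @property
    def orders(self) -> tuple[int, int]:
        return self.phi_coeffs.shape[1], self.psi_coeffs.shape[1]

    def phi(self, i: int, c_glucose: float) -> float:
        """Glucose contribution φᵢ(c) at panel line i; φᵢ(0) = 0 exactly."""
        return _polyval_no_const(self.phi_coeffs[i], c_glucose)

    def psi(self, i: int, c_fructose: float) -> float:
        """Fructose contribution ψᵢ(c) at panel line i; ψᵢ(0) = 0 exactly."""
        return _polyval_no_const(self.psi_coeffs[i], c_fructose)

    def phi_values(self, c_glucose: float) -> np.ndarray:
        powers = np.array([c_glucose ** j for j in range(1, self.phi_coeffs.shape[1] + 1)])
        return self.phi_coeffs @ powers

    def psi_values(self, c_fructose: float) -> np.ndarray:
        powers = np.array([c_fructose ** j for j in range(1, self.psi_coeffs.shape[1] + 1)])
        return self.psi_coeffs @ powers

    def predict_delta_s(self, c_glucose: float, c_fructose: float) -> np.ndarray:
        """Model peak heights kᵢ + φᵢ(cg) + ψᵢ(cf) at every panel line."""
        return self.k.k + self.phi_values(c_glucose) + self.psi_values(c_fructose)

    def with_water_constants(self, k: WaterConstants) -> "BasisModel":
        """Same bases, different cycle's water constants (cycle-local k)."""
        return replace(self, k=k)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "panel": {
                "wavenumbers_cm-1": list(self.panel.nus),
                "search_halfwidth_cm-1": self.panel.search_halfwidth,
            },
            "water_constants": {
                "k": self.k.k.tolist(),
                "cycle_name": self.k.cycle_name,
                "n_water_sets": self.k.n_water_sets,
            },
            "phi_coeffs": self.phi_coeffs.tolist(),
            "psi_coeffs": self.psi_coeffs.tolist(),
            "c_max_g_per_l": self.c_max,
        }

    def save(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "BasisModel":
        panel = WavenumberPanel(
            nus=tuple(d["panel"]["wavenumbers_cm-1"]),
            search_halfwidth=d["panel"]["search_halfwidth_cm-1"],
        )
        wc = d["water_constants"]
        k = WaterConstants(
            k=np.array(wc["k"]), cycle_name=wc["cycle_name"],
            n_water_sets=wc["n_water_sets"],
        )
        return cls(
            panel=panel, k=k,
            phi_coeffs=np.array(d["phi_coeffs"]),
            psi_coeffs=np.array(d["psi_coeffs"]),
            c_max=float(d["c_max_g_per_l"]),
        )

    @classmethod
    def load(cls, path) -> "BasisModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _fit_analyte(cycle: Cycle, which: str, panel: WavenumberPanel,
                 baseline_config: BaselineConfig, order: int,
                 peaks: Optional[Sequence[PeakVector]] = None
                 ) -> tuple[np.ndarray, np.ndarray, WaterConstants, float]:
    """Fit one analyte's per-wavenumber bases from its pure-solution cycle."""
    if peaks is None:
        peaks = cycle_peaks(cycle, baseline_config, panel)
    kc = estimate_water_constants(cycle, panel, baseline_config, peaks=peaks)
    idx = 0 if which == "glucose" else 1
    points = []
    for s, pv in zip(cycle.sets, peaks):
        if s.is_water:
            continue
        if s.condition is None:
            raise CalibrationError(
                f"training cycle {cycle.name!r} contains a set with unknown condition"
            )
        other = s.condition[1 - idx]
        if other != 0:
            raise CalibrationError(
                f"training cycle {cycle.name!r} must contain pure {which} solutions; "
                f"set {s.label!r} has condition {s.condition}"
            )
        points.append((s.condition[idx], pv.delta_s - kc.k))
    if not points:
        raise CalibrationError(f"cycle {cycle.name!r} has no {which} sets to fit")
    cvals = np.array([c for c, _ in points])
    Y = np.vstack([y for _, y in points])  # (n_points, n_wavenumbers)
    coeffs = np.empty((panel.n, order))
    residuals = np.empty(panel.n)
    for i in range(panel.n):
        coeffs[i], residuals[i] = fit_basis(cvals, Y[:, i], order)
    return coeffs, residuals, kc, float(cvals.max())


def calibrate(glucose_cycle: Cycle, fructose_cycle: Cycle,
              panel: WavenumberPanel = WavenumberPanel(),
              orders: tuple[int, int] = (2, 2),
              baseline_config: BaselineConfig = BaselineConfig(),
              glucose_peaks: Optional[Sequence[PeakVector]] = None,
              fructose_peaks: Optional[Sequence[PeakVector]] = None) -> BasisModel:
    """Run the full training chain on the two pure-analyte cycles.

    Averages replicates, baseline-corrects, extracts peaks, estimates each
    training cycle's water constants, and fits φᵢ (order ``orders[0]``) from
    the glucose cycle and ψᵢ (order ``orders[1]``) from the fructose cycle.
    The returned model carries the glucose cycle's water constants; use
    :meth:`BasisModel.with_water_constants` to attach the constants of the
    cycle being analyzed (calibration is cycle-local).
    """
    n_g, n_f = orders
    if n_g not in VALID_ORDERS or n_f not in VALID_ORDERS:
        raise FitError(f"orders must be in {VALID_ORDERS}, got {orders}")
    phi, phi_res, k_g, cmax_g = _fit_analyte(
        glucose_cycle, "glucose", panel, baseline_config, n_g, peaks=glucose_peaks)
    psi, psi_res, _, cmax_f = _fit_analyte(
        fructose_cycle, "fructose", panel, baseline_config, n_f, peaks=fructose_peaks)
    return BasisModel(
        panel=panel, k=k_g, phi_coeffs=phi, psi_coeffs=psi,
        c_max=max(cmax_g, cmax_f), phi_residuals=phi_res, psi_residuals=psi_res,
    )
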