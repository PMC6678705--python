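"""Modified asymmetric least squares smoothing (ALSS) baseline correction.

The plasmonic resonance of the nanoantennas forms a broad, smooth background
in each SEIRA reflectance spectrum, on top of which the narrow vibrational
features of water, glucose and fructose ride. ALSS reconstructs that
background as the minimiser of

    sum_i w_i (y_i - z_i)^2  +  lam * sum_i (Delta^2 z_i)^2

with the asymmetric weight rule ``w_i = p`` where ``y_i > z_i`` and
``w_i = 1 - p`` otherwise, iterated to a fixed point of the weights. The
modification used here: grid points inside configurable exclusion windows
receive weight exactly zero, so the strongly deformed region around the
vibrational lines has no influence on the fit while the smoothness penalty
still bridges the window with a smooth interpolant. Dividing the measured
spectrum by the reconstructed baseline yields the pure vibrational spectrum
rBC.

Peak amplitudes in rBC depend strongly on (lam, p); quantitative work
therefore keeps one global parameter choice across all spectra that are
compared (defaults: lam=500, p=0.99, exclusion [1000, 1100] cm⁻¹). lam is
defined on the index grid (standard Whittaker convention), so it is tied to
the sampling density: data on a coarser or finer grid needs re-tuning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import solveh_banded

from .errors import ConfigurationError, GridMismatchError
from .spectra import Spectrum

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BaselineConfig:
    """Parameters of the modified ALSS baseline estimator.

    lam : smoothness weight (> 0); larger values give stiffer baselines.
    p : asymmetry weight in (0, 1); points above the current baseline get
        weight p, points below get 1 - p. p close to 1 pulls the baseline
        toward the upper envelope of the data.
    exclusion_windows : [lo, hi] wavenumber intervals (cm⁻¹) whose points get
        zero weight.
    max_iter / tol : iteration cap and weight-change threshold for the
        fixed-point loop.
    """

    lam: float = 500.0
    p: float = 0.99
    exclusion_windows: tuple = ((1000.0, 1100.0),)
    max_iter: int = 50
    tol: float = 1e-8

    def __post_init__(self):
        if not self.lam > 0:
            raise ConfigurationError(f"lam must be > 0, got {self.lam}")
        if not 0 < self.p < 1:
            raise ConfigurationError(f"p must lie in (0, 1), got {self.p}")
        if not self.max_iter >= 1:
            raise ConfigurationError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ConfigurationError("tol must be > 0")
        windows = tuple((float(lo), float(hi)) for lo, hi in self.exclusion_windows)
        for lo, hi in windows:
            if not lo < hi:
                raise ConfigurationError(f"exclusion window [{lo}, {hi}] has lo >= hi")
        object.__setattr__(self, "exclusion_windows", windows)


@dataclass(frozen=True)
class BaselineResult:
    """ALSS output: the baseline spectrum plus convergence diagnostics."""

    baseline: Spectrum
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class CorrectedSpectrum:
    """Baseline-corrected spectrum rBC = measured / baseline, with provenance."""

    spectrum: Spectrum  # kind == "corrected"
    baseline: Spectrum
    config: Optional[BaselineConfig] = None

    @property
    def rbc(self) -> np.ndarray:
        return self.spectrum.values

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.spectrum.wavenumbers


def exclusion_mask(wavenumbers: np.ndarray, config: BaselineConfig) -> np.ndarray:
    """Boolean mask of grid points falling inside any exclusion window."""
    mask = np.zeros(wavenumbers.shape, dtype=bool)
    for lo, hi in config.exclusion_windows:
        inside = (wavenumbers >= lo) & (wavenumbers <= hi)
        if not inside.any():
            logger.warning(
                "exclusion window [%g, %g] cm-1 does not overlap the grid; ignored", lo, hi
            )
        mask |= inside
    return mask


def _whittaker_banded(n: int, lam: float) -> np.ndarray:
    """Upper banded form (3, n) of lam * D2'D2 for solveh_banded."""
    ab = np.zeros((3, n))
    # diagonal of D2'D2: [1, 5, 6, ..., 6, 5, 1]
    d = np.full(n, 6.0)
    d[[0, -1]] = 1.0
    d[[1, -2]] = 5.0
    # first off-diagonal: [-2, -4, ..., -4, -2]
    o1 = np.full(n - 1, -4.0)
    o1[[0, -1]] = -2.0
    ab[2, :] = lam * d
    ab[1, 1:] = lam * o1
    ab[0, 2:] = lam  # second off-diagonal is constant 1
    return ab


def _solve_weighted(ab_pen: np.ndarray, w: np.ndarray, y: np.ndarray) -> np.ndarray:
    ab = ab_pen.copy()
    ab[2, :] += w
    return solveh_banded(ab, w * y, lower=False)


def alss_baseline(spectrum: Spectrum, config: BaselineConfig = BaselineConfig()) -> BaselineResult:
    """Estimate the smooth baseline of a raw spectrum by modified ALSS.

    Weights start at 1 on all non-excluded points; each iteration solves the
    penalized weighted least-squares system with a symmetric banded solver and
    updates the asymmetric weights. The loop stops when the weight vector is
    unchanged (fixed point) or after ``max_iter`` iterations, in which case
    the result carries ``converged=False``.
    """
    y = spectrum.values
    n = y.size
    excl = exclusion_mask(spectrum.wavenumbers, config)
    if excl.all():
        raise ConfigurationError("all grid points are excluded; nothing to fit")

    ab_pen = _whittaker_banded(n, config.lam)
    w = np.where(excl, 0.0, 1.0)
    z = _solve_weighted(ab_pen, w, y)
    # residuals within tau of zero count as "below": without the tie band,
    # data the smoother fits exactly flips weights on rounding jitter forever
    tau = 1e-8 * max(1.0, float(np.max(np.abs(y))))
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        w_new = np.where(excl, 0.0, np.where(y - z > tau, config.p, 1.0 - config.p))
        if np.max(np.abs(w_new - w)) <= config.tol:
            converged = True
            break
        w = w_new
        z = _solve_weighted(ab_pen, w, y)
    if not converged:
        logger.warning("ALSS did not reach a weight fixed point in %d iterations", config.max_iter)
    return BaselineResult(
        baseline=Spectrum(spectrum.wavenumbers, z, kind="baseline"),
        converged=converged,
        n_iter=it,
    )


def divide_baseline(spectrum: Spectrum, baseline: Spectrum,
                    config: Optional[BaselineConfig] = None) -> CorrectedSpectrum:
    """rBC(ν) = measured(ν) / baseline(ν), elementwise on a shared grid."""
    spectrum.require_same_grid(baseline)
    nonpos = baseline.values <= 0
    if nonpos.any():
        nu_bad = spectrum.wavenumbers[np.argmax(nonpos)]
        raise ValueError(f"baseline is not strictly positive at {nu_bad:g} cm-1")
    rbc = spectrum.values / baseline.values
    return CorrectedSpectrum(
        spectrum=Spectrum(spectrum.wavenumbers, rbc, kind="corrected"),
        baseline=baseline,
        config=config,
    )


def correct_spectrum(spectrum: Spectrum,
                     config: BaselineConfig = BaselineConfig()) -> CorrectedSpectrum:
    """Convenience: ALSS baseline then division, in one call."""
    result = alss_baseline(spectrum, config)
    return divide_baseline(spectrum, result.baseline, config)


def baseline_sensitivity(spectrum: Spectrum, lam_grid: Sequence[float],
                         config: BaselineConfig, panel) -> "pandas.DataFrame":
    """Peak heights at the panel wavenumbers as a function of lam.

    One row per lam value. Peak *positions* are stable across lam while the
    extracted amplitudes are not — which is why quantitative comparison
    requires a single global lam for all spectra.
    """
    import pandas as pd

    from .features import extract_peaks

    lam_grid = list(lam_grid)
    if not lam_grid:
        raise ConfigurationError("lam_grid must not be empty")
    rows = []
    for lam in lam_grid:
        cfg = BaselineConfig(
            lam=float(lam), p=config.p, exclusion_windows=config.exclusion_windows,
            max_iter=config.max_iter, tol=config.tol,
        )
        pv = extract_peaks(correct_spectrum(spectrum, cfg), panel)
        row = {"lam": float(lam)}
        for nu, ds, arg in zip(panel.nus, pv.delta_s, pv.argmax_nus):
            row[f"delta_s_{nu:g}"] = ds
            row[f"argmax_{nu:g}"] = arg
        rows.append(row)
    return pd.DataFrame(rows)
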