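"""Replicate averaging and peak-height extraction.

The thirty replicate spectra of a measurement set are averaged pointwise
before baseline correction; the peak height Δs at each characteristic
wavenumber is then the maximum of rBC − 1 within a small search window
around the nominal line position. Heights are measured relative to unity
because rBC is a ratio: a feature-free spectrum divides to ≈ 1, so pure
water produces the small constants kᵢ rather than values near 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .baseline import BaselineConfig, CorrectedSpectrum, correct_spectrum
from .spectra import MeasurementSet, Spectrum


@dataclass(frozen=True)
class WavenumberPanel:
    """Characteristic wavenumbers evaluated by the pipeline.

    Defaults to [1034, 1063, 1078] cm⁻¹: 1034 and 1078 are glucose ring
    C–C/C–O stretches, 1063 is fructose; the fructose line at 1080 cm⁻¹ is
    spectrally merged with 1078 and deliberately not evaluated separately.
    At least two wavenumbers are required for the two-analyte inversion.
    """

    nus: tuple = (1034.0, 1063.0, 1078.0)
    search_halfwidth: float = 2.0

    def __post_init__(self):
        nus = tuple(float(nu) for nu in self.nus)
        object.__setattr__(self, "nus", nus)
        if len(nus) < 2:
            raise ValueError("panel needs at least 2 characteristic wavenumbers")
        if not all(a < b for a, b in zip(nus, nus[1:])):
            raise ValueError("panel wavenumbers must be strictly increasing")
        if not self.search_halfwidth >= 0:
            raise ValueError("search_halfwidth must be >= 0")

    @property
    def n(self) -> int:
        return len(self.nus)


@dataclass(frozen=True)
class PeakVector:
    """Δs values at the panel wavenumbers for one measurement set."""

    delta_s: np.ndarray
    set_label: str
    argmax_nus: np.ndarray  # wavenumber at which each maximum was found

    def __post_init__(self):
        ds = np.asarray(self.delta_s, dtype=float)
        object.__setattr__(self, "delta_s", ds)
        object.__setattr__(self, "argmax_nus", np.asarray(self.argmax_nus, dtype=float))
        if not np.all(np.isfinite(ds)):
            raise ValueError("peak heights must be finite")

    @property
    def n(self) -> int:
        return int(self.delta_s.size)


def average_set(mset: MeasurementSet) -> tuple[Spectrum, np.ndarray]:
    """Pointwise mean and standard deviation across the replicates of a set.

    Returns ``(mean_spectrum, pointwise_sd)``. The SD (ddof=1 when more than
    one replicate) is diagnostic only; the mean spectrum feeds the pipeline.
    """
    stack = np.vstack([rep.values for rep in mset.replicates])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros(stack.shape[1])
    return mset.replicates[0].with_values(mean, kind="raw"), sd


def extract_peaks(corrected: Union[CorrectedSpectrum, Spectrum],
                  panel: WavenumberPanel) -> PeakVector:
    """Peak heights Δs(νᵢ) = max(rBC − 1) within νᵢ ± search_halfwidth.

    The local-maximum search absorbs small grid misalignment of the nominal
    line positions; the argmax wavenumber is recorded per peak.
    """
    if isinstance(corrected, CorrectedSpectrum):
        nu, rbc, label = corrected.wavenumbers, corrected.rbc, ""
    else:
        nu, rbc, label = corrected.wavenumbers, corrected.values, ""
    delta = rbc - 1.0
    heights = np.empty(panel.n)
    argmaxes = np.empty(panel.n)
    for i, nui in enumerate(panel.nus):
        sel = np.flatnonzero(np.abs(nu - nui) <= panel.search_halfwidth)
        if sel.size == 0:
            raise ValueError(
                f"characteristic wavenumber {nui:g} cm-1 (±{panel.search_halfwidth:g}) "
                "is outside the spectrum grid"
            )
        k = sel[np.argmax(delta[sel])]
        heights[i] = delta[k]
        argmaxes[i] = nu[k]
    return PeakVector(delta_s=heights, set_label=label, argmax_nus=argmaxes)


def peaks_for_set(mset: MeasurementSet, baseline_config: BaselineConfig,
                  panel: WavenumberPanel) -> PeakVector:
    """Full per-set feature chain: average replicates → ALSS-correct → extract.

    Averaging precedes baseline correction so the ALSS sees the smoother
    representative spectrum of the set.
    """
    mean_spectrum, _ = average_set(mset)
    corrected = correct_spectrum(mean_spectrum, baseline_config)
    pv = extract_peaks(corrected, panel)
    return PeakVector(delta_s=pv.delta_s, set_label=mset.label, argmax_nus=pv.argmax_nus)


def cycle_peaks(cycle, baseline_config: BaselineConfig,
                panel: WavenumberPanel) -> list[PeakVector]:
    """Peak vectors for every set of a cycle, in cycle order."""
    return [peaks_for_set(s, baseline_config, panel) for s in cycle.sets]
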