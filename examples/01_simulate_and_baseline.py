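"""Simulate one SEIRA spectrum and baseline-correct it.

Builds a noiseless 50 g/l glucose spectrum on the standard 900-1200 cm^-1
grid, reconstructs the plasmonic baseline with the modified ALSS (lambda=500,
p=0.99, exclusion window 1000-1100 cm^-1), divides it out, and reports the
peak heights at the three characteristic wavenumbers.
"""

import numpy as np

from seiraquant import (
    BaselineConfig, SimTruth, WavenumberPanel, correct_spectrum,
    extract_peaks, simulate_spectrum,
)

truth = SimTruth(noise_sigma=0.0)
grid = 900.0 + np.arange(301.0)
spectrum = simulate_spectrum((50.0, 0.0), truth, grid)

corrected = correct_spectrum(spectrum, BaselineConfig())
peaks = extract_peaks(corrected, WavenumberPanel())

print("50 g/l glucose, noiseless:")
for nu, ds, arg in zip((1034, 1063, 1078), peaks.delta_s, peaks.argmax_nus):
    print(f"  delta_s({nu} cm-1) = {ds:.4f}   (max found at {arg:g} cm-1)")
print(
    "\nThe 1034 and 1078 cm-1 peaks (glucose lines) dominate; the height at\n"
    "1063 cm-1 is mostly the water constant plus line overlap. These delta_s\n"
    "values are the inputs to calibration and inversion."
)
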