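"""Typed exceptions raised across the pipeline.

Every error a caller may want to catch selectively has its own class; all
inherit from :class:`SeiraQuantError` so ``except SeiraQuantError`` catches
anything this package raises deliberately.
"""


class SeiraQuantError(Exception):
    """Base class for all errors raised by seiraquant."""


class SpectrumParseError(SeiraQuantError):
    """A spectrum file could not be parsed (missing columns, bad cells, duplicates)."""

    def __init__(self, message: str, path=None, row=None):
        detail = message
        if path is not None:
            detail += f" [file: {path}"
            if row is not None:
                detail += f", row: {row}"
            detail += "]"
        super().__init__(detail)
        self.path = path
        self.row = row


class GridMismatchError(SeiraQuantError):
    """Two spectra combined arithmetically do not share a wavenumber grid."""


class ManifestError(SeiraQuantError):
    """A cycle manifest is inconsistent (missing files, bad structure)."""


class ConfigurationError(SeiraQuantError):
    """A configuration value is invalid or self-contradictory."""


class CalibrationError(SeiraQuantError):
    """Calibration cannot proceed (e.g. no pure-water sets in a cycle)."""


class FitError(SeiraQuantError):
    """A basis-function fit is underdetermined or otherwise infeasible."""


class EvaluationError(SeiraQuantError):
    """Evaluation against known concentrations is impossible (unknown conditions)."""
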