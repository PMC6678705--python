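"""Data model and plain-text I/O for spectra, measurement sets, and cycles.

A :class:`Spectrum` is a single wavenumber-indexed relative-reflectance trace.
Replicate spectra taken at one solution condition form a
:class:`MeasurementSet`; an ordered sequence of sets flushed through the flow
cell (water interleaved with analyte solutions) forms a :class:`Cycle`.

Files are delimited text (CSV by default), one spectrum per file, with a JSON
manifest per cycle. Wavenumbers are always cm⁻¹; spectra are stored in
increasing wavenumber order regardless of file order.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import GridMismatchError, ManifestError, SpectrumParseError

SPECTRUM_KINDS = ("raw", "baseline", "corrected")

#: minimum number of grid points for a usable spectrum
MIN_POINTS = 8


@dataclass(frozen=True)
class Spectrum:
    """One reflectance trace on a strictly increasing wavenumber grid (cm⁻¹).

    ``kind`` distinguishes raw measurements, reconstructed baselines (which
    must be strictly positive because they are used as divisors), and
    baseline-corrected spectra (rBC).
    """

    wavenumbers: np.ndarray
    values: np.ndarray
    kind: str = "raw"

    def __post_init__(self):
        nu = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavenumbers", nu)
        object.__setattr__(self, "values", y)
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"kind must be one of {SPECTRUM_KINDS}, got {self.kind!r}")
        if nu.ndim != 1 or y.ndim != 1 or nu.shape != y.shape:
            raise ValueError("wavenumbers and values must be 1-d arrays of equal length")
        if nu.size < MIN_POINTS:
            raise ValueError(f"spectrum needs at least {MIN_POINTS} points, got {nu.size}")
        if not np.all(np.isfinite(nu)) or not np.all(np.isfinite(y)):
            raise ValueError("wavenumbers and values must be finite")
        if not np.all(np.diff(nu) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if self.kind == "baseline" and not np.all(y > 0):
            raise ValueError("baseline values must be strictly positive (they divide)")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def same_grid(self, other: "Spectrum") -> bool:
        return self.wavenumbers.shape == other.wavenumbers.shape and np.array_equal(
            self.wavenumbers, other.wavenumbers
        )

    def require_same_grid(self, other: "Spectrum") -> None:
        if not self.same_grid(other):
            raise GridMismatchError("spectra do not share a wavenumber grid")

    def with_values(self, values: np.ndarray, kind: Optional[str] = None) -> "Spectrum":
        return Spectrum(self.wavenumbers, np.asarray(values, float), kind or self.kind)


Condition = tuple[float, float]  # (c_glucose, c_fructose) in g/l


@dataclass
class MeasurementSet:
    """Replicate raw spectra acquired at one solution condition.

    ``condition`` is ``(c_glucose, c_fructose)`` in g/l, or ``None`` when the
    true concentrations are unknown (blind samples).
    """

    label: str
    condition: Optional[Condition]
    replicates: list[Spectrum]

    def __post_init__(self):
        if len(self.replicates) < 1:
            raise ValueError(f"set {self.label!r} has no replicate spectra")
        if self.condition is not None:
            cg, cf = self.condition
            if cg < 0 or cf < 0:
                raise ValueError(f"set {self.label!r}: concentrations must be >= 0")
            self.condition = (float(cg), float(cf))
        ref = self.replicates[0]
        for k, rep in enumerate(self.replicates[1:], start=1):
            if not ref.same_grid(rep):
                raise GridMismatchError(
                    f"set {self.label!r}: replicate {k} grid differs from replicate 0"
                )

    @property
    def is_water(self) -> bool:
        return self.condition == (0.0, 0.0)

    @property
    def grid(self) -> np.ndarray:
        return self.replicates[0].wavenumbers


@dataclass
class Cycle:
    """Ordered measurement sets from one flow-cell run.

    Water-constant calibration needs at least one pure-water set; a cycle
    without one is constructed with ``has_water=False`` (and a warning) so the
    failure surfaces at calibration time with context, not at load time.
    """

    name: str
    sets: list[MeasurementSet]
    has_water: bool = field(init=False)

    def __post_init__(self):
        if not self.sets:
            raise ValueError(f"cycle {self.name!r} has no sets")
        ref = self.sets[0].grid
        for s in self.sets[1:]:
            if not np.array_equal(ref, s.grid):
                raise GridMismatchError(
                    f"cycle {self.name!r}: set {s.label!r} is on a different grid"
                )
        self.has_water = any(s.is_water for s in self.sets)
        if not self.has_water:
            warnings.warn(
                f"cycle {self.name!r} contains no pure-water set; "
                "water-constant calibration will fail",
                stacklevel=2,
            )

    def water_sets(self) -> list[MeasurementSet]:
        return [s for s in self.sets if s.is_water]

    def analyte_sets(self) -> list[MeasurementSet]:
        return [s for s in self.sets if s.condition is None or not s.is_water]


@dataclass(frozen=True)
class Dialect:
    """Column/delimiter mapping for spectrum files.

    Exists so externally produced tables (different headers, TSV, comment
    conventions) can be read without conversion.
    """

    wavenumber_column: str = "wavenumber_cm-1"
    reflectance_column: str = "reflectance"
    delimiter: str = ","
    comment: str = "#"


DEFAULT_DIALECT = Dialect()


def read_spectrum(path, dialect: Dialect = DEFAULT_DIALECT, kind: str = "raw") -> Spectrum:
    """Read one spectrum from a delimited-text file.

    Rows are sorted by wavenumber; duplicate wavenumbers, non-numeric cells,
    missing columns and short files raise :class:`SpectrumParseError` naming
    the file (and row where identifiable).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=dialect.delimiter, comment=dialect.comment or None)
    except FileNotFoundError:
        raise ManifestError(f"spectrum file not found: {path}")
    except Exception as exc:  # malformed CSV
        raise SpectrumParseError(f"cannot parse delimited text: {exc}", path=path)

    for col in (dialect.wavenumber_column, dialect.reflectance_column):
        if col not in df.columns:
            raise SpectrumParseError(
                f"missing column {col!r} (found {list(df.columns)})", path=path
            )
    nu_raw = pd.to_numeric(df[dialect.wavenumber_column], errors="coerce")
    y_raw = pd.to_numeric(df[dialect.reflectance_column], errors="coerce")
    for name, series in ((dialect.wavenumber_column, nu_raw), (dialect.reflectance_column, y_raw)):
        bad = ~np.isfinite(series.to_numpy(dtype=float))
        if bad.any():
            row = int(np.argmax(bad))
            raise SpectrumParseError(
                f"non-numeric or non-finite value in column {name!r}", path=path, row=row
            )
    nu = nu_raw.to_numpy(dtype=float)
    y = y_raw.to_numpy(dtype=float)
    if nu.size < MIN_POINTS:
        raise SpectrumParseError(
            f"spectrum has {nu.size} rows; at least {MIN_POINTS} required", path=path
        )
    order = np.argsort(nu, kind="stable")
    nu, y = nu[order], y[order]
    dup = np.flatnonzero(np.diff(nu) == 0)
    if dup.size:
        raise SpectrumParseError(
            f"duplicated wavenumber {nu[dup[0]]:g} cm-1", path=path, row=int(dup[0])
        )
    try:
        return Spectrum(nu, y, kind=kind)
    except ValueError as exc:
        raise SpectrumParseError(str(exc), path=path)


def write_spectrum(spectrum: Spectrum, path, dialect: Dialect = DEFAULT_DIALECT) -> Path:
    """Write one spectrum as delimited text; float64 round-trips bit-exactly."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            f"{dialect.wavenumber_column}{dialect.delimiter}{dialect.reflectance_column}\n"
        )
        for nu, y in zip(spectrum.wavenumbers, spectrum.values):
            # shortest exact decimal repr of the float64 values
            fh.write(f"{float(nu)!r}{dialect.delimiter}{float(y)!r}\n")
    return path


MANIFEST_NAME = "cycle.json"


def write_cycle(cycle: Cycle, directory, dialect: Dialect = DEFAULT_DIALECT) -> Path:
    """Write a cycle as one file per replicate plus a JSON manifest.

    Returns the manifest path. ``read_cycle(write_cycle(c))`` reproduces the
    cycle bit-exactly on values and preserves set ordering.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"name": cycle.name, "sets": []}
    for i, mset in enumerate(cycle.sets):
        files = []
        for j, rep in enumerate(mset.replicates):
            fname = f"set{i:02d}_{_safe(mset.label)}_rep{j:02d}.csv"
            write_spectrum(rep, directory / fname, dialect)
            files.append(fname)
        cg, cf = (mset.condition if mset.condition is not None else (None, None))
        manifest["sets"].append(
            {
                "label": mset.label,
                "c_glucose_g_per_l": cg,
                "c_fructose_g_per_l": cf,
                "files": files,
            }
        )
    mpath = directory / MANIFEST_NAME
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return mpath


def read_cycle(manifest_path, dialect: Dialect = DEFAULT_DIALECT) -> Cycle:
    """Read a cycle from its manifest; inverse of :func:`write_cycle`."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    try:
        with open(manifest_path) as fh:
            manifest = json.load(fh)
    except FileNotFoundError:
        raise ManifestError(f"manifest not found: {manifest_path}")
    except json.JSONDecodeError as exc:
        raise ManifestError(f"manifest is not valid JSON: {manifest_path}: {exc}")
    if "name" not in manifest or "sets" not in manifest:
        raise ManifestError(f"manifest missing 'name' or 'sets': {manifest_path}")
    base = manifest_path.parent
    sets = []
    for entry in manifest["sets"]:
        cg = entry.get("c_glucose_g_per_l")
        cf = entry.get("c_fructose_g_per_l")
        condition = None if cg is None or cf is None else (float(cg), float(cf))
        files = entry.get("files", [])
        if not files:
            raise ManifestError(
                f"set {entry.get('label')!r} lists no spectrum files: {manifest_path}"
            )
        reps = []
        for fname in files:
            fpath = base / fname
            if not fpath.exists():
                raise ManifestError(f"spectrum file listed in manifest is missing: {fpath}")
            reps.append(read_spectrum(fpath, dialect))
        sets.append(MeasurementSet(label=entry["label"], condition=condition, replicates=reps))
    return Cycle(name=manifest["name"], sets=sets)


def _safe(label: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in label)
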