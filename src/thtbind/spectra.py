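"""Tabular spectroscopy I/O: spectra, decay histograms and experiment manifests.

File dialect is deliberately minimal: two (spectra) or three (decays) numeric
columns, comma or tab separated, optional single header line, ``#`` comment
lines skipped, decimal point only.  Wavelengths are nanometres, times are
nanoseconds, and manifest concentrations are molar throughout the package;
mixed µM/M bookkeeping is a classic source of silent 10⁶ errors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Spectrum", "DecayCurve", "ExperimentManifest", "SpectrumValidationError",
    "read_spectrum", "write_spectrum", "read_decay", "write_decay",
    "read_manifest", "write_manifest", "resample_to_grid",
]


class SpectrumValidationError(ValueError):
    """Raised when a spectrum, decay or manifest violates its invariants."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.array(x, dtype=float, copy=True)  # copy: instances freeze their arrays
    if arr.ndim != 1:
        raise SpectrumValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise SpectrumValidationError(f"{name} contains a non-finite value at index {bad}")
    return arr


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-resolved absorbance or fluorescence measurement.

    Parameters
    ----------
    wavelengths : array-like
        Strictly increasing wavelength grid in nm.
    values : array-like
        Absorbance (dimensionless, as measured — not path normalized) or
        fluorescence intensity (arbitrary units).
    mode : {"absorption", "emission"}
    path_length_cm : float
        Cuvette path length, cm.  Consumers normalize on demand.
    slit_nm : float, optional
        Spectral slit width metadata.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    mode: str = "absorption"
    path_length_cm: float = 1.0
    slit_nm: float | None = None

    def __post_init__(self):
        wl = _as_float_array(self.wavelengths, "wavelengths")
        vals = _as_float_array(self.values, "values")
        if wl.size != vals.size:
            raise SpectrumValidationError(
                f"grid and values differ in length ({wl.size} vs {vals.size})")
        dw = np.diff(wl)
        if wl.size > 1 and not np.all(dw > 0):
            bad = int(np.flatnonzero(dw <= 0)[0])
            raise SpectrumValidationError(
                f"wavelength grid not strictly increasing at index {bad} "
                f"({wl[bad]} -> {wl[bad + 1]} nm)")
        if self.mode not in ("absorption", "emission"):
            raise SpectrumValidationError(f"unknown spectrum mode {self.mode!r}")
        if not self.path_length_cm > 0:
            raise SpectrumValidationError("path_length_cm must be positive")
        wl.flags.writeable = False
        vals.flags.writeable = False
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.wavelengths.size

    def value_at(self, wavelength_nm: float) -> float:
        """Linearly interpolated value at one wavelength (no extrapolation)."""
        wl = self.wavelengths
        if not (wl[0] <= wavelength_nm <= wl[-1]):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside data range "
                f"[{wl[0]}, {wl[-1]}] nm")
        return float(np.interp(wavelength_nm, wl, self.values))

    def with_values(self, values) -> "Spectrum":
        """Copy of this spectrum with replaced values (same grid/metadata)."""
        return dataclasses.replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class DecayCurve:
    """TCSPC photon-count histogram with its instrument response function.

    ``time_ns`` must be uniformly binned; ``counts`` and ``irf_counts`` are
    non-negative and share the grid.
    """

    time_ns: np.ndarray
    counts: np.ndarray
    irf_counts: np.ndarray
    excitation_nm: float = 440.0
    emission_nm: float = 490.0

    def __post_init__(self):
        t = _as_float_array(self.time_ns, "time_ns")
        c = _as_float_array(self.counts, "counts")
        irf = _as_float_array(self.irf_counts, "irf_counts")
        if not (t.size == c.size == irf.size):
            raise SpectrumValidationError(
                "decay grid, counts and IRF must have identical length "
                f"({t.size}, {c.size}, {irf.size})")
        if t.size < 2:
            raise SpectrumValidationError("decay needs at least two bins")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12) or dt[0] <= 0:
            raise SpectrumValidationError("time bins must be uniform and increasing")
        if np.any(c < 0) or np.any(irf < 0):
            raise SpectrumValidationError("counts and IRF counts must be non-negative")
        for name, arr in (("time_ns", t), ("counts", c), ("irf_counts", irf)):
            arr.flags.writeable = False
            object.__setattr__(self, name, arr)

    @property
    def bin_width_ns(self) -> float:
        return float(self.time_ns[1] - self.time_ns[0])

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class ExperimentManifest:
    """One microdialysis titration point.

    C0_M is the total dye loaded into the dye chamber, Cp_M the fibril
    concentration in monomer-equivalent molar.
    """

    C0_M: float
    Cp_M: float
    path_length_cm: float = 1.0
    pH: float = 7.4
    gdnhcl_M: float = 0.0
    id: str = ""
    volume_ratio: float = 1.0  # sample/reference chamber volume; 1 for symmetric devices
    seed: int | None = None

    def __post_init__(self):
        if not self.C0_M > 0:
            raise SpectrumValidationError(f"C0_M must be positive, got {self.C0_M}")
        if self.Cp_M < 0:
            raise SpectrumValidationError(f"Cp_M must be non-negative, got {self.Cp_M}")
        if not self.path_length_cm > 0:
            raise SpectrumValidationError("path_length_cm must be positive")
        if self.gdnhcl_M < 0:
            raise SpectrumValidationError("gdnhcl_M must be non-negative")
        if not self.volume_ratio > 0:
            raise SpectrumValidationError("volume_ratio must be positive")


# ---------------------------------------------------------------------------
# file I/O


def _sniff_delimiter(line: str, dialect: str | None) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    return "," if line.count(",") >= line.count("\t") else "\t"


def _read_columns(path, n_cols: int, dialect: str | None = None) -> np.ndarray:
    """Read numeric columns, skipping '#' comments and one optional header."""
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(_sniff_delimiter(line, dialect))]
            try:
                vals = [float(p) for p in parts[:n_cols]]
            except ValueError:
                if not rows:  # tolerate a single header line
                    continue
                raise ValueError(
                    f"{path}:{lineno}: non-numeric cell in {line!r}") from None
            if len(vals) < n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} columns, got {len(vals)}")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no numeric data rows")
    return np.asarray(rows, dtype=float)


def read_spectrum(path, dialect: str | None = None, mode: str = "absorption",
                  path_length_cm: float = 1.0) -> Spectrum:
    """Read a two-column (wavelength, value) CSV/TSV spectrum."""
    data = _read_columns(path, 2, dialect)
    return Spectrum(data[:, 0], data[:, 1], mode=mode, path_length_cm=path_length_cm)


def write_spectrum(spectrum: Spectrum, path, dialect: str = "csv") -> None:
    sep = "," if dialect == "csv" else "\t"
    with open(path, "w") as fh:
        fh.write(f"# mode={spectrum.mode} path_length_cm={spectrum.path_length_cm!r}\n")
        fh.write(f"wavelength_nm{sep}value\n")
        for w, v in zip(spectrum.wavelengths, spectrum.values):
            fh.write(f"{float(w)!r}{sep}{float(v)!r}\n")


def read_decay(path, dialect: str | None = None, excitation_nm: float = 440.0,
               emission_nm: float = 490.0) -> DecayCurve:
    """Read a three-column (time_ns, counts, irf_counts) CSV/TSV decay."""
    data = _read_columns(path, 3, dialect)
    return DecayCurve(data[:, 0], data[:, 1], data[:, 2],
                      excitation_nm=excitation_nm, emission_nm=emission_nm)


def write_decay(decay: DecayCurve, path, dialect: str = "csv") -> None:
    sep = "," if dialect == "csv" else "\t"
    with open(path, "w") as fh:
        fh.write(f"time_ns{sep}counts{sep}irf_counts\n")
        for t, c, i in zip(decay.time_ns, decay.counts, decay.irf_counts):
            fh.write(f"{float(t)!r}{sep}{float(c)!r}{sep}{float(i)!r}\n")


_MANIFEST_KEYS = {f.name for f in dataclasses.fields(ExperimentManifest)}


def read_manifest(path) -> ExperimentManifest:
    """Read a YAML experiment manifest (keys C0_M, Cp_M, path_length_cm, ...)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: manifest must be a YAML mapping")
    unknown = set(raw) - _MANIFEST_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown manifest keys {sorted(unknown)}")
    return ExperimentManifest(**raw)


def write_manifest(manifest: ExperimentManifest, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(manifest), fh, sort_keys=False)


def resample_to_grid(spectrum: Spectrum, grid) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid (no extrapolation)."""
    grid = _as_float_array(grid, "grid")
    wl = spectrum.wavelengths
    if grid[0] < wl[0] or grid[-1] > wl[-1]:
        raise ValueError(
            f"target grid [{grid[0]}, {grid[-1]}] nm outside data range "
            f"[{wl[0]}, {wl[-1]}] nm (no extrapolation)")
    vals = np.interp(grid, wl, spectrum.values)
    return dataclasses.replace(spectrum, wavelengths=grid, values=vals)
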