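"""Spectra, fluorophores and instrument configurations: types and file I/O.

A fluorophore is described by a peak-normalized excitation spectrum (the
relative efficiency with which light of each wavelength excites it) and a
peak-normalized emission spectrum (the relative intensity it emits at each
wavelength), both resampled onto a common 1-nm integer grid.  An instrument
is a set of lasers and, per laser, bandpass-filtered detectors.

Canonical on-disk formats
-------------------------
Fluorophore library
    CSV with columns ``fluorophore,kind,wavelength_nm,intensity`` where
    ``kind`` is ``ex`` or ``em``; one row per sampled point.
Brightness table (optional)
    CSV with columns ``fluorophore,brightness``.  Brightness is the product
    of molar extinction coefficient and quantum yield; at load it is rescaled
    so the brightest library member has brightness 1.
Instrument configuration
    JSON or YAML::

        {name, lasers: [{name, wavelength_nm}],
         detectors: [{name, laser, bandpass_lo_nm, bandpass_hi_nm}],
         autofluorescence: {detector: value}}   # optional
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "WORKING_GRID",
    "Spectrum",
    "Fluorophore",
    "Laser",
    "Detector",
    "Instrument",
    "SpectraError",
    "resample_spectrum",
    "normalize_spectrum",
    "read_fluorophore_library",
    "write_fluorophore_library",
    "read_instrument_config",
    "write_instrument_config",
]

#: Common wavelength grid, 300-900 nm at 1-nm steps.  Covers the excitation
#: and emission of every visible-range fluorophore in common catalogues.
WORKING_GRID: np.ndarray = np.arange(300, 901, dtype=np.int64)
WORKING_GRID.setflags(write=False)


class SpectraError(ValueError):
    """Malformed spectrum, library or instrument input."""


@dataclass(frozen=True)
class Spectrum:
    """Relative intensity as a function of wavelength.

    Wavelengths are strictly ascending integers (nm); intensities are
    dimensionless and non-negative.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=np.int64)
        it = np.asarray(self.intensities, dtype=np.float64)
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size or wl.size == 0:
            raise SpectraError("spectrum needs matching 1-d wavelength/intensity arrays")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise SpectraError("wavelengths must be strictly ascending")
        if np.any(it < 0) or not np.all(np.isfinite(it)):
            raise SpectraError("intensities must be finite and >= 0")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)

    @property
    def peak_wavelength(self) -> int:
        return int(self.wavelengths[int(np.argmax(self.intensities))])

    def value_at(self, wavelength: float) -> float:
        """Linearly interpolated intensity; zero outside the support."""
        return float(np.interp(wavelength, self.wavelengths, self.intensities,
                               left=0.0, right=0.0))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (np.array_equal(self.wavelengths, other.wavelengths)
                and np.array_equal(self.intensities, other.intensities))


def resample_spectrum(spectrum: Spectrum, grid: np.ndarray = WORKING_GRID) -> Spectrum:
    """Resample onto `grid` by linear interpolation, zero outside the support.

    A single-point spectrum becomes a delta on the nearest grid point.
    Idempotent for spectra already on the grid.
    """
    grid = np.asarray(grid, dtype=np.int64)
    if spectrum.wavelengths.size == 1:
        values = np.zeros(grid.size)
        values[int(np.argmin(np.abs(grid - spectrum.wavelengths[0])))] = spectrum.intensities[0]
        return Spectrum(grid, values)
    values = np.interp(grid, spectrum.wavelengths, spectrum.intensities,
                       left=0.0, right=0.0)
    return Spectrum(grid, values)


def normalize_spectrum(spectrum: Spectrum) -> Spectrum:
    """Scale so the maximum intensity is exactly 1.

    Raises
    ------
    SpectraError
        If every intensity is zero.
    """
    peak = float(spectrum.intensities.max())
    if peak <= 0.0:
        raise SpectraError("cannot normalize an all-zero spectrum")
    if peak == 1.0:
        return spectrum
    return Spectrum(spectrum.wavelengths, spectrum.intensities / peak)


@dataclass(frozen=True)
class Fluorophore:
    """A fluorescent species: name, excitation/emission spectra, brightness.

    After library loading both spectra live on :data:`WORKING_GRID` with peak
    1, so excitation values read directly as efficiencies in [0, 1].
    ``brightness`` (if present) is normalized to the brightest library member.
    """

    name: str
    excitation: Spectrum
    emission: Spectrum
    brightness: float | None = None

    def on_grid(self, grid: np.ndarray = WORKING_GRID) -> "Fluorophore":
        """Return a copy with both spectra resampled and peak-normalized."""
        return replace(
            self,
            excitation=normalize_spectrum(resample_spectrum(self.excitation, grid)),
            emission=normalize_spectrum(resample_spectrum(self.emission, grid)),
        )


@dataclass(frozen=True)
class Laser:
    name: str
    wavelength: int

    def __post_init__(self) -> None:
        if not (WORKING_GRID[0] <= self.wavelength <= WORKING_GRID[-1]):
            raise SpectraError(
                f"laser {self.name!r}: wavelength {self.wavelength} nm outside "
                f"the working grid {WORKING_GRID[0]}-{WORKING_GRID[-1]} nm")


@dataclass(frozen=True)
class Detector:
    """A bandpass-filtered channel owned by one laser."""

    name: str
    laser: Laser
    bandpass_lo: int
    bandpass_hi: int

    def __post_init__(self) -> None:
        if self.bandpass_lo >= self.bandpass_hi:
            raise SpectraError(
                f"detector {self.name!r}: bandpass {self.bandpass_lo}-"
                f"{self.bandpass_hi} nm is empty (lo must be < hi)")


@dataclass(frozen=True)
class Instrument:
    """A cytometer configuration: lasers, detectors, optional autofluorescence.

    ``autofluorescence`` maps detector names to an additive background
    signal measured from unstained cells; it is treated as bleed-through,
    never as signal.
    """

    name: str
    lasers: tuple[Laser, ...]
    detectors: tuple[Detector, ...]
    autofluorescence: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "lasers", tuple(self.lasers))
        object.__setattr__(self, "detectors", tuple(self.detectors))
        names = [d.name for d in self.detectors]
        if len(set(names)) != len(names):
            raise SpectraError("detector names must be unique")
        known = {l.name for l in self.lasers}
        for d in self.detectors:
            if d.laser.name not in known:
                raise SpectraError(
                    f"detector {d.name!r} references unknown laser {d.laser.name!r}")
        unknown_af = set(self.autofluorescence) - set(names)
        if unknown_af:
            raise SpectraError(
                f"autofluorescence given for unknown detectors: {sorted(unknown_af)}")
        if any(v < 0 for v in self.autofluorescence.values()):
            raise SpectraError("autofluorescence baselines must be >= 0")

    @property
    def detector_names(self) -> list[str]:
        return [d.name for d in self.detectors]


# ---------------------------------------------------------------------------
# library I/O

_KINDS = ("ex", "em")


def read_fluorophore_library(path: str | Path,
                             brightness_path: str | Path | None = None
                             ) -> list[Fluorophore]:
    """Load a fluorophore library CSV, resampled and peak-normalized.

    Parameters
    ----------
    path
        CSV with columns ``fluorophore,kind,wavelength_nm,intensity``.
    brightness_path
        Optional CSV ``fluorophore,brightness``; values are rescaled so the
        library maximum is 1.

    Returns
    -------
    list of Fluorophore, in first-appearance order, spectra on the working
    grid with peak 1.
    """
    table = pd.read_csv(path, float_precision="round_trip")
    required = {"fluorophore", "kind", "wavelength_nm", "intensity"}
    if not required.issubset(table.columns):
        raise SpectraError(f"library file {path}: missing columns "
                           f"{sorted(required - set(table.columns))}")
    bad_kind = set(table["kind"].unique()) - set(_KINDS)
    if bad_kind:
        raise SpectraError(f"library file {path}: unknown kind values {sorted(bad_kind)}")

    brightness: dict[str, float] = {}
    if brightness_path is not None:
        btab = pd.read_csv(brightness_path, float_precision="round_trip")
        if not {"fluorophore", "brightness"}.issubset(btab.columns):
            raise SpectraError(f"brightness file {brightness_path}: need columns "
                               "'fluorophore' and 'brightness'")
        if btab["fluorophore"].duplicated().any():
            raise SpectraError("duplicate fluorophore in brightness table")
        brightness = dict(zip(btab["fluorophore"], btab["brightness"].astype(float)))

    names = list(dict.fromkeys(table["fluorophore"]))
    unknown_bright = set(brightness) - set(names)
    if unknown_bright:
        raise SpectraError(f"brightness given for unknown fluorophores: "
                           f"{sorted(unknown_bright)}")
    bmax = max(brightness.values()) if brightness else None
    if bmax is not None and bmax <= 0:
        raise SpectraError("brightness values must include a positive maximum")

    library: list[Fluorophore] = []
    for name in names:
        rows = table[table["fluorophore"] == name]
        spectra: dict[str, Spectrum] = {}
        for kind in _KINDS:
            sub = rows[rows["kind"] == kind].sort_values("wavelength_nm")
            if sub.empty:
                raise SpectraError(f"fluorophore {name!r}: no {kind!r} rows")
            if sub["wavelength_nm"].duplicated().any():
                raise SpectraError(f"fluorophore {name!r}: duplicate {kind!r} wavelengths")
            spec = Spectrum(sub["wavelength_nm"].to_numpy(dtype=np.int64),
                            sub["intensity"].to_numpy(dtype=np.float64))
            spec = resample_spectrum(spec)
            if spec.intensities.max() <= 0.0:
                raise SpectraError(
                    f"fluorophore {name!r}: {kind!r} spectrum has no positive "
                    "intensity on the working grid")
            spectra[kind] = normalize_spectrum(spec)
        b = brightness.get(name)
        library.append(Fluorophore(name, spectra["ex"], spectra["em"],
                                   None if b is None else b / bmax))
    return library


def write_fluorophore_library(library: list[Fluorophore], path: str | Path,
                              brightness_path: str | Path | None = None) -> None:
    """Write a library in the canonical CSV dialect (round-trips with read)."""
    rows = []
    for f in library:
        for kind, spec in (("ex", f.excitation), ("em", f.emission)):
            for wl, it in zip(spec.wavelengths, spec.intensities):
                rows.append((f.name, kind, int(wl), float(it)))
    pd.DataFrame(rows, columns=["fluorophore", "kind", "wavelength_nm", "intensity"]
                 ).to_csv(path, index=False)
    if brightness_path is not None:
        brows = [(f.name, f.brightness) for f in library if f.brightness is not None]
        pd.DataFrame(brows, columns=["fluorophore", "brightness"]
                     ).to_csv(brightness_path, index=False)


# ---------------------------------------------------------------------------
# instrument I/O

def read_instrument_config(path: str | Path) -> Instrument:
    """Load an instrument configuration from JSON or YAML."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise SpectraError(f"instrument config {path}: expected a mapping")
    try:
        lasers = {l["name"]: Laser(l["name"], int(l["wavelength_nm"]))
                  for l in data["lasers"]}
        detectors = []
        for d in data["detectors"]:
            if d["laser"] not in lasers:
                raise SpectraError(f"detector {d['name']!r} references unknown "
                                   f"laser {d['laser']!r}")
            detectors.append(Detector(d["name"], lasers[d["laser"]],
                                      int(d["bandpass_lo_nm"]), int(d["bandpass_hi_nm"])))
    except KeyError as exc:
        raise SpectraError(f"instrument config {path}: missing key {exc}") from exc
    return Instrument(
        name=data.get("name", Path(path).stem),
        lasers=tuple(lasers.values()),
        detectors=tuple(detectors),
        autofluorescence={k: float(v) for k, v in
                          (data.get("autofluorescence") or {}).items()},
    )


def write_instrument_config(instrument: Instrument, path: str | Path) -> None:
    """Write an instrument configuration as JSON (also valid YAML)."""
    data = {
        "name": instrument.name,
        "lasers": [{"name": l.name, "wavelength_nm": int(l.wavelength)}
                   for l in instrument.lasers],
        "detectors": [{"name": d.name, "laser": d.laser.name,
                       "bandpass_lo_nm": int(d.bandpass_lo),
                       "bandpass_hi_nm": int(d.bandpass_hi)}
                      for d in instrument.detectors],
    }
    if instrument.autofluorescence:
        data["autofluorescence"] = dict(instrument.autofluorescence)
    Path(path).write_text(json.dumps(data, indent=2) + "\n")
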