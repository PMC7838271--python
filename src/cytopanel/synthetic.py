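"""Synthetic fluorophore libraries, instruments and noisy measurements.

Stands in for catalogue spectra and real cytometer measurements so the whole
pipeline is exercisable offline.  Fluorophores get Gaussian excitation and
emission curves (peak-normalized, emission red-shifted by a positive Stokes
shift); instruments get a multi-laser layout with contiguous, non-overlapping
bandpass windows red of each laser line, mimicking common PMT-bank designs
(e.g. 5 lasers / 19 channels or 3 lasers / 7 channels).  Simulated
measurements are per-detector normalized predictions perturbed with
truncated Gaussian noise.

Everything is deterministic given the spec's seed, and generated libraries
round-trip exactly through the canonical CSV dialect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .panel_scoring import Panel
from .signal_model import SignalMatrix, normalize_per_detector
from .spectra_io import (Detector, Fluorophore, Instrument, Laser, Spectrum,
                         SpectraError, WORKING_GRID, normalize_spectrum)
from .validation import NormalizedPanelMatrix

__all__ = [
    "SyntheticSpec",
    "DEFAULT_LASER_WAVELENGTHS",
    "generate_fluorophore",
    "generate_library",
    "generate_instrument",
    "cytoflex_like_instrument",
    "macsquant_like_instrument",
    "simulate_measurements",
]

#: UV, violet, blue, yellow-green and red lines of a typical 5-laser cytometer.
DEFAULT_LASER_WAVELENGTHS = (355, 405, 488, 561, 638)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic fluorophore generator.

    Peak positions, Gaussian widths (sigma), Stokes shifts and brightness
    are drawn uniformly from the stated ranges.  The defaults give
    moderately overlapping visible-range spectra comparable to common
    fluorescent-protein libraries.
    """

    count: int = 8
    excitation_peak_range: tuple[int, int] = (380, 650)
    sigma_range: tuple[float, float] = (15.0, 30.0)
    stokes_range: tuple[float, float] = (20.0, 60.0)
    brightness_range: tuple[float, float] = (0.3, 1.0)
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.excitation_peak_range
        if not (WORKING_GRID[0] <= lo <= hi <= WORKING_GRID[-1]):
            raise SpectraError("excitation peaks must lie within the working grid")
        if self.stokes_range[0] <= 0:
            raise SpectraError("Stokes shifts must be positive")
        if self.count < 1:
            raise SpectraError("count must be >= 1")


def _gaussian(grid: np.ndarray, peak: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - peak) / sigma) ** 2)


def generate_fluorophore(spec: SyntheticSpec, rng: np.random.Generator,
                         name: str = "F001") -> Fluorophore:
    """Draw one Gaussian-spectrum fluorophore.

    The emission peak is the excitation peak plus a positive Stokes shift,
    so emission is always strictly red-shifted.  Both spectra live on the
    working grid with peak value 1.
    """
    ex_peak = rng.uniform(*spec.excitation_peak_range)
    stokes = rng.uniform(*spec.stokes_range)
    ex_sigma = rng.uniform(*spec.sigma_range)
    em_sigma = rng.uniform(*spec.sigma_range)
    brightness = rng.uniform(*spec.brightness_range)
    grid = np.asarray(WORKING_GRID, dtype=float)
    ex = normalize_spectrum(Spectrum(WORKING_GRID, _gaussian(grid, ex_peak, ex_sigma)))
    em = normalize_spectrum(Spectrum(WORKING_GRID,
                                     _gaussian(grid, ex_peak + stokes, em_sigma)))
    return Fluorophore(name, ex, em, brightness)


def generate_library(spec: SyntheticSpec) -> list[Fluorophore]:
    """Generate ``spec.count`` fluorophores named F001, F002, ...

    Deterministic given ``spec.seed``.  Brightness is rescaled so the
    brightest member has brightness exactly 1, as library loading would do.
    """
    rng = np.random.default_rng(spec.seed)
    library = [generate_fluorophore(spec, rng, name=f"F{i + 1:03d}")
               for i in range(spec.count)]
    bmax = max(f.brightness for f in library)
    return [Fluorophore(f.name, f.excitation, f.emission, f.brightness / bmax)
            for f in library]


def generate_instrument(n_lasers: int,
                        detectors_per_laser: int | Sequence[int],
                        laser_wavelengths: Sequence[int] = DEFAULT_LASER_WAVELENGTHS,
                        bandpass_width: int = 30,
                        offset: int = 10,
                        name: str = "synthetic") -> Instrument:
    """Build a layout of contiguous bandpass windows red of each laser line.

    Per laser, windows start ``offset`` nm red of the line and tile without
    gaps or overlap: [line+offset, line+offset+width], then the next window.

    Raises
    ------
    SpectraError
        If any window would extend past the working grid.
    """
    if isinstance(detectors_per_laser, int):
        per_laser = [detectors_per_laser] * n_lasers
    else:
        per_laser = list(detectors_per_laser)
    if len(per_laser) != n_lasers or len(laser_wavelengths) < n_lasers:
        raise SpectraError("need one detector count and wavelength per laser")
    lasers, detectors = [], []
    for i in range(n_lasers):
        laser = Laser(f"L{laser_wavelengths[i]}", int(laser_wavelengths[i]))
        lasers.append(laser)
        lo = laser.wavelength + offset
        for j in range(per_laser[i]):
            hi = lo + bandpass_width
            if hi > int(WORKING_GRID[-1]):
                raise SpectraError(
                    f"detector window {lo}-{hi} nm exceeds the working grid")
            detectors.append(Detector(f"{laser.name}-D{j + 1}", laser, lo, hi))
            lo = hi + 1
    return Instrument(name, tuple(lasers), tuple(detectors))


def cytoflex_like_instrument() -> Instrument:
    """A 5-laser, 19-detector layout (3 UV channels + 4 per visible laser)."""
    return generate_instrument(5, (3, 4, 4, 4, 4), name="synthetic-5L19D")


def macsquant_like_instrument() -> Instrument:
    """A 3-laser, 7-detector layout (2 + 3 + 2 channels)."""
    return generate_instrument(3, (2, 3, 2), laser_wavelengths=(405, 488, 561),
                               name="synthetic-3L7D")


def simulate_measurements(panel: Panel, matrix: SignalMatrix,
                          noise_sigma: float = 0.02,
                          seed: int = 0) -> NormalizedPanelMatrix:
    """Noisy stand-in for a measured normalized intensity matrix.

    Per-detector normalized predictions are perturbed with additive Gaussian
    noise, clipped at zero, and re-normalized per detector.  With
    ``noise_sigma = 0`` the result equals the normalized predictions exactly.
    """
    sub = matrix.values.loc[list(panel.fluorophores), list(panel.detectors)]
    normalized = normalize_per_detector(sub)
    if noise_sigma == 0:
        return NormalizedPanelMatrix(normalized, "measured")
    rng = np.random.default_rng(seed)
    noisy = np.clip(normalized.to_numpy()
                    + rng.normal(0.0, noise_sigma, normalized.shape), 0.0, None)
    frame = pd.DataFrame(noisy, index=normalized.index, columns=normalized.columns)
    return NormalizedPanelMatrix(normalize_per_detector(frame), "measured")
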