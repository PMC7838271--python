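"""Predicted per-detector signal for every fluorophore on an instrument.

The predicted signal of fluorophore *f* in detector *d* (owned by laser *l*)
is

    S(f, d) = ex_f(lambda_l) * (sum of em_f over the bandpass of d)
                               / (sum of em_f over the whole grid)
              [* brightness_f, optionally]

i.e. the monochromatic excitation efficiency at the laser line times the
fraction of the fluorophore's total emission falling inside the detector's
bandpass (inclusive endpoints, discrete 1-nm sum), optionally scaled by the
normalized molecular brightness.  All three factors lie in [0, 1], so does
the product.  Lasers are treated as monochromatic delta lines of equal
power, and each detector sees light only from its owning laser.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra_io import Detector, Fluorophore, Instrument, Laser, WORKING_GRID

__all__ = [
    "SignalMatrix",
    "SignalModelError",
    "excitation_efficiency",
    "emission_fraction",
    "predict_signal",
    "build_signal_matrix",
    "normalize_per_detector",
]


class SignalModelError(ValueError):
    pass


def excitation_efficiency(fluorophore: Fluorophore, laser: Laser) -> float:
    """Peak-normalized excitation intensity at the laser wavelength, in [0, 1]."""
    return fluorophore.excitation.value_at(laser.wavelength)


def emission_fraction(fluorophore: Fluorophore, detector: Detector) -> float:
    """Fraction of total emission captured by the detector's bandpass.

    Discrete sum over grid wavelengths with ``bandpass_lo <= w <= bandpass_hi``
    (both endpoints inclusive) divided by the sum over the full grid.
    """
    em = fluorophore.emission
    total = em.intensities.sum()
    if total <= 0.0:
        return 0.0
    mask = (em.wavelengths >= detector.bandpass_lo) & (em.wavelengths <= detector.bandpass_hi)
    return float(em.intensities[mask].sum() / total)


def predict_signal(fluorophore: Fluorophore, detector: Detector,
                   use_brightness: bool = False) -> float:
    """Predicted signal of one fluorophore in one detector, >= 0.

    With ``use_brightness`` the product is additionally scaled by the
    fluorophore's library-normalized brightness.
    """
    value = (excitation_efficiency(fluorophore, detector.laser)
             * emission_fraction(fluorophore, detector))
    if use_brightness:
        if fluorophore.brightness is None:
            raise SignalModelError(
                f"brightness requested but absent for {fluorophore.name!r}")
        value *= fluorophore.brightness
    return value


@dataclass(frozen=True)
class SignalMatrix:
    """Fluorophore x detector grid of predicted signals.

    ``values`` is a DataFrame indexed by fluorophore name with one column per
    detector.  ``autofluorescence`` holds the per-detector background that is
    added to bleed-through (all zero unless enabled at build time).
    """

    values: pd.DataFrame
    autofluorescence: pd.Series
    brightness_applied: bool = False
    autofluorescence_applied: bool = False

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr < 0)):
            raise SignalModelError("signal values must be finite and >= 0")
        if list(self.autofluorescence.index) != list(self.values.columns):
            raise SignalModelError("autofluorescence index must match detectors")

    @property
    def fluorophores(self) -> list[str]:
        return list(self.values.index)

    @property
    def detectors(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="fluorophore")


def build_signal_matrix(library: list[Fluorophore], instrument: Instrument,
                        use_brightness: bool = False,
                        use_autofluorescence: bool = False) -> SignalMatrix:
    """Predict the signal of every library fluorophore in every detector.

    Raises
    ------
    SignalModelError
        Empty library/instrument, duplicate names, or brightness requested
        while absent for some fluorophores (all offenders listed).
    """
    if not library:
        raise SignalModelError("library is empty")
    if not instrument.detectors:
        raise SignalModelError("instrument has no detectors")
    names = [f.name for f in library]
    if len(set(names)) != len(names):
        raise SignalModelError("duplicate fluorophore names in library")
    if use_brightness:
        missing = [f.name for f in library if f.brightness is None]
        if missing:
            raise SignalModelError(f"brightness requested but absent for: {missing}")

    grid_ok = [f if np.array_equal(f.excitation.wavelengths, WORKING_GRID)
               and np.array_equal(f.emission.wavelengths, WORKING_GRID)
               else f.on_grid() for f in library]
    values = np.empty((len(library), len(instrument.detectors)))
    for j, det in enumerate(instrument.detectors):
        for i, f in enumerate(grid_ok):
            values[i, j] = predict_signal(f, det, use_brightness)
    frame = pd.DataFrame(values, index=names, columns=instrument.detector_names)
    af = pd.Series(0.0, index=instrument.detector_names)
    if use_autofluorescence:
        for det, baseline in instrument.autofluorescence.items():
            af[det] = baseline
    return SignalMatrix(frame, af, brightness_applied=use_brightness,
                        autofluorescence_applied=use_autofluorescence)


def normalize_per_detector(values: pd.DataFrame) -> pd.DataFrame:
    """Scale each detector column so its maximum is 1.

    Raises
    ------
    SignalModelError
        Naming any detector whose values are all zero.
    """
    maxima = values.max(axis=0)
    dead = [str(c) for c in values.columns[maxima <= 0.0]]
    if dead:
        raise SignalModelError(f"detectors with all-zero values: {dead}")
    return values / maxima
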