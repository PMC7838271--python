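"""Panels, validity, the three-tier score, and the panel comparator.

An n-color panel assigns n distinct fluorophores to n distinct detectors.
A panel is *valid* when every assigned detector records strictly positive
signal for its own fluorophore.  Two panels are compared lexicographically:

1. number of detectors whose total bleed-through is within a fraction
   ``eta`` of their own signal (more is better; default eta = 0.10),
2. geometric mean of the assigned signals (higher is better),
3. arithmetic mean of the per-detector total bleed-through (lower is
   better),

and panels equal on all three tiers are equivalent.  Bleed-through in a
detector is the sum of the signals of all *other* panel fluorophores in
that detector, plus the detector's autofluorescence baseline when enabled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .signal_model import SignalMatrix

__all__ = [
    "ZERO_SIGNAL_CUTOFF",
    "DEFAULT_ETA",
    "Panel",
    "PanelScore",
    "PanelError",
    "detector_signal",
    "detector_bleedthrough",
    "is_valid",
    "score_panel",
    "compare_panels",
]

#: Signals at or below this are treated as zero when judging validity.
ZERO_SIGNAL_CUTOFF = 1e-12

#: Default tolerated bleed-through as a fraction of a detector's signal.
DEFAULT_ETA = 0.10


class PanelError(ValueError):
    pass


@dataclass(frozen=True)
class Panel:
    """n fluorophore -> detector assignments, pairwise distinct on both sides."""

    fluorophores: tuple[str, ...]
    detectors: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fluorophores", tuple(self.fluorophores))
        object.__setattr__(self, "detectors", tuple(self.detectors))
        if len(self.fluorophores) != len(self.detectors) or not self.fluorophores:
            raise PanelError("need equal, non-zero numbers of fluorophores and detectors")
        if len(set(self.fluorophores)) != len(self.fluorophores):
            raise PanelError("panel fluorophores must be distinct")
        if len(set(self.detectors)) != len(self.detectors):
            raise PanelError("panel detectors must be distinct")

    @property
    def n(self) -> int:
        return len(self.fluorophores)

    @property
    def assignments(self) -> list[tuple[str, str]]:
        return list(zip(self.fluorophores, self.detectors))

    def fluorophore_for(self, detector: str) -> str:
        try:
            return self.fluorophores[self.detectors.index(detector)]
        except ValueError:
            raise PanelError(f"detector {detector!r} is not assigned in this panel")

    def to_dict(self) -> dict[str, str]:
        return {d: f for f, d in self.assignments}


@dataclass(frozen=True)
class PanelScore:
    """Three-tier score of a panel at a given eta."""

    within_eta_count: int
    geomean_signal: float
    mean_bleedthrough: float
    eta: float
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.within_eta_count <= self.n):
            raise PanelError("within_eta_count must lie in [0, n]")
        for v in (self.geomean_signal, self.mean_bleedthrough):
            if not math.isfinite(v) or v < 0:
                raise PanelError("score components must be finite and >= 0")

    def sort_key(self) -> tuple[float, float, float]:
        """Ascending sort under this key ranks best panels first."""
        return (-self.within_eta_count, -self.geomean_signal, self.mean_bleedthrough)


def detector_signal(panel: Panel, matrix: SignalMatrix, detector: str) -> float:
    """Signal of the fluorophore the detector is meant to measure."""
    return float(matrix.values.at[panel.fluorophore_for(detector), detector])


def detector_bleedthrough(panel: Panel, matrix: SignalMatrix, detector: str) -> float:
    """Total off-target signal in a detector.

    Sum of the matrix entries of every other panel fluorophore in this
    detector, plus the detector's autofluorescence baseline.
    """
    own = panel.fluorophore_for(detector)
    col = matrix.values[detector]
    total = float(sum(col.at[f] for f in panel.fluorophores if f != own))
    return total + float(matrix.autofluorescence.at[detector])


def is_valid(panel: Panel, matrix: SignalMatrix) -> bool:
    """True iff every assigned detector sees strictly positive own signal."""
    return all(detector_signal(panel, matrix, d) > ZERO_SIGNAL_CUTOFF
               for d in panel.detectors)


def _score_arrays(S: np.ndarray, af: np.ndarray, f_idx: np.ndarray,
                  d_idx: np.ndarray, eta: float) -> tuple[int, float, float, int]:
    """Canonical scoring kernel: (within, geomean, mean_bleed, n_zero_signal).

    Every scoring path (single panels, the annealer, the vectorized
    enumerator) funnels through the same reduction recipe — assignments
    re-ordered by ascending fluorophore row, bleed computed as
    (column sum + autofluorescence) - own signal, and the two aggregates
    reduced over sorted values — so the score of a given panel is
    bit-identical everywhere and comparator ties behave deterministically.
    """
    order = np.argsort(f_idx)
    sub = S[np.ix_(f_idx[order], d_idx[order])]
    sig = sub.diagonal()
    bleed = (sub.sum(axis=0) + af[d_idx[order]]) - sig
    n_zero = int(np.count_nonzero(sig <= ZERO_SIGNAL_CUTOFF))
    within = int(np.count_nonzero(bleed <= eta * sig))
    geo = 0.0 if n_zero else float(np.exp(np.log(np.sort(sig)).mean()))
    return within, geo, float(np.sort(bleed).mean()), n_zero


def score_panel(panel: Panel, matrix: SignalMatrix, eta: float = DEFAULT_ETA) -> PanelScore:
    """Compute the three-tier score of a panel.

    The geometric mean is evaluated as exp(mean(log s)); any zero signal
    short-circuits it to 0, so a panel cannot hide a dead detector behind
    large signals elsewhere.  The within-eta test is inclusive
    (bleed <= eta * signal).
    """
    f_idx = matrix.values.index.get_indexer(list(panel.fluorophores))
    d_idx = matrix.values.columns.get_indexer(list(panel.detectors))
    if (f_idx < 0).any() or (d_idx < 0).any():
        raise PanelError("panel references fluorophores or detectors absent "
                         "from the signal matrix")
    within, geomean, mean_bleed, _ = _score_arrays(
        matrix.values.to_numpy(), matrix.autofluorescence.to_numpy(),
        f_idx, d_idx, eta)
    return PanelScore(within_eta_count=within, geomean_signal=geomean,
                      mean_bleedthrough=mean_bleed, eta=eta, n=panel.n)


def compare_panels(score_a: PanelScore, score_b: PanelScore) -> int:
    """Lexicographic comparison: 1 if A is better, -1 if B is, 0 if equivalent.

    Raises
    ------
    PanelError
        If the two scores were computed with different eta.
    """
    if score_a.eta != score_b.eta:
        raise PanelError(f"cannot compare scores with different eta "
                         f"({score_a.eta} vs {score_b.eta})")
    if score_a.within_eta_count != score_b.within_eta_count:
        return 1 if score_a.within_eta_count > score_b.within_eta_count else -1
    if score_a.geomean_signal != score_b.geomean_signal:
        return 1 if score_a.geomean_signal > score_b.geomean_signal else -1
    if score_a.mean_bleedthrough != score_b.mean_bleedthrough:
        return 1 if score_a.mean_bleedthrough < score_b.mean_bleedthrough else -1
    return 0
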