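"""Agreement between predicted and measured per-detector intensities.

Predicted and measured panel matrices are compared after per-detector
normalization (every detector's values scaled so its maximum is 1).  Two
agreement notions are used: *signals match* — in every detector the same
fluorophore carries the normalized value 1 in prediction and measurement —
and *within tolerance* — every (detector, fluorophore) entry differs by at
most a tolerance (0.05, 0.10 and 0.20 by default; comparisons inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel_scoring import Panel, detector_bleedthrough, detector_signal
from .signal_model import SignalMatrix, normalize_per_detector

__all__ = [
    "DEFAULT_TOLERANCES",
    "NormalizedPanelMatrix",
    "ValidationError",
    "predicted_panel_matrix",
    "read_measured_matrix",
    "signals_match",
    "within_tolerance",
    "agreement_summary",
    "bleedthrough_report",
]

DEFAULT_TOLERANCES = (0.05, 0.10, 0.20)

_TIE_EPS = 1e-9  # two entries both at 1 within this are an ambiguous argmax


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizedPanelMatrix:
    """Per-detector normalized intensities of a panel's fluorophores.

    ``values``: DataFrame, fluorophore rows x detector columns, each column
    max exactly 1 and all entries in [0, 1].  ``source`` is ``"predicted"``
    or ``"measured"``.
    """

    values: pd.DataFrame
    source: str

    def __post_init__(self) -> None:
        if self.source not in ("predicted", "measured"):
            raise ValidationError("source must be 'predicted' or 'measured'")
        arr = self.values.to_numpy(dtype=float)
        if np.any(arr < 0) or np.any(arr > 1 + 1e-12):
            raise ValidationError("normalized values must lie in [0, 1]")
        if arr.size and not np.allclose(arr.max(axis=0), 1.0, atol=1e-9):
            raise ValidationError("each detector column must have maximum 1")


def predicted_panel_matrix(panel: Panel, matrix: SignalMatrix) -> NormalizedPanelMatrix:
    """Restrict a signal matrix to the panel and normalize per detector."""
    sub = matrix.values.loc[list(panel.fluorophores), list(panel.detectors)]
    return NormalizedPanelMatrix(normalize_per_detector(sub), "predicted")


def read_measured_matrix(path: str | Path, panel: Panel) -> NormalizedPanelMatrix:
    """Load measured normalized intensities from CSV ``detector,fluorophore,value``."""
    table = pd.read_csv(path, float_precision="round_trip")
    need = {"detector", "fluorophore", "value"}
    if not need.issubset(table.columns):
        raise ValidationError(f"measured matrix {path}: missing columns "
                              f"{sorted(need - set(table.columns))}")
    frame = table.pivot(index="fluorophore", columns="detector", values="value")
    missing = (set(panel.fluorophores) - set(frame.index)
               | set(panel.detectors) - set(frame.columns))
    if missing or frame.isna().any().any():
        raise ValidationError(f"measured matrix {path}: incomplete panel coverage")
    frame = frame.loc[list(panel.fluorophores), list(panel.detectors)]
    return NormalizedPanelMatrix(frame, "measured")


def _aligned(predicted: NormalizedPanelMatrix, measured: NormalizedPanelMatrix,
             panel: Panel) -> tuple[pd.DataFrame, pd.DataFrame]:
    fl, dt = list(panel.fluorophores), list(panel.detectors)
    for m, label in ((predicted, "predicted"), (measured, "measured")):
        if (not set(fl) <= set(m.values.index)
                or not set(dt) <= set(m.values.columns)):
            raise ValidationError(f"{label} matrix does not cover the panel")
    return predicted.values.loc[fl, dt], measured.values.loc[fl, dt]


def signals_match(predicted: NormalizedPanelMatrix, measured: NormalizedPanelMatrix,
                  panel: Panel) -> bool:
    """True iff each detector's value-1 fluorophore agrees in both matrices.

    Raises
    ------
    ValidationError
        If any detector carries two entries at 1 (ambiguous argmax).
    """
    p, m = _aligned(predicted, measured, panel)
    for frame, label in ((p, "predicted"), (m, "measured")):
        for det in frame.columns:
            col = frame[det].to_numpy()
            if np.count_nonzero(col >= 1.0 - _TIE_EPS) > 1:
                raise ValidationError(
                    f"{label} matrix: detector {det!r} has a tied maximum; "
                    "resolve manually")
    return all(p[det].idxmax() == m[det].idxmax() for det in p.columns)


def within_tolerance(predicted: NormalizedPanelMatrix,
                     measured: NormalizedPanelMatrix,
                     panel: Panel, tol: float) -> bool:
    """True iff every entry differs by at most ``tol`` (inclusive)."""
    if tol <= 0:
        raise ValidationError("tolerance must be > 0")
    p, m = _aligned(predicted, measured, panel)
    return bool((np.abs(p.to_numpy() - m.to_numpy()) <= tol).all())


def agreement_summary(panels: Sequence[Panel],
                      predicted: Sequence[NormalizedPanelMatrix],
                      measured: Sequence[NormalizedPanelMatrix],
                      tols: Sequence[float] = DEFAULT_TOLERANCES) -> pd.DataFrame:
    """Percent of panels passing each agreement metric.

    Returns a one-row-per-metric DataFrame with columns ``metric`` and
    ``percent``: ``signals_match`` plus ``within_<tol>`` for each tolerance.
    """
    if not panels or len(panels) != len(predicted) or len(panels) != len(measured):
        raise ValidationError("need equal, non-empty panel/prediction/measurement lists")
    rows = [("signals_match",
             100.0 * sum(signals_match(p, m, pn) for pn, p, m
                         in zip(panels, predicted, measured)) / len(panels))]
    for tol in tols:
        passing = sum(within_tolerance(p, m, pn, tol)
                      for pn, p, m in zip(panels, predicted, measured))
        rows.append((f"within_{tol:.2f}", 100.0 * passing / len(panels)))
    return pd.DataFrame(rows, columns=["metric", "percent"])


def bleedthrough_report(panel: Panel, matrix: SignalMatrix,
                        eta: float = 0.10) -> pd.DataFrame:
    """Per-detector signal, bleed-through, their ratio and the within-eta flag.

    The report's ``within_eta`` count (sum of the flag column) is the first
    tier of the panel score.
    """
    rows = []
    for det in panel.detectors:
        sig = detector_signal(panel, matrix, det)
        bleed = detector_bleedthrough(panel, matrix, det)
        ratio = bleed / sig if sig > 0 else np.inf
        rows.append({"detector": det,
                     "fluorophore": panel.fluorophore_for(det),
                     "signal": sig, "bleedthrough": bleed,
                     "bleed_over_signal": ratio,
                     "within_eta": bleed <= eta * sig})
    return pd.DataFrame(rows)
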