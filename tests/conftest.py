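import numpy as np
import pandas as pd
import pytest

import cytopanel as cp
from cytopanel.signal_model import SignalMatrix


def make_matrix(values: dict[str, dict[str, float]],
                autofluorescence: dict[str, float] | None = None) -> SignalMatrix:
    """Hand-built signal matrix from {fluorophore: {detector: value}}."""
    frame = pd.DataFrame(values).T
    af = pd.Series(0.0, index=frame.columns)
    applied = False
    if autofluorescence:
        for det, value in autofluorescence.items():
            af[det] = value
        applied = True
    return SignalMatrix(frame, af, autofluorescence_applied=applied)


@pytest.fixture
def toy_matrix() -> SignalMatrix:
    """Two fluorophores on two detectors with small cross-talk."""
    return make_matrix({
        "f1": {"d1": 0.9, "d2": 0.02},
        "f2": {"d1": 0.05, "d2": 0.8},
    })


@pytest.fixture
def toy_panel() -> cp.Panel:
    return cp.Panel(("f1", "f2"), ("d1", "d2"))


@pytest.fixture(scope="session")
def small_library() -> list[cp.Fluorophore]:
    return cp.generate_library(cp.SyntheticSpec(count=5, seed=7))


@pytest.fixture(scope="session")
def small_instrument() -> cp.Instrument:
    return cp.macsquant_like_instrument()


@pytest.fixture(scope="session")
def flex_library() -> list[cp.Fluorophore]:
    """The default 8-fluorophore synthetic library."""
    return cp.generate_library(cp.SyntheticSpec())


@pytest.fixture(scope="session")
def flex_instrument() -> cp.Instrument:
    """The 5-laser / 19-detector synthetic layout."""
    return cp.cytoflex_like_instrument()


@pytest.fixture(scope="session")
def flex_matrix(flex_library, flex_instrument) -> SignalMatrix:
    return cp.build_signal_matrix(flex_library, flex_instrument)


def random_matrix(rng: np.random.Generator, n_fluor: int, n_det: int,
                  zero_fraction: float = 0.5) -> SignalMatrix:
    """Random sparse signal matrix for oracle tests."""
    values = rng.random((n_fluor, n_det))
    values[rng.random((n_fluor, n_det)) < zero_fraction] = 0.0
    frame = pd.DataFrame(values,
                         index=[f"f{i}" for i in range(n_fluor)],
                         columns=[f"d{j}" for j in range(n_det)])
    return SignalMatrix(frame, pd.Series(0.0, index=frame.columns))
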