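"""Exhaustive and simulated-annealing search over n-color panel space.

The space of n-color panels for a library of F fluorophores and an
instrument with D detectors has C(F, n) * P(D, n) members: choose the n
fluorophores, then assign them injectively to detectors.  Small spaces are
searched exhaustively (vectorized, subset by subset); large ones with
multistart simulated annealing over a scalar surrogate energy whose tier-1
term dominates, so that a one-detector improvement in the within-eta count
always outweighs any change in the lower tiers.  Candidate answers are
always ranked with the exact lexicographic comparator, never the surrogate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .panel_scoring import (DEFAULT_ETA, Panel, PanelScore, ZERO_SIGNAL_CUTOFF,
                            _score_arrays, compare_panels)
from .signal_model import SignalMatrix, build_signal_matrix
from .spectra_io import Fluorophore, Instrument

__all__ = [
    "SAParams",
    "SearchError",
    "NoValidPanelError",
    "count_panels",
    "enumerate_panels",
    "count_valid_panels",
    "exhaustive_search",
    "panel_ranks",
    "propose_neighbor",
    "sa_energy",
    "simulated_annealing",
    "multistart_sa",
]

#: Refuse exhaustive search above this many panels unless forced.
EXHAUSTIVE_BUDGET = 10**8

_BLOCK = 200_000  # detector-arrangement rows scored per vectorized block


class SearchError(ValueError):
    pass


class NoValidPanelError(RuntimeError):
    """Raised when a search finds no valid panel at all."""


# ---------------------------------------------------------------------------
# counting and enumeration

def count_panels(n_fluorophores: int, n_detectors: int, n: int) -> int:
    """Exact size of the n-color panel space: C(F, n) * P(D, n)."""
    if n < 1 or n > n_fluorophores or n > n_detectors:
        raise SearchError(f"panel size {n} must satisfy 1 <= n <= "
                          f"min(F={n_fluorophores}, D={n_detectors})")
    return math.comb(n_fluorophores, n) * math.perm(n_detectors, n)


def enumerate_panels(library: Sequence[Fluorophore] | Sequence[str],
                     instrument: Instrument | Sequence[str],
                     n: int) -> Iterator[Panel]:
    """Yield every distinct panel once, in deterministic order.

    Order is lexicographic by fluorophore subset (library order), then by
    detector arrangement (permutation order).  Accepts either full objects
    or plain name sequences.
    """
    fnames = [f.name if isinstance(f, Fluorophore) else f for f in library]
    dnames = (instrument.detector_names if isinstance(instrument, Instrument)
              else list(instrument))
    count_panels(len(fnames), len(dnames), n)  # validates n
    for combo in itertools.combinations(fnames, n):
        for arrangement in itertools.permutations(dnames, n):
            yield Panel(combo, arrangement)


def count_valid_panels(matrix: SignalMatrix, n: int) -> int:
    """Exact number of valid n-color panels, by census rather than enumeration.

    Works on the boolean signal > 0 matrix: for each n-subset of
    fluorophores, counts injective fluorophore -> detector assignments whose
    every pair has positive signal (a rectangular-permanent count, computed
    by memoized recursion over used-detector bitmasks).  Exact integer.
    """
    B = matrix.values.to_numpy() > ZERO_SIGNAL_CUTOFF
    F, D = B.shape
    count_panels(F, D, n)  # validates n
    allowed = [sum(1 << j for j in range(D) if B[i, j]) for i in range(F)]

    def injective_count(rows: tuple[int, ...]) -> int:
        memo: dict[tuple[int, int], int] = {}

        def rec(i: int, used: int) -> int:
            if i == len(rows):
                return 1
            key = (i, used)
            hit = memo.get(key)
            if hit is not None:
                return hit
            free = allowed[rows[i]] & ~used
            total = 0
            while free:
                bit = free & -free
                total += rec(i + 1, used | bit)
                free ^= bit
            memo[key] = total
            return total

        return rec(0, 0)

    return sum(injective_count(rows)
               for rows in itertools.combinations(range(F), n))


# ---------------------------------------------------------------------------
# vectorized scoring core

def _perm_array(n_detectors: int, n: int) -> np.ndarray:
    total = math.perm(n_detectors, n)
    flat = np.fromiter(
        itertools.chain.from_iterable(itertools.permutations(range(n_detectors), n)),
        dtype=np.int16, count=total * n)
    return flat.reshape(total, n)


def _scored_blocks(S: np.ndarray, af: np.ndarray, n: int, eta: float):
    """Yield scored blocks of the full panel space.

    Yields tuples (subset_index, subset_rows, perm_offset, perm_block,
    valid, within, geomean, mean_bleed) covering every panel exactly once in
    enumeration order.
    """
    F, D = S.shape
    perms = _perm_array(D, n)
    col_extra = af  # added to every bleed-through total
    for s_idx, rows in enumerate(itertools.combinations(range(F), n)):
        S_sub = S[list(rows)]                     # (n, D)
        colsum = S_sub.sum(axis=0) + col_extra    # (D,)
        for off in range(0, perms.shape[0], _BLOCK):
            block = perms[off:off + _BLOCK]       # (B, n)
            sig = S_sub[np.arange(n)[None, :], block]
            bleed = colsum[block] - sig  # colsum already includes autofluorescence
            valid = (sig > ZERO_SIGNAL_CUTOFF).all(axis=1)
            within = (bleed <= eta * sig).sum(axis=1)
            # aggregate over sorted values so a panel's score is bit-identical
            # regardless of the order its assignments are listed in
            with np.errstate(divide="ignore"):
                geo = np.where(valid,
                               np.exp(np.log(np.maximum(np.sort(sig, axis=1),
                                                        1e-300)).mean(axis=1)),
                               0.0)
            yield (s_idx, rows, off, block, valid, within, geo,
                   np.sort(bleed, axis=1).mean(axis=1))


def _resolve_matrix(library, instrument, matrix: SignalMatrix | None,
                    use_brightness: bool, use_autofluorescence: bool) -> SignalMatrix:
    if matrix is not None:
        return matrix
    return build_signal_matrix(library, instrument, use_brightness,
                               use_autofluorescence)


def exhaustive_search(library: Sequence[Fluorophore], instrument: Instrument,
                      n: int, eta: float = DEFAULT_ETA,
                      top_k: int | None = None, *,
                      use_brightness: bool = False,
                      use_autofluorescence: bool = False,
                      matrix: SignalMatrix | None = None,
                      force: bool = False) -> list[tuple[Panel, PanelScore]]:
    """Score every panel and return the valid ones, best first.

    Ties under the comparator keep enumeration order, so the ranking is
    deterministic.  Refuses spaces above :data:`EXHAUSTIVE_BUDGET` panels
    unless ``force`` is set.

    Returns an empty list when no panel is valid.
    """
    matrix = _resolve_matrix(library, instrument, matrix,
                             use_brightness, use_autofluorescence)
    S = matrix.values.to_numpy()
    af = matrix.autofluorescence.to_numpy()
    F, D = S.shape
    total = count_panels(F, D, n)
    if total > EXHAUSTIVE_BUDGET and not force:
        raise SearchError(
            f"{total} panels exceed the exhaustive budget of {EXHAUSTIVE_BUDGET}; "
            "pass force=True to override")

    fnames = matrix.fluorophores
    dnames = matrix.detectors
    keep = total if top_k is None else top_k
    # accumulated candidate pool, pruned to `keep` after each block
    pool: dict[str, np.ndarray] = {}

    def _prune(cand: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        order = np.lexsort((cand["gidx"], cand["bleed"], -cand["geo"], -cand["within"]))
        order = order[:keep]
        return {k: v[order] for k, v in cand.items()}

    P_total = math.perm(D, n)
    for s_idx, rows, off, block, valid, within, geo, bleed in _scored_blocks(
            S, af, n, eta):
        idx = np.flatnonzero(valid)
        if idx.size == 0:
            continue
        gidx = np.int64(s_idx) * P_total + off + idx
        cand = {
            "within": within[idx].astype(np.int64),
            "geo": geo[idx],
            "bleed": bleed[idx],
            "gidx": gidx,
            "subset": np.full(idx.size, s_idx, dtype=np.int64),
            "perm": (off + idx).astype(np.int64),
        }
        if pool:
            pool = {k: np.concatenate([pool[k], cand[k]]) for k in cand}
        else:
            pool = cand
        if pool["gidx"].size > 4 * max(keep, 1):
            pool = _prune(pool)
    if not pool:
        return []
    pool = _prune(pool)

    combos = list(itertools.combinations(range(F), n))
    results: list[tuple[Panel, PanelScore]] = []
    for within, geo, bleed, s_idx, p_idx in zip(
            pool["within"], pool["geo"], pool["bleed"], pool["subset"], pool["perm"]):
        rows = combos[int(s_idx)]
        arrangement = _nth_permutation(D, n, int(p_idx))
        panel = Panel(tuple(fnames[r] for r in rows),
                      tuple(dnames[d] for d in arrangement))
        results.append((panel, PanelScore(int(within), float(geo), float(bleed),
                                          eta, n)))
    return results


def _nth_permutation(n_items: int, k: int, index: int) -> tuple[int, ...]:
    """The index-th k-permutation of range(n_items), in itertools order."""
    pool = list(range(n_items))
    out = []
    for pos in range(k):
        stride = math.perm(n_items - pos - 1, k - pos - 1)
        q, index = divmod(index, stride)
        out.append(pool.pop(q))
    return tuple(out)


def panel_ranks(matrix: SignalMatrix, n: int, eta: float,
                scores: Sequence[PanelScore]) -> list[int]:
    """Rank of each score within the full valid-panel space.

    Rank = 1 + number of valid panels strictly better under the comparator;
    equivalent panels share the lowest rank.  Streams over the whole space
    once regardless of how many query scores are given.
    """
    S = matrix.values.to_numpy()
    af = matrix.autofluorescence.to_numpy()
    triples = [(s.within_eta_count, s.geomean_signal, s.mean_bleedthrough)
               for s in scores]
    unique = sorted(set(triples))
    which = {t: i for i, t in enumerate(unique)}
    better = np.zeros(len(unique), dtype=np.int64)
    for _, _, _, _, valid, within, geo, bleed in _scored_blocks(S, af, n, eta):
        idx = np.flatnonzero(valid)
        if idx.size == 0:
            continue
        w, g, b = within[idx], geo[idx], bleed[idx]
        for i, (qw, qg, qb) in enumerate(unique):
            better[i] += int(np.count_nonzero(
                (w > qw)
                | ((w == qw) & (g > qg))
                | ((w == qw) & (g == qg) & (b < qb))))
    return [int(better[which[t]]) + 1 for t in triples]


# ---------------------------------------------------------------------------
# simulated annealing

@dataclass(frozen=True)
class SAParams:
    """Geometric-cooling schedule and restart policy.

    The run length is derived from the schedule:
    ceil(ln(min_temperature / initial_temperature) / ln(cooling_rate)),
    9,206 iterations under the defaults.
    """

    initial_temperature: float = 1.0
    cooling_rate: float = 0.999
    min_temperature: float = 1e-4
    restarts: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.cooling_rate < 1):
            raise SearchError("cooling_rate must lie in (0, 1)")
        if not (0 < self.min_temperature < self.initial_temperature):
            raise SearchError("need 0 < min_temperature < initial_temperature")
        if self.restarts < 1:
            raise SearchError("restarts must be >= 1")

    @property
    def n_steps(self) -> int:
        return math.ceil(math.log(self.min_temperature / self.initial_temperature)
                         / math.log(self.cooling_rate))

    @classmethod
    def large_problem(cls, restarts: int = 50, seed: int = 0) -> "SAParams":
        """Hotter start and slower cooling for very large panel spaces."""
        return cls(initial_temperature=10.0, cooling_rate=0.9995,
                   min_temperature=1e-4, restarts=restarts, seed=seed)


def propose_neighbor(panel: Panel, library: Sequence[Fluorophore] | Sequence[str],
                     instrument: Instrument | Sequence[str],
                     rng: np.random.Generator) -> Panel:
    """One random elementary move on a panel.

    With probability 1/2 swap a panel fluorophore for an unused library
    fluorophore; otherwise move one assignment to an unused detector.  When
    no fluorophore is unused the move is always a detector move, and when no
    detector is unused either, two assigned detector slots are swapped.
    """
    fnames = [f.name if isinstance(f, Fluorophore) else f for f in library]
    dnames = (instrument.detector_names if isinstance(instrument, Instrument)
              else list(instrument))
    f_idx = np.array([fnames.index(f) for f in panel.fluorophores])
    d_idx = np.array([dnames.index(d) for d in panel.detectors])
    f_idx, d_idx = _neighbor_idx(f_idx, d_idx, len(fnames), len(dnames), rng)
    return Panel(tuple(fnames[i] for i in f_idx), tuple(dnames[i] for i in d_idx))


def _neighbor_idx(f_idx: np.ndarray, d_idx: np.ndarray, F: int, D: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = f_idx.size
    if F == n and D == n and n == 1:
        return f_idx, d_idx  # 1x1x1 space has no neighbors
    swap_fluor = F > n and rng.random() < 0.5
    slot = int(rng.integers(n))
    if swap_fluor:
        unused = np.setdiff1d(np.arange(F), f_idx, assume_unique=False)
        f_idx = f_idx.copy()
        f_idx[slot] = unused[int(rng.integers(unused.size))]
    else:
        d_idx = d_idx.copy()
        if D > n:
            unused = np.setdiff1d(np.arange(D), d_idx, assume_unique=False)
            d_idx[slot] = unused[int(rng.integers(unused.size))]
        else:
            other = int(rng.integers(n - 1))
            other = other if other < slot else other + 1
            d_idx[slot], d_idx[other] = d_idx[other], d_idx[slot]
    return f_idx, d_idx


def _steepest_descent(S: np.ndarray, af: np.ndarray, f_idx: np.ndarray,
                      d_idx: np.ndarray, eta: float
                      ) -> tuple[tuple, np.ndarray, np.ndarray]:
    """Greedy comparator descent from a valid panel to a local optimum.

    Explores single fluorophore swaps, single detector moves, within-panel
    detector exchanges, and compound moves (replace a fluorophore and move
    its detector in one step); takes the best strictly-improving neighbor
    until none exists.  The compound moves let the descent cross ridges
    where changing the fluorophore alone would transiently lose validity.
    Deterministic: candidates are examined in a fixed order.
    """
    F, D = S.shape
    n = f_idx.size

    def key(f: np.ndarray, d: np.ndarray):
        w, g, b, z = _score_arrays(S, af, f, d, eta)
        return None if z else (w, g, -b)

    current = key(f_idx, d_idx)
    while True:
        best = None
        unused_f = np.setdiff1d(np.arange(F), f_idx)
        unused_d = np.setdiff1d(np.arange(D), d_idx)
        candidates: list[tuple[np.ndarray, np.ndarray]] = []
        for slot in range(n):
            for fu in unused_f:
                f2 = f_idx.copy()
                f2[slot] = fu
                candidates.append((f2, d_idx))
                for du in unused_d:
                    d2 = d_idx.copy()
                    d2[slot] = du
                    candidates.append((f2, d2))
            for du in unused_d:
                d2 = d_idx.copy()
                d2[slot] = du
                candidates.append((f_idx, d2))
        for a, b in itertools.combinations(range(n), 2):
            d2 = d_idx.copy()
            d2[a], d2[b] = d2[b], d2[a]
            candidates.append((f_idx, d2))
        for f2, d2 in candidates:
            k = key(f2, d2)
            if k is not None and (best is None or k > best[0]):
                best = (k, f2, d2)
        if best is None or best[0] <= current:
            return current, f_idx, d_idx
        current, f_idx, d_idx = best


def sa_energy(panel: Panel, matrix: SignalMatrix, eta: float = DEFAULT_ETA,
              n: int | None = None) -> float:
    """Scalar surrogate of the lexicographic objective; lower is better.

    E = (n - within_eta) + 0.5 * (1 - min(geomean, 1))
        + 0.25 * min(mean_bleed, 1) + n * (#detectors with zero signal).

    A tier-1 difference contributes at least 1 while the two lower tiers
    together contribute at most 0.75, so tier-1 order is preserved; zero
    E only for a perfect panel.
    """
    n = panel.n if n is None else n
    fmap = {name: i for i, name in enumerate(matrix.fluorophores)}
    dmap = {name: i for i, name in enumerate(matrix.detectors)}
    f_idx = np.array([fmap[f] for f in panel.fluorophores])
    d_idx = np.array([dmap[d] for d in panel.detectors])
    parts = _score_arrays(matrix.values.to_numpy(), matrix.autofluorescence.to_numpy(),
                       f_idx, d_idx, eta)
    return _energy(*parts, n=n)


def _energy(within: int, geo: float, bleed: float, n_zero: int, n: int) -> float:
    return ((n - within) + 0.5 * (1.0 - min(geo, 1.0))
            + 0.25 * min(bleed, 1.0) + n * n_zero)


def simulated_annealing(library: Sequence[Fluorophore] | None,
                        instrument: Instrument | None, n: int,
                        eta: float = DEFAULT_ETA,
                        params: SAParams = SAParams(),
                        seed: int | None = None, *,
                        use_brightness: bool = False,
                        use_autofluorescence: bool = False,
                        matrix: SignalMatrix | None = None
                        ) -> tuple[Panel, PanelScore]:
    """One simulated-annealing run; deterministic given its seed.

    Starts from a random panel (re-drawn up to 100 times seeking validity),
    proposes elementary moves, accepts improvements always and worsenings
    with probability exp(-dE / T) under geometric cooling, tracks the best
    *valid* panel seen anywhere along the run under the exact lexicographic
    comparator, and finishes with a deterministic steepest comparator
    descent from that panel.

    Raises
    ------
    NoValidPanelError
        If no valid panel was encountered during the whole run.
    """
    matrix = _resolve_matrix(library, instrument, matrix,
                             use_brightness, use_autofluorescence)
    S = matrix.values.to_numpy()
    af = matrix.autofluorescence.to_numpy()
    F, D = S.shape
    count_panels(F, D, n)  # validates n
    rng = np.random.default_rng(params.seed if seed is None else seed)

    f_idx = rng.choice(F, size=n, replace=False)
    d_idx = rng.choice(D, size=n, replace=False)
    within, geo, bleed, n_zero = _score_arrays(S, af, f_idx, d_idx, eta)
    for _ in range(100):
        if n_zero == 0:
            break
        f_idx = rng.choice(F, size=n, replace=False)
        d_idx = rng.choice(D, size=n, replace=False)
        within, geo, bleed, n_zero = _score_arrays(S, af, f_idx, d_idx, eta)

    energy = _energy(within, geo, bleed, n_zero, n)
    best = None  # (within, geo, -bleed), f_idx, d_idx
    if n_zero == 0:
        best = ((within, geo, -bleed), f_idx.copy(), d_idx.copy())

    T = params.initial_temperature
    while T >= params.min_temperature:
        cand_f, cand_d = _neighbor_idx(f_idx, d_idx, F, D, rng)
        w2, g2, b2, z2 = _score_arrays(S, af, cand_f, cand_d, eta)
        e2 = _energy(w2, g2, b2, z2, n)
        if e2 <= energy or rng.random() < math.exp(-(e2 - energy) / T):
            f_idx, d_idx, energy = cand_f, cand_d, e2
            if z2 == 0:
                key = (w2, g2, -b2)
                if best is None or key > best[0]:
                    best = (key, cand_f.copy(), cand_d.copy())
        T *= params.cooling_rate

    if best is None:
        raise NoValidPanelError("simulated annealing encountered no valid panel")
    # finish with a deterministic comparator descent from the best state seen
    (bw, bg, nbb), bf, bd = _steepest_descent(S, af, best[1], best[2], eta)
    fnames, dnames = matrix.fluorophores, matrix.detectors
    panel = Panel(tuple(fnames[i] for i in bf), tuple(dnames[i] for i in bd))
    return panel, PanelScore(bw, bg, -nbb, eta, n)


def multistart_sa(library: Sequence[Fluorophore] | None,
                  instrument: Instrument | None, n: int,
                  eta: float = DEFAULT_ETA,
                  params: SAParams = SAParams(), *,
                  use_brightness: bool = False,
                  use_autofluorescence: bool = False,
                  matrix: SignalMatrix | None = None
                  ) -> tuple[Panel, PanelScore]:
    """Best of `params.restarts` independent runs with seeds seed + i.

    The winner is chosen with the exact comparator; on ties the run with
    the smallest index wins, so the result does not depend on execution
    order.

    Raises
    ------
    NoValidPanelError
        If every restart failed to find a valid panel.
    """
    matrix = _resolve_matrix(library, instrument, matrix,
                             use_brightness, use_autofluorescence)
    best: tuple[Panel, PanelScore] | None = None
    for i in range(params.restarts):
        try:
            panel, score = simulated_annealing(
                None, None, n, eta, params, seed=params.seed + i, matrix=matrix)
        except NoValidPanelError:
            continue
        if best is None or compare_panels(score, best[1]) > 0:
            best = (panel, score)
    if best is None:
        raise NoValidPanelError(
            f"no valid panel found in {params.restarts} simulated-annealing runs")
    return best
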