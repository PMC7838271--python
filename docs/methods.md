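# Methods

## Problem

Multicolor fluorescence experiments (flow cytometry, plate readers,
microscopy) must assign each fluorescent reporter to one detector channel of
a specific instrument.  A poor assignment wastes signal or drowns a channel
in spillover from the other reporters.  `cytopanel` treats this as a
combinatorial design problem: given a library of F fluorophores (excitation
and emission spectra, optional brightness) and an instrument with lasers and
bandpass-filtered detectors, find the n-color panel — n distinct
fluorophores injectively assigned to detectors — that maximizes per-channel
signal while minimizing bleed-through.

## Signal model

All spectra are resampled by linear interpolation onto a common 1-nm integer
grid (300–900 nm, covering visible-range fluorophores in public catalogues)
and peak-normalized, so excitation values read as efficiencies in [0, 1].
The predicted signal of fluorophore *f* in detector *d* owned by laser *l*
is

    S(f, d) = ex_f(λ_l) · Σ_{λ∈[lo_d, hi_d]} em_f(λ) / Σ_λ em_f(λ)   [· B_f]

— the excitation efficiency at the laser line (lasers are treated as
monochromatic, equal-power delta lines; each detector sees only its owning
laser) times the fraction of total emission inside the detector's bandpass
(discrete 1-nm sum, endpoints inclusive), optionally times the molecular
brightness B_f (extinction coefficient × quantum yield, rescaled so the
brightest library member is 1).  Both factors and their product lie in
[0, 1].  Detector quantum efficiency, filter transmission curves, laser
power and PMT gain are not modeled.  Cellular autofluorescence, when
supplied, is a per-detector additive baseline that always counts as
bleed-through and never as signal, and does not affect validity.

In a panel, the *signal* of a detector is S for its assigned fluorophore;
its *bleed-through* is the sum of S over all other panel fluorophores in
that detector, plus the autofluorescence baseline.  A panel is *valid* when
every assigned detector has strictly positive signal (values ≤ 1e-12 are
treated as zero).

## Ranking panels

Panels are compared lexicographically on three tiers:

1. the number of detectors whose bleed-through is within a fraction η of
   their own signal (inclusive: bleed ≤ η·signal; default η = 0.10,
   configurable);
2. the geometric mean of the assigned signals, computed as
   exp(mean(log s)) with any zero signal collapsing it to 0, so one dead
   channel cannot hide behind bright ones;
3. the arithmetic mean of the per-detector bleed-through (lower is better).

Equal on all three tiers ⇒ equivalent; when a single winner is needed,
enumeration order breaks ties, which keeps every ranking deterministic.

All scoring paths (single-panel scoring, the annealer, the vectorized
enumerator) share one kernel that re-orders assignments by fluorophore row
and reduces over sorted values.  This makes a panel's score bit-identical
regardless of which code path produced it or how its assignments were
listed — without it, last-ulp differences in summation order silently break
comparator ties between identical panels.

## Search

The space of n-color panels has C(F, n)·P(D, n) members (counted exactly in
integer arithmetic).  Exhaustive search scores the whole space subset by
subset with vectorized NumPy (about 78 million panels in ~15 s on one core)
and refuses, without an override, spaces above 10^8 panels.  An exact
validity census is available separately: on the boolean signal > 0 matrix it
counts injective assignments per fluorophore subset by memoized recursion
over used-detector bitmasks, which is exact and far cheaper than
enumeration.

Large spaces are searched by multistart simulated annealing.  The scalar
surrogate energy of a panel is

    E = (n − within_η) + 0.5·(1 − min(geomean, 1))
        + 0.25·min(mean_bleed, 1) + n·(#zero-signal detectors)

so a tier-1 difference (≥ 1) always dominates the bounded lower-tier terms
(≤ 0.75) and invalid panels are heavily penalized; E = 0 only for a perfect
panel.  Moves: with probability 1/2 swap one panel fluorophore for an unused
library fluorophore, otherwise move one assignment to an unused detector
(or exchange two assigned detectors when all detectors are in use).
Acceptance is Metropolis (accept if ΔE ≤ 0, else with probability
exp(−ΔE/T)) under geometric cooling T ← 0.999·T from T₀ = 1 down to 10⁻⁴,
which gives ⌈ln(10⁻⁴)/ln(0.999)⌉ = 9,206 iterations per run.  A hotter
preset (T₀ = 10, α = 0.9995) is provided for very large problems.

Two refinements matter in practice.  The run tracks the best *valid* panel
seen anywhere along the trajectory under the exact comparator (never the
surrogate), and finishes with a deterministic steepest-descent phase over a
richer neighborhood that also includes compound moves (replace a
fluorophore and move its detector in one step).  The compound moves let the
descent cross ridges where changing the fluorophore alone would transiently
lose validity; without them runs occasionally finish in a local optimum
several hundred ranks from the top.  With them, all 200 independent runs on
the reference synthetic instance reach the exhaustive optimum
(`scripts/acceptance.py` recomputes this).

Multistart runs `restarts` independent runs (default 50) with seeds
base + i and returns the comparator-best valid result; ties go to the
lowest run index, so the answer is independent of execution order.  Every
run is deterministic given its seed.

## Validation metrics

Predicted and measured intensity matrices are compared after per-detector
normalization to a maximum of 1.  Two metrics: *signals match* — in every
detector the same fluorophore carries the value 1 in both matrices (a tied
maximum is an error, not a pass); *within tolerance* — every entry differs
by at most the tolerance, inclusively, checked at 0.05, 0.10 and 0.20 by
default.  The tolerance check covers signal and bleed-through entries
alike.  Measured data enter only as already-normalized tables; raw FCS
files, compensation and gating are out of scope.

## Synthetic data

The generator stands in for catalogue spectra and real measurements so the
whole pipeline runs offline.  Fluorophores get Gaussian excitation/emission
curves; the defaults — 8 fluorophores, excitation peaks uniform on
380–650 nm, widths (σ) 15–30 nm, Stokes shifts 20–60 nm, brightness
0.3–1 — give moderately overlapping visible-range spectra comparable to
common fluorescent-protein libraries.  Instruments are laser banks with
contiguous, non-overlapping 30-nm windows red of each line; the reference
layouts are 5 lasers / 19 detectors (355/405/488/561/638 nm) and 3 lasers /
7 detectors.  Simulated measurements perturb normalized predictions with
additive Gaussian noise (default σ = 0.02), clip at zero and re-normalize.

What this does not emulate: real spectra are asymmetric with long red
tails, brightness varies with environment, real filter sets overlap between
lasers, and measurement noise is neither Gaussian nor independent across
channels.  Passing tests on synthetic data therefore demonstrate the
correctness of the machinery (counting, scoring, ranking, search,
agreement metrics), not the accuracy of any particular biological
prediction.  Census fractions (e.g. the share of valid panels) depend
strongly on spectral overlap and differ between synthetic and catalogue
libraries.

## Problem sizes used in the shipped checks

Exhaustive-vs-annealing comparisons use the 8-fluorophore / 19-detector /
5-color instance (78,140,160 panels, ~5.6 million valid); oracle-equivalence
checks enumerate all instances with F, D ≤ 6, n ≤ 3; the large-panel
demonstration designs a 10-color panel from a 188-fluorophore library with
10 multistart runs of the hot schedule.  These sizes keep the full test
suite and the acceptance script in the minutes range on one core.

## Known limitations

- The signal model is deliberately linear and monochromatic; instruments
  whose effective excitation deviates strongly (broadband sources, steep
  filter edges) need a richer model.
- The annealing energy weights (1 / 0.5 / 0.25 / n) preserve tier-1
  dominance but conflate tiers 2 and 3 inside one temperature scale; the
  exact comparator is therefore always used for final ranking and for the
  best-seen tracking.
- `count_valid_panels` is exponential in n per subset in the worst case;
  it is intended for library-scale F with small n (n ≤ 10).
- Equivalent panels share a rank; reported ranks are
  1 + (number of strictly better valid panels).
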