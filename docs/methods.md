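# Methods

## The pipeline

`apopcal` implements a systematic population-of-models workflow for
ventricular AP variability in six stages:

1. **Grid construction** (`sweep.GridSpec`, `build_grid`) — a full factorial
   product over six conductance scale factors (g_to, g_Kr, g_Ks, g_K1,
   g_Ca,L, g_NaK as multipliers of a control model, 1.0 = control).
   Enumeration is canonical (axis order to, Kr, Ks, K1, CaL, NaK; last axis
   fastest) so that stacking, storage and parallel execution are all
   reproducible from the grid alone.
2. **Paced simulation** (`sweep.run_paced`, `run_sweep`) against any object
   satisfying the `CellModel` contract.
3. **Biomarker extraction** (`biomarkers`) on the final steady beat.
4. **Calibration** (`calibration`) against per-CL APD₅₀/APD₉₀ bounds.
5. **Goodness-of-fit ranking** (`fit_metrics`) of biomarker combinations
   against NRMSD-based selection.
6. **CBDR visualisation** (`cbdr`) of any per-grid-point scalar.

## The phenomenological cell

The bundled toy cell is a closed-form waveform generator, not an ODE system.
Its purpose is to give every downstream stage realistic, non-trivial
structure — not to reproduce any published rabbit model quantitatively.

Steady-state APD₉₀ is log-linear in the scale factors with saturating rate
dependence:

    APD90_inf(s, CL) = [A − B·exp(−CL/τ_CL)] · Π_i s_i^{c_i}

with A = 230 ms, B = 150 ms, τ_CL = 600 ms and exponents
c_CaL = +0.30, c_Kr = −0.20, c_K1 = −0.15, c_Ks = −0.10, c_NaK = −0.10,
c_to = −0.05. The signs encode the expected physiology (more repolarising
current → shorter APD; more Ca²⁺ inflow → longer APD) and the magnitudes
order the currents' influence. Beat n of the pacing transient has
APD₉₀(n) = APD90_inf·(1 + δ·ρ^{n−1}) with δ = 0.08, ρ = 0.90: a geometric
approach to steady state that guarantees the steady-state detector
terminates. APD₅₀ = 0.78·APD₉₀ throughout.

The voltage waveform is a linear 2 ms upstroke from
V_rest = −85 − 3·ln s_K1 − ln s_NaK (mV) to +35 mV, followed by a logistic
repolarisation calibrated so the 50 %/90 % crossings fall exactly at
APD₅₀(n)/APD₉₀(n), minus a transient-outward notch
a_to·s_to·u·e^{1−u}, u = (t−t_up)/12 ms. The Ca²⁺ transient is a
double-exponential (rise 15 ms, decay 0.35·APD90_inf) normalised so its
peak is Ca_dia + Amp, with Ca_dia = 0.20·s_CaL^0.5·s_NaK^−0.3 µM and
Amp = 0.45·s_CaL·s_NaK^−0.25 µM. Constants are fixed so the control cell's
APDs land inside the bundled physiological ranges at every CL; they can be
overridden through the `toy_model:` config block.

A beat whose APD₉₀(n) ≥ CL cannot repolarise within the cycle and raises a
degenerate-beat condition, which the sweep records as a flagged all-NaN
entry rather than an error (such sets simply fail calibration).

Because each beat is available in closed form, the model's `advance(state,
n_beats)` is O(1) in the beat count: state is the number of beats completed,
and only the requested final beat is materialised. A 1,000 s protocol
therefore costs two beat evaluations per parameter set, which is what makes
the full 15,625 × 3-CL sweep run in tens of seconds on one CPU at dt = 1 ms
(the problem sizes used throughout the tests and the acceptance script).

### What the toy model does and does not emulate

It emulates the features the pipeline is sensitive to: monotone log-linear
biomarker responses, rate dependence, beat-to-beat convergence, a notched AP
morphology, and a Ca²⁺ transient coupled to the same scale factors. It does
not emulate ionic mechanisms, alternans, restitution, stochastic gating, or
the non-linear current interactions of biophysical models — so passing
tests demonstrate the *pipeline's* correctness, not physiological fidelity
of any conclusion drawn from the toy population. Detailed CellML-derived
models attach through the `CellModel` contract (deterministic stimulus-
aligned pacing, uniform-dt output, composition law
advance(T/2)∘advance(T/2) = advance(T); ODE adapters should integrate at
relative/absolute tolerances 1e−7/1e−9 and resample).

## Pacing and steady state

`run_paced` paces for the nominal protocol duration (default 1,000 s), then
compares the last two stimulus-aligned beats pointwise on V_m: steady iff
max_j |V_n(j) − V_{n−1}(j)| < tol·(max V_n − min V_n) with tol = 0.05.
The check applies to V_m only (Ca is not constrained). If the criterion
fails, pacing is extended in 100-beat increments up to twice the nominal
duration, after which the entry is flagged non-steady but retained;
non-steady entries fail calibration. Beats are aligned at stimulus onset and
resampled to a uniform dt (default 1 ms) before comparison.

## Biomarkers

All derivatives are first-order forward differences on the uniform grid,
with ties in dV/dt_max broken at the earliest sample (mV/ms ≡ V/s).
Threshold crossings (APD, CTD) are linearly interpolated between bracketing
samples so durations are not quantised to dt. Numerical conventions worth
noting:

* V_rest is taken at the first sample of the beat window (the sample before
  the stimulus) rather than a diastolic minimum — correct for the toy
  waveform, overridable by ODE adapters with different diastolic behaviour.
* The APD repolarisation search starts at the beat's voltage peak, so
  rise-phase samples below the 50 % level can never masquerade as the
  crossing (visible at dt ≤ 0.5 ms, where the upstroke has several samples).
* V_plat is the point after the activation spike where dV/dt is closest to
  zero from below: the first non-positive local maximum of the derivative,
  or the last non-positive derivative sample before dV/dt turns positive
  (the notch-recovery case). If repolarisation is monotone with strictly
  decreasing derivative, V_plat falls back to V at 20 ms after the upstroke
  and is flagged.
* CTD₅₀/CTD₉₀ measure from the maximal dCa/dt point to the decay-phase
  crossing of Ca_dia + 0.5·CaT / Ca_dia + 0.1·CaT; the search starts at the
  Ca peak because "reduced by 50 %" is a decay-phase notion.
* Undefined biomarkers (threshold never reached, flat transient) are NaN;
  the record is kept and fails calibration.

The parameter-recovery suite verifies that measured APD₅₀/APD₉₀ match the
closed-form nominal values within 2·dt + 0.5 ms across the entire default
grid — the bound combines two one-sample interpolation errors with the
sub-0.05 mV residual of the notch at the crossing times.

## Calibration

Bounds are inclusive ("within the range"). The bundled `table1` preset (ms):

| CL (ms) | APD₅₀ | APD₉₀ |
|---|---|---|
| 400 | 104–135 | 142–185 |
| 600 | 116–159 | 160–220 |
| 1000 | 137–188 | 167–230 |

`extend_apd_ranges` widens the bounds for the expanded-search seeding step;
the default reading scales each bound (lower ×(1−f), upper ×(1+f)), with a
midpoint-symmetric alternative available since either reading of "extended
by ±10 %" is defensible. `propose_expanded_grid` turns the level
distribution of the (extended-range) passers into a concrete window shift:
each axis moves by round(gain·(mean level index − centre index)) steps of
0.15, gain 2 by default — a deliberately simple rendering of "follow the
underlying trend". The `expanded_mahajan` grid preset ships the concrete
published-style expanded windows verbatim so that search is reproducible
independent of this rule.

## Goodness-of-fit

NRMSD is normalised by the *reference* trace's range, making V and Ca scores
commensurate; members are ranked by the sum. Selection-by-biomarkers sweeps
the acceptable percentage difference θ from 0 in 0.1-point steps and keeps
the θ whose match count is closest to the target (~250), ties toward the
stricter θ. The percentage-overlap denominator is the NRMSD-selected set
(the gold standard); |A|, union and mean denominators are available. The
default selection universe is the full population; restricting to the
calibrated subset is a caller choice.

## CBDR

Stacking maps grid point (i₁…i₆) to column i(x_high)·L² + i(x_mid)·L +
i(x_low) and the analogous row, row 0 at the bottom. The clutter objective
sums |Δ| over each unordered adjacent pixel pair once; pairs touching a
masked pixel (missing or non-finite values, e.g. non-steady sets)
contribute 0 rather than a penalty. The optimiser is genuinely exhaustive
over the 720 slot assignments — no heuristic — and only scores one
representative of each transpose-equivalent pair (reversing all three
(x, y) pairs transposes the image without changing the cost); ties resolve
to the lexicographically smallest flattened name tuple. Raw biomarker
values are used in the objective (normalisation is a caller choice).
Membership stacks encode, per pixel, the subset of CLs at which the point
passed calibration as a bitmask, stacked in the unoptimised canonical order
so stacks remain directly comparable.

## Persistence and determinism

Bulk results go to HDF5 (one group per CL: scales N×6, biomarkers N×11,
flags, optional final-beat traces), tables to CSV, summaries to JSON,
configuration to YAML. Results are keyed by grid position, never completion
order, so serial and multi-process sweeps produce byte-identical tables.
The pipeline contains no randomness; the config `seed` field is reserved
for future stochastic models.

## Known limitations

* The toy cell is phenomenological; quantitative population counts from it
  characterise the pipeline, not rabbit physiology.
* Dimensional stacking requires equal level counts on all six axes.
* The steady-state rule inspects V_m only; Ca²⁺ may still be drifting in
  models with slow Ca cycling.
* NRMSD is unsuitable for noisy experimental references — that is precisely
  the motivation for the biomarker-combination surrogates.
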