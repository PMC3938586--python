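"""Phenomenological six-conductance action-potential / Ca2+-transient generator.

This closed-form "toy cell" stands in for a biophysically detailed ventricular
myocyte model so that the whole sweep → biomarker → calibration → ranking
pipeline is exercisable without external model definitions.  It reproduces the
qualitative features the pipeline depends on:

* a paced AP waveform with a fast upstroke, a transient-outward notch, a
  plateau and a sigmoidal repolarisation whose APD50/APD90 depend
  log-linearly and monotonically on the six conductance multipliers;
* rate dependence: steady-state APD90 shortens at short cycle lengths,
  ``APD90_inf = [A - B exp(-CL/tau_CL)] * prod_i s_i^{c_i}``;
* a geometric beat-to-beat approach to steady state,
  ``APD90(n) = APD90_inf * (1 + delta * rho^(n-1))``;
* a Ca2+ transient (double-exponential rise/decay) whose diastolic level and
  amplitude scale with the L-type Ca2+ and Na+/K+ pump multipliers.

It does not attempt quantitative agreement with any published rabbit model;
its constants are fixed so the control cell's APDs fall inside the bundled
physiological ranges at every cycle length, giving the calibration filter a
non-trivial pass/fail structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Any

import numpy as np

from .core import (
    CONDUCTANCES,
    BeatTrace,
    DegenerateBeatError,
    ModelInputError,
    PacingProtocol,
    ScaleVector,
)

__all__ = [
    "ToyModelConstants",
    "ToyCellModel",
    "steady_apd90",
    "beat_apd90",
    "beat_trace",
    "make_population",
]


@dataclass(frozen=True)
class ToyModelConstants:
    """Fixed constants of the phenomenological cell.

    Rate dependence: ``A`` (ms), ``B`` (ms), ``tau_cl`` (ms).
    Log-linear sensitivities ``c_*`` (dimensionless exponents on each scale
    factor).  ``r`` is the APD50/APD90 ratio; ``delta`` and ``rho`` set the
    geometric beat-to-beat transient.  Voltage shape: resting potential
    ``v_rest0`` (mV), peak ``v_peak`` (mV), upstroke duration ``t_up`` (ms),
    notch amplitude ``a_to`` (mV) and time constant ``tau_to`` (ms).  Calcium:
    rise time constant ``tau_rise`` (ms), decay coefficient ``tau_dec_coeff``
    (fraction of APD90), diastolic level ``ca_dia0`` (uM) and amplitude
    ``amp0`` (uM).
    """

    A: float = 230.0
    B: float = 150.0
    tau_cl: float = 600.0
    c_to: float = -0.05
    c_Kr: float = -0.20
    c_Ks: float = -0.10
    c_K1: float = -0.15
    c_CaL: float = 0.30
    c_NaK: float = -0.10
    r: float = 0.78
    delta: float = 0.08
    rho: float = 0.90
    v_rest0: float = -85.0
    v_peak: float = 35.0
    t_up: float = 2.0
    a_to: float = 6.0
    tau_to: float = 12.0
    tau_rise: float = 15.0
    tau_dec_coeff: float = 0.35
    ca_dia0: float = 0.20
    amp0: float = 0.45

    def exponents(self) -> np.ndarray:
        """Sensitivity exponents in canonical conductance order."""
        return np.array(
            [getattr(self, f"c_{name}") for name in CONDUCTANCES], dtype=float
        )

    def with_overrides(self, overrides: dict[str, Any] | None) -> "ToyModelConstants":
        """Return a copy with fields replaced from a config mapping."""
        if not overrides:
            return self
        unknown = set(overrides) - {f for f in self.__dataclass_fields__}
        if unknown:
            raise ModelInputError(f"unknown toy-model constants: {sorted(unknown)}")
        return replace(self, **{k: float(v) for k, v in overrides.items()})


DEFAULT_CONSTANTS = ToyModelConstants()

_MIN_CL = 200.0


def steady_apd90(
    s: ScaleVector, cl: float, k: ToyModelConstants = DEFAULT_CONSTANTS
) -> float:
    """Steady-state nominal APD90 (ms) of the toy cell.

    ``APD90_inf = [A - B exp(-CL/tau_cl)] * prod_i s_i^{c_i}`` — strictly
    increasing in s_CaL and strictly decreasing in every K+/pump multiplier.
    """
    if not isinstance(s, ScaleVector):
        s = ScaleVector.from_iterable(s)
    if cl < _MIN_CL:
        raise ModelInputError(f"cycle length must be >= {_MIN_CL} ms, got {cl}")
    base = k.A - k.B * math.exp(-cl / k.tau_cl)
    factor = float(np.prod(s.as_array() ** k.exponents()))
    return base * factor


def beat_apd90(
    s: ScaleVector, cl: float, beat_index: int, k: ToyModelConstants = DEFAULT_CONSTANTS
) -> float:
    """Nominal APD90 of beat ``beat_index`` (1-based) during the pacing transient."""
    if beat_index < 1 or beat_index != int(beat_index):
        raise ModelInputError(f"beat_index must be an integer >= 1, got {beat_index}")
    return steady_apd90(s, cl, k) * (1.0 + k.delta * k.rho ** (beat_index - 1))


def _ca_decay_tau(apd90_inf: float, k: ToyModelConstants) -> float:
    return k.tau_dec_coeff * apd90_inf


def beat_trace(
    s: ScaleVector,
    cl: float,
    beat_index: int,
    dt: float = 1.0,
    k: ToyModelConstants = DEFAULT_CONSTANTS,
) -> BeatTrace:
    """Sampled Vm/Ca2+ waveform of one paced beat.

    The beat window is [0, CL) sampled at ``dt`` with the first sample at the
    stimulus (t = 0).  Raises :class:`DegenerateBeatError` if the beat's APD90
    does not fit in the cycle.
    """
    if not isinstance(s, ScaleVector):
        s = ScaleVector.from_iterable(s)
    if dt <= 0 or dt >= cl:
        raise ModelInputError(f"dt must satisfy 0 < dt < CL, got dt={dt}")
    apd90_inf = steady_apd90(s, cl, k)
    apd90_n = apd90_inf * (1.0 + k.delta * k.rho ** (beat_index - 1))
    if beat_index < 1:
        raise ModelInputError(f"beat_index must be >= 1, got {beat_index}")
    if apd90_n >= cl:
        raise DegenerateBeatError(
            f"APD90 {apd90_n:.1f} ms does not fit in CL {cl:.0f} ms"
        )
    apd50_n = k.r * apd90_n

    n = math.ceil(cl / dt)
    t = np.arange(n) * dt

    v_rest = k.v_rest0 - 3.0 * math.log(s.s_K1) - 1.0 * math.log(s.s_NaK)
    amp = k.v_peak - v_rest

    # sigmoidal repolarisation calibrated so V crosses the 50 % / 90 %
    # repolarisation levels exactly at APD50(n) / APD90(n)
    t_half = apd50_n
    k_s = (apd90_n - apd50_n) / math.log(9.0)
    sigma = 1.0 / (1.0 + np.exp((t - t_half) / k_s))
    tau = (t - k.t_up) / k.tau_to
    notch = k.a_to * s.s_to * tau * np.exp(1.0 - tau)
    vm = np.where(
        t < k.t_up,
        v_rest + amp * t / k.t_up,
        v_rest + amp * sigma - notch,
    )

    tau_dec = _ca_decay_tau(apd90_inf, k)
    ca_dia = k.ca_dia0 * s.s_CaL**0.5 * s.s_NaK**-0.3
    ca_amp = k.amp0 * s.s_CaL * s.s_NaK**-0.25
    w = np.exp(-t / tau_dec) - np.exp(-t / k.tau_rise)
    if math.isclose(tau_dec, k.tau_rise):
        t_pk = k.tau_rise
    else:
        t_pk = math.log(tau_dec / k.tau_rise) * k.tau_rise * tau_dec / (tau_dec - k.tau_rise)
    w_max = math.exp(-t_pk / tau_dec) - math.exp(-t_pk / k.tau_rise)
    cai = ca_dia + ca_amp * w / w_max

    return BeatTrace(dt=dt, vm=vm, cai=cai)


@dataclass
class ToyCellModel:
    """Cell-model-contract adapter around the closed-form beat generator.

    State is simply the number of beats completed; advancing by N beats is
    O(1) in N because each beat's waveform is available in closed form, so a
    1,000 s pacing protocol costs the same as a single beat.
    """

    constants: ToyModelConstants = DEFAULT_CONSTANTS

    def initial_state(self, s: ScaleVector) -> int:
        if not isinstance(s, ScaleVector):
            raise ModelInputError("toy model requires a ScaleVector")
        return 0

    def advance(
        self, state: int, s: ScaleVector, cl: float, dt: float, n_beats: int
    ) -> tuple[int, BeatTrace]:
        """Pace ``n_beats`` further beats; return new state and the last beat."""
        if n_beats < 1:
            raise ModelInputError(f"n_beats must be >= 1, got {n_beats}")
        new_state = state + int(n_beats)
        return new_state, beat_trace(s, cl, new_state, dt, self.constants)


def make_population(
    grid,
    cl: float,
    dt: float = 1.0,
    k: ToyModelConstants = DEFAULT_CONSTANTS,
    rel_tol: float = 1e-9,
) -> list[tuple[ScaleVector, BeatTrace]]:
    """Steady-state (ScaleVector, BeatTrace) pairs for every grid point.

    Fixture generator: the beat index is chosen so the remaining geometric
    transient is below ``rel_tol`` of the steady APD90, i.e. the trace is a
    steady beat to numerical precision.  Deterministic.
    """
    from .sweep import build_grid  # local import to avoid a cycle

    n_steady = 1 + math.ceil(
        (math.log(rel_tol) - math.log(k.delta)) / math.log(k.rho)
    )
    return [
        (s, beat_trace(s, cl, n_steady, dt, k)) for s in build_grid(grid)
    ]
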