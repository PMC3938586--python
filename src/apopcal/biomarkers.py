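"""AP and Ca2+-transient biomarkers measured on a steady-state beat.

Eleven numeric biomarkers per beat: the upstroke time and maximal upstroke
velocity (t_dvdt_max, dvdt_max), resting and plateau potential (v_rest,
v_plat), action-potential durations at 50 %/90 % repolarisation (apd50,
apd90), diastolic/systolic Ca2+ and transient amplitude (ca_dia, ca_sys,
cat_amp) and Ca2+-transient durations at 50 %/90 % recovery (ctd50, ctd90).

Durations are measured from the maximal-upstroke point; threshold crossings
are linearly interpolated between bracketing samples so they are not
quantised to the sample interval.  Derivatives are first-order forward
differences on the uniform grid, with ties in the maximum broken at the
earliest time.  A biomarker whose defining crossing never occurs within the
beat is NaN (the record is retained but fails calibration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import BeatTrace, ModelInputError, ScaleVector

__all__ = [
    "BIOMARKER_COLUMNS",
    "BiomarkerRecord",
    "dvdt_max_point",
    "apd_at_fraction",
    "v_rest",
    "v_plat",
    "v_plat_point",
    "ca_biomarkers",
    "compute_record",
]

BIOMARKER_COLUMNS: tuple[str, ...] = (
    "t_dvdt_max",
    "dvdt_max",
    "v_rest",
    "v_plat",
    "apd50",
    "apd90",
    "ca_dia",
    "ca_sys",
    "cat_amp",
    "ctd50",
    "ctd90",
)


@dataclass
class BiomarkerRecord:
    """The eleven biomarkers plus provenance for one (parameter set, CL)."""

    t_dvdt_max: float
    dvdt_max: float
    v_rest: float
    v_plat: float
    apd50: float
    apd90: float
    ca_dia: float
    ca_sys: float
    cat_amp: float
    ctd50: float
    ctd90: float
    steady: bool
    degenerate: bool
    scales: ScaleVector | None = None
    cl: float | None = None


def _forward_diff(y: np.ndarray, dt: float) -> np.ndarray:
    return np.diff(y) / dt


def dvdt_max_point(trace: BeatTrace) -> tuple[float, float]:
    """Time (ms) and magnitude (V/s) of the maximal upstroke velocity.

    The forward difference between samples j and j+1 is attributed to sample
    j; mV/ms is numerically identical to V/s.  On a flat trace the rate is 0
    at the first sample.
    """
    if trace.vm.size < 3:
        raise ModelInputError("need at least 3 samples for a derivative")
    d = _forward_diff(trace.vm, trace.dt)
    i = int(np.argmax(d))  # argmax returns the first maximum: earliest tie
    return i * trace.dt, float(d[i])


def apd_at_fraction(trace: BeatTrace, frac: float) -> float:
    """AP duration at fractional repolarisation ``frac`` (0.5 or 0.9).

    Time from the maximal-upstroke point to the first instant at which
    ``V <= V_rest + (1 - frac) * (V_max - V_rest)``, with the crossing
    linearly interpolated.  NaN if the threshold is never reached.
    """
    if not (0 < frac < 1):
        raise ModelInputError(f"frac must lie in (0, 1), got {frac}")
    t_up, _ = dvdt_max_point(trace)
    i0 = int(round(t_up / trace.dt))
    v = trace.vm
    rest = float(v[0])
    threshold = rest + (1.0 - frac) * (float(v.max()) - rest)
    # repolarisation crossing: search from the voltage peak so rise-phase
    # samples below the threshold are never mistaken for it
    start = max(i0 + 1, int(np.argmax(v)))
    below = np.nonzero(v[start:] <= threshold)[0]
    if below.size == 0:
        return math.nan
    j = start + int(below[0])
    v_hi, v_lo = float(v[j - 1]), float(v[j])
    if v_hi <= threshold or v_hi == v_lo:
        t_cross = j * trace.dt
    else:
        t_cross = (j - 1 + (v_hi - threshold) / (v_hi - v_lo)) * trace.dt
    return t_cross - t_up


def v_rest(trace: BeatTrace) -> float:
    """Diastolic potential: Vm at the sample immediately before the stimulus
    (equivalently the first sample of the stimulus-aligned beat window)."""
    return float(trace.vm[0])


def v_plat(trace: BeatTrace) -> float:
    """Plateau potential.

    Vm at the first sample after the maximal-upstroke point where the
    derivative is <= 0 and is a local maximum of the derivative, i.e. the
    point after the activation spike where dVm/dt comes closest to zero from
    below (the notch recovery on a notched AP).  If repolarisation is
    monotone and no such local maximum exists, falls back to Vm 20 ms after
    the upstroke.
    """
    _, value, _ = v_plat_point(trace)
    return value


def v_plat_point(trace: BeatTrace) -> tuple[float, float, bool]:
    """(time ms, Vm mV, fallback_used) of the plateau detection point."""
    t_up, _ = dvdt_max_point(trace)
    i0 = int(round(t_up / trace.dt))
    d = _forward_diff(trace.vm, trace.dt)
    inner = d[1:-1]  # candidate indices j = 1 .. d.size - 2
    # closest-to-zero from below: a local maximum of the (non-positive)
    # derivative, or the last non-positive sample before dV/dt turns positive
    local_max = (inner <= 0) & (inner >= d[:-2]) & ((inner >= d[2:]) | (d[2:] > 0))
    candidates = np.nonzero(local_max)[0] + 1
    candidates = candidates[candidates > i0]
    if candidates.size:
        j = int(candidates[0])
        return j * trace.dt, float(trace.vm[j]), False
    j_fb = min(int(round((t_up + 20.0) / trace.dt)), trace.vm.size - 1)
    return j_fb * trace.dt, float(trace.vm[j_fb]), True


def ca_biomarkers(trace: BeatTrace) -> tuple[float, float, float, float, float]:
    """Diastolic/systolic Ca2+, transient amplitude and CTD50/CTD90.

    ``ca_dia`` is Ca at the sample before the stimulus, ``ca_sys`` the beat
    maximum, ``cat_amp`` their difference.  CTD_x is the time from the
    maximal-dCa/dt point to the first decay-phase instant at which
    ``Ca <= ca_dia + (1 - x) * cat_amp`` (interpolated); NaN when Ca does
    not recover or the transient is flat.
    """
    ca = trace.cai
    ca_dia = float(ca[0])
    i_sys = int(np.argmax(ca))
    ca_sys = float(ca[i_sys])
    cat_amp = ca_sys - ca_dia
    if cat_amp <= 0:
        return ca_dia, ca_sys, cat_amp, math.nan, math.nan
    d = _forward_diff(ca, trace.dt)
    i_up = int(np.argmax(d))
    t_up = i_up * trace.dt

    def ctd(frac: float) -> float:
        threshold = ca_dia + (1.0 - frac) * cat_amp
        start = max(i_sys, i_up + 1)
        below = np.nonzero(ca[start:] <= threshold)[0]
        if below.size == 0:
            return math.nan
        j = start + int(below[0])
        c_hi, c_lo = float(ca[j - 1]), float(ca[j])
        if c_hi <= threshold or c_hi == c_lo:
            t_cross = j * trace.dt
        else:
            t_cross = (j - 1 + (c_hi - threshold) / (c_hi - c_lo)) * trace.dt
        return t_cross - t_up

    return ca_dia, ca_sys, cat_amp, ctd(0.5), ctd(0.9)


def compute_record(paced, s: ScaleVector, cl: float) -> BiomarkerRecord:
    """All eleven biomarkers of the final paced beat, with provenance.

    A degenerate paced result (no repolarisation within the cycle) yields an
    all-NaN record flagged ``degenerate=True``.
    """
    nan = math.nan
    if paced.final is None:
        return BiomarkerRecord(
            *([nan] * 11), steady=False, degenerate=True, scales=s, cl=cl
        )
    trace = paced.final
    t_dv, dv = dvdt_max_point(trace)
    ca_dia, ca_sys, cat_amp, ctd50, ctd90 = ca_biomarkers(trace)
    return BiomarkerRecord(
        t_dvdt_max=t_dv,
        dvdt_max=dv,
        v_rest=v_rest(trace),
        v_plat=v_plat(trace),
        apd50=apd_at_fraction(trace, 0.5),
        apd90=apd_at_fraction(trace, 0.9),
        ca_dia=ca_dia,
        ca_sys=ca_sys,
        cat_amp=cat_amp,
        ctd50=ctd50,
        ctd90=ctd90,
        steady=bool(paced.steady),
        degenerate=bool(paced.degenerate),
        scales=s,
        cl=cl,
    )
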