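"""Shared domain types for the conductance-sweep pipeline.

The swept space is six dimensionless multipliers applied to the maximal
conductances of the transient outward (to), rapid (Kr) and slow (Ks) delayed
rectifier K+, inward rectifier K+ (K1), L-type Ca2+ (CaL) and Na+/K+ pump
(NaK) currents of a ventricular myocyte model.  A multiplier of 1.0 is the
published control model.  All modules agree on the canonical axis order
defined by :data:`CONDUCTANCES`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterator

import numpy as np

#: Canonical conductance order; grid enumeration and dimensional stacking
#: both rely on it (last axis varies fastest when a grid is enumerated).
CONDUCTANCES: tuple[str, ...] = ("to", "Kr", "Ks", "K1", "CaL", "NaK")

#: Column names used for scale factors in tables and HDF5 stores.
SCALE_COLUMNS: tuple[str, ...] = tuple(f"s_{name}" for name in CONDUCTANCES)


class ModelInputError(ValueError):
    """A scale vector, cycle length or protocol parameter is out of domain."""


class DegenerateBeatError(RuntimeError):
    """The action potential does not repolarise within one pacing cycle."""


@dataclass(frozen=True)
class ScaleVector:
    """Six named positive conductance multipliers (1.0 = control)."""

    s_to: float = 1.0
    s_Kr: float = 1.0
    s_Ks: float = 1.0
    s_K1: float = 1.0
    s_CaL: float = 1.0
    s_NaK: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ModelInputError(
                    f"conductance multiplier {f.name} must be finite and > 0, got {v!r}"
                )

    def as_tuple(self) -> tuple[float, ...]:
        return (self.s_to, self.s_Kr, self.s_Ks, self.s_K1, self.s_CaL, self.s_NaK)

    def as_array(self) -> np.ndarray:
        return np.array(self.as_tuple(), dtype=float)

    @classmethod
    def from_iterable(cls, values) -> "ScaleVector":
        vals = tuple(float(v) for v in values)
        if len(vals) != 6:
            raise ModelInputError(f"expected 6 scale factors, got {len(vals)}")
        return cls(*vals)

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_tuple())


@dataclass
class BeatTrace:
    """Uniformly sampled membrane potential and intracellular Ca2+ for one beat.

    Attributes
    ----------
    dt : sample interval in ms; the first sample is at t = 0 (stimulus onset).
    vm : membrane potential in mV.
    cai : intracellular Ca2+ concentration in uM, same length as ``vm``.
    """

    dt: float
    vm: np.ndarray
    cai: np.ndarray

    def __post_init__(self) -> None:
        self.vm = np.asarray(self.vm, dtype=float)
        self.cai = np.asarray(self.cai, dtype=float)
        if self.dt <= 0:
            raise ModelInputError(f"dt must be > 0, got {self.dt}")
        if self.vm.shape != self.cai.shape or self.vm.ndim != 1:
            raise ModelInputError("vm and cai must be 1-D arrays of equal length")

    @property
    def t(self) -> np.ndarray:
        """Sample times in ms."""
        return np.arange(self.vm.size) * self.dt

    @property
    def n_samples(self) -> int:
        return self.vm.size


@dataclass(frozen=True)
class PacingProtocol:
    """Pacing protocol: cycle length, sampling and steady-state tolerance.

    ``max_time`` is the nominal pacing duration in ms (default 1,000 s); after
    that many beats the last two beats are compared with the 5 % pointwise
    rule.  ``steady_tol`` is the allowed pointwise difference as a fraction of
    the beat's voltage range.
    """

    cl: float
    dt: float = 1.0
    max_time: float = 1_000_000.0
    steady_tol: float = 0.05

    def __post_init__(self) -> None:
        if self.cl <= 0:
            raise ModelInputError(f"cycle length must be > 0, got {self.cl}")
        if self.dt <= 0 or self.dt >= self.cl:
            raise ModelInputError(f"dt must satisfy 0 < dt < CL, got dt={self.dt}")
        if not (0 < self.steady_tol < 1):
            raise ModelInputError(
                f"steady_tol must lie in (0, 1), got {self.steady_tol}"
            )
        if self.max_time < self.cl:
            raise ModelInputError("max_time must allow at least one beat")
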