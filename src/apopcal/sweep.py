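"""Factorial grid construction, pacing-protocol execution and steady-state detection.

A sweep runs every point of a six-axis conductance grid through a pacing
protocol at one or more cycle lengths, against any model satisfying the
:class:`CellModel` contract, and collects one biomarker record per
(scale vector, cycle length).  Results are keyed by grid position, never by
completion order, so serial and parallel executions are byte-identical.
"""

from __future__ import annotations

import itertools
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Any, Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .core import (
    CONDUCTANCES,
    SCALE_COLUMNS,
    BeatTrace,
    DegenerateBeatError,
    ModelInputError,
    PacingProtocol,
    ScaleVector,
)

__all__ = [
    "GridSpec",
    "CellModel",
    "PacedResult",
    "SweepStore",
    "build_grid",
    "is_steady_state",
    "run_paced",
    "run_sweep",
]

#: Default five-level factor grid: 0 %, +/-15 %, +/-30 % around control.
DEFAULT_LEVELS = (0.70, 0.85, 1.00, 1.15, 1.30)

#: Expanded grid used for the second, trend-following parameter search
#: (per-current windows shifted along the direction favoured by the
#: extended-range calibration step).
EXPANDED_MAHAJAN_LEVELS = {
    "to": (0.85, 1.00, 1.15, 1.30, 1.45),
    "Kr": (0.85, 1.00, 1.15, 1.30, 1.45),
    "Ks": (1.45, 1.60, 1.75, 1.90, 2.05),
    "K1": (0.85, 1.00, 1.15, 1.30, 1.45),
    "CaL": (1.30, 1.45, 1.60, 1.75, 1.90),
    "NaK": (0.55, 0.70, 0.85, 1.00, 1.15),
}


@dataclass(frozen=True)
class GridSpec:
    """Ordered scale levels per conductance axis.

    Each axis must be non-empty, strictly increasing and positive.  The full
    factorial product is enumerated in canonical axis order (to, Kr, Ks, K1,
    CaL, NaK) with the last axis varying fastest.
    """

    levels: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {name: DEFAULT_LEVELS for name in CONDUCTANCES}
    )

    def __post_init__(self) -> None:
        if set(self.levels) != set(CONDUCTANCES):
            raise ModelInputError(
                f"grid must define exactly the axes {CONDUCTANCES}, "
                f"got {sorted(self.levels)}"
            )
        clean = {}
        for name in CONDUCTANCES:
            axis = tuple(float(v) for v in self.levels[name])
            if len(axis) == 0:
                raise ModelInputError(f"axis {name} is empty")
            if any(v <= 0 for v in axis):
                raise ModelInputError(f"axis {name} has non-positive levels")
            if any(b <= a for a, b in zip(axis, axis[1:])):
                raise ModelInputError(f"axis {name} must be strictly increasing")
            clean[name] = axis
        object.__setattr__(self, "levels", clean)

    @classmethod
    def default(cls) -> "GridSpec":
        return cls()

    @classmethod
    def expanded_mahajan(cls) -> "GridSpec":
        return cls(levels=dict(EXPANDED_MAHAJAN_LEVELS))

    @classmethod
    def from_preset(cls, name: str) -> "GridSpec":
        presets = {"default": cls.default, "expanded_mahajan": cls.expanded_mahajan}
        if name not in presets:
            raise ModelInputError(
                f"unknown grid preset {name!r}; choose from {sorted(presets)}"
            )
        return presets[name]()

    @property
    def size(self) -> int:
        return int(np.prod([len(self.levels[n]) for n in CONDUCTANCES]))

    def axis_sizes(self) -> tuple[int, ...]:
        return tuple(len(self.levels[n]) for n in CONDUCTANCES)

    def to_dict(self) -> dict[str, list[float]]:
        return {name: list(self.levels[name]) for name in CONDUCTANCES}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GridSpec":
        return cls(levels={k: tuple(v) for k, v in d.items()})


@runtime_checkable
class CellModel(Protocol):
    """Behavioural contract a cell model must satisfy to be swept.

    ``advance`` paces ``n_beats`` further stimulus-aligned beats at cycle
    length ``cl`` and returns the new state plus the final beat sampled on a
    uniform ``dt`` grid.  Implementations must be deterministic and satisfy
    the composition law: advancing twice by N/2 beats equals advancing once
    by N.  ODE-backed adapters should integrate with relative/absolute
    tolerances of 1e-7/1e-9 (or better) and resample their output to ``dt``.
    """

    def initial_state(self, s: ScaleVector) -> Any: ...

    def advance(
        self, state: Any, s: ScaleVector, cl: float, dt: float, n_beats: int
    ) -> tuple[Any, BeatTrace]: ...


@dataclass
class PacedResult:
    """Outcome of pacing one parameter set to (attempted) steady state."""

    final: BeatTrace | None
    penultimate: BeatTrace | None
    steady: bool
    degenerate: bool
    beats_run: int
    total_time: float


def build_grid(spec: GridSpec) -> list[ScaleVector]:
    """Full factorial product of the grid axes as ScaleVectors.

    Canonical order: axes in (to, Kr, Ks, K1, CaL, NaK) order, last axis
    fastest; a pure function of the spec (stable across serialisation).
    """
    if not isinstance(spec, GridSpec):
        raise ModelInputError("build_grid expects a GridSpec")
    axes = [spec.levels[name] for name in CONDUCTANCES]
    return [ScaleVector(*combo) for combo in itertools.product(*axes)]


def is_steady_state(beat_n: BeatTrace, beat_prev: BeatTrace, tol: float = 0.05) -> bool:
    """Pointwise 5 %-of-amplitude steady-state criterion on Vm.

    True iff ``max_j |V_n(j) - V_prev(j)| < tol * (max V_n - min V_n)``.
    Applied to membrane potential only.
    """
    if beat_n.vm.size != beat_prev.vm.size or beat_n.dt != beat_prev.dt:
        raise ModelInputError("beats must share length and dt for comparison")
    amplitude = float(beat_n.vm.max() - beat_n.vm.min())
    max_diff = float(np.abs(beat_n.vm - beat_prev.vm).max())
    return max_diff < tol * amplitude


def run_paced(
    model: CellModel,
    s: ScaleVector,
    protocol: PacingProtocol,
    hard_cap_factor: float = 2.0,
    extension_beats: int = 100,
) -> PacedResult:
    """Pace one parameter set for the protocol duration and check steady state.

    Paces for ``protocol.max_time``, then compares the last two full
    stimulus-aligned beats.  If not steady, pacing is extended in increments
    of ``extension_beats`` beats up to ``hard_cap_factor * max_time``; if the
    criterion still fails the result is flagged ``steady=False``.  A beat
    that does not repolarise within the cycle yields a flagged degenerate
    record rather than an exception.
    """
    cl, dt = protocol.cl, protocol.dt
    n_target = max(2, int(protocol.max_time // cl))
    cap = max(n_target, int(hard_cap_factor * protocol.max_time // cl))
    state = model.initial_state(s)
    try:
        state, prev = model.advance(state, s, cl, dt, n_target - 1)
        state, last = model.advance(state, s, cl, dt, 1)
        beats = n_target
        steady = is_steady_state(last, prev, protocol.steady_tol)
        while not steady and beats + extension_beats <= cap:
            state, prev = model.advance(state, s, cl, dt, extension_beats - 1)
            state, last = model.advance(state, s, cl, dt, 1)
            beats += extension_beats
            steady = is_steady_state(last, prev, protocol.steady_tol)
    except DegenerateBeatError:
        return PacedResult(
            final=None,
            penultimate=None,
            steady=False,
            degenerate=True,
            beats_run=0,
            total_time=0.0,
        )
    return PacedResult(
        final=last,
        penultimate=prev,
        steady=steady,
        degenerate=False,
        beats_run=beats,
        total_time=beats * cl,
    )


@dataclass
class SweepStore:
    """In-memory sweep result: one biomarker table per cycle length.

    ``tables[cl]`` is a DataFrame with the six scale columns, the eleven
    biomarker columns (see :mod:`apopcal.biomarkers`), and ``steady`` /
    ``degenerate`` flags, in canonical grid order.  ``traces[cl]``, when
    kept, holds the final-beat ``vm`` and ``cai`` arrays (N x T).
    """

    grid: GridSpec
    cls: tuple[int, ...]
    dt: float
    tables: dict[int, pd.DataFrame]
    traces: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)

    def scale_tuples(self) -> list[tuple[float, ...]]:
        return [s.as_tuple() for s in build_grid(self.grid)]


def _sweep_chunk(args) -> tuple[int, list[list[float]], list[np.ndarray] | None, list[np.ndarray] | None]:
    """Worker: biomarker rows for one contiguous chunk of grid points."""
    from .biomarkers import BIOMARKER_COLUMNS, compute_record

    (model, vectors, protocol, store_traces, start) = args
    rows: list[list[float]] = []
    vms: list[np.ndarray] | None = [] if store_traces else None
    cais: list[np.ndarray] | None = [] if store_traces else None
    n_samples = int(np.ceil(protocol.cl / protocol.dt))
    for s in vectors:
        paced = run_paced(model, s, protocol)
        record = compute_record(paced, s, protocol.cl)
        rows.append(
            list(s.as_tuple())
            + [getattr(record, c) for c in BIOMARKER_COLUMNS]
            + [float(record.steady), float(record.degenerate)]
        )
        if store_traces:
            if paced.final is None:
                vms.append(np.full(n_samples, np.nan))
                cais.append(np.full(n_samples, np.nan))
            else:
                vms.append(paced.final.vm)
                cais.append(paced.final.cai)
    return start, rows, vms, cais


def run_sweep(
    model: CellModel,
    grid: GridSpec,
    cls: list[int],
    dt: float = 1.0,
    max_time: float = 1_000_000.0,
    steady_tol: float = 0.05,
    workers: int = 1,
    store_traces: bool = False,
    chunk_size: int = 512,
) -> SweepStore:
    """Run the pacing protocol over the whole grid at every cycle length.

    Individual degenerate/failed entries are recorded and flagged, never
    abort the sweep.  The output is keyed by grid position, so the resulting
    tables are independent of ``workers`` and of scheduling order.
    """
    from .biomarkers import BIOMARKER_COLUMNS

    if not cls:
        raise ModelInputError("at least one cycle length is required")
    vectors = build_grid(grid)
    columns = list(SCALE_COLUMNS) + list(BIOMARKER_COLUMNS) + ["steady", "degenerate"]
    tables: dict[int, pd.DataFrame] = {}
    traces: dict[int, dict[str, np.ndarray]] = {}
    for cl in cls:
        protocol = PacingProtocol(cl=cl, dt=dt, max_time=max_time, steady_tol=steady_tol)
        chunks = [
            (model, vectors[i : i + chunk_size], protocol, store_traces, i)
            for i in range(0, len(vectors), chunk_size)
        ]
        if workers > 1 and len(chunks) > 1:
            with ProcessPoolExecutor(max_workers=workers) as pool:
                results = list(pool.map(_sweep_chunk, chunks))
        else:
            results = [_sweep_chunk(c) for c in chunks]
        results.sort(key=lambda r: r[0])
        rows = [row for _, chunk_rows, _, _ in results for row in chunk_rows]
        table = pd.DataFrame(rows, columns=columns)
        table["steady"] = table["steady"].astype(bool)
        table["degenerate"] = table["degenerate"].astype(bool)
        tables[int(cl)] = table
        if store_traces:
            traces[int(cl)] = {
                "vm": np.vstack([vm for _, _, vms, _ in results for vm in vms]),
                "cai": np.vstack([ca for _, _, _, cais in results for ca in cais]),
            }
    return SweepStore(
        grid=grid, cls=tuple(int(c) for c in cls), dt=dt, tables=tables, traces=traces
    )
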