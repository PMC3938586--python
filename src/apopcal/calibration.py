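"""Calibration of the model population to physiological APD ranges.

A parameter set is physiological at a cycle length if its beat reached steady
state and both APD50 and APD90 fall inside experimentally derived inclusive
bounds for rabbit epicardium.  The bundled ``table1`` preset holds those
bounds per cycle length (400/600/1,000 ms).  The module also intersects
passing sets across cycle lengths, summarises the conductance-level
distribution of the passers, and implements the extended-range / expanded-grid
procedure used when no parameter set matches at a cycle length: widen the APD
bounds by a moderate fraction, look at where the few passers sit in the grid,
and shift each conductance window along that trend.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CONDUCTANCES, SCALE_COLUMNS, ModelInputError
from .sweep import GridSpec

__all__ = [
    "PhysRange",
    "TABLE1_RANGES",
    "filter_physiological",
    "intersect_across_cls",
    "level_distribution",
    "extend_apd_ranges",
    "propose_expanded_grid",
    "biomarker_histogram",
]

ScaleTuple = tuple[float, ...]


@dataclass(frozen=True)
class PhysRange:
    """Per-CL inclusive APD50/APD90 bounds (ms) used for calibration.

    ``bounds[cl] = (apd50_lo, apd50_hi, apd90_lo, apd90_hi)``.
    """

    bounds: dict[int, tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        for cl, (a_lo, a_hi, b_lo, b_hi) in self.bounds.items():
            if not (0 < a_lo < a_hi and 0 < b_lo < b_hi):
                raise ModelInputError(f"invalid APD bounds at CL {cl}")

    @classmethod
    def table1(cls) -> "PhysRange":
        """Normal rabbit epicardial APD50/APD90 ranges per cycle length."""
        return cls(
            bounds={
                400: (104.0, 135.0, 142.0, 185.0),
                600: (116.0, 159.0, 160.0, 220.0),
                1000: (137.0, 188.0, 167.0, 230.0),
            }
        )

    @classmethod
    def from_preset(cls, name: str) -> "PhysRange":
        if name != "table1":
            raise ModelInputError(f"unknown range preset {name!r}")
        return cls.table1()

    def to_dict(self) -> dict[str, list[float]]:
        return {str(cl): list(v) for cl, v in self.bounds.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PhysRange":
        return cls(bounds={int(k): tuple(float(x) for x in v) for k, v in d.items()})


TABLE1_RANGES = PhysRange.table1()


def filter_physiological(
    records: pd.DataFrame, ranges: PhysRange, cl: int
) -> set[ScaleTuple]:
    """Parameter sets whose APD50 and APD90 both fall inside the bounds.

    ``records`` is a sweep biomarker table at the given CL.  A record passes
    iff it is steady, not degenerate, and both APDs lie within the inclusive
    bounds; NaN biomarkers fail.  Returns the passing scale tuples.
    """
    if cl not in ranges.bounds:
        raise ModelInputError(f"no physiological range defined for CL {cl} ms")
    a_lo, a_hi, b_lo, b_hi = ranges.bounds[cl]
    if len(records) == 0:
        return set()
    ok = (
        records["steady"].to_numpy(dtype=bool)
        & ~records["degenerate"].to_numpy(dtype=bool)
        & (records["apd50"].to_numpy() >= a_lo)
        & (records["apd50"].to_numpy() <= a_hi)
        & (records["apd90"].to_numpy() >= b_lo)
        & (records["apd90"].to_numpy() <= b_hi)
    )
    scales = records.loc[ok, list(SCALE_COLUMNS)].to_numpy()
    return {tuple(row) for row in scales}


def intersect_across_cls(
    result_sets: dict[int, set[ScaleTuple]],
) -> dict[tuple[int, ...], set[ScaleTuple]]:
    """Exact set intersections for every combination of >= 2 cycle lengths."""
    if len(result_sets) < 2:
        raise ModelInputError("need passing sets at >= 2 cycle lengths")
    cls_sorted = sorted(result_sets)
    out: dict[tuple[int, ...], set[ScaleTuple]] = {}
    for k in range(2, len(cls_sorted) + 1):
        for combo in itertools.combinations(cls_sorted, k):
            inter = set(result_sets[combo[0]])
            for cl in combo[1:]:
                inter &= result_sets[cl]
            out[combo] = inter
    return out


def level_distribution(
    passing: set[ScaleTuple], grid: GridSpec
) -> dict[str, dict[float, int]]:
    """Per-conductance counts of each grid level among passing sets.

    Every axis's counts sum to ``len(passing)``.
    """
    counts: dict[str, dict[float, int]] = {
        name: {lvl: 0 for lvl in grid.levels[name]} for name in CONDUCTANCES
    }
    for tup in passing:
        for name, value in zip(CONDUCTANCES, tup):
            if value not in counts[name]:
                raise ModelInputError(
                    f"scale {value} not a grid level of axis {name}"
                )
            counts[name][value] += 1
    return counts


def extend_apd_ranges(
    ranges: PhysRange, frac: float = 0.10, mode: str = "bounds"
) -> PhysRange:
    """Moderately widened APD bounds used to seed the expanded-grid search.

    ``mode="bounds"`` (default) scales each bound: lower x (1 - frac), upper
    x (1 + frac).  ``mode="midpoint"`` widens each interval about its
    midpoint by the same fraction of its half-width.
    """
    if frac < 0:
        raise ModelInputError("extension fraction must be >= 0")
    new: dict[int, tuple[float, float, float, float]] = {}
    for cl, (a_lo, a_hi, b_lo, b_hi) in ranges.bounds.items():
        if mode == "bounds":
            new[cl] = (
                a_lo * (1 - frac),
                a_hi * (1 + frac),
                b_lo * (1 - frac),
                b_hi * (1 + frac),
            )
        elif mode == "midpoint":
            am, ah = (a_lo + a_hi) / 2, (a_hi - a_lo) / 2
            bm, bh = (b_lo + b_hi) / 2, (b_hi - b_lo) / 2
            new[cl] = (
                am - ah * (1 + frac),
                am + ah * (1 + frac),
                bm - bh * (1 + frac),
                bm + bh * (1 + frac),
            )
        else:
            raise ModelInputError(f"unknown extension mode {mode!r}")
    try:
        return PhysRange(bounds=new)
    except ModelInputError:
        # lower bounds collapsed to <= 0; permitted at the boundary but flagged
        import warnings

        warnings.warn(
            "APD range extension produced non-positive lower bounds", stacklevel=2
        )
        return _unchecked_range(new)


def _unchecked_range(bounds) -> PhysRange:
    obj = object.__new__(PhysRange)
    object.__setattr__(obj, "bounds", bounds)
    return obj


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def propose_expanded_grid(
    passing_extended: set[ScaleTuple],
    grid: GridSpec,
    step: float = 0.15,
    gain: float = 2.0,
) -> GridSpec:
    """Shift each conductance window along the trend of the passing sets.

    For each axis the mean level *index* of the passers is compared to the
    centre index; the window is translated by ``round(gain * offset)`` steps
    of size ``step``.  A symmetric passer distribution leaves the axis
    unchanged.  Requires a non-empty passing set (obtained, if necessary,
    from a calibration against extended APD ranges).
    """
    if not passing_extended:
        raise ModelInputError(
            "cannot propose an expanded grid from an empty passing set; "
            "calibrate against extended APD ranges first"
        )
    new_levels: dict[str, tuple[float, ...]] = {}
    for ax, name in enumerate(CONDUCTANCES):
        axis = grid.levels[name]
        index_of = {lvl: i for i, lvl in enumerate(axis)}
        try:
            idx = [index_of[tup[ax]] for tup in passing_extended]
        except KeyError as exc:
            raise ModelInputError(
                f"passing set contains a non-grid level on axis {name}"
            ) from exc
        centre = (len(axis) - 1) / 2
        offset = float(np.mean(idx)) - centre
        shift = _round_half_away(gain * offset)
        new_levels[name] = tuple(lvl + shift * step for lvl in axis)
    return GridSpec(levels=new_levels)


def biomarker_histogram(
    records: pd.DataFrame, biomarker: str, bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (counts, bin edges) of one biomarker across the population.

    Bins are aligned to multiples of ``bin_width``; NaN values (undefined
    biomarkers) are dropped.  Counts sum to the number of finite values.
    """
    if bin_width <= 0:
        raise ModelInputError("bin_width must be > 0")
    values = records[biomarker].to_numpy(dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return np.array([], dtype=int), np.array([])
    lo = math.floor(values.min() / bin_width) * bin_width
    n_bins = max(1, math.ceil((values.max() - lo) / bin_width + 1e-12))
    edges = lo + np.arange(n_bins + 1) * bin_width
    counts, edges = np.histogram(values, bins=edges)
    return counts, edges
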