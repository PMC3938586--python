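"""Dimensional stacking and clutter-based dimension reordering (CBDR).

A six-dimensional regular grid with L levels per axis is embedded in an
L^3 x L^3 image by nesting pairs of axes: two "low order" axes form a small
L x L tile, two "medium order" axes arrange L x L copies of that tile, and
two "high order" axes arrange the result again.  Pixel (row 0, column 0) —
by convention the bottom-left of the rendered image — holds the point with
every axis at its minimum level.

The stack order is optimised by exhaustively scoring all 720 assignments of
the six conductances to the six slots with a clutter objective: the sum of
absolute differences between horizontally and vertically adjacent pixels.
The minimum-clutter order places the axes with the smallest effect at low
order and those with the largest effect at high order, revealing structure
in the swept space.  Reversing every (x, y) pair transposes the image and
leaves the cost unchanged; the lexicographically smaller of the two
equivalent orders is reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core import CONDUCTANCES, ModelInputError
from .sweep import GridSpec, build_grid

__all__ = [
    "StackOrder",
    "StackImage",
    "stack_image",
    "clutter_cost",
    "optimize_order",
    "membership_stack",
]

ScaleTuple = tuple[float, ...]


@dataclass(frozen=True)
class StackOrder:
    """Assignment of the six conductances to (x, y) slots, low to high order.

    ``pairs[0]`` is the low-order (innermost) (x, y) pair, ``pairs[2]`` the
    high-order (outermost) pair; together they must name each conductance
    exactly once.
    """

    pairs: tuple[tuple[str, str], tuple[str, str], tuple[str, str]]

    def __post_init__(self) -> None:
        flat = [n for pair in self.pairs for n in pair]
        if sorted(flat) != sorted(CONDUCTANCES):
            raise ModelInputError(
                f"stack order must be a permutation of {CONDUCTANCES}, got {flat}"
            )

    @property
    def x_axes(self) -> tuple[str, str, str]:
        """(x_low, x_mid, x_high)."""
        return tuple(p[0] for p in self.pairs)

    @property
    def y_axes(self) -> tuple[str, str, str]:
        """(y_low, y_mid, y_high)."""
        return tuple(p[1] for p in self.pairs)

    def transposed(self) -> "StackOrder":
        """The equivalent order with every (x, y) pair reversed."""
        return StackOrder(pairs=tuple((y, x) for x, y in self.pairs))

    def flat(self) -> tuple[str, ...]:
        return tuple(n for pair in self.pairs for n in pair)

    def __str__(self) -> str:
        return "  ".join(f"({x},{y})" for x, y in self.pairs)

    @classmethod
    def unoptimised(cls) -> "StackOrder":
        """Canonical-axis-order stacking, used when stacks must be compared
        across biomarkers or cycle lengths without reordering."""
        return cls(pairs=((CONDUCTANCES[0], CONDUCTANCES[1]),
                          (CONDUCTANCES[2], CONDUCTANCES[3]),
                          (CONDUCTANCES[4], CONDUCTANCES[5])))


@dataclass
class StackImage:
    """L^3 x L^3 scalar field from dimensional stacking of a six-axis grid.

    ``data[row, col]`` with row 0 at the bottom of the rendered image;
    ``mask`` is True where no value was supplied (or the value was not
    finite).  ``order`` records the stacking used and ``label`` what the
    pixel values mean.
    """

    data: np.ndarray
    mask: np.ndarray
    order: StackOrder
    label: str = ""

    @property
    def side(self) -> int:
        return self.data.shape[0]


def _values_volume(
    values: dict[ScaleTuple, float], grid: GridSpec
) -> tuple[np.ndarray, np.ndarray, int]:
    sizes = grid.axis_sizes()
    if len(set(sizes)) != 1:
        raise ModelInputError(
            "dimensional stacking requires the same level count on every axis"
        )
    level = sizes[0]
    index_of = [
        {lvl: i for i, lvl in enumerate(grid.levels[name])} for name in CONDUCTANCES
    ]
    vol = np.full(sizes, np.nan)
    for tup, value in values.items():
        try:
            idx = tuple(index_of[ax][tup[ax]] for ax in range(6))
        except KeyError as exc:
            raise ModelInputError(f"scale tuple {tup} is not a grid point") from exc
        vol[idx] = value
    mask = ~np.isfinite(vol)
    return vol, mask, level


def _stack_from_volume(vol: np.ndarray, order: StackOrder, level: int) -> np.ndarray:
    # axis positions in the canonical volume
    pos = {name: i for i, name in enumerate(CONDUCTANCES)}
    x_low, x_mid, x_high = order.x_axes
    y_low, y_mid, y_high = order.y_axes
    # row-major reshape of [y_high, y_mid, y_low, x_high, x_mid, x_low] gives
    # row = i(y_high)*L^2 + i(y_mid)*L + i(y_low), col likewise from x slots
    perm = (pos[y_high], pos[y_mid], pos[y_low], pos[x_high], pos[x_mid], pos[x_low])
    return vol.transpose(perm).reshape(level**3, level**3)


def stack_image(
    values: dict[ScaleTuple, float],
    grid: GridSpec,
    order: StackOrder,
    label: str = "",
) -> StackImage:
    """Dimensionally stack per-grid-point scalars into an L^3 x L^3 image.

    Column index = i(x_high)*L^2 + i(x_mid)*L + i(x_low) and likewise for
    rows, with row 0 at the bottom: the all-minimum point maps to the
    bottom-left pixel.  Grid points absent from ``values`` are masked.
    """
    vol, _, level = _values_volume(values, grid)
    data = _stack_from_volume(vol, order, level)
    return StackImage(data=data, mask=~np.isfinite(data), order=order, label=label)


def clutter_cost(img: StackImage) -> float:
    """Sum of |difference| over horizontally and vertically adjacent pixels.

    Each unordered adjacent pair is counted once; any pair touching a masked
    pixel contributes 0.
    """
    d = np.where(img.mask, np.nan, img.data)
    horiz = np.abs(d[:, 1:] - d[:, :-1])
    vert = np.abs(d[1:, :] - d[:-1, :])
    return float(np.nansum(horiz) + np.nansum(vert))


def _all_orders() -> list[StackOrder]:
    orders = []
    for perm in itertools.permutations(CONDUCTANCES):
        orders.append(
            StackOrder(pairs=((perm[0], perm[1]), (perm[2], perm[3]), (perm[4], perm[5])))
        )
    return orders


def optimize_order(
    values: dict[ScaleTuple, float], grid: GridSpec
) -> tuple[StackOrder, float]:
    """Exhaustive minimum-clutter search over all 720 slot assignments.

    Ties are broken by the lexicographically smallest flattened name tuple;
    of the two transpose-equivalent representations of each solution the
    lexicographically smaller is returned.
    """
    vol, _, level = _values_volume(values, grid)
    best: tuple[float, tuple[str, ...], StackOrder] | None = None
    for order in _all_orders():
        # transpose-equivalent orders have identical cost; score the
        # lexicographically smaller representative only
        if order.flat() > order.transposed().flat():
            continue
        data = _stack_from_volume(vol, order, level)
        cost = clutter_cost(StackImage(data=data, mask=~np.isfinite(data), order=order))
        key = (cost, order.flat())
        if best is None or key < (best[0], best[1]):
            best = (cost, order.flat(), order)
    assert best is not None
    return best[2], best[0]


def membership_stack(
    passing: dict[int, set[ScaleTuple]],
    grid: GridSpec,
    order: StackOrder | None = None,
) -> tuple[StackImage, dict[int, tuple[int, ...]]]:
    """Categorical stack of calibration membership across cycle lengths.

    Each pixel's integer code is a bitmask over the sorted cycle lengths
    (bit i set iff the point passed at the i-th CL); code 0 means the point
    passed nowhere and the full-bitmask code marks the intersection of all
    CLs.  Returns the image and a legend mapping code -> passing CL tuple.
    By default the unoptimised canonical order is used so membership stacks
    at different settings are directly comparable.
    """
    if order is None:
        order = StackOrder.unoptimised()
    cls_sorted = sorted(passing)
    codes: dict[ScaleTuple, float] = {}
    for s in build_grid(grid):
        tup = s.as_tuple()
        code = 0
        for i, cl in enumerate(cls_sorted):
            if tup in passing[cl]:
                code |= 1 << i
        codes[tup] = float(code)
    legend = {
        code: tuple(cl for i, cl in enumerate(cls_sorted) if code & (1 << i))
        for code in range(1 << len(cls_sorted))
    }
    img = stack_image(codes, grid, order, label="membership")
    return img, legend
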