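"""Independent brute-force re-implementations used as test oracles.

These deliberately share no code with the package: stacking is done with
per-pixel dictionary loops and the clutter objective by explicit pair
enumeration, so agreement with the package is a genuine cross-check.
"""

from itertools import permutations

AXES = ("to", "Kr", "Ks", "K1", "CaL", "NaK")


def brute_force_stack(values_by_index, level, x_axes, y_axes):
    """Pixel dict {(row, col): value} from per-axis-index values.

    ``values_by_index`` maps a 6-tuple of level indices (in canonical axis
    order) to a scalar.  ``x_axes``/``y_axes`` are (low, mid, high) axis
    names.
    """
    axis_pos = {name: i for i, name in enumerate(AXES)}
    pixels = {}
    for idx, value in values_by_index.items():
        col = (
            idx[axis_pos[x_axes[2]]] * level * level
            + idx[axis_pos[x_axes[1]]] * level
            + idx[axis_pos[x_axes[0]]]
        )
        row = (
            idx[axis_pos[y_axes[2]]] * level * level
            + idx[axis_pos[y_axes[1]]] * level
            + idx[axis_pos[y_axes[0]]]
        )
        pixels[(row, col)] = value
    return pixels


def brute_force_cost(pixels, side):
    """Sum of |difference| over adjacent pixel pairs, each counted once."""
    total = 0.0
    for row in range(side):
        for col in range(side):
            if (row, col) not in pixels:
                continue
            v = pixels[(row, col)]
            if (row, col + 1) in pixels:
                total += abs(v - pixels[(row, col + 1)])
            if (row + 1, col) in pixels:
                total += abs(v - pixels[(row + 1, col)])
    return total


def brute_force_optimum(values_by_index, level):
    """(min cost, flat slot tuple) over all 720 slot assignments."""
    best_cost = None
    best_flat = None
    for perm in permutations(AXES):
        x_axes = (perm[0], perm[2], perm[4])
        y_axes = (perm[1], perm[3], perm[5])
        pixels = brute_force_stack(values_by_index, level, x_axes, y_axes)
        cost = brute_force_cost(pixels, level**3)
        flat = perm
        if (
            best_cost is None
            or cost < best_cost
            or (cost == best_cost and flat < best_flat)
        ):
            best_cost, best_flat = cost, flat
    return best_cost, best_flat
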