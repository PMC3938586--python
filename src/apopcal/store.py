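"""HDF5 persistence of sweep results and CSV/JSON reporting glue."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .biomarkers import BIOMARKER_COLUMNS
from .core import SCALE_COLUMNS
from .sweep import GridSpec, SweepStore

__all__ = [
    "FORMAT_VERSION",
    "StoreFormatError",
    "save_store",
    "load_store",
    "export_biomarker_csv",
    "report",
]

FORMAT_VERSION = 1


class StoreFormatError(RuntimeError):
    """The on-disk store was written by an incompatible format version."""


def save_store(store: SweepStore, path: str | Path) -> None:
    """Write a sweep store to HDF5: one group per cycle length.

    Datasets per group: ``scales`` (N x 6), ``biomarkers`` (N x 11),
    ``steady`` and ``degenerate`` flags, and optionally the final-beat
    ``vm`` / ``cai`` trace matrices.
    """
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["grid"] = json.dumps(store.grid.to_dict())
        f.attrs["cls"] = list(store.cls)
        f.attrs["dt"] = store.dt
        for cl in store.cls:
            g = f.create_group(f"cl_{cl}")
            table = store.tables[cl]
            g.create_dataset("scales", data=table[list(SCALE_COLUMNS)].to_numpy())
            g.create_dataset(
                "biomarkers", data=table[list(BIOMARKER_COLUMNS)].to_numpy()
            )
            g.create_dataset("steady", data=table["steady"].to_numpy(dtype=bool))
            g.create_dataset(
                "degenerate", data=table["degenerate"].to_numpy(dtype=bool)
            )
            if cl in store.traces:
                g.create_dataset("vm", data=store.traces[cl]["vm"])
                g.create_dataset("cai", data=store.traces[cl]["cai"])


def load_store(path: str | Path) -> SweepStore:
    """Read a sweep store written by :func:`save_store`."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise StoreFormatError(
                f"store format version {version} != supported {FORMAT_VERSION}"
            )
        grid = GridSpec.from_dict(json.loads(f.attrs["grid"]))
        cls = tuple(int(c) for c in f.attrs["cls"])
        dt = float(f.attrs["dt"])
        tables: dict[int, pd.DataFrame] = {}
        traces: dict[int, dict[str, np.ndarray]] = {}
        for cl in cls:
            g = f[f"cl_{cl}"]
            table = pd.DataFrame(
                np.hstack([g["scales"][...], g["biomarkers"][...]]),
                columns=list(SCALE_COLUMNS) + list(BIOMARKER_COLUMNS),
            )
            table["steady"] = g["steady"][...].astype(bool)
            table["degenerate"] = g["degenerate"][...].astype(bool)
            tables[cl] = table
            if "vm" in g:
                traces[cl] = {"vm": g["vm"][...], "cai": g["cai"][...]}
    return SweepStore(grid=grid, cls=cls, dt=dt, tables=tables, traces=traces)


def export_biomarker_csv(store: SweepStore, path: str | Path) -> None:
    """Flat CSV of all biomarker tables with a leading cycle-length column."""
    frames = []
    for cl in store.cls:
        table = store.tables[cl].copy()
        table.insert(0, "cl", cl)
        frames.append(table)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def report(
    calib_sets: dict[int, set],
    intersections: dict[tuple[int, ...], set],
    grid_size: int,
    fitrank: pd.DataFrame | None = None,
    stack_orders: dict[str, str] | None = None,
) -> dict:
    """JSON-able summary of a calibration run.

    Mirrors the published layout: per-CL passing counts and every
    CL-combination intersection count, plus (optionally) the
    biomarker-combination overlap table and optimal stack orders.
    """
    out: dict = {
        "grid_size": int(grid_size),
        "counts": {str(cl): len(calib_sets[cl]) for cl in sorted(calib_sets)},
        "intersections": {
            "+".join(str(c) for c in combo): len(members)
            for combo, members in sorted(intersections.items())
        },
    }
    if fitrank is not None:
        out["biomarker_overlap"] = fitrank.to_dict(orient="records")
    if stack_orders:
        out["stack_orders"] = dict(stack_orders)
    return out
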