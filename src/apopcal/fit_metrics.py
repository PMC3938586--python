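"""Waveform goodness-of-fit (NRMSD) and biomarker-combination ranking.

The gold-standard comparison between a population member and the reference
(control) model output is the normalised root-mean-square deviation

    NRMSD = sqrt( (1/N) * sum_j (M_cand(j) - M_ref(j))^2 ) / (M_max - M_min)

where M_max/M_min are the reference signal's extrema.  Normalisation by the
reference range makes the voltage and calcium deviations dimensionless and
directly comparable, so members can be ranked by V_NRMSD + Ca_NRMSD.

Because full-waveform comparison is expensive (and ill-suited to noisy
experimental data), cheap surrogates built from biomarker combinations are
scored by how well they reproduce the NRMSD-selected set: for each
combination the acceptable percentage difference is increased until as close
as possible to a target number of members (~250) match, and the percentage
overlap with the NRMSD-selected members of the same size is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ModelInputError, SCALE_COLUMNS

__all__ = [
    "SelectionResult",
    "nrmsd",
    "combined_nrmsd_scores",
    "select_by_nrmsd",
    "select_by_biomarkers",
    "percent_overlap",
    "rank_combinations",
    "DEFAULT_COMBINATIONS",
]

ScaleTuple = tuple[float, ...]

#: Biomarker combinations scored by default: every non-empty subset of the
#: three headline biomarkers plus the remaining single biomarkers.
DEFAULT_COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("apd50",),
    ("apd90",),
    ("cat_amp",),
    ("apd50", "apd90"),
    ("apd50", "cat_amp"),
    ("apd90", "cat_amp"),
    ("apd50", "apd90", "cat_amp"),
    ("dvdt_max",),
    ("v_rest",),
    ("v_plat",),
    ("ctd50",),
    ("ctd90",),
)


@dataclass
class SelectionResult:
    """A selected subset of parameter sets with the threshold that chose it."""

    selected: set[ScaleTuple]
    threshold: float  # percentage difference, or the NRMSD cutoff score
    count: int


def nrmsd(
    reference: np.ndarray,
    candidate: np.ndarray,
    m_max: float | None = None,
    m_min: float | None = None,
) -> float:
    """Root-mean-square deviation normalised by the reference signal's range.

    Zero iff the traces are identical; invariant under a common offset and
    under common rescaling of both traces together with the extrema.
    """
    reference = np.asarray(reference, dtype=float)
    candidate = np.asarray(candidate, dtype=float)
    if reference.shape != candidate.shape:
        raise ModelInputError("reference and candidate traces differ in length")
    if m_max is None:
        m_max = float(reference.max())
    if m_min is None:
        m_min = float(reference.min())
    if m_max <= m_min:
        raise ModelInputError("reference range is degenerate (M_max <= M_min)")
    rms = float(np.sqrt(np.mean((candidate - reference) ** 2)))
    return rms / (m_max - m_min)


def combined_nrmsd_scores(
    vm: np.ndarray,
    cai: np.ndarray,
    ref_vm: np.ndarray,
    ref_cai: np.ndarray,
) -> np.ndarray:
    """V_NRMSD + Ca_NRMSD for each row of the (N x T) population trace arrays."""
    vm = np.atleast_2d(np.asarray(vm, dtype=float))
    cai = np.atleast_2d(np.asarray(cai, dtype=float))
    if vm.shape[1] != ref_vm.size or cai.shape[1] != ref_cai.size:
        raise ModelInputError("population and reference traces differ in length")
    v_range = float(ref_vm.max() - ref_vm.min())
    c_range = float(ref_cai.max() - ref_cai.min())
    if v_range <= 0 or c_range <= 0:
        raise ModelInputError("reference range is degenerate (M_max <= M_min)")
    v_score = np.sqrt(np.mean((vm - ref_vm[None, :]) ** 2, axis=1)) / v_range
    c_score = np.sqrt(np.mean((cai - ref_cai[None, :]) ** 2, axis=1)) / c_range
    return v_score + c_score


def select_by_nrmsd(
    scale_tuples: list[ScaleTuple],
    scores: np.ndarray,
    target_count: int = 250,
) -> SelectionResult:
    """The ``target_count`` members with the smallest combined NRMSD.

    Ties at the cutoff are broken by canonical scale-tuple order.  Members
    with NaN scores (degenerate beats) are never selected.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scale_tuples) != scores.size:
        raise ModelInputError("scores and scale tuples differ in length")
    order = sorted(
        (i for i in range(scores.size) if np.isfinite(scores[i])),
        key=lambda i: (scores[i], scale_tuples[i]),
    )
    take = order[: min(target_count, len(order))]
    selected = {scale_tuples[i] for i in take}
    cutoff = float(scores[take[-1]]) if take else float("nan")
    return SelectionResult(selected=selected, threshold=cutoff, count=len(selected))


def select_by_biomarkers(
    records: pd.DataFrame,
    reference: dict[str, float] | pd.Series,
    combination: tuple[str, ...],
    target_count: int = 250,
    theta_step: float = 0.1,
    theta_max: float = 100.0,
) -> SelectionResult:
    """Select members whose biomarkers all lie within a percentage band.

    A record matches at threshold theta iff for every biomarker b in the
    combination ``|x_b - ref_b| / |ref_b| <= theta / 100``.  theta is swept
    from 0 in steps of ``theta_step`` percentage points; the returned theta
    minimises ``|match count - target_count]`` with ties resolved toward the
    smaller (stricter) theta.
    """
    if not combination:
        raise ModelInputError("biomarker combination must be non-empty")
    for b in combination:
        ref_b = float(reference[b])
        if ref_b == 0 or not np.isfinite(ref_b):
            raise ModelInputError(
                f"reference biomarker {b!r} is zero or undefined; "
                "relative differences are not defined"
            )
    rel = np.stack(
        [
            np.abs(records[b].to_numpy(dtype=float) - float(reference[b]))
            / abs(float(reference[b]))
            for b in combination
        ]
    )
    worst = np.max(rel, axis=0) * 100.0  # percentage points
    worst = np.where(np.isfinite(worst), worst, np.inf)
    thetas = np.arange(0.0, theta_max + theta_step / 2, theta_step)
    counts = np.searchsorted(np.sort(worst), thetas, side="right")
    best = int(np.argmin(np.abs(counts - target_count)))  # first best: smaller theta
    theta = float(thetas[best])
    mask = worst <= theta
    scales = records.loc[mask, list(SCALE_COLUMNS)].to_numpy()
    selected = {tuple(row) for row in scales}
    return SelectionResult(selected=selected, threshold=theta, count=int(mask.sum()))


def percent_overlap(
    a: SelectionResult | set,
    b: SelectionResult | set,
    denominator: str = "b",
) -> float:
    """Percentage overlap between two selections.

    The default denominator is the size of ``b`` — by convention the
    NRMSD-selected (gold standard) set.  Alternatives: "a", "union", "mean".
    """
    set_a = a.selected if isinstance(a, SelectionResult) else set(a)
    set_b = b.selected if isinstance(b, SelectionResult) else set(b)
    inter = len(set_a & set_b)
    if denominator == "b":
        denom = len(set_b)
    elif denominator == "a":
        denom = len(set_a)
    elif denominator == "union":
        denom = len(set_a | set_b)
    elif denominator == "mean":
        denom = (len(set_a) + len(set_b)) / 2
    else:
        raise ModelInputError(f"unknown overlap denominator {denominator!r}")
    if denom == 0:
        return 0.0
    return 100.0 * inter / denom


def rank_combinations(
    records: pd.DataFrame,
    reference: dict[str, float] | pd.Series,
    nrmsd_selection: SelectionResult,
    combinations: tuple[tuple[str, ...], ...] = DEFAULT_COMBINATIONS,
    target_count: int = 250,
    theta_step: float = 0.1,
    denominator: str = "b",
) -> pd.DataFrame:
    """Score each biomarker combination by overlap with the NRMSD selection.

    Returns a DataFrame (combination, threshold_pct, n_selected, overlap_pct)
    sorted by descending overlap, ties by combination name.
    """
    rows = []
    for combo in combinations:
        sel = select_by_biomarkers(
            records, reference, combo, target_count=target_count, theta_step=theta_step
        )
        rows.append(
            {
                "combination": "+".join(combo),
                "threshold_pct": sel.threshold,
                "n_selected": sel.count,
                "overlap_pct": percent_overlap(sel, nrmsd_selection, denominator),
            }
        )
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["overlap_pct", "combination"], ascending=[False, True], ignore_index=True
    )
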