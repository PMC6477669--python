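"""Threshold-based surrogate composition selection by curve correlation.

Candidate force–strain curves are compared against reference (group-average)
curves: both are linearly resampled onto a common grid over the shared
strain span (21 points by default), an R² is computed with the reference as
the "observed" series, and a composition is admitted for a group when its
R² meets the selection threshold (0.8 by default).  The best candidate per
group is the R² argmax, with lexicographic label tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import r_squared

__all__ = [
    "LabeledCurve",
    "SelectionReport",
    "resample_common_grid",
    "correlate_curves",
    "select_surrogates",
    "admit_by_threshold",
]

SELECTION_THRESHOLD = 0.8
DEFAULT_N_GRID = 21


@dataclass(frozen=True)
class LabeledCurve:
    """A labeled force–strain curve (strain as compressive magnitude)."""

    label: str
    strain: np.ndarray
    force: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.strain, dtype=float)
        f = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "strain", s)
        object.__setattr__(self, "force", f)
        if len(s) != len(f):
            raise ValueError("strain and force arrays differ in length")
        if np.any(np.diff(s) <= 0):
            raise ValueError("strain must be strictly increasing")


@dataclass(frozen=True)
class SelectionReport:
    """Correlation table plus per-group admitted sets and best candidates.

    ``scores``: group → {candidate label → R²};
    ``admitted``: group → sorted list of labels with R² ≥ threshold;
    ``best``: group → argmax label; ``ties``: group → True when the argmax
    was shared and broken lexicographically.
    """

    scores: dict[str, dict[str, float]]
    admitted: dict[str, list[str]]
    best: dict[str, str]
    ties: dict[str, bool]
    threshold: float


def resample_common_grid(curve: LabeledCurve, grid) -> LabeledCurve:
    """Linearly interpolate a curve onto a strain grid inside its span."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = curve.strain[0], curve.strain[-1]
    if grid.min() < lo - 1e-12 or grid.max() > hi + 1e-12:
        raise ValueError(
            f"grid [{grid.min():g}, {grid.max():g}] outside curve span "
            f"[{lo:g}, {hi:g}]; extrapolation not performed"
        )
    return LabeledCurve(
        label=curve.label,
        strain=grid,
        force=np.interp(grid, curve.strain, curve.force),
    )


def shared_grid(a: LabeledCurve, b: LabeledCurve, n_grid: int = DEFAULT_N_GRID):
    """Evenly spaced grid over the two curves' shared strain span."""
    lo = max(a.strain[0], b.strain[0])
    hi = min(a.strain[-1], b.strain[-1])
    if hi <= lo:
        raise ValueError(
            f"curves {a.label!r} and {b.label!r} have no overlapping strain span"
        )
    return np.linspace(lo, hi, n_grid)


def correlate_curves(
    candidate: LabeledCurve, reference: LabeledCurve, n_grid: int = DEFAULT_N_GRID
) -> float:
    """R² of a candidate against a reference on their shared-span grid.

    The reference plays "observed" in the R² (its variance normalizes the
    residuals).
    """
    grid = shared_grid(candidate, reference, n_grid)
    cand = resample_common_grid(candidate, grid)
    ref = resample_common_grid(reference, grid)
    return r_squared(ref.force, cand.force)


def admit_by_threshold(
    scores: dict[str, float], threshold: float = SELECTION_THRESHOLD
) -> tuple[list[str], str, bool]:
    """Apply the selection rule to one group's score column.

    Returns (admitted labels sorted, best label, tie flag); admission is
    R² ≥ threshold, best is the argmax with lexicographic tie-break.
    """
    if not scores:
        raise ValueError("empty score column")
    admitted = sorted(label for label, r2 in scores.items() if r2 >= threshold)
    best_r2 = max(scores.values())
    top = sorted(label for label, r2 in scores.items() if r2 == best_r2)
    return admitted, top[0], len(top) > 1


def select_surrogates(
    candidates: list[LabeledCurve],
    references: dict[str, LabeledCurve],
    threshold: float = SELECTION_THRESHOLD,
    n_grid: int = DEFAULT_N_GRID,
) -> SelectionReport:
    """Correlate every candidate against every reference group and select."""
    if not candidates or not references:
        raise ValueError("need at least one candidate and one reference")
    scores: dict[str, dict[str, float]] = {}
    admitted: dict[str, list[str]] = {}
    best: dict[str, str] = {}
    ties: dict[str, bool] = {}
    for group, ref in references.items():
        col = {
            cand.label: correlate_curves(cand, ref, n_grid) for cand in candidates
        }
        scores[group] = col
        admitted[group], best[group], ties[group] = admit_by_threshold(col, threshold)
    return SelectionReport(
        scores=scores, admitted=admitted, best=best, ties=ties, threshold=threshold
    )
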