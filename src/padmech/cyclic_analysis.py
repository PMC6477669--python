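"""Cyclic load–unload segmentation, hysteresis energy dissipation, repeatability.

The energy dissipation ratio (EDR) of one hysteresis loop is the area
enclosed by the loop divided by the area under its loading branch, both
integrated over displacement (N·mm) by the trapezoid rule:

    EDR = (A_load − A_unload) / A_load.

Repeatability follows the ±10 %-of-maximum-load rule: a cycle train passes
when every cycle's peak force deviates from the mean peak force by no more
than the tolerance times the overall maximum peak force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core_mechanics import CompressionRecord

__all__ = [
    "HysteresisLoop",
    "EDRResult",
    "RepeatabilityResult",
    "segment_cycles",
    "energy_dissipation_ratio",
    "repeatability_check",
]

#: Minimum peak prominence as a fraction of max displacement (noise guard).
PEAK_PROMINENCE_FRACTION = 0.01

#: EDR values this far outside [0, 1] are treated as numerical noise and
#: clipped; anything farther out raises.
EDR_NOISE_TOLERANCE = 1e-9


@dataclass(frozen=True)
class HysteresisLoop:
    """One loading branch plus (optionally) its unloading branch.

    Branch arrays are (displacement mm, force N); loading displacement is
    nondecreasing, unloading nonincreasing.  A loading-only loop (monotone
    ramp with no unloading) carries empty unloading arrays and
    ``loading_only=True``.
    """

    loading_displacement: np.ndarray
    loading_force: np.ndarray
    unloading_displacement: np.ndarray
    unloading_force: np.ndarray
    cycle_index: int = 0
    loading_only: bool = False

    def __post_init__(self) -> None:
        for name in (
            "loading_displacement",
            "loading_force",
            "unloading_displacement",
            "unloading_force",
        ):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.loading_displacement) != len(self.loading_force):
            raise ValueError("loading branch arrays differ in length")
        if len(self.unloading_displacement) != len(self.unloading_force):
            raise ValueError("unloading branch arrays differ in length")
        if np.any(np.diff(self.loading_displacement) < 0):
            raise ValueError("loading displacement must be nondecreasing")
        if len(self.unloading_displacement) and np.any(
            np.diff(self.unloading_displacement) > 0
        ):
            raise ValueError("unloading displacement must be nonincreasing")

    @property
    def peak_force(self) -> float:
        forces = [self.loading_force.max()]
        if len(self.unloading_force):
            forces.append(self.unloading_force.max())
        return float(max(forces))


@dataclass(frozen=True)
class EDRResult:
    """Energy dissipation ratio with its constituent areas (N·mm)."""

    edr: float
    loading_area: float
    hysteresis_area: float


@dataclass(frozen=True)
class RepeatabilityResult:
    """Per-cycle peak-force deviations and the pass/fail verdict.

    Deviations are peak minus mean-of-peaks; two normalizations are
    reported: as a fraction of the overall maximum load (the convention the
    verdict uses) and as a fraction of the mean peak.
    """

    passed: bool
    tolerance: float
    peak_forces: np.ndarray
    deviations: np.ndarray
    deviations_frac_of_max: np.ndarray
    deviations_frac_of_mean: np.ndarray


def segment_cycles(record: CompressionRecord) -> list[HysteresisLoop]:
    """Split a multi-cycle record into hysteresis loops at displacement peaks.

    Each loop runs trough → peak (loading) and peak → next trough
    (unloading).  A strictly monotone nondecreasing displacement history
    yields a single loading-only loop.  Peaks need a prominence of at least
    1 % of the maximum displacement, so small sensor wiggles do not split
    cycles.
    """
    d = record.displacement
    if len(d) == 0 or np.ptp(d) == 0:
        raise ValueError("record has no displacement excursion to segment")

    prominence = PEAK_PROMINENCE_FRACTION * float(np.max(d))
    peaks, _ = find_peaks(d, prominence=prominence)

    if len(peaks) == 0:
        if np.all(np.diff(d) >= 0):
            return [
                HysteresisLoop(
                    loading_displacement=d,
                    loading_force=record.force,
                    unloading_displacement=np.empty(0),
                    unloading_force=np.empty(0),
                    cycle_index=0,
                    loading_only=True,
                )
            ]
        # ends on the global maximum: treat the final sample as the peak
        peaks = np.array([len(d) - 1])

    loops: list[HysteresisLoop] = []
    troughs = _troughs_between(d, peaks)
    for k, p in enumerate(peaks):
        lo, hi = troughs[k], troughs[k + 1]
        loading = slice(lo, p + 1)
        unloading = slice(p, hi + 1)
        loops.append(
            HysteresisLoop(
                loading_displacement=d[loading],
                loading_force=record.force[loading],
                unloading_displacement=d[unloading] if hi > p else np.empty(0),
                unloading_force=record.force[unloading] if hi > p else np.empty(0),
                cycle_index=k,
                loading_only=hi <= p,
            )
        )
    return loops


def _troughs_between(d: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Boundary indices: start, argmin between consecutive peaks, end."""
    bounds = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(a + int(np.argmin(d[a : b + 1])))
    bounds.append(len(d) - 1)
    return np.asarray(bounds)


def energy_dissipation_ratio(loop: HysteresisLoop) -> EDRResult:
    """EDR of one loop: hysteresis area over loading area (trapezoid rule)."""
    if loop.loading_only or len(loop.unloading_displacement) == 0:
        raise ValueError("loop has no unloading branch; EDR undefined")
    a_load = float(
        np.trapezoid(loop.loading_force, loop.loading_displacement)
    )
    if a_load <= 0:
        raise ValueError(f"loading area must be > 0, got {a_load:g}")
    # unloading branch descends; integrate over increasing displacement
    a_unload = float(
        np.trapezoid(loop.unloading_force[::-1], loop.unloading_displacement[::-1])
    )
    hyst = a_load - a_unload
    edr = hyst / a_load
    if edr < -EDR_NOISE_TOLERANCE or edr > 1.0 + EDR_NOISE_TOLERANCE:
        raise ValueError(
            f"EDR {edr!r} outside [0, 1] beyond noise tolerance; "
            "check branch segmentation"
        )
    edr = min(max(edr, 0.0), 1.0)
    return EDRResult(edr=edr, loading_area=a_load, hysteresis_area=hyst)


def repeatability_check(
    loops: list[HysteresisLoop], tolerance: float = 0.10
) -> RepeatabilityResult:
    """±tolerance-of-maximum-load repeatability verdict over cycle peaks.

    The verdict compares the maximum peak-to-peak variation of the cycle
    peak forces against ``tolerance`` times the overall maximum load; the
    per-cycle deviations (from the mean peak) are reported under both
    normalizations for inspection.
    """
    if len(loops) < 2:
        raise ValueError(f"repeatability needs at least 2 loops, got {len(loops)}")
    peaks = np.array([lp.peak_force for lp in loops])
    mean = peaks.mean()
    overall_max = peaks.max()
    dev = peaks - mean
    frac_max = dev / overall_max if overall_max > 0 else np.zeros_like(dev)
    frac_mean = dev / mean if mean > 0 else np.zeros_like(dev)
    passed = bool(np.ptp(peaks) <= tolerance * overall_max)
    return RepeatabilityResult(
        passed=passed,
        tolerance=tolerance,
        peak_forces=peaks,
        deviations=dev,
        deviations_frac_of_max=frac_max,
        deviations_frac_of_mean=frac_mean,
    )
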