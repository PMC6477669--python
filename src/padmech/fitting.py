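"""Least-squares identification of Yeoh parameters from stress–stretch data.

The identification mirrors a spreadsheet-solver workflow: evaluate the
model stress at every measured stretch, square the residuals against the
measured stresses, and minimize the sum.  Because the uniaxial Yeoh stress
is linear in (c1, c2, c3) the problem has a unique global least-squares
solution whenever the design is non-degenerate; the solver still runs a
derivative-based multi-start (the plant procedure specifies no
initialization) and keeps the best sum of squared residuals, tie-broken by
the smallest coefficient norm.

Goodness of fit is the coefficient of determination R² between measured and
predicted stresses; fits with R² above 0.95 are flagged as highly accurate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core_mechanics import StressStretchCurve
from .yeoh_model import YeohParameters

__all__ = ["FitResult", "fit_yeoh", "r_squared", "classify_fit"]

#: Default accuracy threshold on R² (strict inequality).
FIT_R2_THRESHOLD = 0.95

# Convergence tolerances for the trust-region solver.
_FTOL = 1e-14
_XTOL = 1e-14
_GTOL = 1e-14
_MAX_NFEV = 10_000


@dataclass(frozen=True)
class FitResult:
    """Outcome of one Yeoh parameter identification."""

    params: YeohParameters
    r_squared: float
    residual_sum_squares: float
    n_points: int
    converged: bool
    n_starts_used: int

    def __post_init__(self) -> None:
        if self.r_squared > 1.0 + 1e-12:
            raise ValueError(f"R² cannot exceed 1, got {self.r_squared}")
        if self.residual_sum_squares < 0:
            raise ValueError("residual sum of squares cannot be negative")
        if self.n_points < 4:
            raise ValueError("a valid fit requires at least 4 points")


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot.

    SS_tot is taken about the mean of ``observed``.  Can be negative for
    predictions worse than the observed mean; never exceeds 1.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"shape mismatch: {obs.shape} vs {pred.shape}")
    if obs.size < 2:
        raise ValueError("need at least 2 points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values are constant; R² undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _design_matrix(lam: np.ndarray) -> np.ndarray:
    # σ(λ; c) = J @ c with columns 2(λ²−1/λ)·{1, 2x, 3x²}, x = I1 − 3.
    x = lam**2 + 2.0 / lam - 3.0
    g = 2.0 * (lam**2 - 1.0 / lam)
    return np.column_stack([g, 2.0 * g * x, 3.0 * g * x**2])


def _default_starts(init: YeohParameters | None) -> list[np.ndarray]:
    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(init.as_array())
    starts.append(np.zeros(3))
    for m in np.logspace(-4, 0, 4):
        starts.append(np.full(3, m))
    return starts


def fit_yeoh(
    curve: StressStretchCurve,
    init: YeohParameters | None = None,
    bounds: tuple | None = None,
) -> FitResult:
    """Fit Yeoh coefficients to a signed stress–stretch curve.

    Parameters
    ----------
    curve : StressStretchCurve
        Measured curve in the signed convention (compression: λ<1, σ<0).
    init : YeohParameters, optional
        Extra starting point prepended to the default multi-start set.
    bounds : (lower, upper), optional
        Box bounds on (c1, c2, c3), e.g. ``((0, 0, 0), np.inf)`` for a
        non-negativity constraint.  Default unconstrained.

    Raises
    ------
    ValueError
        Fewer than 4 distinct stretch points, or a degenerate (constant
        stretch) curve.
    """
    lam = curve.stretch
    sig = curve.stress
    if len(np.unique(lam)) < 4:
        raise ValueError(
            f"need at least 4 distinct stretch points, got {len(np.unique(lam))}"
        )
    if np.ptp(lam) == 0:
        raise ValueError("all stretches identical; fit is degenerate")

    design = _design_matrix(lam)

    def residuals(c: np.ndarray) -> np.ndarray:
        return design @ c - sig

    def jac(c: np.ndarray) -> np.ndarray:
        return design

    lsq_bounds = (-np.inf, np.inf) if bounds is None else bounds
    best = None
    starts = _default_starts(init)
    for c0 in starts:
        res = least_squares(
            residuals,
            c0,
            jac=jac,
            bounds=lsq_bounds,
            method="trf",
            ftol=_FTOL,
            xtol=_XTOL,
            gtol=_GTOL,
            max_nfev=_MAX_NFEV,
        )
        ssr = float(2.0 * res.cost)
        cand = (ssr, float(np.linalg.norm(res.x)), res)
        if best is None or cand[:2] < best[:2]:
            best = cand

    ssr, _, res = best
    params = YeohParameters(*res.x, label=curve.label)
    predicted = design @ res.x
    return FitResult(
        params=params,
        r_squared=r_squared(sig, predicted),
        residual_sum_squares=ssr,
        n_points=len(lam),
        converged=bool(res.status > 0),
        n_starts_used=len(starts),
    )


def classify_fit(result: FitResult, threshold: float = FIT_R2_THRESHOLD) -> bool:
    """True when the fit is "highly accurate": R² strictly above threshold."""
    return result.r_squared > threshold
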