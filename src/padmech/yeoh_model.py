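"""Incompressible isotropic Yeoh hyperelastic model.

The strain energy is the standard cubic reduced polynomial in the first
Cauchy–Green invariant,

    ψ(I1) = c1·(I1 − 3) + c2·(I1 − 3)² + c3·(I1 − 3)³   [MPa],

and under uniaxial loading with incompressibility (λ2 = λ3 = λ^(−1/2), so
I1 = λ² + 2/λ) the stress–stretch relation is

    σ(λ) = 2·(λ² − 1/λ)·(c1 + 2·c2·(I1 − 3) + 3·c3·(I1 − 3)²),

which is λ·dψ/dλ, the uniaxial true (Cauchy) stress of this energy.  This
is the relation fitted to the surrogate test data, so both the forward
generator and the fitter use it.  With c2 = c3 = 0 it degenerates exactly to
the neo-Hookean σ = 2·c1·(λ² − 1/λ).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import math
import numpy as np
import pandas as pd

from .core_mechanics import DomainError

__all__ = [
    "YeohParameters",
    "PrincipalStretches",
    "invariants",
    "uniaxial_I1",
    "strain_energy",
    "uniaxial_stress",
    "load_reference_parameters",
]

#: Reject stretches at or below this to avoid the 1/λ singularity.
MIN_STRETCH = 1e-6


@dataclass(frozen=True)
class YeohParameters:
    """Yeoh coefficients (c1, c2, c3) in MPa.

    No sign constraint is imposed: the identification procedure is
    unconstrained by default, and nothing in the model requires positivity
    (although all tabulated surrogate values are positive).
    """

    c1: float
    c2: float
    c3: float
    label: str = ""
    rate_mm_per_s: float | None = None

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "c3"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3], dtype=float)


@dataclass(frozen=True)
class PrincipalStretches:
    """The three principal stretches of a homogeneous deformation."""

    lambda1: float
    lambda2: float
    lambda3: float

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3"):
            v = getattr(self, name)
            if not (v > 0):
                raise DomainError(f"{name} must be > 0, got {v}")

    @property
    def is_incompressible(self) -> bool:
        return abs(self.lambda1 * self.lambda2 * self.lambda3 - 1.0) < 1e-9


def invariants(stretches: PrincipalStretches) -> tuple[float, float, float]:
    """Cauchy–Green invariants (I1, I2, I3) from principal stretches.

    I1 = Σ λi², I3 = Π λi².  I2 is computed as the sum of λi²·λj² over
    *ordered* pairs i ≠ j (six terms, so I2 = 6 at the reference state);
    this convention is twice the classical symmetric-function I2 and is kept
    because nothing downstream (the uniaxial stress relation depends on I1
    only) consumes it.
    """
    lams = np.array([stretches.lambda1, stretches.lambda2, stretches.lambda3])
    sq = lams**2
    i1 = float(np.sum(sq))
    i2 = float(np.sum(np.outer(sq, sq)) - np.sum(sq**2))
    i3 = float(np.prod(sq))
    return i1, i2, i3


def _check_stretch(lam) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= MIN_STRETCH):
        raise DomainError(f"stretch must exceed {MIN_STRETCH:g}")
    return lam


def uniaxial_I1(lam):
    """First invariant under incompressible uniaxial loading: λ² + 2/λ."""
    lam = _check_stretch(lam)
    return lam**2 + 2.0 / lam


def strain_energy(lam, params: YeohParameters):
    """Strain energy density ψ(λ) in MPa; ψ(1) = 0."""
    x = uniaxial_I1(lam) - 3.0
    return params.c1 * x + params.c2 * x**2 + params.c3 * x**3


def uniaxial_stress(lam, params: YeohParameters):
    """Uniaxial stress σ(λ) in MPa (signed: compression λ<1 gives σ<0).

    Vectorized over λ; scalar in, scalar out.
    """
    lam = _check_stretch(lam)
    x = lam**2 + 2.0 / lam - 3.0
    sigma = 2.0 * (lam**2 - 1.0 / lam) * (
        params.c1 + 2.0 * params.c2 * x + 3.0 * params.c3 * x**2
    )
    if np.ndim(lam) == 0:
        return float(sigma)
    return sigma


def load_reference_parameters() -> dict[str, YeohParameters]:
    """Packaged per-rate Yeoh parameter sets for the surrogate compositions.

    Keys: ``control-1.96``, ``control-180``, ``control-1800`` (the healthy
    60-20-10-10 control surrogate at each displacement rate), ``plantar-pain``
    (55-20-15-10) and ``diabetes`` (45-20-20-15), both at 1.96 mm/s.  The
    diabetes row's published rate string reads "mm/min" where every sibling
    row reads "mm/s"; the verbatim label is preserved and the normalized
    ``rate_mm_per_s`` follows the sibling-row unit.
    """
    with resources.files("padmech.data").joinpath("yeoh_parameters.csv").open() as fh:
        df = pd.read_csv(fh)
    out: dict[str, YeohParameters] = {}
    for row in df.itertuples():
        out[row.key] = YeohParameters(
            c1=row.c1_MPa,
            c2=row.c2_MPa,
            c3=row.c3_MPa,
            label=row.label,
            rate_mm_per_s=row.rate_mm_per_s,
        )
    return out
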