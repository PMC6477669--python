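"""Domain types and machine-to-material coordinate conversion.

Units are fixed package-wide: millimetres, newtons, seconds — so stress in
N/mm² is numerically MPa with no conversion factor.

Sign convention: internal curves are *signed, tension-positive*.  A
compression test therefore produces stretches λ < 1 and stresses σ < 0;
:func:`magnitude_view` flips to the (compressive strain, |σ|) plane used for
reporting and plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "SpecimenGeometry",
    "CompressionRecord",
    "StressStretchCurve",
    "CompositionRecord",
    "to_stress_stretch",
    "from_stress_stretch",
    "magnitude_view",
    "load_compositions",
]


class DomainError(ValueError):
    """Raised when a quantity leaves its physically meaningful domain."""


@dataclass(frozen=True)
class SpecimenGeometry:
    """Cylindrical test-specimen geometry.

    Parameters
    ----------
    diameter : float
        Specimen diameter in mm.
    height : float
        Undeformed specimen height in mm.
    """

    diameter: float
    height: float

    def __post_init__(self) -> None:
        if not (self.diameter > 0):
            raise DomainError(f"diameter must be > 0, got {self.diameter}")
        if not (self.height > 0):
            raise DomainError(f"height must be > 0, got {self.height}")

    @property
    def cross_section_area(self) -> float:
        """Undeformed cross-sectional area in mm², π·d²/4."""
        return math.pi * self.diameter**2 / 4.0


#: Mold-chamber geometry used throughout: 40 mm diameter, 18 mm depth.
DEFAULT_GEOMETRY = SpecimenGeometry(diameter=40.0, height=18.0)


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class CompressionRecord:
    """One sampled (time, displacement, force) history from a compression test.

    Displacement is compression-positive (piston travel into the specimen,
    mm); force is the resisting load (N).  ``displacement_rate`` is the
    nominal piston speed and is metadata only.
    """

    time: np.ndarray
    displacement: np.ndarray
    force: np.ndarray
    displacement_rate: float
    geometry: SpecimenGeometry
    label: str = ""

    def __post_init__(self) -> None:
        t = _as_float_array(self.time, "time")
        d = _as_float_array(self.displacement, "displacement")
        f = _as_float_array(self.force, "force")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "force", f)
        n = len(t)
        if not (len(d) == len(f) == n):
            raise ValueError(
                f"array length mismatch: time={n}, displacement={len(d)}, force={len(f)}"
            )
        if n < 2:
            raise ValueError(f"record needs at least 2 samples, got {n}")
        if np.any(np.diff(t) < 0):
            raise ValueError("time must be monotone nondecreasing")
        if np.any(d < 0):
            raise ValueError("displacement must be compression-positive (>= 0)")
        if np.max(d) > self.geometry.height:
            raise DomainError(
                f"max displacement {np.max(d):g} mm exceeds specimen height "
                f"{self.geometry.height:g} mm"
            )

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class StressStretchCurve:
    """Paired (λ, σ) samples in the signed convention (compression: λ<1, σ<0)."""

    stretch: np.ndarray
    stress: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        lam = _as_float_array(self.stretch, "stretch")
        sig = _as_float_array(self.stress, "stress")
        object.__setattr__(self, "stretch", lam)
        object.__setattr__(self, "stress", sig)
        if len(lam) != len(sig):
            raise ValueError(
                f"length mismatch: stretch={len(lam)}, stress={len(sig)}"
            )
        if np.any(lam <= 0):
            raise DomainError("stretch must be > 0")

    @property
    def strain(self) -> np.ndarray:
        """Signed engineering strain ε = λ − 1."""
        return self.stretch - 1.0

    def __len__(self) -> int:
        return len(self.stretch)


def to_stress_stretch(record: CompressionRecord) -> StressStretchCurve:
    """Convert a machine record to engineering stress–stretch coordinates.

    ε_i = −displacement_i / height, λ_i = 1 + ε_i, σ_i = −force_i / area.
    With mm/N units the stress is numerically in MPa.
    """
    area = record.geometry.cross_section_area
    if area <= 0:
        raise DomainError("specimen cross-section area must be > 0")
    strain = -record.displacement / record.geometry.height
    stretch = 1.0 + strain
    stress = -record.force / area
    return StressStretchCurve(stretch=stretch, stress=stress, label=record.label)


def from_stress_stretch(
    curve: StressStretchCurve, geometry: SpecimenGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`to_stress_stretch`: recover (displacement, force)."""
    displacement = -(curve.stretch - 1.0) * geometry.height
    force = -curve.stress * geometry.cross_section_area
    return displacement, force


def magnitude_view(curve: StressStretchCurve) -> tuple[np.ndarray, np.ndarray]:
    """Compression-branch curve as (compressive strain, |σ|) magnitude pairs.

    Raises
    ------
    DomainError
        If the curve contains tensile samples (λ > 1).
    """
    if np.any(curve.stretch > 1.0 + 1e-12):
        raise DomainError("magnitude_view supports compression branches only (λ ≤ 1)")
    return 1.0 - curve.stretch, np.abs(curve.stress)


@dataclass(frozen=True)
class CompositionRecord:
    """Four-part elastomer composition in weight percent.

    Order: Shore 00-10 part A, Shore 00-10 part B, Shore 30A part A,
    Shore 30A part B.  The conventional name is "A-B-C-D" with the fractions
    in that order (e.g. "60-20-10-10").
    """

    shore0010_part_a: float
    shore0010_part_b: float
    shore30a_part_a: float
    shore30a_part_b: float
    name: str = field(default="")

    def __post_init__(self) -> None:
        fracs = self.fractions
        if any(f <= 0 for f in fracs):
            raise ValueError(f"all weight fractions must be > 0, got {fracs}")
        total = sum(fracs)
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"weight fractions must sum to 100, got {total!r}")
        if not self.name:
            object.__setattr__(self, "name", "-".join(_fmt_frac(f) for f in fracs))

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        return (
            self.shore0010_part_a,
            self.shore0010_part_b,
            self.shore30a_part_a,
            self.shore30a_part_b,
        )


def _fmt_frac(f: float) -> str:
    return f"{f:g}"


def load_compositions() -> list[CompositionRecord]:
    """Load the packaged table of the 15 tested elastomer compositions."""
    with resources.files("padmech.data").joinpath("compositions.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        CompositionRecord(
            shore0010_part_a=row.shore0010_part_a,
            shore0010_part_b=row.shore0010_part_b,
            shore30a_part_a=row.shore30a_part_a,
            shore30a_part_b=row.shore30a_part_b,
        )
        for row in df.itertuples()
    ]
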